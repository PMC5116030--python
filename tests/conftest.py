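import numpy as np
import pytest

from mbrdme import build_ball_mesh, build_interval_mesh, make_rng


@pytest.fixture
def rng():
    return make_rng(1234)


@pytest.fixture(scope="session")
def unit_ball_res2():
    return build_ball_mesh(1.0, 2)


@pytest.fixture
def interval20():
    return build_interval_mesh(0.0, 1.0, 20)


@pytest.fixture(scope="session")
def example1_sweep():
    """Shared 1D moving-boundary convergence sweep (mesoscale vs BD oracle).

    v = 0.5 over the full τ_split ladder for the convergence-trend property,
    v = 0.05 at the ladder endpoints for the noise-dominated regime.
    Computed once per session; used by several convergence tests.
    """
    from mbrdme.analysis import ConvergenceGrid, convergence_study

    fast = convergence_study(
        ConvergenceGrid(dt_splits=(0.2, 0.1, 0.05, 0.01), velocities=(0.5,),
                        replicates=20, seed=2026)
    )
    slow = convergence_study(
        ConvergenceGrid(dt_splits=(0.2, 0.01), velocities=(0.05,),
                        replicates=20, seed=2026)
    )
    import pandas as pd

    return pd.concat([fast, slow], ignore_index=True)
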