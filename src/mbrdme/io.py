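"""Text-format I/O: Gmsh MSH (ASCII v2) meshes, legacy VTK snapshots,
YAML model definitions, and delimited trajectory tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .mesh import BOUNDARY, INTERIOR, Mesh, _recompute_geometry, build_ball_mesh, build_interval_mesh
from .nsm import InvalidModelError, Reaction, ReactionNetwork, Species, SystemState


# ---------------------------------------------------------------------------
# Gmsh MSH ASCII v2 (tetrahedral meshes)


def write_msh(mesh: Mesh, path) -> None:
    """Write a 3D mesh as Gmsh MSH ASCII v2 (tetrahedra + boundary triangles)."""
    if mesh.dimension != 3:
        raise ValueError("MSH export supports 3D meshes")
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_vertices)]
    for i, p in enumerate(mesh.vertex_coords, start=1):
        lines.append(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}")
    lines += ["$EndNodes", "$Elements"]
    tris = mesh.boundary_facets if mesh.boundary_facets is not None else np.zeros((0, 3), int)
    lines.append(str(len(mesh.cells) + len(tris)))
    eid = 1
    for tri in tris:  # physical tag 2 marks the boundary surface
        lines.append(f"{eid} 2 2 2 2 " + " ".join(str(v + 1) for v in tri))
        eid += 1
    for tet in mesh.cells:  # physical tag 1 marks the volume
        lines.append(f"{eid} 4 2 1 1 " + " ".join(str(v + 1) for v in tet))
        eid += 1
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")


def read_msh(path) -> Mesh:
    """Read a tetrahedral Gmsh MSH ASCII v2 file.

    Boundary triangles present in the file are used as boundary facets;
    otherwise the boundary is recovered as the set of tet faces that occur
    exactly once.
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    verts = []
    tets = []
    tris = []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                verts.append([float(parts[1]), float(parts[2]), float(parts[3])])
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                conn = [int(v) - 1 for v in parts[3 + ntags:]]
                if etype == 4:
                    tets.append(conn)
                elif etype == 2:
                    tris.append(conn)
    if not tets:
        raise ValueError(f"{path}: no tetrahedra found")
    verts = np.asarray(verts)
    cells = np.asarray(tets, dtype=np.int64)
    if np.any(cells < 0) or cells.max() >= len(verts):
        raise ValueError(f"{path}: cell references an invalid vertex index")
    if tris:
        facets = np.asarray(tris, dtype=np.int64)
    else:
        from collections import Counter

        counter = Counter()
        for tet in cells:
            for f in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
                counter[tuple(sorted(tet[list(f)]))] += 1
        facets = np.array([f for f, c in counter.items() if c == 1], dtype=np.int64)
    # fix inverted tets
    from .mesh import _tet_volumes

    vols = _tet_volumes(verts, cells)
    neg = vols < 0
    cells[neg, 1], cells[neg, 2] = cells[neg, 2].copy(), cells[neg, 1].copy()
    labels = np.full(len(verts), INTERIOR, dtype=object)
    labels[np.unique(facets)] = BOUNDARY
    mesh = Mesh(
        dimension=3, vertex_coords=verts, cells=cells,
        subdomain_labels=labels, boundary_facets=facets,
    )
    _recompute_geometry(mesh)
    return mesh


# ---------------------------------------------------------------------------
# legacy ASCII VTK snapshots


def write_vtk(mesh: Mesh, path, fields: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh and per-voxel scalar ``fields`` as legacy ASCII VTK.

    On 3D meshes voxels are vertices, so fields are POINT_DATA; on 1D meshes
    voxels are line cells, so fields are CELL_DATA.
    """
    fields = fields or {}
    lines = [
        "# vtk DataFile Version 3.0",
        "mbrdme snapshot",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_vertices} double",
    ]
    for p in mesh.vertex_coords:
        coords = list(p) + [0.0] * (3 - len(p))
        lines.append(" ".join(f"{c:.17g}" for c in coords))
    npc = mesh.cells.shape[1]
    lines.append(f"CELLS {len(mesh.cells)} {len(mesh.cells) * (npc + 1)}")
    for cell in mesh.cells:
        lines.append(f"{npc} " + " ".join(str(v) for v in cell))
    vtk_type = 3 if mesh.dimension == 1 else 10  # VTK_LINE / VTK_TETRA
    lines.append(f"CELL_TYPES {len(mesh.cells)}")
    lines += [str(vtk_type)] * len(mesh.cells)
    if fields:
        section = "CELL_DATA" if mesh.dimension == 1 else "POINT_DATA"
        lines.append(f"{section} {mesh.n_voxels}")
        for name, values in fields.items():
            values = np.asarray(values)
            if len(values) != mesh.n_voxels:
                raise ValueError(f"field {name!r} length {len(values)} != {mesh.n_voxels}")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.17g}" for v in values]
    Path(path).write_text("\n".join(lines) + "\n")


def write_state_table(state: SystemState, species_names, path) -> None:
    """Delimited snapshot: one row per (voxel, species) with a nonzero count."""
    with open(path, "w") as fh:
        fh.write("voxel\tspecies\tcount\n")
        for s, name in enumerate(species_names):
            for i in np.flatnonzero(state.counts[:, s]):
                fh.write(f"{i}\t{name}\t{state.counts[i, s]}\n")


# ---------------------------------------------------------------------------
# model definition files


def _parse_mesh_section(section: dict) -> Mesh:
    if "file" in section:
        return read_msh(section["file"])
    builder = section.get("builder")
    if builder == "interval":
        return build_interval_mesh(
            float(section.get("left", 0.0)),
            float(section.get("right", 1.0)),
            int(section["n_vox"]),
        )
    if builder == "ball":
        return build_ball_mesh(float(section["radius"]), int(section.get("resolution", 2)))
    raise InvalidModelError(f"unknown mesh specification: {section!r}")


def load_model(path) -> tuple[Mesh, ReactionNetwork, SystemState, dict]:
    """Load a YAML model definition.

    Schema::

        mesh: {builder: interval|ball, ...} | {file: mesh.msh}
        species:
          - {name: S, diffusion: 1.0, subdomain: all|boundary|interior}
        reactions:
          - {reactants: {S: 1}, products: {S_b: 1}, rate: 50.0,
             subdomain: boundary, scale_by_inverse_volume: true}
        initial: {S: 10000}            # placed uniformly by voxel volume
        velocity: {type: none|constant_left|radial|tip_growth, ...}

    ``scale_by_inverse_volume`` applies the geometry hook rate/V_i (e.g. the
    mesoscopic conversion k_a/h of a microscopic surface binding rate on a 1D
    mesh).  Returns (mesh, network, initial state, velocity section).
    """
    cfg = yaml.safe_load(Path(path).read_text())
    mesh = _parse_mesh_section(cfg["mesh"])
    species = [
        Species(
            s["name"],
            diffusion_constant=float(s.get("diffusion", 0.0)),
            subdomain_restriction=s.get("subdomain", "all"),
        )
        for s in cfg["species"]
    ]
    reactions = []
    for r in cfg.get("reactions", []):
        hook = (lambda m, i: 1.0 / m.voxel_volumes[i]) if r.get("scale_by_inverse_volume") else None
        reactions.append(
            Reaction(
                {k: int(v) for k, v in (r.get("reactants") or {}).items()},
                {k: int(v) for k, v in (r.get("products") or {}).items()},
                rate_constant=float(r["rate"]),
                subdomain=r.get("subdomain", "all"),
                rate_hook=hook,
                name=r.get("name", ""),
            )
        )
    network = ReactionNetwork(species, reactions)
    counts = np.zeros((mesh.n_voxels, network.n_species), dtype=np.int64)
    for name, total in (cfg.get("initial") or {}).items():
        s = network.index(name)
        restrict = network.species[s].subdomain_restriction
        vox = mesh.voxels_in(restrict)
        w = mesh.voxel_volumes[vox]
        ideal = int(total) * w / w.sum()
        counts[vox, s] = np.floor(ideal).astype(np.int64)
        rem = int(total) - counts[vox, s].sum()
        order = np.argsort(-(ideal - np.floor(ideal)))
        counts[vox[order[:rem]], s] += 1
    state = SystemState(counts)
    state.validate(mesh, network)
    return mesh, network, state, cfg.get("velocity") or {"type": "none"}
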