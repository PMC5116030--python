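"""Numba event-loop kernels for the NSM and the 1D Brownian-dynamics solver.

The kernels operate on plain arrays and receive a ``numpy.random.Generator``;
its bit-generator state advances in place, so callers can snapshot/restore it
for replay (required by the rejection-based adaptive stepper).
"""

import numpy as np
from numba import njit

# reaction order codes
ORDER_ZERO = 0
ORDER_UNI = 1
ORDER_BI = 2
ORDER_DIMER = 3


@njit(cache=True)
def _sift_up(times, heap, pos, i):
    while i > 0:
        parent = (i - 1) // 2
        if times[heap[i]] < times[heap[parent]]:
            heap[i], heap[parent] = heap[parent], heap[i]
            pos[heap[i]] = i
            pos[heap[parent]] = parent
            i = parent
        else:
            break


@njit(cache=True)
def _sift_down(times, heap, pos, i, n):
    while True:
        left = 2 * i + 1
        right = left + 1
        smallest = i
        if left < n and times[heap[left]] < times[heap[smallest]]:
            smallest = left
        if right < n and times[heap[right]] < times[heap[smallest]]:
            smallest = right
        if smallest == i:
            return
        heap[i], heap[smallest] = heap[smallest], heap[i]
        pos[heap[i]] = i
        pos[heap[smallest]] = smallest
        i = smallest


@njit(cache=True)
def _rxn_prop(x, vol, r_order, r_sp1, r_sp2, r_ratec, m, i):
    c = r_ratec[m, i]
    if c == 0.0:
        return 0.0
    o = r_order[m]
    if o == ORDER_ZERO:
        return c * vol[i]
    if o == ORDER_UNI:
        return c * x[i, r_sp1[m]]
    if o == ORDER_BI:
        return c * x[i, r_sp1[m]] * x[i, r_sp2[m]] / vol[i]
    xa = x[i, r_sp1[m]]
    return c * xa * (xa - 1) * 0.5 / vol[i]


@njit(cache=True)
def _voxel_totals(x, vol, outrate, r_order, r_sp1, r_sp2, r_ratec, i):
    a_r = 0.0
    for m in range(r_order.shape[0]):
        a_r += _rxn_prop(x, vol, r_order, r_sp1, r_sp2, r_ratec, m, i)
    a_d = 0.0
    for s in range(x.shape[1]):
        a_d += x[i, s] * outrate[s, i]
    return a_r, a_d


@njit(cache=True)
def _update_voxel(i, now, x, vol, outrate, r_order, r_sp1, r_sp2, r_ratec,
                  a_rxn, a_dif, times, heap, pos, rng):
    a_r, a_d = _voxel_totals(x, vol, outrate, r_order, r_sp1, r_sp2, r_ratec, i)
    a_rxn[i] = a_r
    a_dif[i] = a_d
    tot = a_r + a_d
    if tot > 0.0:
        times[i] = now + rng.standard_exponential() / tot
    else:
        times[i] = np.inf
    _sift_up(times, heap, pos, pos[i])
    _sift_down(times, heap, pos, pos[i], heap.shape[0])


@njit(cache=True)
def nsm_kernel(x, t0, sample_times, out, vol,
               dif_indptr, dif_cols, dif_rates, outrate,
               r_order, r_sp1, r_sp2, r_ratec, r_net, rng):
    """Exact NSM realization; records the state at each sample time.

    ``x`` (K, S) is modified in place and equals the state at the final
    sample time on return.  Each affected voxel gets a freshly drawn
    exponential next-event time after an event (statistically exact by
    memorylessness).  Returns the number of executed events.
    """
    K, S = x.shape
    M = r_order.shape[0]
    nt = sample_times.shape[0]
    a_rxn = np.zeros(K)
    a_dif = np.zeros(K)
    times = np.empty(K)
    heap = np.empty(K, np.int64)
    pos = np.empty(K, np.int64)
    for i in range(K):
        a_r, a_d = _voxel_totals(x, vol, outrate, r_order, r_sp1, r_sp2, r_ratec, i)
        a_rxn[i] = a_r
        a_dif[i] = a_d
        tot = a_r + a_d
        times[i] = t0 + rng.standard_exponential() / tot if tot > 0.0 else np.inf
        heap[i] = i
        pos[i] = i
    for i in range(K // 2 - 1, -1, -1):
        _sift_down(times, heap, pos, i, K)

    n_events = 0
    k = 0
    while True:
        i = heap[0]
        te = times[i]
        while k < nt and te >= sample_times[k]:
            for a in range(K):
                for b in range(S):
                    out[k, a, b] = x[a, b]
            k += 1
        if k >= nt:
            return n_events
        u = rng.random() * (a_rxn[i] + a_dif[i])
        if u < a_rxn[i]:
            m_sel = -1
            acc = 0.0
            for m in range(M):
                p = _rxn_prop(x, vol, r_order, r_sp1, r_sp2, r_ratec, m, i)
                acc += p
                if u < acc and p > 0.0:
                    m_sel = m
                    break
            if m_sel < 0:  # float roundoff: take the last live channel
                for m in range(M - 1, -1, -1):
                    if _rxn_prop(x, vol, r_order, r_sp1, r_sp2, r_ratec, m, i) > 0.0:
                        m_sel = m
                        break
            for s in range(S):
                x[i, s] += r_net[m_sel, s]
                if x[i, s] < 0:
                    raise RuntimeError("negative copy number: internal NSM invariant violated")
            _update_voxel(i, te, x, vol, outrate, r_order, r_sp1, r_sp2, r_ratec,
                          a_rxn, a_dif, times, heap, pos, rng)
        else:
            u -= a_rxn[i]
            s_sel = -1
            for s in range(S):
                blk = x[i, s] * outrate[s, i]
                if u < blk and blk > 0.0:
                    s_sel = s
                    break
                u -= blk
            if s_sel < 0:
                for s in range(S - 1, -1, -1):
                    if x[i, s] * outrate[s, i] > 0.0:
                        s_sel = s
                        break
            j_sel = -1
            xc = float(x[i, s_sel])
            for idx in range(dif_indptr[s_sel, i], dif_indptr[s_sel, i + 1]):
                r = xc * dif_rates[idx]
                if u < r:
                    j_sel = dif_cols[idx]
                    break
                u -= r
            if j_sel < 0:
                j_sel = dif_cols[dif_indptr[s_sel, i + 1] - 1]
            x[i, s_sel] -= 1
            x[j_sel, s_sel] += 1
            if x[i, s_sel] < 0:
                raise RuntimeError("negative copy number: internal NSM invariant violated")
            _update_voxel(i, te, x, vol, outrate, r_order, r_sp1, r_sp2, r_ratec,
                          a_rxn, a_dif, times, heap, pos, rng)
            _update_voxel(j_sel, te, x, vol, outrate, r_order, r_sp1, r_sp2, r_ratec,
                          a_rxn, a_dif, times, heap, pos, rng)
        n_events += 1


# ---------------------------------------------------------------------------
# 1D Brownian dynamics with a reactive (absorbing/desorbing) moving left end


@njit(cache=True)
def _ih_push(h, n, v):
    h[n] = v
    i = n
    while i > 0:
        p = (i - 1) // 2
        if h[i] < h[p]:
            h[i], h[p] = h[p], h[i]
            i = p
        else:
            break
    return n + 1


@njit(cache=True)
def _ih_pop(h, n):
    top = h[0]
    n -= 1
    h[0] = h[n]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        m = i
        if l < n and h[l] < h[m]:
            m = l
        if r < n and h[r] < h[m]:
            m = r
        if m == i:
            break
        h[i], h[m] = h[m], h[i]
        i = m
    return top, n


@njit(cache=True)
def bd_kernel(pos, n_free, n_bound0, L0, R, D, k_a, k_d, v, dt, n_steps, rng):
    """Euler–Maruyama Brownian dynamics on [L(t), R].

    Free particles take Gaussian steps (variance 2 D dt); the right end
    reflects; a particle touching/crossing the left end binds with the
    reactive-boundary probability k_a*sqrt(pi*dt/D) and is otherwise
    specularly reflected.  Bound particles unbind as a discrete-time
    geometric process matching per-step probability 1-exp(-k_d*dt) and
    re-enter at the current left end.  The left end is frozen during a step
    and advanced by -v*dt afterwards.
    """
    p_bind = k_a * np.sqrt(np.pi * dt / D)
    sigma = np.sqrt(2.0 * D * dt)
    cap = pos.shape[0]
    unbind = np.empty(cap, np.int64)
    n_heap = 0
    for _ in range(n_bound0):
        g = int(np.ceil(rng.standard_exponential() / (k_d * dt))) if k_d > 0 else np.int64(2 ** 62)
        n_heap = _ih_push(unbind, n_heap, g - 1)
    L = L0
    for step in range(n_steps):
        i = 0
        while i < n_free:
            z = pos[i] + sigma * rng.standard_normal()
            if z > R:
                z = 2.0 * R - z
            if z <= L:
                if rng.random() < p_bind:
                    g = int(np.ceil(rng.standard_exponential() / (k_d * dt))) if k_d > 0 else np.int64(2 ** 62)
                    n_heap = _ih_push(unbind, n_heap, step + g)
                    n_free -= 1
                    pos[i] = pos[n_free]
                    continue
                z = 2.0 * L - z
            pos[i] = z
            i += 1
        while n_heap > 0 and unbind[0] <= step:
            _, n_heap = _ih_pop(unbind, n_heap)
            pos[n_free] = L
            n_free += 1
        L -= v * dt
    return n_free, n_heap, L
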