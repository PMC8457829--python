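"""Numba kernels for exact stochastic simulation of birth-hop-death lattices.

The RNG is numpy's legacy MT19937 stream as exposed inside numba's nopython
mode, seeded explicitly per run; trajectories are therefore bit-reproducible
for a fixed (config, seed) on any platform.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ssa_lattice", "ssa_reversible"]


@njit(cache=False)
def _pick_weighted(counts, lo, hi, target):
    """Index in [lo, hi) with cumulative-count crossing of ``target``."""
    acc = 0.0
    for i in range(lo, hi):
        acc += counts[i]
        if target < acc:
            return i
    # float round-off fallback: last occupied cell in range
    for i in range(hi - 1, lo - 1, -1):
        if counts[i] > 0:
            return i
    return -1


@njit(cache=False)
def ssa_lattice(seed, n_cells, inj, hop, kd, sample_times, counts_out):
    """Exact SSA of the irreversible birth-hop-death lattice from zero state.

    Events: injection into cell 0 at rate ``inj``; symmetric nearest-
    neighbour hops at ``hop`` per molecule (reflecting at both ends);
    degradation at ``kd`` per molecule.  State snapshots are written to
    ``counts_out[k]`` at each ``sample_times[k]`` (value just before the
    first event past that time).
    """
    np.random.seed(seed)
    counts = np.zeros(n_cells, dtype=np.int64)
    t = 0.0
    total = 0
    si = 0
    n_samples = sample_times.shape[0]
    last = n_cells - 1
    while si < n_samples:
        a_deg = kd * total
        a_hl = hop * (total - counts[0])
        a_hr = hop * (total - counts[last])
        a_tot = inj + a_deg + a_hl + a_hr
        dt = -np.log(np.random.random()) / a_tot
        t_next = t + dt
        while si < n_samples and sample_times[si] < t_next:
            for j in range(n_cells):
                counts_out[si, j] = counts[j]
            si += 1
        if si >= n_samples:
            break
        t = t_next
        r = np.random.random() * a_tot
        if r < inj:
            counts[0] += 1
            total += 1
        elif r < inj + a_deg:
            i = _pick_weighted(counts, 0, n_cells, (r - inj) / kd)
            if i >= 0:
                counts[i] -= 1
                total -= 1
        elif r < inj + a_deg + a_hl:
            i = _pick_weighted(counts, 1, n_cells, (r - inj - a_deg) / hop)
            if i >= 0:
                counts[i] -= 1
                counts[i - 1] += 1
        else:
            i = _pick_weighted(counts, 0, last, (r - inj - a_deg - a_hl) / hop)
            if i >= 0:
                counts[i] -= 1
                counts[i + 1] += 1
    return counts


@njit(cache=False)
def ssa_reversible(seed, n_cells, ks, ks_rev, kd, kd_rev, hop_f, hop_r,
                   t_burnin, sample_times, counts_out):
    """Exact SSA of the reversible lattice with entropy bookkeeping.

    Reactions (per the reversible-kinetics construction): synthesis into
    cell 0 at ``ks`` with first-order reverse ``ks_rev``; degradation ``kd``
    per molecule with zeroth-order reverse ``kd_rev`` in every cell;
    right/left hops ``hop_f``/``hop_r`` per molecule.  Every fired event
    adds ``ln(a_fwd(n)/a_rev(n'))`` to the entropy tally, giving the
    stochastic total entropy production along the path (in k_B).

    Returns ``(entropy_after_burnin, time_after_burnin)``; snapshots are
    written at ``sample_times`` as in :func:`ssa_lattice`.
    """
    np.random.seed(seed)
    counts = np.zeros(n_cells, dtype=np.int64)
    t = 0.0
    total = 0
    si = 0
    n_samples = sample_times.shape[0]
    last = n_cells - 1
    entropy = 0.0
    entropy_mark = 0.0
    marked = False
    t_end = t_burnin
    if n_samples > 0 and sample_times[n_samples - 1] > t_end:
        t_end = sample_times[n_samples - 1]
    while True:
        a_syn = ks
        a_syn_r = ks_rev * counts[0]
        a_deg = kd * total
        a_deg_r = kd_rev * n_cells
        a_hr = hop_f * (total - counts[last])
        a_hl = hop_r * (total - counts[0])
        a_tot = a_syn + a_syn_r + a_deg + a_deg_r + a_hr + a_hl
        dt = -np.log(np.random.random()) / a_tot
        t_next = t + dt
        while si < n_samples and sample_times[si] < t_next:
            for j in range(n_cells):
                counts_out[si, j] = counts[j]
            si += 1
        if not marked and t_next >= t_burnin:
            entropy_mark = entropy
            marked = True
        if t_next > t_end and si >= n_samples:
            break
        t = t_next
        r = np.random.random() * a_tot
        if r < a_syn:
            entropy += np.log(ks / (ks_rev * (counts[0] + 1)))
            counts[0] += 1
            total += 1
        elif r < a_syn + a_syn_r:
            entropy += np.log(ks_rev * counts[0] / ks)
            counts[0] -= 1
            total -= 1
        elif r < a_syn + a_syn_r + a_deg:
            i = _pick_weighted(counts, 0, n_cells, (r - a_syn - a_syn_r) / kd)
            if i >= 0:
                entropy += np.log(kd * counts[i] / kd_rev)
                counts[i] -= 1
                total -= 1
        elif r < a_syn + a_syn_r + a_deg + a_deg_r:
            i = int((r - a_syn - a_syn_r - a_deg) / kd_rev)
            if i >= n_cells:
                i = n_cells - 1
            entropy += np.log(kd_rev / (kd * (counts[i] + 1)))
            counts[i] += 1
            total += 1
        elif r < a_syn + a_syn_r + a_deg + a_deg_r + a_hr:
            i = _pick_weighted(counts, 0, last,
                               (r - a_syn - a_syn_r - a_deg - a_deg_r) / hop_f)
            if i >= 0:
                entropy += np.log(hop_f * counts[i] / (hop_r * (counts[i + 1] + 1)))
                counts[i] -= 1
                counts[i + 1] += 1
        else:
            i = _pick_weighted(counts, 1, n_cells,
                               (r - a_syn - a_syn_r - a_deg - a_deg_r - a_hr) / hop_r)
            if i >= 0:
                entropy += np.log(hop_r * counts[i] / (hop_f * (counts[i - 1] + 1)))
                counts[i] -= 1
                counts[i - 1] += 1
    return entropy - entropy_mark, t_end - t_burnin
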