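"""Numba kernels: exact direct-method Gillespie simulation of lattice
birth-hop-death systems.

Molecules are stored as a position list, so every event costs O(1): the total
rate is beta + n (2h + nu) (1D) or beta + n (4h + nu) (2D), a uniformly chosen
molecule either hops or dies, and hops that would cross a reflecting boundary
are rejected (statistically exact for a memoryless clock).  Per-event work is
limited to updating the counts of a small set of probe regions, plus clipped
time-integral accumulation of n and n^2 inside the observation window.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def lattice_1d(seed, n_sites, source, source2, beta, hop, nu, burn, window,
               n_reps, probe_id, n_probes, sample_dt, n_samples, max_mol):
    """1D birth-hop-death chain with reflecting ends.

    probe_id maps site -> probe index (or -1).  Returns per replicate and probe
    the occupancy integrals int n dt and int n^2 dt over the window, the birth
    count in the window, sampled counts at burn + k*sample_dt, and the
    whole-lattice occupancy integral.  err != 0 means max_mol was exceeded.
    """
    np.random.seed(seed)
    occ1 = np.zeros((n_reps, n_probes))
    occ2 = np.zeros((n_reps, n_probes))
    births = np.zeros(n_reps, dtype=np.int64)
    samples = np.zeros((n_reps, n_samples, n_probes), dtype=np.int32)
    total_occ = np.zeros(n_reps)
    err = 0
    mol_rate = 2.0 * hop + nu
    t_end = burn + window
    for rep in range(n_reps):
        pos = np.empty(max_mol, dtype=np.int64)
        counts = np.zeros(n_probes, dtype=np.int64)
        n = 0
        t = 0.0
        s_idx = 0
        while t < t_end:
            R = beta + n * mol_rate
            dt = -np.log(np.random.random()) / R
            t_new = t + dt
            lo = burn if t < burn else t
            hi = t_end if t_new > t_end else t_new
            if hi > lo:
                w = hi - lo
                for p in range(n_probes):
                    occ1[rep, p] += w * counts[p]
                    occ2[rep, p] += w * counts[p] * counts[p]
                total_occ[rep] += w * n
            while s_idx < n_samples and burn + s_idx * sample_dt < t_new:
                for p in range(n_probes):
                    samples[rep, s_idx, p] = counts[p]
                s_idx += 1
            if t_new > t_end:
                break
            t = t_new
            u = np.random.random() * R
            if u < beta:
                if n >= max_mol:
                    err = 1
                    break
                # alternate the two central injection sites so an even subcell
                # split keeps the source symmetric about the cell centre
                site0 = source if np.random.random() < 0.5 else source2
                pos[n] = site0
                n += 1
                if probe_id[site0] >= 0:
                    counts[probe_id[site0]] += 1
                if t >= burn:
                    births[rep] += 1
            else:
                k = np.int64(np.random.random() * n)
                if k == n:
                    k = n - 1
                site = pos[k]
                v = np.random.random() * mol_rate
                if v < 2.0 * hop:
                    new = site - 1 if v < hop else site + 1
                    if 0 <= new < n_sites:
                        if probe_id[site] != probe_id[new]:
                            if probe_id[site] >= 0:
                                counts[probe_id[site]] -= 1
                            if probe_id[new] >= 0:
                                counts[probe_id[new]] += 1
                        pos[k] = new
                else:
                    if probe_id[site] >= 0:
                        counts[probe_id[site]] -= 1
                    pos[k] = pos[n - 1]
                    n -= 1
        if err != 0:
            break
    return occ1, occ2, births, samples, total_occ, err


@njit(cache=True)
def lattice_2d(seed, nx, ny, source_x, source_x2, beta_total, hop, nu, burn,
               window, n_reps, px0, px1, py0, py1, sample_dt, n_samples,
               max_mol):
    """2D birth-hop-death lattice: x reflecting, y periodic.

    Production (total rate beta_total) injects at x = source_x with uniform
    random y, emulating a transverse line of source cells.  A single probe
    rectangle [px0, px1) x [py0, py1) is tracked (y interval taken modulo ny).
    """
    np.random.seed(seed)
    occ1 = np.zeros(n_reps)
    occ2 = np.zeros(n_reps)
    samples = np.zeros((n_reps, n_samples), dtype=np.int32)
    total_occ = np.zeros(n_reps)
    err = 0
    mol_rate = 4.0 * hop + nu
    t_end = burn + window
    for rep in range(n_reps):
        posx = np.empty(max_mol, dtype=np.int64)
        posy = np.empty(max_mol, dtype=np.int64)
        n = 0
        count = 0
        t = 0.0
        s_idx = 0
        while t < t_end:
            R = beta_total + n * mol_rate
            dt = -np.log(np.random.random()) / R
            t_new = t + dt
            lo = burn if t < burn else t
            hi = t_end if t_new > t_end else t_new
            if hi > lo:
                w = hi - lo
                occ1[rep] += w * count
                occ2[rep] += w * count * count
                total_occ[rep] += w * n
            while s_idx < n_samples and burn + s_idx * sample_dt < t_new:
                samples[rep, s_idx] = count
                s_idx += 1
            if t_new > t_end:
                break
            t = t_new
            u = np.random.random() * R
            if u < beta_total:
                if n >= max_mol:
                    err = 1
                    break
                posx[n] = source_x if np.random.random() < 0.5 else source_x2
                posy[n] = np.int64(np.random.random() * ny) % ny
                if px0 <= posx[n] < px1 and py0 <= posy[n] < py1:
                    count += 1
                n += 1
            else:
                k = np.int64(np.random.random() * n)
                if k == n:
                    k = n - 1
                x = posx[k]
                y = posy[k]
                was_in = px0 <= x < px1 and py0 <= y < py1
                v = np.random.random() * mol_rate
                if v < 4.0 * hop:
                    if v < hop:
                        if x > 0:
                            x -= 1
                    elif v < 2.0 * hop:
                        if x < nx - 1:
                            x += 1
                    elif v < 3.0 * hop:
                        y = (y - 1) % ny
                    else:
                        y = (y + 1) % ny
                    posx[k] = x
                    posy[k] = y
                    now_in = px0 <= x < px1 and py0 <= y < py1
                    if was_in and not now_in:
                        count -= 1
                    elif now_in and not was_in:
                        count += 1
                else:
                    if was_in:
                        count -= 1
                    posx[k] = posx[n - 1]
                    posy[k] = posy[n - 1]
                    n -= 1
        if err != 0:
            break
    return occ1, occ2, samples, total_occ, err
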