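"""Numba-compiled inner loops for the Metropolis dynamics.

One MC step = one translation attempt followed by one internal-state switch
attempt.  All randomness comes from an explicit PCG32 stream carried in a
two-element uint64 array, so trajectories are bit-reproducible from their
seed independently of global RNG state.

Energies here are plain float64; with the reference half-integer couplings
every energy is exactly representable, so incremental bookkeeping agrees
exactly with full recomputation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MULT = np.uint64(6364136223846793005)


@njit(cache=True)
def _pcg32(rng):
    """Advance the PCG32 stream; returns a uint32 in [0, 2^32)."""
    old = rng[0]
    rng[0] = old * _MULT + rng[1]
    xorshifted = np.uint32(((old >> np.uint64(18)) ^ old) >> np.uint64(27))
    rot = np.uint32(old >> np.uint64(59))
    return np.uint32((xorshifted >> rot) | (xorshifted << ((np.uint32(32) - rot) & np.uint32(31))))


@njit(cache=True)
def _uniform(rng):
    return _pcg32(rng) * 2.3283064365386963e-10  # 2**-32


@njit(cache=True)
def _randbelow(rng, n):
    return np.int64(_pcg32(rng) % np.uint32(n))


@njit(cache=True)
def seed_rng(seed):
    """Initialize a PCG32 state array from a nonnegative integer seed."""
    rng = np.empty(2, dtype=np.uint64)
    rng[1] = (np.uint64(seed) << np.uint64(1)) | np.uint64(1)
    rng[0] = np.uint64(0)
    _pcg32(rng)
    rng[0] = rng[0] + np.uint64(seed) * np.uint64(2891336453)
    _pcg32(rng)
    return rng


@njit(cache=True)
def _pair_energy(i, j, si, sj, Iadj, Js, Jw, Jhalf):
    """Pair interaction; minimum over targets sharing the bond."""
    best = np.inf
    found = False
    for m in range(Iadj.shape[0]):
        if Iadj[m, i, j]:
            found = True
            sm = m + 1
            if si == sm and sj == sm:
                e = Js
            elif si == sm or sj == sm:
                e = Jhalf
            else:
                e = Jw
            if e < best:
                best = e
    if not found:
        return Jw
    return best


@njit(cache=True)
def _site_energy(grid, states, k, r, c, L, Iadj, Js, Jw, Jhalf):
    """Interaction energy of particle k placed at (r, c) with its neighbors."""
    e = 0.0
    sk = states[k]
    for d in range(4):
        if d == 0:
            nr, nc = r, (c + 1) % L
        elif d == 1:
            nr, nc = r, (c - 1) % L
        elif d == 2:
            nr, nc = (r + 1) % L, c
        else:
            nr, nc = (r - 1) % L, c
        j = grid[nr, nc]
        if j >= 0 and j != k:
            e += _pair_energy(k, j, sk, states[j], Iadj, Js, Jw, Jhalf)
    return e


@njit(cache=True)
def _step(grid, pos, states, Iadj, L, N, M, Js, Jw, Jhalf, dmu, rng):
    """One MC step: translate attempt then switch attempt.

    Returns (dE, dS_increment) accumulated over the two attempts.
    """
    dE_tot = 0.0
    dS = 0.0

    # -- translation attempt ----------------------------------------------
    k = _randbelow(rng, N)
    d = _randbelow(rng, 4)
    r, c = pos[k, 0], pos[k, 1]
    if d == 0:
        nr, nc = r, (c + 1) % L
    elif d == 1:
        nr, nc = r, (c - 1) % L
    elif d == 2:
        nr, nc = (r + 1) % L, c
    else:
        nr, nc = (r - 1) % L, c
    if grid[nr, nc] == -1:  # occupied destination rejects before any energy
        grid[r, c] = -1
        e_old = _site_energy(grid, states, k, r, c, L, Iadj, Js, Jw, Jhalf)
        e_new = _site_energy(grid, states, k, nr, nc, L, Iadj, Js, Jw, Jhalf)
        dE = e_new - e_old
        accept = dE <= 0.0 or _uniform(rng) < np.exp(-dE)
        if accept:
            grid[nr, nc] = k
            pos[k, 0], pos[k, 1] = nr, nc
            dE_tot += dE
            dS += -dE  # log ratio of forward/reverse Metropolis probabilities
        else:
            grid[r, c] = k

    # -- internal-state switch attempt ------------------------------------
    if M > 1:
        k = _randbelow(rng, N)
        s_old = states[k]
        s_new = 1 + _randbelow(rng, M - 1)
        if s_new >= s_old:
            s_new += 1
        r, c = pos[k, 0], pos[k, 1]
        cnt_new = 0
        cnt_old = 0
        dE = 0.0
        for d in range(4):
            if d == 0:
                nr, nc = r, (c + 1) % L
            elif d == 1:
                nr, nc = r, (c - 1) % L
            elif d == 2:
                nr, nc = (r + 1) % L, c
            else:
                nr, nc = (r - 1) % L, c
            j = grid[nr, nc]
            if j >= 0 and j != k:
                sj = states[j]
                if sj == s_new:
                    cnt_new += 1
                if sj == s_old:
                    cnt_old += 1
                dE += (_pair_energy(k, j, s_new, sj, Iadj, Js, Jw, Jhalf)
                       - _pair_energy(k, j, s_old, sj, Iadj, Js, Jw, Jhalf))
        sign = 0
        if cnt_new >= 2:
            sign += 1
        if cnt_old >= 2:
            sign -= 1
        a = -dE + sign * dmu
        accept = a >= 0.0 or _uniform(rng) < np.exp(a)
        if accept:
            states[k] = s_new
            dE_tot += dE
            dS += a  # drive_sign of the reverse switch is exactly -sign
    return dE_tot, dS


@njit(cache=True)
def total_energy_kernel(pos, states, Iadj, L, Js, Jw, Jhalf):
    """Full Eq.-style double-loop energy; the incremental-bookkeeping oracle."""
    n = pos.shape[0]
    E = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dr = abs(pos[i, 0] - pos[j, 0])
            if dr > L - dr:
                dr = L - dr
            dc = abs(pos[i, 1] - pos[j, 1])
            if dc > L - dc:
                dc = L - dc
            if dr + dc == 1:
                E += _pair_energy(i, j, states[i], states[j], Iadj, Js, Jw, Jhalf)
    return E


@njit(cache=True)
def distances_kernel(grid, pos, Iadj, L, out):
    """Hamming distances d_m between board adjacency and each target."""
    M = Iadj.shape[0]
    n = pos.shape[0]
    for m in range(M):
        t = 0
        for i in range(n):
            for j in range(i + 1, n):
                t += Iadj[m, i, j]
        out[m] = t
    for i in range(n):
        r, c = pos[i, 0], pos[i, 1]
        for d in range(2):  # right and down cover each periodic edge once
            nr = r if d == 0 else (r + 1) % L
            nc = (c + 1) % L if d == 0 else c
            j = grid[nr, nc]
            if j >= 0 and j != i:
                for m in range(M):
                    out[m] += 1 - 2 * np.int64(Iadj[m, i, j])


@njit(cache=True)
def run_kernel(grid, pos, states, Iadj, L, N, M, Js, Jw, Jhalf, dmu,
               n_steps, record_every, E0, Emin, halt_on_assembly, rng,
               rec_step, rec_E, rec_dS, rec_d):
    """Run up to n_steps MC steps, recording every record_every steps.

    Recording starts at step 0.  Assembly (any d_m = 0 or E <= Emin) is
    checked at recorded steps only.  Returns (n_recorded, T_FAS, E, dS);
    T_FAS = -1 when no assembly was detected.
    """
    M_T = Iadj.shape[0]
    E = E0
    dS = 0.0
    dvec = np.empty(M_T, dtype=np.int64)
    n_rec = 0
    t_fas = np.int64(-1)

    distances_kernel(grid, pos, Iadj, L, dvec)
    rec_step[0] = 0
    rec_E[0] = E
    rec_dS[0] = 0.0
    for m in range(M_T):
        rec_d[0, m] = dvec[m]
    n_rec = 1
    assembled = E <= Emin + 1e-9
    for m in range(M_T):
        if dvec[m] == 0:
            assembled = True
    if assembled:
        t_fas = 0
        if halt_on_assembly:
            return n_rec, t_fas, E, dS

    for step in range(1, n_steps + 1):
        dE, ds = _step(grid, pos, states, Iadj, L, N, M, Js, Jw, Jhalf, dmu, rng)
        E += dE
        dS += ds
        if step % record_every == 0:
            distances_kernel(grid, pos, Iadj, L, dvec)
            rec_step[n_rec] = step
            rec_E[n_rec] = E
            rec_dS[n_rec] = dS
            for m in range(M_T):
                rec_d[n_rec, m] = dvec[m]
            n_rec += 1
            if t_fas < 0:
                assembled = E <= Emin + 1e-9
                for m in range(M_T):
                    if dvec[m] == 0:
                        assembled = True
                if assembled:
                    t_fas = step
                    if halt_on_assembly:
                        break
    return n_rec, t_fas, E, dS


@njit(cache=True)
def run_energy_audit(grid, pos, states, Iadj, L, N, M, Js, Jw, Jhalf, dmu,
                     n_steps, rng):
    """Step the dynamics while comparing incremental E to full recomputation.

    Returns the maximum absolute discrepancy over all steps.
    """
    E = total_energy_kernel(pos, states, Iadj, L, Js, Jw, Jhalf)
    worst = 0.0
    for _ in range(n_steps):
        dE, _ds = _step(grid, pos, states, Iadj, L, N, M, Js, Jw, Jhalf, dmu, rng)
        E += dE
        Eb = total_energy_kernel(pos, states, Iadj, L, Js, Jw, Jhalf)
        diff = abs(E - Eb)
        if diff > worst:
            worst = diff
    return worst


@njit(cache=True)
def run_visit_counts(grid, pos, states, Iadj, L, N, M, Js, Jw, Jhalf, dmu,
                     n_steps, rng, counts):
    """Accumulate visit counts of two-particle configurations.

    ``counts`` is an (L*L, L*L) int64 array indexed by the flat cells of
    particles 0 and 1; incremented after every MC step.  Used for
    equilibrium (detailed-balance) checks on micro-systems with N = 2.
    """
    for _ in range(n_steps):
        _step(grid, pos, states, Iadj, L, N, M, Js, Jw, Jhalf, dmu, rng)
        c0 = pos[0, 0] * L + pos[0, 1]
        c1 = pos[1, 0] * L + pos[1, 1]
        counts[c0, c1] += 1
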