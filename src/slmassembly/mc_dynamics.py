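"""Single-particle Metropolis dynamics with the self-healing drive.

One MC step is a translation attempt (uniform particle, uniform direction,
rejected outright when the destination tile is occupied) followed by an
internal-state switch attempt (independent uniform particle, uniform new
state different from the current one).  Translations are accepted with
p = min(1, exp(-dE)); switches with q = min(1, exp(-dE + sign * delta_mu)),
where sign is +1 when two or more lattice neighbors already share the
proposed state, -1 when two or more share the current state, and the sum
of both when both conditions hold.  With delta_mu > 0 the dynamics break
detailed balance; the trajectory entropy production is accumulated as the
log ratio of forward and reverse acceptance probabilities of each accepted
move.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import _kernels
from .lattice_model import (
    LatticeState,
    ModelParams,
    TargetSet,
    total_energy,
)

__all__ = [
    "MoveProposal", "Trajectory", "acceptance_translate", "acceptance_switch",
    "drive_sign", "entropy_increment", "mc_iteration", "run_trajectory",
    "random_initial_state",
]


def acceptance_translate(delta_E: float) -> float:
    """Metropolis acceptance probability p = min(1, exp(-delta_E))."""
    return min(1.0, math.exp(-delta_E))


def acceptance_switch(delta_E: float, sign: int, delta_mu: float) -> float:
    """Driven acceptance q = min(1, exp(-delta_E + sign * delta_mu))."""
    if delta_mu < 0:
        raise ValueError("delta_mu must be >= 0")
    return min(1.0, math.exp(-delta_E + sign * delta_mu))


def drive_sign(state: LatticeState, particle: int, proposed_state: int) -> int:
    """Drive direction of a state-switch proposal: -1, 0 or +1.

    +1 if >= 2 lattice nearest neighbors are already in the proposed state,
    -1 if >= 2 are in the particle's current state; both conditions sum.
    """
    if proposed_state == state.states[particle]:
        raise ValueError("proposed state must differ from the current one")
    L = state.L
    r, c = state.positions[particle]
    cnt_new = cnt_old = 0
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        j = state.grid[(r + dr) % L, (c + dc) % L]
        if j >= 0 and j != particle:
            if state.states[j] == proposed_state:
                cnt_new += 1
            if state.states[j] == state.states[particle]:
                cnt_old += 1
    return (1 if cnt_new >= 2 else 0) - (1 if cnt_old >= 2 else 0)


@dataclass(frozen=True)
class MoveProposal:
    """A proposed elementary move (translation or internal-state switch)."""

    kind: Literal["translate", "switch"]
    particle: int
    detail: tuple  # destination cell (translate) or proposed state (switch)
    delta_E: float
    drive_sign: int = 0


def entropy_increment(move: MoveProposal, accepted: bool,
                      delta_mu: float = 0.0) -> float:
    """Entropy production of one move: log(p_forward / p_reverse) if accepted.

    The reverse of a translation is the inverse displacement with energy
    difference -delta_E; the reverse of a switch proposes the old state in
    the post-move neighborhood, where the neighbor states are unchanged and
    the drive sign is exactly the negative of the forward one.  Rejected
    moves contribute nothing.
    """
    if not accepted:
        return 0.0
    sign = move.drive_sign if move.kind == "switch" else 0
    p_fwd = acceptance_switch(move.delta_E, sign, delta_mu)
    p_rev = acceptance_switch(-move.delta_E, -sign, delta_mu)
    return math.log(p_fwd / p_rev)


def _iadj_f8(targets: TargetSet) -> np.ndarray:
    return np.ascontiguousarray(targets.adjacency)


def mc_iteration(state: LatticeState, rng: np.ndarray, params: ModelParams,
                 targets: TargetSet) -> tuple[float, float]:
    """Advance one MC step in place; returns (delta_E, entropy increment).

    ``rng`` is a PCG32 state array from :func:`_kernels.seed_rng`; passing
    the same array across calls continues the stream deterministically.
    """
    dE, dS = _kernels._step(
        state.grid, state.positions, state.states, _iadj_f8(targets),
        state.L, state.N, targets.M_T,
        params.J_s, params.J_w, params.J_half, params.delta_mu, rng,
    )
    return float(dE), float(dS)


@dataclass
class Trajectory:
    """Recorded observables of one realization.

    ``steps`` are the recorded MC step indices (spacing ``record_every``),
    ``E`` the energy series, ``dS`` the cumulative entropy production, and
    ``d`` the (n, M_T) per-target adjacency distances.  ``T_FAS`` is the
    first recorded step satisfying the assembly criterion (d_m = 0 or
    E <= ground-state energy); when no assembly occurred within the cap,
    ``censored`` is True and T_FAS equals T_cap.
    """

    steps: np.ndarray
    E: np.ndarray
    dS: np.ndarray
    d: np.ndarray
    T_FAS: int
    censored: bool
    params: ModelParams
    seed: int

    @property
    def n_recorded(self) -> int:
        return len(self.steps)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in self.params.to_dict().items():
                fh.write(f"# {k} = {v}\n")
            fh.write(f"# rng_seed = {self.seed}\n")
            fh.write(f"# T_FAS = {self.T_FAS}\n")
            fh.write(f"# censored = {int(self.censored)}\n")
            fh.write("# one MC step = one translation attempt + one switch attempt\n")
            cols = ["step", "E", "dS"] + [f"d_{m+1}" for m in range(self.d.shape[1])]
            fh.write(",".join(cols) + "\n")
            for i in range(self.n_recorded):
                row = [str(int(self.steps[i])), repr(float(self.E[i])),
                       repr(float(self.dS[i]))]
                row += [str(int(v)) for v in self.d[i]]
                fh.write(",".join(row) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        meta: dict[str, str] = {}
        body = io.StringIO()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "=" in line:
                        k, _, v = line[1:].partition("=")
                        meta[k.strip()] = v.strip()
                else:
                    body.write(line)
        body.seek(0)
        df = pd.read_csv(body, float_precision="round_trip")
        pkeys = ModelParams._KEYS
        params = ModelParams(**{
            k: (float(meta[k]) if k in ("J_s", "J_w", "J_half", "delta_mu")
                else int(meta[k]))
            for k in pkeys if k in meta
        })
        dcols = [c for c in df.columns if c.startswith("d_")]
        return cls(
            steps=df["step"].to_numpy(np.int64),
            E=df["E"].to_numpy(float),
            dS=df["dS"].to_numpy(float),
            d=df[dcols].to_numpy(np.int64),
            T_FAS=int(meta["T_FAS"]),
            censored=bool(int(meta["censored"])),
            params=params,
            seed=int(meta["rng_seed"]),
        )


def random_initial_state(params: ModelParams, seed: int) -> LatticeState:
    """Uniform placement of the N particles on distinct cells, all states 1."""
    rng = np.random.default_rng(seed)
    cells = rng.choice(params.L * params.L, size=params.N, replace=False)
    pos = np.column_stack([cells // params.L, cells % params.L])
    return LatticeState.from_positions(
        pos, np.ones(params.N, dtype=np.int16), params.L)


def run_trajectory(params: ModelParams, targets: TargetSet,
                   seed: int | None = None,
                   halt_on_assembly: bool = True) -> Trajectory:
    """Simulate one realization and record E, dS and d_m.

    The initial placement is uniform over distinct cells with all internal
    states equal to 1.  Assembly is detected at recorded steps as d_m = 0
    for any target or E at (or below) the assembled-target energy; by
    default the run halts there, otherwise it continues to T_cap.
    """
    if params.T_cap < params.record_every:
        raise ValueError("T_cap must be >= record_every")
    seed = params.seed if seed is None else seed
    state = random_initial_state(params, seed)
    iadj = _iadj_f8(targets)
    E0 = float(_kernels.total_energy_kernel(
        state.positions, state.states, iadj, params.L,
        params.J_s, params.J_w, params.J_half))
    Emin = targets.ground_state_energy(params)
    max_rec = params.T_cap // params.record_every + 1
    rec_step = np.zeros(max_rec, dtype=np.int64)
    rec_E = np.zeros(max_rec, dtype=np.float64)
    rec_dS = np.zeros(max_rec, dtype=np.float64)
    rec_d = np.zeros((max_rec, targets.M_T), dtype=np.int64)
    rng = _kernels.seed_rng(seed)
    n_rec, t_fas, _E, _dS = _kernels.run_kernel(
        state.grid, state.positions, state.states, iadj,
        params.L, params.N, targets.M_T,
        params.J_s, params.J_w, params.J_half, params.delta_mu,
        params.T_cap, params.record_every, E0, Emin,
        halt_on_assembly, rng,
        rec_step, rec_E, rec_dS, rec_d,
    )
    censored = t_fas < 0
    return Trajectory(
        steps=rec_step[:n_rec].copy(),
        E=rec_E[:n_rec].copy(),
        dS=rec_dS[:n_rec].copy(),
        d=rec_d[:n_rec].copy(),
        T_FAS=params.T_cap if censored else int(t_fas),
        censored=censored,
        params=params,
        seed=seed,
    )
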