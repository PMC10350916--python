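"""Static structure of the lattice self-assembly model.

N distinguishable particles live on an L x L square lattice with periodic
boundary conditions.  Each particle i carries an internal state
s_i in {1..M_T} selecting one of M_T stored target structures.  A target m
is a placement of all N labeled particles on distinct cells; its adjacency
matrix I^m has I^m_ij = 1 when particles i and j occupy nearest-neighbor
cells in that layout.  Pairwise interactions depend on whether a
board-adjacent pair is a "neighboring pair" of some target and on whether
the internal states match that target:

* strong attraction J_s when both states equal the target index,
* intermediate J_half when exactly one state matches,
* weak attraction J_w when neither matches or the pair is not a
  neighboring pair of any target.

The total energy sums the pair interaction over all board-adjacent pairs;
the stored targets (all states equal to the target index) are the global
energy minima.  Energies are in units of k_B T throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ModelParams", "TargetSet", "LatticeState",
    "build_target_adjacency", "compact_targets", "pair_interaction",
    "total_energy", "distance_to_target", "board_adjacency",
]


class InvalidLayoutError(ValueError):
    """A target layout places two particles on the same cell."""


class InvalidStateError(ValueError):
    """An internal state outside 1..M_T was supplied."""


@dataclass(frozen=True)
class ModelParams:
    """Model and simulation parameters.

    Defaults are the reference parameter set of the study: N=25 particles on
    an L=15 lattice with M_T=2 stored targets, strong/weak energies
    J_s=-4, J_w=-1 (k_B T), and a step cap of 5e7 Monte Carlo iterations.
    ``J_half`` (the half-matching interaction) defaults to (J_s+J_w)/2.
    ``record_every`` defaults so that a full-length trajectory is sampled
    at ~5e4 points.
    """

    N: int = 25
    L: int = 15
    M_T: int = 2
    J_s: float = -4.0
    J_w: float = -1.0
    J_half: float | None = None
    delta_mu: float = 0.0
    T_cap: int = 50_000_000
    record_every: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J_half is None:
            object.__setattr__(self, "J_half", (self.J_s + self.J_w) / 2.0)
        if self.record_every is None:
            object.__setattr__(self, "record_every", max(1, self.T_cap // 50_000))
        if self.N < 1 or self.N > self.L * self.L:
            raise ValueError(f"need 1 <= N <= L*L, got N={self.N}, L={self.L}")
        if self.L < 3:
            raise ValueError("lattice side L must be >= 3")
        if self.M_T < 1:
            raise ValueError("M_T must be >= 1")
        if self.T_cap < 1 or self.record_every < 1:
            raise ValueError("T_cap and record_every must be >= 1")
        if self.T_cap < self.record_every:
            raise ValueError("T_cap must be >= record_every")
        if self.delta_mu < 0:
            raise ValueError("delta_mu must be >= 0")

    # -- serialization (flat key-value YAML) --------------------------------

    _KEYS = ("N", "L", "M_T", "J_s", "J_w", "J_half", "delta_mu",
             "T_cap", "record_every", "seed")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._KEYS}

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ModelParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        return cls(**{k: data[k] for k in cls._KEYS if k in data})

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def build_target_adjacency(layout: np.ndarray) -> np.ndarray:
    """Adjacency matrix I^m of one target layout.

    ``layout`` is an (N, 2) integer array of (row, col) cells.  I^m_ij = 1
    iff cells of particles i and j are lattice nearest neighbors.  Layouts
    are absolute finite shapes; no periodic wrap is applied here (target
    recognition on the periodic board happens through adjacency comparison,
    which is translation invariant).
    """
    layout = np.asarray(layout, dtype=np.int64)
    if layout.ndim != 2 or layout.shape[1] != 2:
        raise InvalidLayoutError("layout must be an (N, 2) array of cells")
    n = layout.shape[0]
    cells = {tuple(rc) for rc in layout.tolist()}
    if len(cells) != n:
        raise InvalidLayoutError("duplicate cell occupancy in target layout")
    diff = np.abs(layout[:, None, :] - layout[None, :, :])
    adj = (diff.sum(axis=2) == 1).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return adj


def _snake_order(rows: int, cols: int) -> np.ndarray:
    """Boustrophedon cell ordering of a rows x cols block."""
    cells = []
    for r in range(rows):
        rng = range(cols) if r % 2 == 0 else range(cols - 1, -1, -1)
        cells.extend((r, c) for c in rng)
    return np.array(cells, dtype=np.int64)


def compact_targets(N: int, M_T: int) -> "TargetSet":
    """Default target set: M_T compact rectangular blocks of the N particles.

    Target 1 fills the block in row-major particle order, target 2 in
    boustrophedon order (a genuinely different adjacency matrix with the
    same bond count), and targets m >= 3 use seeded random permutations of
    the block cells.  For N=25 each target is the compact 5x5 square with
    40 internal bonds.
    """
    cols = int(np.ceil(np.sqrt(N)))
    rows = int(np.ceil(N / cols))
    block = np.array([(r, c) for r in range(rows) for c in range(cols)][:N],
                     dtype=np.int64)
    layouts = []
    for m in range(1, M_T + 1):
        if m == 1:
            layouts.append(block.copy())
        elif m == 2:
            layouts.append(_snake_order(rows, cols)[:N])
        else:
            perm = np.random.default_rng(1000 + m).permutation(N)
            layouts.append(block[perm])
    return TargetSet.from_layouts(layouts)


@dataclass(frozen=True)
class TargetSet:
    """The encoded target structures and their adjacency tensors I^m."""

    layouts: np.ndarray          # (M_T, N, 2) int
    adjacency: np.ndarray        # (M_T, N, N) uint8

    @classmethod
    def from_layouts(cls, layouts: Sequence[np.ndarray]) -> "TargetSet":
        arrs = [np.asarray(l, dtype=np.int64) for l in layouts]
        n = arrs[0].shape[0]
        if any(a.shape != (n, 2) for a in arrs):
            raise InvalidLayoutError("all layouts must place the same N particles")
        adj = np.stack([build_target_adjacency(a) for a in arrs])
        return cls(layouts=np.stack(arrs), adjacency=adj)

    @property
    def M_T(self) -> int:
        return self.layouts.shape[0]

    @property
    def N(self) -> int:
        return self.layouts.shape[1]

    def n_bonds(self, m: int) -> int:
        """Number of nearest-neighbor bonds in target m (1-based)."""
        self._check_m(m)
        return int(self.adjacency[m - 1].sum() // 2)

    def ground_state_energy(self, params: ModelParams) -> float:
        """Energy of the best fully assembled target: min_m J_s * bonds(m)."""
        return min(params.J_s * self.n_bonds(m) for m in range(1, self.M_T + 1))

    def assembled_state(self, m: int, params: ModelParams) -> "LatticeState":
        """The lattice state with target m assembled and all states = m."""
        self._check_m(m)
        return LatticeState.from_positions(
            self.layouts[m - 1] % params.L,
            np.full(self.N, m, dtype=np.int16),
            params.L,
        )

    def _check_m(self, m: int) -> None:
        if not 1 <= m <= self.M_T:
            raise IndexError(f"target index m={m} outside 1..{self.M_T}")

    # -- plain-text layout IO ----------------------------------------------

    def save_layouts(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# target layouts; coordinates are 0-based (row, col)\n")
            for m in range(self.M_T):
                fh.write(f"# target: {m + 1}\n")
                fh.write("particle_id\trow\tcol\n")
                for i, (r, c) in enumerate(self.layouts[m]):
                    fh.write(f"{i}\t{r}\t{c}\n")

    @classmethod
    def load_layouts(cls, path: str | Path) -> "TargetSet":
        layouts: list[list[tuple[int, int, int]]] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line.startswith("# target:"):
                layouts.append([])
            elif not line or line.startswith("#") or line.startswith("particle_id"):
                continue
            else:
                i, r, c = (int(v) for v in line.split())
                layouts[-1].append((i, r, c))
        out = []
        for rows in layouts:
            rows.sort()
            out.append(np.array([(r, c) for _, r, c in rows], dtype=np.int64))
        return cls.from_layouts(out)


@dataclass
class LatticeState:
    """Occupancy grid, particle positions, and internal states at one instant.

    ``grid[r, c]`` is -1 for an empty cell, else the 0-based particle label;
    ``positions`` is (N, 2); ``states`` holds s_i in 1..M_T.
    """

    grid: np.ndarray
    positions: np.ndarray
    states: np.ndarray

    @classmethod
    def from_positions(cls, positions: np.ndarray, states: np.ndarray,
                       L: int) -> "LatticeState":
        positions = np.asarray(positions, dtype=np.int64)
        states = np.asarray(states, dtype=np.int16)
        n = positions.shape[0]
        grid = np.full((L, L), -1, dtype=np.int32)
        for i, (r, c) in enumerate(positions):
            if grid[r, c] != -1:
                raise InvalidLayoutError(f"cell ({r},{c}) doubly occupied")
            grid[r, c] = i
        state = cls(grid=grid, positions=positions.copy(), states=states.copy())
        return state

    @property
    def L(self) -> int:
        return self.grid.shape[0]

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    def validate(self, M_T: int | None = None) -> None:
        occ = np.argwhere(self.grid >= 0)
        if len(occ) != self.N:
            raise InvalidLayoutError("grid occupancy does not match particle count")
        for r, c in occ:
            i = self.grid[r, c]
            if tuple(self.positions[i]) != (r, c):
                raise InvalidLayoutError("grid/positions mismatch")
        if M_T is not None and (np.any(self.states < 1) or np.any(self.states > M_T)):
            raise InvalidStateError("internal states outside 1..M_T")

    def copy(self) -> "LatticeState":
        return LatticeState(self.grid.copy(), self.positions.copy(),
                            self.states.copy())


def board_adjacency(state: LatticeState) -> np.ndarray:
    """Board nearest-neighbor matrix B(i, j) with periodic boundaries."""
    L, n = state.L, state.N
    B = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        r, c = state.positions[i]
        for dr, dc in ((0, 1), (1, 0)):
            j = state.grid[(r + dr) % L, (c + dc) % L]
            if j >= 0 and j != i:
                B[i, j] = 1
                B[j, i] = 1
    return B


def pair_interaction(i: int, j: int, s_i: int, s_j: int,
                     targets: TargetSet, params: ModelParams) -> float:
    """Interaction energy J(s_i, s_j) of particles i and j (0-based labels).

    If the pair is a neighboring pair of several targets, the most
    attractive (minimum) of the per-target energies applies.
    """
    if i == j:
        raise ValueError("pair interaction requires i != j")
    for s in (s_i, s_j):
        if not 1 <= s <= targets.M_T:
            raise InvalidStateError(f"state {s} outside 1..{targets.M_T}")
    best = None
    for m in range(1, targets.M_T + 1):
        if targets.adjacency[m - 1, i, j]:
            if s_i == m and s_j == m:
                e = params.J_s
            elif s_i == m or s_j == m:
                e = params.J_half
            else:
                e = params.J_w
            best = e if best is None else min(best, e)
    return params.J_w if best is None else best


def total_energy(state: LatticeState, targets: TargetSet,
                 params: ModelParams) -> float:
    """Total energy E = sum_{i<j} B(i,j) J(s_i, s_j) (periodic board)."""
    B = board_adjacency(state)
    ii, jj = np.nonzero(np.triu(B, 1))
    return float(sum(
        pair_interaction(int(i), int(j), int(state.states[i]),
                         int(state.states[j]), targets, params)
        for i, j in zip(ii, jj)
    ))


def distance_to_target(state: LatticeState, m: int,
                       targets: TargetSet) -> int:
    """Hamming distance d_m between board adjacency and target-m adjacency.

    d_m = sum_{i<j} |B(i,j) - I^m_ij|; zero exactly when the current
    adjacency pattern reproduces target m (anywhere on the periodic board).
    """
    targets._check_m(m)
    B = board_adjacency(state)
    diff = np.abs(B.astype(np.int64) - targets.adjacency[m - 1].astype(np.int64))
    return int(np.triu(diff, 1).sum())
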