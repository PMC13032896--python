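"""Balanced uniform designs over the discrete peptide space.

A U-type design is an n x s matrix of levels 1..q in which every level
appears exactly n/q times in each column, so each row maps to one peptide
and every residue occupies every position with frequency exactly 1/q.
Designs are scored by the mixture L2-discrepancy (MD2), a squared distance
between the design's empirical distribution on the unit cube and the
uniform distribution that blends the centred and wrap-around L2 criteria:

    MD2(P) = (19/12)^s
             - (2/n) sum_i prod_j (5/3 - 1/4|x_ij - 1/2| - 1/4|x_ij - 1/2|^2)
             + (1/n^2) sum_i sum_k prod_j (15/8 - 1/4|x_ij - 1/2|
                     - 1/4|x_kj - 1/2| - 3/4|x_ij - x_kj| + 1/2|x_ij - x_kj|^2)

MD2 is minimised by a stochastic-optimisation adaptive threshold-acceptance
(SOAT) search whose move set — swapping two entries within one column —
preserves exact balance by construction.  Worsening moves are accepted while
their MD2 increase stays below a decaying threshold, which lets the search
escape local optima early and behave greedily late.

Levels are mapped to the unit cube by the centred convention
x = (u - 0.5)/q, which keeps points off the cube boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BalanceError, ConfigError, DomainError
from .peptide_space import AA_INDEX, AMINO_ACIDS

__all__ = [
    "LevelDesign",
    "SoatConfig",
    "DesignSeries",
    "level_to_unit",
    "md2",
    "md2_of_design",
    "random_balanced_design",
    "soat_optimize",
    "series_sizes",
    "build_series",
    "occupancy_table",
    "design_to_peptides",
    "peptides_to_design",
    "save_design",
    "load_design",
]


@dataclass(frozen=True)
class LevelDesign:
    """An n x s balanced design with integer levels in 1..q."""

    matrix: np.ndarray
    q: int
    seed: int | None = None
    md2_value: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int64)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.size == 0:
            raise DomainError("design matrix must be a non-empty 2-D array")
        n, s = m.shape
        if n % self.q:
            raise BalanceError(f"run count n={n} is not divisible by q={self.q}")
        if m.min() < 1 or m.max() > self.q:
            raise DomainError(f"levels must lie in 1..{self.q}")
        per = n // self.q
        for j in range(s):
            counts = np.bincount(m[:, j], minlength=self.q + 1)[1:]
            if not np.all(counts == per):
                raise BalanceError(
                    f"column {j} violates balance: each of the {self.q} levels "
                    f"must appear exactly {per} times"
                )

    @property
    def n(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def s(self) -> int:
        return int(self.matrix.shape[1])


def level_to_unit(design: LevelDesign | np.ndarray, q: int | None = None) -> np.ndarray:
    """Map integer levels 1..q to the open unit interval via x = (u - 0.5)/q."""
    if isinstance(design, LevelDesign):
        m, q = design.matrix, design.q
    else:
        m = np.asarray(design)
        if q is None:
            raise DomainError("q is required when passing a bare level matrix")
    return (m - 0.5) / q


def _f1(x: np.ndarray) -> np.ndarray:
    a = np.abs(x - 0.5)
    return 5.0 / 3.0 - 0.25 * a - 0.25 * a * a


def _kernel(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ax = np.abs(x - 0.5)
    ay = np.abs(y - 0.5)
    d = np.abs(x - y)
    return 15.0 / 8.0 - 0.25 * ax - 0.25 * ay - 0.75 * d + 0.5 * d * d


def md2(points: np.ndarray, chunk: int = 1024) -> float:
    """Mixture L2-discrepancy of a set of points in the unit cube.

    Evaluates the closed form exactly; the pairwise double sum is processed
    in row blocks so memory stays O(chunk * n).
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.size == 0:
        raise DomainError("empty design")
    if x.min() < 0.0 or x.max() > 1.0:
        raise DomainError("coordinates must lie in [0, 1]")
    n, s = x.shape
    term1 = (19.0 / 12.0) ** s
    term2 = 2.0 / n * _f1(x).prod(axis=1).sum()
    total = 0.0
    for i0 in range(0, n, chunk):
        blk = x[i0 : i0 + chunk]
        prod = np.ones((blk.shape[0], n))
        for j in range(s):
            prod *= _kernel(blk[:, j][:, None], x[:, j][None, :])
        total += prod.sum()
    term3 = total / (n * n)
    return float(term1 - term2 + term3)


def _tables(q: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level value table F1[q] and pair-kernel table K[q, q]."""
    xu = (np.arange(1, q + 1) - 0.5) / q
    return _f1(xu), _kernel(xu[:, None], xu[None, :])


def md2_of_design(design: LevelDesign, chunk: int = 2048) -> float:
    """MD2 of a level design, using q x q kernel lookup tables.

    Exploits the discreteness of the level grid; agrees with :func:`md2`
    applied to :func:`level_to_unit` to floating-point accuracy.
    """
    idx = design.matrix - 1
    n, s = idx.shape
    F1, K = _tables(design.q)
    term1 = (19.0 / 12.0) ** s
    term2 = 2.0 / n * F1[idx].prod(axis=1).sum()
    total = 0.0
    for i0 in range(0, n, chunk):
        blk = idx[i0 : i0 + chunk]
        prod = np.ones((blk.shape[0], n))
        for j in range(s):
            prod *= K[blk[:, j][:, None], idx[:, j][None, :]]
        total += prod.sum()
    return float(term1 - term2 + total / (n * n))


def random_balanced_design(n: int, s: int, q: int, seed: int | None = None) -> LevelDesign:
    """Independent random column permutations of the balanced level multiset."""
    if n % q:
        raise BalanceError(f"run count n={n} is not divisible by q={q}")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(1, q + 1), n // q)
    cols = [rng.permutation(base) for _ in range(s)]
    return LevelDesign(np.column_stack(cols), q=q, seed=seed)


@dataclass(frozen=True)
class SoatConfig:
    """Budget and threshold schedule for the SOAT search.

    ``inner_loops=None`` defaults to 200*s.  The initial acceptance threshold
    is the ``initial_threshold_quantile`` quantile of |dMD2| over 100 probe
    moves, and is multiplied by ``threshold_decay`` after every outer loop.
    """

    outer_loops: int = 50
    inner_loops: int | None = None
    initial_threshold_quantile: float = 0.3
    threshold_decay: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_loops <= 0 or (self.inner_loops is not None and self.inner_loops <= 0):
            raise ConfigError("loop counts must be positive")
        if not 0.0 < self.initial_threshold_quantile < 1.0:
            raise ConfigError("initial_threshold_quantile must lie in (0, 1)")
        if not 0.0 < self.threshold_decay < 1.0:
            raise ConfigError("threshold_decay must lie in (0, 1)")


class _SoatState:
    """Incremental MD2 bookkeeping for within-column swaps."""

    def __init__(self, idx: np.ndarray, q: int):
        self.idx = idx  # 0-based levels, mutated in place
        self.q = q
        self.n, self.s = idx.shape
        self.F1, self.K = _tables(q)
        self.rowprod = self.F1[idx].prod(axis=1)
        self.term1 = (19.0 / 12.0) ** self.s
        self.value = self._full_value()

    def _full_value(self) -> float:
        n = self.n
        total = 0.0
        for i0 in range(0, n, 2048):
            blk = self.idx[i0 : i0 + 2048]
            prod = np.ones((blk.shape[0], n))
            for j in range(self.s):
                prod *= self.K[blk[:, j][:, None], self.idx[:, j][None, :]]
            total += prod.sum()
        return float(self.term1 - 2.0 / n * self.rowprod.sum() + total / (n * n))

    def _cross(self, r: int) -> np.ndarray:
        """Kernel products of every row against row r."""
        prod = np.ones(self.n)
        for j in range(self.s):
            prod *= self.K[self.idx[:, j], self.idx[r, j]]
        return prod

    def delta(self, c: int, r1: int, r2: int) -> tuple[float, np.ndarray, np.ndarray]:
        """MD2 change if levels at (r1, c) and (r2, c) were swapped."""
        idx, K, F1, n = self.idx, self.K, self.F1, self.n
        a, b = idx[r1, c], idx[r2, c]
        d_term2 = -2.0 / n * (
            self.rowprod[r1] * (F1[b] / F1[a] - 1.0)
            + self.rowprod[r2] * (F1[a] / F1[b] - 1.0)
        )
        A = self._cross(r1)
        B = self._cross(r2)
        col = idx[:, c]
        ratio_ab = K[col, b] / K[col, a]
        ratio_ba = K[col, a] / K[col, b]
        dA = A * (ratio_ab - 1.0)
        dB = B * (ratio_ba - 1.0)
        mask_sum = dA.sum() - dA[r1] - dA[r2] + dB.sum() - dB[r1] - dB[r2]
        d_diag = A[r1] * (K[b, b] / K[a, a] - 1.0) + B[r2] * (K[a, a] / K[b, b] - 1.0)
        # the (r1, r2) cross term is invariant: its column-c factor K[a,b] is symmetric
        d_term3 = (2.0 * mask_sum + d_diag) / (n * n)
        return float(d_term2 + d_term3), A, B

    def apply(self, c: int, r1: int, r2: int, delta: float) -> None:
        idx, F1 = self.idx, self.F1
        a, b = idx[r1, c], idx[r2, c]
        self.rowprod[r1] *= F1[b] / F1[a]
        self.rowprod[r2] *= F1[a] / F1[b]
        idx[r1, c], idx[r2, c] = b, a
        self.value += delta

    def resync(self) -> None:
        """Full recomputation to cap floating-point drift."""
        self.rowprod = self.F1[self.idx].prod(axis=1)
        self.value = self._full_value()


def soat_optimize(
    n: int,
    s: int,
    q: int,
    cfg: SoatConfig | None = None,
    return_trace: bool = False,
) -> LevelDesign | tuple[LevelDesign, pd.DataFrame]:
    """Minimise MD2 over balanced designs by threshold-accepting column swaps.

    Starts from a random balanced design, proposes swaps of two entries within
    a random column (balance-preserving), accepts any improvement and any
    worsening below the current threshold, and returns the best design seen.
    """
    cfg = cfg or SoatConfig()
    inner = cfg.inner_loops if cfg.inner_loops is not None else 200 * s
    rng = np.random.default_rng(cfg.seed)
    start = random_balanced_design(n, s, q, seed=int(rng.integers(2**31)))
    state = _SoatState(start.matrix.copy() - 1, q)

    def propose():
        c = int(rng.integers(s))
        r1, r2 = rng.choice(n, size=2, replace=False)
        return c, int(r1), int(r2)

    # probe moves to scale the initial threshold
    probes = []
    for _ in range(100):
        c, r1, r2 = propose()
        if state.idx[r1, c] == state.idx[r2, c]:
            continue
        d, _, _ = state.delta(c, r1, r2)
        probes.append(abs(d))
    threshold = float(np.quantile(probes, cfg.initial_threshold_quantile)) if probes else 0.0

    best_idx = state.idx.copy()
    best_val = state.value
    accepted = 0
    trace: list[dict] = []
    for outer in range(cfg.outer_loops):
        for _ in range(inner):
            c, r1, r2 = propose()
            if state.idx[r1, c] == state.idx[r2, c]:
                continue
            d, _, _ = state.delta(c, r1, r2)
            if d < threshold:
                state.apply(c, r1, r2, d)
                accepted += 1
                if accepted % 1000 == 0:
                    state.resync()
                if state.value < best_val:
                    best_val = state.value
                    best_idx = state.idx.copy()
                    if return_trace:
                        trace.append(
                            {"outer": outer, "accepted": accepted,
                             "md2": best_val, "threshold": threshold}
                        )
        threshold *= cfg.threshold_decay

    design = LevelDesign(best_idx + 1, q=q, seed=cfg.seed, md2_value=float(best_val))
    if return_trace:
        return design, pd.DataFrame(trace, columns=["outer", "accepted", "md2", "threshold"])
    return design


def series_sizes(start: int = 1000, stop: int = 16000, step: int = 500) -> list[int]:
    """The design-size grid (inclusive of ``stop``)."""
    return list(range(start, stop + 1, step))


@dataclass(frozen=True)
class DesignSeries:
    """A strictly increasing family of designs over the same space."""

    sizes: tuple[int, ...]
    designs: tuple[LevelDesign, ...]
    sampling_fractions: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if list(self.sizes) != sorted(set(self.sizes)):
            raise DomainError("sizes must be strictly increasing")
        if len(self.sizes) != len(self.designs):
            raise DomainError("one design per size is required")
        q = self.designs[0].q
        s = self.designs[0].s
        fracs = tuple(n / q**s for n in self.sizes)
        object.__setattr__(self, "sampling_fractions", fracs)


def build_series(
    start: int = 1000,
    stop: int = 16000,
    step: int = 500,
    s: int = 4,
    q: int = 20,
    cfg: SoatConfig | None = None,
) -> DesignSeries:
    """Build one SOAT design per size, seeded as cfg.seed + index."""
    cfg = cfg or SoatConfig()
    sizes = series_sizes(start, stop, step)
    designs = []
    for i, n in enumerate(sizes):
        designs.append(soat_optimize(n, s, q, replace(cfg, seed=cfg.seed + i)))
    return DesignSeries(tuple(sizes), tuple(designs))


def occupancy_table(design: LevelDesign) -> np.ndarray:
    """(s, q) matrix of per-position level frequencies; rows sum to 1."""
    n = design.n
    out = np.empty((design.s, design.q))
    for j in range(design.s):
        out[j] = np.bincount(design.matrix[:, j], minlength=design.q + 1)[1:] / n
    return out


def design_to_peptides(design: LevelDesign, alphabet: str = AMINO_ACIDS) -> list[str]:
    """Map each run (level-combination) to its peptide sequence."""
    if design.q != len(alphabet):
        raise DomainError(
            f"design has q={design.q} levels but the alphabet has {len(alphabet)} letters"
        )
    letters = np.array(list(alphabet))
    return ["".join(row) for row in letters[design.matrix - 1]]


def peptides_to_design(sequences: Sequence[str], seed: int | None = None) -> LevelDesign:
    """Inverse of :func:`design_to_peptides` (requires exact balance)."""
    m = np.array([[AA_INDEX[ch] + 1 for ch in s] for s in sequences], dtype=np.int64)
    return LevelDesign(m, q=len(AMINO_ACIDS), seed=seed)


def save_design(design: LevelDesign, csv_path: str | Path, cfg: SoatConfig | None = None) -> None:
    """Write a design as residue letters (pos1..posS) plus a JSON sidecar."""
    csv_path = Path(csv_path)
    peps = design_to_peptides(design)
    cols = {f"pos{j + 1}": [p[j] for p in peps] for j in range(design.s)}
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    meta = {
        "n": design.n,
        "s": design.s,
        "q": design.q,
        "seed": design.seed,
        "md2": design.md2_value,
        "soat": None if cfg is None else {
            "outer_loops": cfg.outer_loops,
            "inner_loops": cfg.inner_loops,
            "initial_threshold_quantile": cfg.initial_threshold_quantile,
            "threshold_decay": cfg.threshold_decay,
            "seed": cfg.seed,
        },
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_design(csv_path: str | Path) -> LevelDesign:
    """Read a design written by :func:`save_design`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    seqs = ["".join(row) for row in df.itertuples(index=False)]
    seed = None
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        seed = json.loads(sidecar.read_text()).get("seed")
    return peptides_to_design(seqs, seed=seed)
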