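"""Physicochemical properties and descriptors of short peptides.

Three target properties drive the pipeline:

* **AP** — aggregation propensity, the ratio of initial to final
  solvent-accessible surface area over a coarse-grained MD run.  AP = 1
  means no aggregation; 1.5–2 marks favourable self-assembly; above 2 the
  peptide over-aggregates and precipitates.  AP values are ingested (or
  simulated); only the SASA-ratio post-processing is computed here.
* **logP** — the sum over residues of Wimley–White whole-residue
  water/octanol transfer free energies (kcal/mol).  The bundled scale is
  stored *hydrophobic-positive* (the negative of the published
  water->octanol transfer energies) with neutral histidine; this is the
  orientation that reproduces the full-space centre of -1.62 kcal/mol.
* **pI** — the pH at which the Henderson–Hasselbalch net charge vanishes,
  found by bisection with an EMBOSS-style pKa set.  This is a classical
  calculator, not a learned predictor.

A curated descriptor panel (aromaticity, charge, composition classes,
binding index, van der Waals volume classes) feeds the attribution models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, FormatError, SequenceError
from .peptide_space import AA_INDEX, AMINO_ACIDS, Q, validate_sequence

__all__ = [
    "load_hydrophilicity_scale",
    "load_pka_set",
    "ap_from_sasa",
    "classify_ap",
    "logp",
    "net_charge",
    "isoelectric_point",
    "isoelectric_points",
    "aromatic_count",
    "boman_index",
    "descriptor_vector",
    "descriptor_frame",
    "PeptideDescriptorizer",
    "interval_proportions",
    "IntervalProportions",
    "load_property_table",
    "PropertyTable",
    "full_space_logp",
    "AROMATIC_RESIDUES",
    "DESCRIPTOR_KEYS",
]

AROMATIC_RESIDUES = frozenset("FHWY")

# Composition classes used for descriptor fractions (documented partition):
HYDROPHOBIC_CLASS = frozenset("ACFILMPVW")
CHARGED_CLASS = frozenset("DEHKR")
POLAR_CLASS = frozenset("GNQSTY")

# Normalised van der Waals volume classes (Dubchak CTD grouping):
VDW_SMALL = frozenset("GASCTPD")   # 0 - 2.78
VDW_MEDIUM = frozenset("NVEQIL")   # 2.95 - 4.0
VDW_LARGE = frozenset("MHKFRYW")   # 4.03 - 8.08

# Radzicka & Wolfenden side-chain transfer free energies (kcal/mol) used for
# the Boman-style protein-binding index (proline undetermined, set to 0).
_BINDING_SCALE = {
    "L": 4.92, "I": 4.92, "V": 4.04, "F": 2.98, "M": 2.35, "W": 2.33,
    "A": 1.81, "C": 1.28, "G": 0.94, "Y": -0.14, "T": -2.57, "S": -3.40,
    "H": -4.66, "Q": -5.54, "K": -5.55, "N": -6.64, "E": -6.81, "D": -8.72,
    "R": -14.92, "P": 0.0,
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("udpep.data").joinpath(name)))


def load_hydrophilicity_scale(path: str | Path | None = None) -> dict[str, float]:
    """Load the bundled hydrophobic-positive Wimley–White octanol scale."""
    path = Path(path) if path else _data_path("wimley_white_octanol.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    scale = dict(zip(df["residue"], df["value"].astype(float)))
    missing = set(AMINO_ACIDS) - scale.keys()
    if missing:
        raise FormatError(f"hydrophilicity scale misses residues {sorted(missing)}")
    return scale


@dataclass(frozen=True)
class PkaSet:
    """Ionisable groups: name -> (pKa, sign); termini keyed 'nterm'/'cterm'."""

    groups: Mapping[str, tuple[float, int]]

    def __post_init__(self) -> None:
        for name, (pka, sign) in self.groups.items():
            if not 0.0 < pka < 14.0:
                raise DomainError(f"pKa of {name} must lie in (0, 14), got {pka}")
            if sign not in (-1, 1):
                raise DomainError(f"sign of {name} must be +-1")


def load_pka_set(path: str | Path | None = None) -> PkaSet:
    """Load the bundled EMBOSS-style pKa table."""
    path = Path(path) if path else _data_path("pka_emboss.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    return PkaSet({r.group: (float(r.pka), int(r.sign)) for r in df.itertuples()})


_SCALE = load_hydrophilicity_scale()
_SCALE_VEC = np.array([_SCALE[a] for a in AMINO_ACIDS])
_PKA = load_pka_set()
_BINDING_VEC = np.array([_BINDING_SCALE[a] for a in AMINO_ACIDS])
_AROM_VEC = np.array([a in AROMATIC_RESIDUES for a in AMINO_ACIDS], dtype=float)


# ---------------------------------------------------------------------------
# AP

def ap_from_sasa(sasa_initial: float, sasa_final: float) -> float:
    """Aggregation propensity = SASA_initial / SASA_final."""
    if sasa_initial <= 0 or sasa_final <= 0:
        raise DomainError("SASA values must be positive")
    return float(sasa_initial) / float(sasa_final)


def classify_ap(ap: float) -> int:
    """Bin AP into class 0 [1, 1.5), class 1 [1.5, 2), class 2 [2, 2.5].

    Values above 2.5 are clamped into class 2 with a warning; values below 1
    are outside the model's convention and rejected.
    """
    if ap < 1.0:
        raise DomainError(f"AP {ap} is below the model floor of 1")
    if ap > 2.5:
        warnings.warn(f"AP {ap} exceeds 2.5; clamped to class 2", stacklevel=2)
        return 2
    if ap < 1.5:
        return 0
    if ap < 2.0:
        return 1
    return 2


def classify_ap_array(ap: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_ap` (same binning and clamping rules)."""
    ap = np.asarray(ap, dtype=float)
    if np.any(ap < 1.0):
        raise DomainError("AP values below 1 are outside the model convention")
    if np.any(ap > 2.5):
        warnings.warn("AP values above 2.5 clamped to class 2", stacklevel=2)
    return np.clip(np.digitize(ap, [1.5, 2.0]), 0, 2).astype(int)


# ---------------------------------------------------------------------------
# logP

def logp(seq: str, scale: Mapping[str, float] | None = None) -> float:
    """Sum of per-residue transfer free energies (additive over residues)."""
    validate_sequence(seq)
    scale = scale if scale is not None else _SCALE
    try:
        return float(sum(scale[ch] for ch in seq))
    except KeyError as exc:
        raise SequenceError(f"residue {exc.args[0]!r} missing from the scale") from None


def full_space_logp(k: int = 4) -> np.ndarray:
    """logP of every k-peptide, in lexicographic enumeration order.

    Built by repeated outer sums over the residue scale, which is exactly the
    enumeration of all 20**k sums (index arithmetic matches
    :func:`udpep.peptide_space.enumerate_space`).
    """
    if not 1 <= k <= 6:
        raise DomainError("k must lie in [1, 6]")
    acc = _SCALE_VEC
    for _ in range(k - 1):
        acc = np.add.outer(acc, _SCALE_VEC).ravel()
    return acc


# ---------------------------------------------------------------------------
# charge and pI

def _group_counts(seq: str) -> dict[str, int]:
    counts = {g: 0 for g in _PKA.groups}
    counts["nterm"] = 1
    counts["cterm"] = 1
    for ch in seq:
        if ch in counts:
            counts[ch] += 1
    return counts


def net_charge(seq: str, ph: float = 7.0, pka: PkaSet | None = None) -> float:
    """Henderson–Hasselbalch net charge at ``ph`` including free termini.

    Basic groups contribute +1/(1+10^(pH-pKa)), acidic groups
    -1/(1+10^(pKa-pH)); strictly non-increasing in pH.
    """
    validate_sequence(seq)
    if not 0.0 <= ph <= 14.0:
        raise DomainError(f"pH must lie in [0, 14], got {ph}")
    pka = pka or _PKA
    total = 0.0
    counts = {g: 0 for g in pka.groups}
    counts["nterm"] = counts.get("nterm", 0) + 1
    counts["cterm"] = counts.get("cterm", 0) + 1
    for ch in seq:
        if ch in counts:
            counts[ch] += 1
    for name, (val, sign) in pka.groups.items():
        c = counts.get(name, 0)
        if not c:
            continue
        if sign > 0:
            total += c / (1.0 + 10.0 ** (ph - val))
        else:
            total -= c / (1.0 + 10.0 ** (val - ph))
    return total


def _charge_curve(count_matrix: np.ndarray, ph: np.ndarray, pka: PkaSet) -> np.ndarray:
    """Vectorised net charge for (n, n_groups) counts at per-peptide pH."""
    names = list(pka.groups)
    total = np.zeros(count_matrix.shape[0])
    for gi, name in enumerate(names):
        val, sign = pka.groups[name]
        c = count_matrix[:, gi]
        if sign > 0:
            total += c / (1.0 + 10.0 ** (ph - val))
        else:
            total -= c / (1.0 + 10.0 ** (val - ph))
    return total


def isoelectric_point(seq: str, pka: PkaSet | None = None, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes (bisection on [0, 14]).

    The free termini guarantee one positive and one negative group, so the
    monotone charge curve has a unique root.
    """
    return float(isoelectric_points([seq], pka=pka, tol=tol)[0])


def isoelectric_points(
    sequences: Sequence[str], pka: PkaSet | None = None, tol: float = 1e-4, max_iter: int = 100
) -> np.ndarray:
    """Vectorised bisection pI for many peptides at once."""
    pka = pka or _PKA
    names = list(pka.groups)
    counts = np.zeros((len(sequences), len(names)))
    for r, seq in enumerate(sequences):
        validate_sequence(seq)
        gc = {g: 0 for g in names}
        gc["nterm"] = gc.get("nterm", 0) + 1
        gc["cterm"] = gc.get("cterm", 0) + 1
        for ch in seq:
            if ch in gc:
                gc[ch] += 1
        counts[r] = [gc[g] for g in names]
    lo = np.zeros(len(sequences))
    hi = np.full(len(sequences), 14.0)
    # fixed-depth bisection: 60 halvings shrink the bracket to ~1e-17 pH,
    # far below tol even where the charge curve is steep near the root
    for _ in range(min(max_iter, 60)):
        mid = 0.5 * (lo + hi)
        charge = _charge_curve(counts, mid, pka)
        pos = charge > 0.0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    out = 0.5 * (lo + hi)
    assert np.all(np.abs(_charge_curve(counts, out, pka)) < tol)
    return out


# ---------------------------------------------------------------------------
# descriptors

def aromatic_count(seq: str) -> int:
    """Number of aromatic residues (F, H, W, Y)."""
    validate_sequence(seq)
    return sum(ch in AROMATIC_RESIDUES for ch in seq)


def boman_index(seq: str) -> float:
    """Binding-potential index: minus the mean per-residue solubility value."""
    validate_sequence(seq)
    return -float(np.mean([_BINDING_SCALE[ch] for ch in seq]))


DESCRIPTOR_KEYS: tuple[str, ...] = (
    "aromatic_count",
    "net_charge",
    "logp",
    "pi",
    "frac_hydrophobic",
    "frac_polar",
    "frac_charged",
    "boman_index",
    "vdw_frac_small",
    "vdw_frac_medium",
    "vdw_frac_large",
)


def descriptor_vector(
    seq: str, ph: float = 7.0, keys: Sequence[str] | None = None
) -> dict[str, float]:
    """Deterministic descriptor map for one peptide; key order is fixed."""
    requested = tuple(keys) if keys is not None else DESCRIPTOR_KEYS
    unknown = set(requested) - set(DESCRIPTOR_KEYS)
    if unknown:
        raise ConfigError(f"unknown descriptor keys: {sorted(unknown)}")
    validate_sequence(seq)
    k = len(seq)
    full = {
        "aromatic_count": float(aromatic_count(seq)),
        "net_charge": net_charge(seq, ph),
        "logp": logp(seq),
        "pi": isoelectric_point(seq),
        "frac_hydrophobic": sum(c in HYDROPHOBIC_CLASS for c in seq) / k,
        "frac_polar": sum(c in POLAR_CLASS for c in seq) / k,
        "frac_charged": sum(c in CHARGED_CLASS for c in seq) / k,
        "boman_index": boman_index(seq),
        "vdw_frac_small": sum(c in VDW_SMALL for c in seq) / k,
        "vdw_frac_medium": sum(c in VDW_MEDIUM for c in seq) / k,
        "vdw_frac_large": sum(c in VDW_LARGE for c in seq) / k,
    }
    return {key: full[key] for key in requested}


def descriptor_frame(sequences: Sequence[str], ph: float = 7.0) -> pd.DataFrame:
    """Descriptor table for many peptides (vectorised where it matters)."""
    seqs = list(sequences)
    idx = np.array([[AA_INDEX[c] for c in s] for s in seqs]) if seqs else np.zeros((0, 0), int)
    k = idx.shape[1] if seqs else 0

    def frac(members: frozenset) -> np.ndarray:
        vec = np.array([a in members for a in AMINO_ACIDS], dtype=float)
        return vec[idx].sum(axis=1) / k

    df = pd.DataFrame(
        {
            "aromatic_count": _AROM_VEC[idx].sum(axis=1),
            "net_charge": [net_charge(s, ph) for s in seqs],
            "logp": _SCALE_VEC[idx].sum(axis=1),
            "pi": isoelectric_points(seqs),
            "frac_hydrophobic": frac(HYDROPHOBIC_CLASS),
            "frac_polar": frac(POLAR_CLASS),
            "frac_charged": frac(CHARGED_CLASS),
            "boman_index": -_BINDING_VEC[idx].mean(axis=1),
            "vdw_frac_small": frac(VDW_SMALL),
            "vdw_frac_medium": frac(VDW_MEDIUM),
            "vdw_frac_large": frac(VDW_LARGE),
        },
        index=pd.Index(seqs, name="sequence"),
    )
    return df


class PeptideDescriptorizer:
    """Sklearn-style transformer: sequences -> descriptor matrix.

    Parameters
    ----------
    ph : pH at which the charge descriptor is evaluated.
    keys : descriptor subset (default: the full curated panel).
    """

    def __init__(self, ph: float = 7.0, keys: Sequence[str] | None = None):
        self.ph = ph
        self.keys = keys

    def get_params(self, deep: bool = True) -> dict:
        return {"ph": self.ph, "keys": self.keys}

    def set_params(self, **params) -> "PeptideDescriptorizer":
        for k, v in params.items():
            if k not in {"ph", "keys"}:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: Iterable[str], y=None) -> "PeptideDescriptorizer":
        keys = tuple(self.keys) if self.keys is not None else DESCRIPTOR_KEYS
        unknown = set(keys) - set(DESCRIPTOR_KEYS)
        if unknown:
            raise ConfigError(f"unknown descriptor keys: {sorted(unknown)}")
        self.feature_names_ = keys
        return self

    def transform(self, X: Iterable[str]) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            raise RuntimeError("transformer is not fitted")
        df = descriptor_frame(list(X), ph=self.ph)
        return df[list(self.feature_names_)].to_numpy()

    def fit_transform(self, X: Iterable[str], y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names_, dtype=object)


# ---------------------------------------------------------------------------
# diagnostics and ingest

@dataclass(frozen=True)
class IntervalProportions:
    """Per-bin fractions plus separately reported under/overflow mass."""

    edges: tuple[float, ...]
    fractions: tuple[float, ...]
    underflow: float
    overflow: float

    @property
    def total(self) -> float:
        return sum(self.fractions) + self.underflow + self.overflow


def interval_proportions(values: Sequence[float], edges: Sequence[float]) -> IntervalProportions:
    """Fraction of values in each [e_i, e_{i+1}) bin; totals sum to one."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise DomainError("empty value list")
    e = np.asarray(list(edges), dtype=float)
    if e.size < 2 or np.any(np.diff(e) <= 0):
        raise DomainError("edges must be strictly increasing with >= 2 entries")
    under = float(np.mean(v < e[0]))
    over = float(np.mean(v >= e[-1]))
    inner = np.histogram(v[(v >= e[0]) & (v < e[-1])], bins=e)[0] / v.size
    return IntervalProportions(tuple(e), tuple(inner.tolist()), under, over)


@dataclass(frozen=True)
class PropertyTable:
    """Validated property records plus an ingest report."""

    records: pd.DataFrame
    n_rejected: int
    rejected_rows: tuple[int, ...]
    n_duplicates: int


def load_property_table(path: str | Path) -> PropertyTable:
    """Read a 'sequence,ap,logp,pi'-style CSV, validating sequences.

    Rows with invalid sequences are dropped and counted; duplicate sequences
    are flagged but kept.  At least one of ap/logp/pi must be present.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "sequence" not in df.columns:
        raise FormatError(f"{path} lacks a 'sequence' header (found {list(df.columns)})")
    props = [c for c in ("ap", "logp", "pi") if c in df.columns]
    if not props:
        raise FormatError(f"{path} must contain at least one of ap/logp/pi columns")
    for col in props:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"non-numeric value in column {col!r} at data row {row}")
        df[col] = pd.to_numeric(df[col])
    rejected = []
    for i, s in enumerate(df["sequence"].astype(str)):
        try:
            validate_sequence(s)
        except SequenceError:
            rejected.append(i)
    keep = df.drop(index=df.index[rejected]).reset_index(drop=True)
    n_dup = int(keep["sequence"].duplicated().sum())
    return PropertyTable(keep, len(rejected), tuple(rejected), n_dup)
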