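"""Catalog-level scoring of predicted complexes against a reference.

Given references ``R = {N_1..N_n}`` and predictions ``P = {M_1..M_m}``, with
``t_ij = |N_i ∩ M_j|``:

* ``Sn  = Σ_i max_j t_ij / Σ_i |N_i|`` — clustering-wise sensitivity;
* ``PPV = Σ_j max_i t_ij / Σ_j Σ_i t_ij`` — positive predictive value
  (biased downward for overlapping predictions, by construction);
* ``ACC = sqrt(Sn · PPV)`` — geometric accuracy;
* ``Fraction`` — share of references matched by at least one prediction with
  overlap score OS ≥ 0.25;
* ``MMR`` — total OS weight of a maximum one-to-one bipartite matching between
  references and predictions (edges where OS > 0.25), divided by ``|R|``;
* composite = ACC + Fraction + MMR.

The maximum-weight matching is solved exactly with
:func:`scipy.optimize.linear_sum_assignment`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .postprocess import overlap_score

__all__ = [
    "ComplexCatalog",
    "EvaluationReport",
    "confusion_matrix",
    "accuracy",
    "fraction",
    "mmr",
    "composite",
    "evaluate",
]

MATCH_THRESHOLD = 0.25


@dataclass(frozen=True)
class ComplexCatalog:
    """A named list of protein complexes (reference or predicted)."""

    complexes: tuple[frozenset[str], ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.complexes) != len(self.names):
            raise ValueError("complexes and names differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("catalog names must be unique")
        if any(not c for c in self.complexes):
            raise ValueError("catalog complexes must be nonempty")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    @classmethod
    def from_sets(
        cls, complexes: Iterable[Iterable[str]], names: Sequence[str] | None = None
    ) -> "ComplexCatalog":
        sets = tuple(frozenset(c) for c in complexes)
        if names is None:
            names = tuple(f"C{i + 1:04d}" for i in range(len(sets)))
        return cls(complexes=sets, names=tuple(names))

    @classmethod
    def from_file(
        cls, path: str | Path, named: bool = False, min_size: int = 1
    ) -> "ComplexCatalog":
        """Load a one-complex-per-line membership file.

        With ``named=True`` the first column is the complex name.  Complexes
        smaller than *min_size* are dropped (reference catalogs conventionally
        use ``min_size=3``).
        """
        sets, names = [], []
        with Path(path).open() as fh:
            for i, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split()
                if named:
                    name, members = cols[0], cols[1:]
                else:
                    name, members = f"C{i:04d}", cols
                if len(members) < min_size:
                    continue
                sets.append(frozenset(members))
                names.append(name)
        return cls(complexes=tuple(sets), names=tuple(names))

    @classmethod
    def load_reference(cls, path: str | Path, named: bool = False) -> "ComplexCatalog":
        """Reference catalog loader: complexes with fewer than 3 members are dropped."""
        cat = cls.from_file(path, named=named, min_size=3)
        if len(cat) == 0:
            raise ValueError(f"{path}: no reference complexes of size >= 3")
        return cat


@dataclass(frozen=True)
class EvaluationReport:
    sn: float
    ppv: float
    acc: float
    fraction: float
    mmr: float

    @property
    def composite(self) -> float:
        return self.acc + self.fraction + self.mmr

    def to_tsv(self) -> str:
        header = "sn\tppv\tacc\tfraction\tmmr\tcomposite"
        row = "\t".join(
            f"{x:.6f}"
            for x in (self.sn, self.ppv, self.acc, self.fraction, self.mmr, self.composite)
        )
        return f"{header}\n{row}\n"


def confusion_matrix(ref: ComplexCatalog, pred: ComplexCatalog) -> np.ndarray:
    """``t[i, j] = |N_i ∩ M_j|`` for every reference i and prediction j."""
    t = np.zeros((len(ref), len(pred)), dtype=np.int64)
    for i, n in enumerate(ref.complexes):
        for j, m in enumerate(pred.complexes):
            t[i, j] = len(n & m)
    return t


def accuracy(ref: ComplexCatalog, pred: ComplexCatalog) -> tuple[float, float, float]:
    """``(Sn, PPV, ACC)``; an empty prediction catalog scores (0, 0, 0)."""
    if len(ref) == 0:
        raise ValueError("empty reference catalog")
    if len(pred) == 0:
        return 0.0, 0.0, 0.0
    t = confusion_matrix(ref, pred)
    sn = t.max(axis=1).sum() / sum(len(c) for c in ref.complexes)
    total = t.sum()
    ppv = (t.max(axis=0).sum() / total) if total > 0 else 0.0
    return float(sn), float(ppv), float(np.sqrt(sn * ppv))


def _os_matrix(ref: ComplexCatalog, pred: ComplexCatalog) -> np.ndarray:
    m = np.zeros((len(ref), len(pred)))
    for i, r in enumerate(ref.complexes):
        for j, p in enumerate(pred.complexes):
            m[i, j] = overlap_score(r, p)
    return m


def fraction(
    ref: ComplexCatalog, pred: ComplexCatalog, threshold: float = MATCH_THRESHOLD
) -> float:
    """Share of references matched by some prediction at OS ≥ *threshold*."""
    if len(ref) == 0:
        raise ValueError("empty reference catalog")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if len(pred) == 0:
        return 0.0
    os_mat = _os_matrix(ref, pred)
    return float((os_mat.max(axis=1) >= threshold).sum() / len(ref))


def mmr(
    ref: ComplexCatalog, pred: ComplexCatalog, threshold: float = MATCH_THRESHOLD
) -> float:
    """Maximum matching ratio.

    A bipartite graph links every (reference, prediction) pair with
    OS > *threshold*, weighted by OS; the value is the total weight of a
    maximum-weight one-to-one matching divided by ``|R|``.
    """
    if len(ref) == 0:
        raise ValueError("empty reference catalog")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if len(pred) == 0:
        return 0.0
    w = _os_matrix(ref, pred)
    w[w <= threshold] = 0.0
    rows, cols = linear_sum_assignment(w, maximize=True)
    return float(w[rows, cols].sum() / len(ref))


def composite(report: EvaluationReport) -> float:
    return report.composite


def evaluate(
    ref: ComplexCatalog, pred: ComplexCatalog, match_threshold: float = MATCH_THRESHOLD
) -> EvaluationReport:
    """Full report: Sn, PPV, ACC, Fraction, MMR (and composite)."""
    sn, ppv, acc = accuracy(ref, pred)
    return EvaluationReport(
        sn=sn,
        ppv=ppv,
        acc=acc,
        fraction=fraction(ref, pred, match_threshold),
        mmr=mmr(ref, pred, match_threshold),
    )
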