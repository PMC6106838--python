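"""Merging, removal, and size filtering of candidate clusters.

Two candidate clusters are compared with the overlap score

    OS(A, B) = |A ∩ B|² / (|A| · |B|),

a symmetric match statistic in [0, 1] that equals 1 only for identical sets.
Candidates whose pairwise OS reaches the merge threshold ω are unioned; at the
default ω = 1 this is exactly deduplication.  Complexes smaller than
``min_size`` (default 3) are then dropped — a shared pair of proteins already
scores OS = 0.25 against any size-2 "complex", so tiny clusters would match
references essentially at random.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["PredictionSet", "overlap_score", "merge_and_filter", "read_complexes", "write_complexes"]


def overlap_score(a: Iterable[str], b: Iterable[str]) -> float:
    """``|A∩B|² / (|A||B|)`` for nonempty protein sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap score undefined for empty sets")
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


@dataclass(frozen=True)
class PredictionSet:
    """Final predicted complexes, deterministically ordered."""

    complexes: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)


def _canonical_order(complexes: Iterable[frozenset[str]]) -> tuple[frozenset[str], ...]:
    return tuple(sorted(complexes, key=lambda c: (-len(c), tuple(sorted(c)))))


def merge_and_filter(
    candidates: Sequence[Iterable[str]],
    omega: float = 1.0,
    min_size: int = 3,
) -> PredictionSet:
    """Single forward merge pass at threshold ω, then the minimum-size filter.

    Scanning candidates in order, each survivor absorbs (set union) every later
    candidate whose OS against its *current* members reaches ω.  At ω = 1 the
    result is order-independent deduplication; at ω < 1 candidate order is the
    convention.
    """
    if not (0.0 < omega <= 1.0):
        raise ValueError(f"omega must lie in (0, 1], got {omega!r}")
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size!r}")
    clusters: list[set[str]] = [set(c) for c in candidates if c]
    i = 0
    while i < len(clusters):
        j = i + 1
        while j < len(clusters):
            if overlap_score(clusters[i], clusters[j]) >= omega:
                clusters[i] |= clusters[j]
                del clusters[j]
            else:
                j += 1
        i += 1
    kept = [frozenset(c) for c in clusters if len(c) >= min_size]
    return PredictionSet(complexes=_canonical_order(kept))


def write_complexes(complexes: Iterable[Iterable[str]], path: str | Path) -> None:
    """One complex per line, tab-separated sorted member identifiers."""
    ordered = _canonical_order(frozenset(c) for c in complexes)
    with Path(path).open("w") as fh:
        for c in ordered:
            fh.write("\t".join(sorted(c)) + "\n")


def read_complexes(path: str | Path) -> list[frozenset[str]]:
    """Read a one-complex-per-line, whitespace-separated membership file."""
    out = []
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            out.append(frozenset(line.split()))
    return out
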