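"""Canonical standardization of microsatellite motifs.

A repeat motif is an arbitrary rotation of the repeated word, read from an
arbitrary strand: ``AG``, ``GA``, ``TC`` and ``CT`` all describe the same
dinucleotide repeat.  Standardization maps every motif to one canonical
representative of its equivalence class:

* *partial* standardization canonicalizes under cyclic rotation only;
* *complete* standardization canonicalizes under rotation **and** reverse
  complementation.

The canonical representative is pinned as the lexicographically smallest
string (``A < C < G < T``) of the orbit, which makes ``AG`` the name of the
{AG, GA, TC, CT} class.  Only *primitive* motifs (minimal period equal to
their length) are admitted; ``ATAT`` is a rotation of two copies of ``AT``
and is reported via its primitive root.

Complete standardization of all primitive motifs yields exactly
2, 4, 10, 33, 102 and 350 classes for motif lengths 1..6.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "CanonicalMotif",
    "NonPrimitiveMotifError",
    "primitive_root",
    "is_primitive",
    "reverse_complement",
    "partial_standardize",
    "complete_standardize",
    "enumerate_classes",
]

_BASES = "ACGT"
_RC = str.maketrans("ACGT", "TGCA")


class NonPrimitiveMotifError(ValueError):
    """Raised for motifs whose minimal period is shorter than their length."""

    def __init__(self, motif: str, root: str):
        self.motif = motif
        self.root = root
        super().__init__(
            f"motif {motif!r} is not primitive; its primitive root is {root!r}"
        )


@dataclass(frozen=True)
class CanonicalMotif:
    """A completely standardized motif class."""

    motif_class: str
    motif_length: int

    def __post_init__(self) -> None:
        if len(self.motif_class) != self.motif_length:
            raise ValueError("motif_length must equal len(motif_class)")


def _validate(motif: str) -> None:
    if not motif or len(motif) > 6:
        raise ValueError(f"motif length must be 1..6, got {motif!r}")
    if any(b not in _BASES for b in motif):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")


def primitive_root(motif: str) -> str:
    """Shortest word whose tandem repetition equals ``motif``."""
    n = len(motif)
    for d in range(1, n + 1):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return motif[:d]
    return motif  # pragma: no cover - unreachable


def is_primitive(motif: str) -> bool:
    return primitive_root(motif) == motif


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def partial_standardize(motif: str) -> str:
    """Lexicographically smallest rotation of ``motif`` (strand kept)."""
    _validate(motif)
    if not is_primitive(motif):
        raise NonPrimitiveMotifError(motif, primitive_root(motif))
    return min(_rotations(motif))


def complete_standardize(motif: str) -> CanonicalMotif:
    """Smallest string over all rotations of ``motif`` and of its reverse
    complement."""
    _validate(motif)
    if not is_primitive(motif):
        raise NonPrimitiveMotifError(motif, primitive_root(motif))
    best = min(min(_rotations(motif)), min(_rotations(reverse_complement(motif))))
    return CanonicalMotif(best, len(best))


@lru_cache(maxsize=None)
def enumerate_classes(k: int) -> frozenset[CanonicalMotif]:
    """All canonical classes of primitive motifs of length ``k`` (1..6)."""
    if not 1 <= k <= 6:
        raise ValueError(f"k must be 1..6, got {k}")
    out = set()
    for tup in itertools.product(_BASES, repeat=k):
        m = "".join(tup)
        if is_primitive(m):
            out.add(complete_standardize(m))
    return frozenset(out)
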