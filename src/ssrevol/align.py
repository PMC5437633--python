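"""Seed-and-extend local alignment with Karlin-Altschul E-values.

A compact homology-search engine for flank-based locus mapping: exact-match
word seeds (default word size 11) are looked up in a sorted k-mer index of
the subject sequences, seeds falling on the same diagonal band satisfy a
two-hit rule, and each qualifying band is extended with a banded affine-gap
local alignment (numba kernel).  Both strands are searched.

Hard-masked tract characters (``X``) are forbidden in match/mismatch
columns: the substitution score of any column involving ``X`` is a large
negative sentinel, so optimal alignments bridge masked tracts with gaps and
no reported column ever pairs a mask character with anything.  ``N`` never
matches but may sit in a mismatch column.

E-values use the ungapped Karlin-Altschul approximation
``E = K * m * n * exp(-lambda * S)`` with ``lambda`` solved exactly for the
pinned +2/-3 scoring against a uniform background and ``K`` fixed at 0.3;
the search-space product uses raw lengths.  Hits are only ever thresholded
at 1e-10, far from the approximation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "AlignmentParams",
    "AlignmentHit",
    "SubjectIndex",
    "karlin_lambda",
    "search",
    "filter_hits",
    "passes_filters",
]

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
_CODE[ord("X")] = 5
_CODE[ord("x")] = 5
for lo, up in zip(b"acgt", b"ACGT"):
    _CODE[lo] = _CODE[up]

_RC = str.maketrans("ACGTNXacgtnx", "TGCANXtgcanx")

_BIG_NEG = -100_000  # forbids mask characters in substitution columns


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class AlignmentParams:
    word_size: int = 13
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    band: int = 32
    karlin_k: float = 0.3
    min_query_cover: float = 50.0
    min_identity: float = 70.0
    max_evalue: float = 1e-10
    max_bands_per_subject: int = 8
    max_extensions_per_strand: int = 16
    max_kmer_occurrences: int = 200


@dataclass
class AlignmentHit:
    """One local alignment between a query and a named subject sequence."""

    query_id: str
    subject_id: str
    subject_start: int
    subject_end: int
    query_start: int
    query_end: int
    strand: str
    score: int
    matches: int
    aligned_columns: int
    query_length: int
    e_value: float
    bit_score: float

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.aligned_columns

    @property
    def query_cover(self) -> float:
        return 100.0 * (self.query_end - self.query_start) / self.query_length


@lru_cache(maxsize=None)
def karlin_lambda(match: int, mismatch: int) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1 (uniform bg)."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-9, 10.0))


@njit(cache=True)
def _banded_sw(q, w, off, bw, match, mismatch, gap_open, gap_extend):
    """Banded affine local alignment of q against window w.

    Query position i may align window position j with |j - (i + off)| <= bw.
    Returns (score, qstart, qend, wstart, wend, matches, columns),
    half-open coordinates.  Mask code 5 is forbidden in substitution columns.
    """
    n = q.shape[0]
    m = w.shape[0]
    width = 2 * bw + 1
    NEG = -10_000_000
    H = np.full((n + 1, width), NEG, dtype=np.int64)
    E = np.full((n + 1, width), NEG, dtype=np.int64)
    F = np.full((n + 1, width), NEG, dtype=np.int64)
    # ptr bits: 0 stop, 1 diag, 2 from E (gap in query axis), 3 from F
    PH = np.zeros((n + 1, width), dtype=np.uint8)
    PE = np.zeros((n + 1, width), dtype=np.uint8)  # 1 = extend
    PF = np.zeros((n + 1, width), dtype=np.uint8)
    # row 0: empty-prefix start points
    for d in range(width):
        j = 0 + off + d - bw
        if 0 <= j <= m:
            H[0, d] = 0
    best = 0
    bi = -1
    bd = -1
    for i in range(1, n + 1):
        for d in range(width):
            j = i + off + d - bw
            if j < 0 or j > m:
                continue
            # E: gap consuming window base j (from (i, j-1) -> d-1)
            e_val = NEG
            e_ptr = 0
            if d - 1 >= 0 and j >= 1:
                o = H[i, d - 1] - gap_open - gap_extend
                x = E[i, d - 1] - gap_extend
                if o >= x:
                    e_val = o
                else:
                    e_val = x
                    e_ptr = 1
            E[i, d] = e_val
            PE[i, d] = e_ptr
            # F: gap consuming query base i (from (i-1, j) -> d+1 in row i-1)
            f_val = NEG
            f_ptr = 0
            if d + 1 < width:
                o = H[i - 1, d + 1] - gap_open - gap_extend
                x = F[i - 1, d + 1] - gap_extend
                if o >= x:
                    f_val = o
                else:
                    f_val = x
                    f_ptr = 1
            F[i, d] = f_val
            PF[i, d] = f_ptr
            # H
            h = 0
            ptr = 0
            if j >= 1:
                qa = q[i - 1]
                wb = w[j - 1]
                if qa == 5 or wb == 5:
                    sub = _BIG_NEG
                elif qa == wb and qa < 4:
                    sub = match
                else:
                    sub = mismatch
                diag = H[i - 1, d] + sub
                if diag > h:
                    h = diag
                    ptr = 1
            if e_val > h:
                h = e_val
                ptr = 2
            if f_val > h:
                h = f_val
                ptr = 3
            H[i, d] = h
            PH[i, d] = ptr
            if h > best:
                best = h
                bi = i
                bd = d
    if bi < 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    d = bd
    qend = bi
    wend = bi + off + bd - bw
    matches = 0
    cols = 0
    state = 0  # 0 in H, 1 in E, 2 in F
    while True:
        j = i + off + d - bw
        if state == 0:
            ptr = PH[i, d]
            if ptr == 0:
                break
            if ptr == 1:
                cols += 1
                if q[i - 1] == w[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
            elif ptr == 2:
                state = 1
                continue
            else:
                state = 2
                continue
        elif state == 1:
            cols += 1
            ext = PE[i, d]
            d -= 1
            if ext == 0:
                state = 0
        else:
            cols += 1
            ext = PF[i, d]
            i -= 1
            d += 1
            if ext == 0:
                state = 0
    qstart = i
    wstart = i + off + d - bw
    return best, qstart, qend, wstart, wend, matches, cols


class SubjectIndex:
    """Sorted k-mer index over a set of named subject sequences."""

    def __init__(self, sequences: Mapping[str, str],
                 params: AlignmentParams | None = None):
        self.params = params or AlignmentParams()
        w = self.params.word_size
        self.names = list(sequences)
        self.seqs = {n: _encode(s) for n, s in sequences.items()}
        self.total_length = sum(len(s) for s in self.seqs.values())
        # concatenate with N spacers so no k-mer crosses a boundary
        parts = []
        self.offsets = {}
        pos = 0
        spacer = np.full(w, 4, dtype=np.uint8)
        for n in self.names:
            self.offsets[n] = pos
            parts.append(self.seqs[n])
            pos += len(self.seqs[n])
            parts.append(spacer)
            pos += w
        cat = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
        self._bounds = np.array(
            [(self.offsets[n], self.offsets[n] + len(self.seqs[n]))
             for n in self.names])
        if len(cat) >= w:
            valid = cat < 4
            codes = np.zeros(len(cat) - w + 1, dtype=np.int64)
            okay = np.ones(len(cat) - w + 1, dtype=bool)
            for t in range(w):
                codes = codes * 4 + cat[t:t + len(codes)]
                okay &= valid[t:t + len(codes)]
            self._kpos = np.flatnonzero(okay)
            kc = codes[self._kpos]
            order = np.argsort(kc, kind="stable")
            self._kpos = self._kpos[order]
            self._kcodes = kc[order]
        else:
            self._kpos = np.zeros(0, dtype=np.int64)
            self._kcodes = np.zeros(0, dtype=np.int64)

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._kcodes, code, side="left")
        hi = np.searchsorted(self._kcodes, code, side="right")
        return self._kpos[lo:hi]

    def locate(self, pos: int) -> tuple[str, int]:
        """Map a concatenated coordinate to (sequence name, offset)."""
        i = np.searchsorted(self._bounds[:, 0], pos, side="right") - 1
        return self.names[i], pos - int(self._bounds[i, 0])


def _low_complexity_words(q: np.ndarray, w: int) -> np.ndarray:
    """Mask of word positions whose w-mer is periodic with period <= 3.

    Tandem-repeat words occur in thousands of loci at once and would seed
    spurious extensions everywhere (the flanks, not the repeats, carry the
    homology signal); skipping them is the DUST-style convention.
    """
    n = len(q) - w + 1
    mask = np.zeros(n, dtype=bool)
    for p in (1, 2, 3):
        eq = (q[p:] == q[:-p]).astype(np.int64)
        c = np.concatenate(([0], np.cumsum(eq)))
        span = w - p
        run_ok = (c[span:] - c[:-span]) == span
        mask |= run_ok[:n]
    return mask


def _query_kmer_codes(q: np.ndarray, w: int):
    if len(q) < w:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    valid = q < 4
    codes = np.zeros(len(q) - w + 1, dtype=np.int64)
    okay = np.ones(len(q) - w + 1, dtype=bool)
    for t in range(w):
        codes = codes * 4 + q[t:t + len(codes)]
        okay &= valid[t:t + len(codes)]
    okay &= ~_low_complexity_words(q, w)
    qpos = np.flatnonzero(okay)
    return codes[qpos], qpos


def _search_strand(query_id: str, q: np.ndarray, strand: str,
                   subject: SubjectIndex, params: AlignmentParams
                   ) -> list[AlignmentHit]:
    w = params.word_size
    codes, qpos = _query_kmer_codes(q, w)
    if len(codes) == 0:
        return []
    lo = np.searchsorted(subject._kcodes, codes, side="left")
    hi = np.searchsorted(subject._kcodes, codes, side="right")
    counts = hi - lo
    keep = (counts > 0) & (counts <= params.max_kmer_occurrences)
    if not keep.any():
        return []
    lo, counts, qpos = lo[keep], counts[keep], qpos[keep]
    total = int(counts.sum())
    starts = np.repeat(lo, counts)
    within = np.arange(total) - np.repeat(
        np.cumsum(counts) - counts, counts)
    spos = subject._kpos[starts + within]
    diags = spos - np.repeat(qpos, counts)
    bands = diags // params.band
    uniq, counts = np.unique(bands, return_counts=True)
    qualifying = uniq[counts >= 2]  # two-hit rule
    if len(qualifying) == 0:
        return []
    order = np.argsort(-counts[counts >= 2])
    qualifying = qualifying[order]
    out: list[AlignmentHit] = []
    lam = karlin_lambda(params.match, params.mismatch)
    per_subject: dict[str, int] = {}
    n = len(q)
    n_extended = 0
    for band in qualifying.tolist():
        if n_extended >= params.max_extensions_per_strand:
            break
        sel = bands == band
        d0 = int(np.median(diags[sel]))
        anchor = int(spos[sel].min())
        sname, _ = subject.locate(anchor)
        if per_subject.get(sname, 0) >= params.max_bands_per_subject:
            continue
        per_subject[sname] = per_subject.get(sname, 0) + 1
        n_extended += 1
        sseq = subject.seqs[sname]
        soff = subject.offsets[sname]
        # subject window expected to cover query under diagonal d0
        pad = params.band + 8
        w0 = max(0, d0 - soff - pad)
        w1 = min(len(sseq), d0 - soff + n + pad)
        if w1 <= w0:
            continue
        window = sseq[w0:w1]
        off = (d0 - soff) - w0
        score, qs, qe, ws, we, matches, cols = _banded_sw(
            q, window, off, params.band, params.match, params.mismatch,
            params.gap_open, params.gap_extend)
        if score <= 0 or cols == 0:
            continue
        e_val = params.karlin_k * n * subject.total_length * math.exp(
            -lam * score)
        bit = (lam * score - math.log(params.karlin_k)) / math.log(2)
        if strand == "+":
            q0, q1 = qs, qe
        else:  # report query coordinates on the forward query
            q0, q1 = n - qe, n - qs
        out.append(AlignmentHit(
            query_id=query_id, subject_id=sname,
            subject_start=w0 + ws, subject_end=w0 + we,
            query_start=q0, query_end=q1, strand=strand, score=int(score),
            matches=int(matches), aligned_columns=int(cols), query_length=n,
            e_value=float(e_val), bit_score=float(bit)))
    return out


def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep the best-scoring hit among overlapping subject intervals."""
    hits = sorted(hits, key=lambda h: -h.score)
    kept: list[AlignmentHit] = []
    for h in hits:
        dup = any(k.subject_id == h.subject_id
                  and h.subject_start < k.subject_end
                  and h.subject_end > k.subject_start
                  for k in kept)
        if not dup:
            kept.append(h)
    return kept


def search(query_id: str, query_seq: str, subject: SubjectIndex,
           params: AlignmentParams | None = None) -> list[AlignmentHit]:
    """All local alignments of the query against the indexed subject set,
    both strands, sorted by bit score descending (unfiltered)."""
    params = params or subject.params
    q_fwd = _encode(query_seq)
    q_rev = _encode(revcomp(query_seq))
    hits = _search_strand(query_id, q_fwd, "+", subject, params)
    hits += _search_strand(query_id, q_rev, "-", subject, params)
    return sorted(_dedupe(hits), key=lambda h: -h.bit_score)


def passes_filters(hit: AlignmentHit, params: AlignmentParams) -> bool:
    """Inclusive thresholds: cover >= 50, identity >= 70, E <= 1e-10."""
    return (hit.query_cover >= params.min_query_cover
            and hit.identity >= params.min_identity
            and hit.e_value <= params.max_evalue)


def filter_hits(hits: Sequence[AlignmentHit],
                params: AlignmentParams | None = None) -> list[AlignmentHit]:
    params = params or AlignmentParams()
    return [h for h in hits if passes_filters(h, params)]
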