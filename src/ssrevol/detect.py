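"""Imperfect microsatellite detection.

Scans DNA for tandem repeats of 1-6 nt motifs, tolerating single-base
interruptions (mismatches), in the style of SciRoKo's imperfect search.
The search semantics are pinned as this package's definition:

* A **seed** is a run of exact tandem copies of a primitive motif: at least
  3 copies, and at least 8 bases for 1-2 nt motifs.
* From a seed the locus is **extended in both directions**, scoring
  ``+match_score`` per base matching the expected motif phase and
  ``-mismatch_penalty`` per mismatching base (``N`` never matches).
  Extension stops when more than ``max_successive_mismatch`` consecutive
  mismatches occur, or when the running score would drop more than
  ``mismatch_penalty`` below its running maximum.  The locus is trimmed back
  to the farthest position attaining the maximal score.
* A mismatch consumes exactly one base; the phase for the following base is
  **re-synchronized**: among all rotations of the motif, the one giving the
  longest exact run immediately after the mismatch is adopted (ties prefer
  plain phase continuation, then the smallest rotation offset).  A single
  substitution, insertion or deletion therefore each cost one mismatch.
  Left extension applies the same rules to the reversed sequence with the
  reversed motif.
* A locus is reported iff its span is ``>= min_repeat_length`` **and** its
  score is ``>= min_score``.  Overlapping candidates are resolved by higher
  score, then shorter motif, then leftmost start, then motif string; the
  reported loci are non-overlapping.

Compound repeats (two reported loci closer than ``compound_max_distance``)
are excluded from genomic summaries by :func:`exclude_compounds`.
Coordinates are 0-based half-open in memory and 1-based inclusive in TSV
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import complete_standardize, is_primitive

__all__ = [
    "DetectionConfig",
    "MicrosatelliteLocus",
    "scan_sequence",
    "scan_genome",
    "exclude_compounds",
    "summarize_density",
    "summarize_cds",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds of the imperfect microsatellite search."""

    min_repeat_length: int = 15
    max_successive_mismatch: int = 3
    mismatch_penalty: int = 5
    match_score: int = 1
    min_score: int = 15
    compound_max_distance: int = 100
    motif_lengths: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

    def __post_init__(self) -> None:
        for name in ("min_repeat_length", "mismatch_penalty", "match_score",
                     "min_score"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_successive_mismatch < 0 or self.compound_max_distance < 0:
            raise ValueError("mismatch/compound limits must be >= 0")
        if not set(self.motif_lengths) <= {1, 2, 3, 4, 5, 6}:
            raise ValueError("motif_lengths must be a subset of 1..6")

    def seed_length(self, k: int) -> int:
        """Minimal exact tandem run (bases) that seeds a motif of length k."""
        return max(3 * k, 8) if k <= 2 else 3 * k


@dataclass
class MicrosatelliteLocus:
    """One detected tandem repeat (0-based half-open coordinates)."""

    chromosome: str
    start: int
    end: int
    motif: str
    standardized_motif: str
    repeat_length: int
    mismatch_count: int
    score: int

    @property
    def is_perfect(self) -> bool:
        return self.mismatch_count == 0

    @property
    def motif_length(self) -> int:
        return len(self.motif)


def _resync(seq: str, j: int, motif: str, cont_phase: int) -> int:
    """Phase for position ``j`` after a mismatch at ``j-1``.

    Picks the rotation offset maximizing the exact run starting at ``j``;
    ties prefer ``cont_phase`` then the smallest offset.
    """
    k = len(motif)
    if k == 1 or j >= len(seq):
        return cont_phase
    n = len(seq)
    best_phase, best_run = cont_phase, -1
    order = [cont_phase] + [p for p in range(k) if p != cont_phase]
    for p in order:
        run = 0
        while j + run < n and seq[j + run] == motif[(p + run) % k]:
            run += 1
        if run > best_run:
            best_phase, best_run = p, run
    return best_phase


def _extend(seq: str, i0: int, motif: str, cfg: DetectionConfig):
    """Walk right from ``i0`` (phase 0 of ``motif``) applying the pinned rules.

    Returns ``(best_len, best_score, mismatch_offsets)`` where offsets are
    relative to ``i0`` and restricted to the trimmed span.
    """
    k = len(motif)
    n = len(seq)
    phase = 0
    score = best = 0
    cur_len = best_len = 0
    consec = 0
    mism: list[int] = []
    i = i0
    while i < n:
        c = seq[i]
        if c == motif[phase]:
            score += cfg.match_score
            cur_len += 1
            consec = 0
            phase = (phase + 1) % k
            if score >= best:
                if score > best:
                    best = score
                best_len = cur_len  # rightmost position attaining the max
            i += 1
        else:
            if consec + 1 > cfg.max_successive_mismatch:
                break
            if best - (score - cfg.mismatch_penalty) > cfg.mismatch_penalty:
                break
            score -= cfg.mismatch_penalty
            cur_len += 1
            consec += 1
            mism.append(cur_len - 1)
            phase = _resync(seq, i + 1, motif, (phase + 1) % k)
            i += 1
    return best_len, best, [m for m in mism if m < best_len]


def _candidate_from_anchor(seq: str, rseq: str, s: int, motif: str,
                           cfg: DetectionConfig):
    """Bidirectional extension from an exact-run anchor at ``s``."""
    n = len(seq)
    r_len, r_score, r_mism = _extend(seq, s, motif, cfg)
    l_len, l_score, l_mism = _extend(rseq, n - s, motif[::-1], cfg)
    start = s - l_len
    end = s + r_len
    mm = len(r_mism) + len(l_mism)
    return start, end, r_score + l_score, mm


def _seed_anchors(seq: str, arr: np.ndarray, valid: np.ndarray,
                  cfg: DetectionConfig):
    """Yield ``(start, motif)`` for every maximal exact tandem run that seeds.

    Runs are located with the shifted-equality trick: positions where
    ``seq[i] == seq[i+k]`` chain into period-k runs.
    """
    n = len(seq)
    for k in cfg.motif_lengths:
        if n < cfg.seed_length(k):
            continue
        eq = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
        if not eq.any():
            continue
        # maximal runs of True in eq
        d = np.diff(eq.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if eq[0]:
            starts = np.concatenate(([0], starts))
        if eq[-1]:
            ends = np.concatenate((ends, [len(eq)]))
        min_eq = cfg.seed_length(k) - k
        for a, b in zip(starts, ends):
            if b - a < min_eq:
                continue
            motif = seq[a:a + k]
            if "N" in motif or not is_primitive(motif):
                continue
            yield int(a), motif


def resolve_overlaps(candidates):
    """Greedy non-overlap selection: higher score, shorter motif, leftmost
    start, then motif string.  ``candidates`` are
    ``(start, end, score, mismatch, motif)`` tuples."""
    chosen: list[tuple] = []
    taken: list[tuple[int, int]] = []
    for cand in sorted(candidates,
                       key=lambda c: (-c[2], len(c[4]), c[0], c[4])):
        s, e = cand[0], cand[1]
        if all(e <= ts or s >= te for ts, te in taken):
            chosen.append(cand)
            taken.append((s, e))
    chosen.sort(key=lambda c: c[0])
    return chosen


def scan_sequence(seq: str, config: DetectionConfig | None = None,
                  chromosome: str = "seq") -> list[MicrosatelliteLocus]:
    """Detect perfect and imperfect microsatellites in one sequence."""
    cfg = config or DetectionConfig()
    if not seq:
        return []
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = arr != ord("N")
    rseq = seq[::-1]

    seen: dict[tuple, tuple] = {}
    for s, motif in _seed_anchors(seq, arr, valid, cfg):
        start, end, score, mm = _candidate_from_anchor(seq, rseq, s, motif, cfg)
        if end - start < cfg.min_repeat_length or score < cfg.min_score:
            continue
        key = (start, end, len(motif), mm, score)
        if key not in seen or s < seen[key][0]:
            seen[key] = (s, motif)
    candidates = [(k[0], k[1], k[4], k[3], v[1]) for k, v in seen.items()]
    loci = []
    for start, end, score, mm, motif in resolve_overlaps(candidates):
        loci.append(MicrosatelliteLocus(
            chromosome=chromosome, start=start, end=end, motif=motif,
            standardized_motif=complete_standardize(motif).motif_class,
            repeat_length=end - start, mismatch_count=mm, score=score))
    return loci


def scan_genome(sequences: Mapping[str, str],
                config: DetectionConfig | None = None
                ) -> list[MicrosatelliteLocus]:
    """Scan every named sequence; loci are returned in genome order."""
    out: list[MicrosatelliteLocus] = []
    for name, seq in sequences.items():
        out.extend(scan_sequence(seq, config, chromosome=name))
    return out


def exclude_compounds(loci: Sequence[MicrosatelliteLocus],
                      config: DetectionConfig | None = None
                      ) -> tuple[list[MicrosatelliteLocus],
                                 list[MicrosatelliteLocus]]:
    """Drop compound microsatellites.

    Any pair of same-chromosome loci whose gap is strictly less than
    ``compound_max_distance`` removes *both* members.  Returns
    ``(retained, removed)`` with input order preserved.
    """
    cfg = config or DetectionConfig()
    removed_idx: set[int] = set()
    by_chrom: dict[str, list[tuple[int, MicrosatelliteLocus]]] = {}
    for i, loc in enumerate(loci):
        by_chrom.setdefault(loc.chromosome, []).append((i, loc))
    for entries in by_chrom.values():
        entries.sort(key=lambda t: t[1].start)
        for (i, a), (j, b) in zip(entries, entries[1:]):
            if b.start - a.end < cfg.compound_max_distance:
                removed_idx.update((i, j))
    retained = [l for i, l in enumerate(loci) if i not in removed_idx]
    removed = [l for i, l in enumerate(loci) if i in removed_idx]
    return retained, removed


def summarize_density(loci: Sequence[MicrosatelliteLocus],
                      sequence_lengths: Mapping[str, int]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-motif-length-class density summaries.

    Returns ``(genome_summary, per_chromosome)``.  Density is loci per Mb;
    ``imperfection_percent`` is the share of loci with at least one mismatch;
    ``percent_abundance`` sums to 100 over classes.
    """
    total_bases = sum(sequence_lengths.values())
    if total_bases <= 0:
        raise ValueError("zero-length genome")
    unknown = {l.chromosome for l in loci} - set(sequence_lengths)
    if unknown:
        raise ValueError(f"loci on unknown chromosomes: {sorted(unknown)}")

    def _summary(subset, bases):
        rows = []
        n_all = len(subset)
        for k in range(1, 7):
            sel = [l for l in subset if l.motif_length == k]
            n = len(sel)
            rows.append({
                "motif_length": k,
                "count": n,
                "density_per_mb": n / (bases / 1e6),
                "percent_abundance": 100.0 * n / n_all if n_all else 0.0,
                "imperfection_percent": (
                    100.0 * sum(l.mismatch_count > 0 for l in sel) / n
                    if n else 0.0),
                "mean_repeat_length": (
                    float(np.mean([l.repeat_length for l in sel]))
                    if n else float("nan")),
                "mean_mismatch": (
                    float(np.mean([l.mismatch_count for l in sel]))
                    if n else float("nan")),
            })
        return pd.DataFrame(rows)

    genome = _summary(loci, total_bases)
    chrom_frames = []
    for chrom, length in sequence_lengths.items():
        sub = [l for l in loci if l.chromosome == chrom]
        df = _summary(sub, length)
        df.insert(0, "chromosome", chrom)
        chrom_frames.append(df)
    per_chrom = pd.concat(chrom_frames, ignore_index=True)
    return genome, per_chrom


def summarize_cds(loci_per_gene: Mapping[str, Sequence[MicrosatelliteLocus]],
                  compound_removed: Sequence[MicrosatelliteLocus],
                  cds_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Summary of repeats detected on a CDS set.

    One row per motif-length class plus an ``overall`` row with gene-level
    counts: genes carrying at least one repeat, genes carrying a mismatched
    repeat, and the compound count (reported separately, as compounds are
    excluded from the per-class densities).
    """
    total_mb = sum(cds_lengths.values()) / 1e6
    if total_mb <= 0:
        raise ValueError("zero-length CDS set")
    all_loci = [l for loci in loci_per_gene.values() for l in loci]
    rows = []
    for k in range(1, 7):
        sel = [l for l in all_loci if l.motif_length == k]
        rows.append({
            "category": f"{k}-nt",
            "density_per_mb": len(sel) / total_mb,
            "count": len(sel),
        })
    rows.append({
        "category": "overall",
        "density_per_mb": len(all_loci) / total_mb,
        "count": len(all_loci),
    })
    df = pd.DataFrame(rows)
    df["genes_with_repeat"] = sum(
        1 for loci in loci_per_gene.values() if len(loci) > 0)
    df["genes_with_mismatched_repeat"] = sum(
        1 for loci in loci_per_gene.values()
        if any(l.mismatch_count > 0 for l in loci))
    df["compound_count"] = len(compound_removed)
    df["mean_mismatch"] = (float(np.mean([l.mismatch_count for l in all_loci]))
                           if all_loci else 0.0)
    df["mean_repeat_length"] = (
        float(np.mean([l.repeat_length for l in all_loci]))
        if all_loci else 0.0)
    return df
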