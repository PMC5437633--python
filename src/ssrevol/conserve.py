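"""Flank-based locus conservation mapping between genomes.

For each (sub)genome a **locus library** is built from its detected
microsatellites: every locus is extracted with up to 350 nt of flank on each
side and the repeat tract is hard-masked (``X``), so homology is decided by
flanking context only.  Mononucleotide loci, compound-flagged loci and loci
whose flanked windows overlap another window are excluded, and entries with
a qualifying non-self hit inside their own library are discarded as
non-unique.

Conservation of a progenitor locus in a derived (sub)genome is then decided
by searching the progenitor library against the derived genome's library
(library vs library), keeping hits that pass the inclusive filters
(query cover >= 50%, identity >= 70%, E <= 1e-10), allowing up to two
non-overlapping physical positions (whole-genome duplication), and
requiring reciprocal best-hit confirmation: the matched derived-genome
entry's own top qualifying hit must land back on the progenitor locus
window.  Verdicts are ``conserved``, ``lost`` (no qualifying hit) or
``ambiguous`` (more than two positions, or candidates without reciprocal
support); ambiguous loci are excluded from the conserved/(conserved+lost)
proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentHit, AlignmentParams, SubjectIndex, filter_hits, search
from .detect import MicrosatelliteLocus
from .motifs import CanonicalMotif

__all__ = [
    "LocusLibraryEntry",
    "ConservationRecord",
    "build_library",
    "self_uniqueness_filter",
    "search_genome",
    "search_library",
    "read_tabular_hits",
    "assign_conservation",
    "map_conservation",
    "conservation_proportions",
]

MASK_CHAR = "X"


@dataclass
class LocusLibraryEntry:
    """A masked, flanked locus used for cross-genome homology search."""

    locus_id: str
    source_genome: str
    chromosome: str
    locus_start: int
    locus_end: int
    window_start: int
    window_end: int
    sequence: str
    mask_start: int  # within sequence
    mask_end: int
    motif: str
    motif_class: str
    motif_length: int

    def overlaps_window(self, chrom: str, start: int, end: int) -> bool:
        return (chrom == self.chromosome and start < self.window_end
                and end > self.window_start)


@dataclass
class ConservationRecord:
    """Verdict for one progenitor locus in one derived (sub)genome."""

    locus_id: str
    motif_class: str
    motif_length: int
    status: str  # conserved | lost | ambiguous
    positions: list[tuple[str, int, int]] = field(default_factory=list)
    reciprocal_confirmed: bool = False


def build_library(loci: Sequence[MicrosatelliteLocus],
                  sequences: Mapping[str, str],
                  flank: int = 350,
                  source_genome: str = "genome") -> list[LocusLibraryEntry]:
    """Masked flanked entries for all eligible loci.

    ``loci`` must already be compound-excluded.  1-nt loci are dropped
    (homopolymer sequencing artefacts), flanks are truncated at sequence
    ends, and any two loci whose flanked windows overlap are both dropped.
    """
    windows = []
    for loc in loci:
        if loc.chromosome not in sequences:
            raise ValueError(f"unknown chromosome {loc.chromosome!r}")
        n = len(sequences[loc.chromosome])
        if not 0 <= loc.start < loc.end <= n:
            raise ValueError(f"locus {loc.start}-{loc.end} outside sequence "
                             f"{loc.chromosome!r} of length {n}")
        windows.append((max(0, loc.start - flank),
                        min(n, loc.end + flank), loc))
    # drop both members of any overlapping-window pair (same chromosome)
    dropped = set()
    by_chrom: dict[str, list[int]] = {}
    for i, (_, _, loc) in enumerate(windows):
        by_chrom.setdefault(loc.chromosome, []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: windows[i][0])
        for a, b in zip(idxs, idxs[1:]):
            if windows[b][0] < windows[a][1]:
                dropped.update((a, b))
    entries = []
    for i, (ws, we, loc) in enumerate(windows):
        if i in dropped or loc.motif_length == 1:
            continue
        seq = sequences[loc.chromosome]
        masked = (seq[ws:loc.start] + MASK_CHAR * (loc.end - loc.start)
                  + seq[loc.end:we])
        entries.append(LocusLibraryEntry(
            locus_id=f"{source_genome}|{loc.chromosome}:{loc.start}-{loc.end}",
            source_genome=source_genome, chromosome=loc.chromosome,
            locus_start=loc.start, locus_end=loc.end,
            window_start=ws, window_end=we, sequence=masked,
            mask_start=loc.start - ws, mask_end=loc.end - ws,
            motif=loc.motif, motif_class=loc.standardized_motif,
            motif_length=loc.motif_length))
    return entries


def _library_index(entries: Sequence[LocusLibraryEntry],
                   params: AlignmentParams) -> SubjectIndex:
    return SubjectIndex({e.locus_id: e.sequence for e in entries}, params)


def self_uniqueness_filter(entries: Sequence[LocusLibraryEntry],
                           params: AlignmentParams | None = None
                           ) -> tuple[list[LocusLibraryEntry],
                                      list[LocusLibraryEntry]]:
    """Discard entries with any qualifying non-self hit in their own library."""
    params = params or AlignmentParams()
    if len(entries) <= 1:
        return list(entries), []
    index = _library_index(entries, params)
    retained, discarded = [], []
    for e in entries:
        hits = filter_hits(search(e.locus_id, e.sequence, index, params),
                           params)
        if any(h.subject_id != e.locus_id for h in hits):
            discarded.append(e)
        else:
            retained.append(e)
    return retained, discarded


def search_genome(entry: LocusLibraryEntry,
                  subject: SubjectIndex,
                  params: AlignmentParams | None = None
                  ) -> list[AlignmentHit]:
    """Qualifying hits of one library entry against an indexed subject set
    (a genome or another library), sorted by bit score descending."""
    params = params or subject.params
    return filter_hits(search(entry.locus_id, entry.sequence, subject,
                              params), params)


def search_library(queries: Sequence[LocusLibraryEntry],
                   subject_entries: Sequence[LocusLibraryEntry],
                   params: AlignmentParams | None = None
                   ) -> dict[str, list[AlignmentHit]]:
    """Qualifying hits of every query entry against a subject library."""
    params = params or AlignmentParams()
    index = _library_index(subject_entries, params)
    return {q.locus_id: search_genome(q, index, params) for q in queries}


def read_tabular_hits(path, query_lengths: Mapping[str, int]
                      ) -> dict[str, list[AlignmentHit]]:
    """Adapter for external aligner output in 12-column tabular format
    (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore, 1-based inclusive coordinates).

    Real-genome runs may use an external search tool; the parsed hits plug
    into :func:`assign_conservation` exactly like in-repo search results.
    Hits are returned unfiltered, grouped by query id.
    """
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    out: dict[str, list[AlignmentHit]] = {}
    for r in df.itertuples():
        qlen = query_lengths[r.qseqid]
        s0, s1 = sorted((int(r.sstart), int(r.send)))
        strand = "+" if int(r.send) >= int(r.sstart) else "-"
        matches = int(round(float(r.pident) / 100.0 * int(r.length)))
        out.setdefault(r.qseqid, []).append(AlignmentHit(
            query_id=r.qseqid, subject_id=r.sseqid,
            subject_start=s0 - 1, subject_end=s1,
            query_start=int(r.qstart) - 1, query_end=int(r.qend),
            strand=strand, score=int(round(float(r.bitscore))),
            matches=matches, aligned_columns=int(r.length),
            query_length=qlen, e_value=float(r.evalue),
            bit_score=float(r.bitscore)))
    for hits in out.values():
        hits.sort(key=lambda h: -h.bit_score)
    return out


def assign_conservation(entry: LocusLibraryEntry,
                        hits: Sequence[AlignmentHit],
                        reciprocal_tops: Mapping[str, str],
                        subject_by_id: Mapping[str, LocusLibraryEntry],
                        max_positions: int = 2) -> ConservationRecord:
    """Fold qualifying hits into a conserved/lost/ambiguous verdict.

    ``reciprocal_tops`` maps a subject entry id to the query-library locus id
    of its top qualifying hit in the reciprocal search.
    """
    clusters: list[tuple[str, int, int, str]] = []
    for h in sorted(hits, key=lambda h: -h.bit_score):
        sub = subject_by_id[h.subject_id]
        s0 = sub.window_start + h.subject_start
        s1 = sub.window_start + h.subject_end
        if any(c[0] == sub.chromosome and s0 < c[2] and s1 > c[1]
               for c in clusters):
            continue
        clusters.append((sub.chromosome, s0, s1, h.subject_id))
    if not clusters:
        return ConservationRecord(entry.locus_id, entry.motif_class,
                                  entry.motif_length, "lost")
    if len(clusters) > max_positions:
        return ConservationRecord(
            entry.locus_id, entry.motif_class, entry.motif_length,
            "ambiguous", [(c[0], c[1], c[2]) for c in clusters])
    confirmed = any(reciprocal_tops.get(c[3]) == entry.locus_id
                    for c in clusters)
    status = "conserved" if confirmed else "ambiguous"
    return ConservationRecord(
        entry.locus_id, entry.motif_class, entry.motif_length, status,
        [(c[0], c[1], c[2]) for c in clusters], reciprocal_confirmed=confirmed)


def map_conservation(query_library: Sequence[LocusLibraryEntry],
                     subject_library: Sequence[LocusLibraryEntry],
                     params: AlignmentParams | None = None,
                     max_positions: int = 2) -> list[ConservationRecord]:
    """Full library-vs-library conservation mapping with reciprocal
    validation."""
    params = params or AlignmentParams()
    subject_by_id = {e.locus_id: e for e in subject_library}
    forward = search_library(query_library, subject_library, params)
    reverse = search_library(subject_library, query_library, params)
    reciprocal_tops = {sid: hits[0].subject_id
                       for sid, hits in reverse.items() if hits}
    return [assign_conservation(q, forward[q.locus_id], reciprocal_tops,
                                subject_by_id, max_positions)
            for q in query_library]


def conservation_proportions(records: Sequence[ConservationRecord]
                             ) -> pd.DataFrame:
    """Per motif-length-class conserved proportion.

    ``proportion = conserved / (conserved + lost)``; ambiguous records are
    reported separately and excluded from the denominator.  Classes with an
    empty denominator are flagged undefined (NaN proportion).
    """
    rows = []
    for k in (2, 3, 4, 5, 6):
        sub = [r for r in records if r.motif_length == k]
        c = sum(r.status == "conserved" for r in sub)
        l = sum(r.status == "lost" for r in sub)
        a = sum(r.status == "ambiguous" for r in sub)
        rows.append({"motif_length": str(k), "conserved": c, "lost": l,
                     "ambiguous": a,
                     "proportion": c / (c + l) if c + l else float("nan"),
                     "defined": bool(c + l)})
    c = sum(r.status == "conserved" for r in records)
    l = sum(r.status == "lost" for r in records)
    a = sum(r.status == "ambiguous" for r in records)
    rows.append({"motif_length": "all", "conserved": c, "lost": l,
                 "ambiguous": a,
                 "proportion": c / (c + l) if c + l else float("nan"),
                 "defined": bool(c + l)})
    return pd.DataFrame(rows)
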