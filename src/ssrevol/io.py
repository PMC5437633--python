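"""Readers and writers for the pipeline's file formats.

FASTA goes through Biopython; tabular outputs are TSV via pandas.  Locus
tables are written with 1-based inclusive coordinates (``start_1based``,
``end``) and converted back to the internal 0-based half-open convention
on read.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conserve import ConservationRecord, LocusLibraryEntry
from .detect import MicrosatelliteLocus
from .simulate import PlantedLocus, TEInterval

__all__ = [
    "read_fasta", "write_fasta", "write_gff3", "read_gff3_intervals",
    "write_loci_tsv", "read_loci_tsv", "write_truth_tsv",
    "write_library_fasta", "write_conservation_tsv", "write_circos_links",
    "write_json",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(tes: Sequence[TEInterval], path,
               source: str = "ssrevol-sim") -> None:
    """TE intervals as GFF3 (1-based inclusive per the format)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, t in enumerate(tes, 1):
            fh.write(f"{t.chromosome}\t{source}\ttransposable_element\t"
                     f"{t.start + 1}\t{t.end}\t.\t.\t.\tID=te{i:05d}\n")


def read_gff3_intervals(path,
                        feature_type: str = "transposable_element"
                        ) -> list[TEInterval]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["seqid", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"])
    df = df[df["type"] == feature_type]
    return [TEInterval(r.seqid, int(r.start) - 1, int(r.end))
            for r in df.itertuples()]


_LOCUS_HEADER = ["chrom", "start_1based", "end", "motif", "std_motif",
                 "length", "mismatches", "score"]


def write_loci_tsv(loci: Sequence[MicrosatelliteLocus], path) -> None:
    rows = [{"chrom": l.chromosome, "start_1based": l.start + 1,
             "end": l.end, "motif": l.motif, "std_motif": l.standardized_motif,
             "length": l.repeat_length, "mismatches": l.mismatch_count,
             "score": l.score} for l in loci]
    pd.DataFrame(rows, columns=_LOCUS_HEADER).to_csv(path, sep="\t",
                                                     index=False)


def read_loci_tsv(path) -> list[MicrosatelliteLocus]:
    df = pd.read_csv(path, sep="\t")
    return [MicrosatelliteLocus(
        chromosome=r.chrom, start=int(r.start_1based) - 1, end=int(r.end),
        motif=r.motif, standardized_motif=r.std_motif,
        repeat_length=int(r.length), mismatch_count=int(r.mismatches),
        score=int(r.score)) for r in df.itertuples()]


def write_truth_tsv(truth: Sequence[PlantedLocus], path) -> None:
    rows = [{"chrom": p.chromosome, "start_1based": p.start + 1,
             "end": p.end, "motif": p.motif,
             "std_motif": p.standardized_motif,
             "length": p.true_repeat_length,
             "mismatches": p.true_mismatch_count} for p in truth]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_library_fasta(entries: Sequence[LocusLibraryEntry], path) -> None:
    write_fasta({e.locus_id: e.sequence for e in entries}, path)


def write_conservation_tsv(records: Sequence[ConservationRecord],
                           path) -> None:
    rows = []
    for r in records:
        rows.append({
            "locus_id": r.locus_id, "motif_class": r.motif_class,
            "motif_length": r.motif_length, "status": r.status,
            "reciprocal_confirmed": r.reciprocal_confirmed,
            "positions": ";".join(f"{c}:{s + 1}-{e}"
                                  for c, s, e in r.positions)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_circos_links(records: Sequence[ConservationRecord], path) -> None:
    """Conserved-locus links in a circos-ready 6-column TSV."""
    rows = []
    for r in records:
        if r.status != "conserved":
            continue
        chrom, span = r.locus_id.split("|")[-1].split(":")
        q0, q1 = span.split("-")
        for c, s, e in r.positions:
            rows.append({"query_chrom": chrom, "query_start": int(q0) + 1,
                         "query_end": int(q1), "subject_chrom": c,
                         "subject_start": s + 1, "subject_end": e})
    pd.DataFrame(rows, columns=["query_chrom", "query_start", "query_end",
                                "subject_chrom", "subject_start",
                                "subject_end"]).to_csv(path, sep="\t",
                                                       index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
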