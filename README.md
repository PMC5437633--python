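# ssrevol

Comparative-genomics analysis of microsatellite (SSR) **imperfection,
conservation and decay**, built for polyploid plant genomes such as the
*Gossypium* (cotton) lineage, where an allotetraploid carries two
subgenomes (A\_T, D\_T) derived from diploid progenitors.

The package is aimed at researchers who want to (a) mine perfect and
imperfect tandem repeats from assemblies, (b) relate motif imperfection to
repeat length and genomic abundance, and (c) quantify how fast repeat loci
of each motif-length class are lost after whole-genome duplication.

## What it computes

**Detection.** Sequences are scanned for tandem repeats of primitive 1–6 nt
motifs. A seed of ≥3 exact copies (≥8 bases for 1–2 nt motifs) is extended
in both directions, scoring +1 per base matching the expected motif phase
and −5 per mismatching base; extension stops after >3 consecutive
mismatches or when the score drops more than 5 below its running maximum,
and the locus is trimmed back to the maximal-score endpoint. At each
mismatch the phase re-synchronizes to the best-continuing motif rotation,
so a single-base substitution, insertion or deletion each costs one
mismatch. Loci are reported when span ≥15 nt and score ≥15; a locus is
*perfect* when its mismatch count is 0. Two loci closer than 100 nt are a
compound and excluded from genomic summaries.

**Motif standardization.** Every motif maps to the lexicographically
smallest string over all rotations of itself and of its reverse complement
(so AG ≡ GA ≡ TC ≡ CT → "AG"), giving 2, 4, 10, 33, 102 and 350 canonical
classes for motif lengths 1–6.

**Conservation.** Each locus is extracted with 350 nt flanks and its tract
hard-masked; libraries are searched against each other (seed-and-extend
local alignment, Karlin–Altschul E-values), keeping hits with query cover
≥50 %, identity ≥70 % and E ≤ 1e-10, allowing up to two physical positions
(whole-genome duplication) and requiring reciprocal best-hit confirmation.

**Decay.** A per-class conserved fraction *C* over divergence time *t*
(default 6 My) gives the exponential decay rate λ = −ln(*C*)/*t*; classes
are contrasted against the pooled rate (relative decay / relative loss),
and per-class densities against a reference genome (relative abundance).

**Statistics.** Mismatch-by-length frequency matrices feed a principal
coordinates + canonical-correlation ordination with permutation
significance, a sequential two-factor PERMANOVA (pseudo-F), pairwise
Pearson correlations between mismatch levels, and OLS of mean mismatch on
mean repeat length.

**Simulator.** A first-class synthetic-data module plants repeats of known
motif, length and mismatch count into detector-screened background, and
evolves progenitors into a tetraploid with known per-class loss
probabilities — every downstream stage is validated against exact truth.

## Worked example

Run the bundled synthetic scenario end to end (two diploid progenitors →
allotetraploid → scan → conservation → decay):

```bash
ssrevol run --seed 5 --out demo_run
```

which prints (abridged):

```json
{
  "n_loci": {"A2": 160, "D5": 160, "A_T": 106, "D_T": 109},
  "conservation": {
    "A2_vs_A_T": {"2": 0.375, "3": 0.800, "4": 0.815, "5": 0.861,
                  "6": 0.722, "all": 0.713},
    "D5_vs_D_T": {"2": 0.333, "3": 0.952, "4": 0.833, "5": 0.897,
                  "6": 0.882, "all": 0.736}
  }
}
```

Reading the numbers: of the dinucleotide loci detected in progenitor A2,
only ~38 % are recovered in the A\_T subgenome, while ~86 % of 5-nt loci
survive — the default evolution scenario plants exactly this asymmetry
(2-nt repeats decay fastest, 5-nt slowest), and the pipeline recovers it
from sequence alone. `demo_run/` contains the FASTA/GFF3/TSV outputs of
every stage, including per-class decay rates
(λ = −ln(C)/6 per million years) in `summary.json` and circos-ready link
tables.

Library use mirrors the CLI:

```python
from ssrevol import DetectionConfig, scan_sequence
loci = scan_sequence("ACGT" + "AG" * 10 + "TCCA")
# [MicrosatelliteLocus(chromosome='seq', start=4, end=24, motif='AG', ...)]
```

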