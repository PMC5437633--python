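# Methods

## Imperfect microsatellite search

The scanner reports maximal tandem repeats of primitive 1–6 nt motifs with
single-base interruptions. Its semantics are pinned exactly (they are this
package's definition, with every constant exposed in `DetectionConfig`):

* **Seed.** ≥3 exact copies of a primitive motif; ≥8 bases for 1–2 nt
  motifs. A repeat with no such perfect run is undetectable by
  construction (e.g. a 15 nt hexamer tract, which has only 2.5 copies).
* **Extension and scoring.** +`match_score` (1) per base matching the
  expected phase base, −`mismatch_penalty` (5) per mismatching base
  (`N` never matches). Extension stops after more than
  `max_successive_mismatch` (3) consecutive mismatches, or when the score
  falls more than `mismatch_penalty` below its running maximum; the locus
  is trimmed back to the farthest maximal-score position.
* **Phase re-synchronization.** A mismatch consumes one base; the phase
  for the next base is re-chosen among all motif rotations by the longest
  immediately-following exact run (ties prefer plain continuation, then
  the smallest rotation offset). One substitution, insertion or deletion
  therefore each cost exactly one mismatch; left extension applies the
  same rules to the reversed sequence and reversed motif.
* **Resolution.** Candidates from all seeds are deduplicated and selected
  greedily by higher score, then shorter motif, then leftmost start, then
  motif string; reported loci never overlap.

A consequence of the default scoring worth knowing: a new mismatch is only
admissible once the score is back at its running maximum, i.e. after ≥5
matching bases — mismatches closer together than that truncate the locus.
Loci are reported when span ≥ `min_repeat_length` (15) and score ≥
`min_score` (15). Compound repeats (gap < `compound_max_distance`, 100 nt,
strictly) are excluded pairwise from all genomic summaries; the CDS
summary reports the compound count separately.

The test suite holds the scanner to an exhaustive oracle that re-derives
every locus from every seed position with plain string operations;
equivalence is asserted on >10⁴ randomized sequences including low-entropy
and planted-repeat families. Reverse-complement symmetry holds up to
exact score ties between distinct overlapping candidates, where the
leftmost-start tie-break is intrinsically strand-asymmetric; such ties do
not arise in the tested families.

## Motif standardization

Canonical class = lexicographic minimum (A<C<G<T) over the rotations of
the motif and of its reverse complement; only primitive motifs are
admitted (non-primitive input raises an error carrying the primitive
root). This reproduces the named AG class for {AG, GA, TC, CT} and the
class counts 2, 4, 10, 33, 102, 350 for k = 1..6, and makes all outputs
bit-stable.

## Conservation mapping

Libraries contain each eligible locus with ≤350 nt flanks and the tract
hard-masked with `X` (distinct from `N` so assembly gaps remain
distinguishable). Excluded: 1-nt loci, compound loci, and any pair of
loci whose flanked windows overlap (both members). Entries with a
qualifying non-self hit inside their own library are discarded as
non-unique.

The homology search is authored in-repo so desk-scale runs need no
external executable: exact word seeds (default word size 13) against a
sorted k-mer index, a two-hit rule on diagonal bands, and banded
affine-gap local alignment (match +2, mismatch −3, gap open 5, gap
extend 2, band 32; numba kernel). Seed words that are periodic with
period ≤3 are skipped (DUST-style): tandem words occur in thousands of
loci at once and carry no locus-specific signal — the flanks do. Bands
are extended best-first (by seed count) with per-subject and per-strand
caps, so the dominant true-homolog diagonal is always extended first.
At the default 70 % identity floor a qualifying hit (≥370 aligned
columns) still yields several exact 13-mers in expectation, so the caps
cost no sensitivity at the filter boundary.
Mask characters are forbidden in substitution columns (large negative
sentinel), so optimal alignments bridge masked tracts with gaps, no
reported column pairs a mask character with anything, and identity is
driven by flanks only. E-values use the ungapped Karlin–Altschul form
E = K·m·n·exp(−λS) with λ solved exactly for the +2/−3 scoring against a
uniform background and K fixed at 0.3, without effective-length
adjustment; hits are only thresholded at E ≤ 1e-10, far from the error of
either approximation. Filters are inclusive: cover ≥50 %, identity ≥70 %,
E ≤ 1e-10 pass exactly at the boundary.

Conservation is decided **library vs library**: the progenitor library is
searched against the library of loci detected in the derived (sub)genome.
This matters: if a lost locus keeps its flanks (only the tract decayed), a
masked-flank query would still hit the derived *genome*, but the derived
genome detects no repeat there, so no library entry exists and the locus
is correctly scored lost. Qualifying hits are clustered into
non-overlapping subject positions (best bit score first); ≤2 positions are
candidate duplicated copies, >2 is ambiguous, 0 is lost. A locus is
conserved when at least one candidate's reciprocal top qualifying hit
returns the original entry; candidates without reciprocal support are
scored ambiguous (conservative: excluded from the conserved/(conserved +
lost) denominator rather than counted as losses).

## Decay and abundance

λ = −ln(C)/t with t the divergence time (default 6 My, the median
progenitor/tetraploid estimate; configurable). C = 0 is reported as a
complete-loss sentinel and excluded from rate contrasts rather than mapped
to an infinite rate. "Relative decay" is pinned as λ_k − λ_overall and the
figure-facing "relative loss" as (1−C_k) − (1−C_overall), so a class
decaying at the pooled rate sits on the y = 0 reference line. Relative
abundance is (focal − reference)/reference on per-class densities
(loci/Mb); a zero reference density is flagged undefined. Group
comparisons delegate to scipy (Friedman with chromosomes as the blocking
unit, Kruskal–Wallis, pairwise two-sided t-tests at α = 0.05).

## Ordination and PERMANOVA

Dataset I counts loci of length 20–24 nt with 0 or 1 mismatch; dataset II
counts 25–29 nt with 1 or 2 mismatches; loci under 20 nt are excluded.
Ordination computes principal coordinates per block — with the pinned
Euclidean metric on raw counts this is centred PCA — retaining the fewest
axes reaching ≥95 % variance, then the first squared canonical correlation
between the axis sets via QR + SVD. Significance permutes the row order
of one block; p = (1 + #{perm ≥ obs})/(n_perm + 1) (add-one rule, p never
0). PERMANOVA uses the pseudo-F in the Gower-centred trace form with
sequential (type-I) sums of squares, repeat length entered before
mismatch; labels are permuted jointly, and small instances can be
enumerated exhaustively (where p is the exact proportion over all
permutations). Tests verify the pseudo-F against an explicit
group-centroid computation and against scikit-bio's one-way PERMANOVA, and
calibrate the type-I error to 0.05 ± 0.02 under the null. Euclidean on
raw counts is the default because neither the CAP nor the adonis
convention can be assumed; Bray–Curtis is available as an option.

## Synthetic data: what it emulates, what it does not

The generator plants repeats into i.i.d. background (GC 0.35,
cotton-like) that is rejection-sampled until the detector finds nothing in
it. Planted mismatches are substitutions only, kept ≥6 matching bases
from each other and from the tract ends — inside the detector's
admissibility region — and the first run is always a full seed; the six
bases beyond each tract end are redrawn until no motif rotation continues
≥5 bases, and a final verification scan repairs the chromosome until
detection reproduces the truth table exactly. Defaults: ~35 % imperfect
loci (the real genomes report 15.6–49.1 %), repeat lengths 15–45 nt,
motif-length weights peaked on 2 and 5 nt, ≥120 nt locus spacing (≥720 nt
in conservation scenarios so no flanked windows overlap).

Tetraploid evolution keeps coordinates fixed: a lost locus has its tract
replaced in place by screened random sequence; flanks accumulate
substitutions at 1 % per base (alignable divergence, identity ≈ 99 %,
comfortably above the 70 % filter); surviving tracts are untouched.
Consequently passing tests demonstrate correctness of the machinery under
substitution-only divergence with unique flanks — they do not exercise
indels, segmental rearrangement, TE sequence evolution, selection, or
repetitive flank contexts, all of which real genomes have. TE
annotations are plain intervals; their sequence is not modelled.

## Problem sizes and numerical choices

The decay-recovery check uses 2 500 loci per motif-length class
(~12.5 k loci, ~10 Mb progenitor), chosen by a power analysis of the 15 %
λ tolerance: the binding class is loss 0.1, where 15 % of λ is ≈2.4
binomial standard deviations at n = 2 500. The identity-conservation
check uses ≥200 loci; the detector-oracle equivalence runs 10⁴ sequences
≤200 nt; PERMANOVA calibration uses 500 null data sets at 199
permutations. Permutation p-values are reproducible given the seed; all
simulator randomness flows from one `numpy.random.Generator`, and the
pipeline fans a single global seed into per-stage seeds via
`SeedSequence`.

## Known limitations

* Gapped (indel-tolerant) repeat detection is out of scope; motif lengths
  stop at 6.
* The alignment E-value is an ungapped approximation with fixed K; it is
  suitable for thresholding, not for fine E-value comparisons.
* Reverse-complement symmetry of the scanner can break on exact score
  ties between overlapping candidates (strand-asymmetric tie-break).
* Conservation verdicts depend on loci being detected in the derived
  genome; a tract that decays *below* detection thresholds but is not
  fully lost scores as lost.
* The CDS workflow treats each CDS record independently; splice-aware
  coordinates are not modelled.
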