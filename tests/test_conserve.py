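"""Conservation mapping: library construction rules, uniqueness filtering,
identity/lost/duplicated scenarios and truth recovery."""

import re

import numpy as np
import pytest
from scipy import stats

from conftest import random_dna
from ssrevol.align import AlignmentParams
from ssrevol.conserve import (ConservationRecord, build_library,
                              conservation_proportions, map_conservation,
                              self_uniqueness_filter)
from ssrevol.detect import MicrosatelliteLocus, exclude_compounds, scan_genome
from ssrevol.motifs import complete_standardize
from ssrevol.simulate import (EvolutionScenario, SimulationConfig,
                              evolve_tetraploid, generate_genome)


def _locus(chrom, start, end, motif="AG"):
    return MicrosatelliteLocus(
        chromosome=chrom, start=start, end=end, motif=motif,
        standardized_motif=complete_standardize(motif).motif_class,
        repeat_length=end - start, mismatch_count=0, score=end - start)


def _truth_key(locus_id):
    m = re.match(r".+\|(.+):(\d+)-(\d+)", locus_id)
    return m.group(1), int(m.group(2)), int(m.group(3))


class TestBuildLibrary:
    def test_flank_truncation_at_sequence_start(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 10_000)
        seq = seq[:100] + "AG" * 10 + seq[120:]
        lib = build_library([_locus("c", 100, 120)], {"c": seq})
        assert len(lib) == 1
        e = lib[0]
        assert e.window_start == 0 and e.window_end == 470
        assert e.mask_start == 100 and e.mask_end == 120
        assert set(e.sequence[e.mask_start:e.mask_end]) == {"X"}
        assert "X" not in e.sequence[:e.mask_start]
        assert "X" not in e.sequence[e.mask_end:]

    def test_overlapping_windows_both_excluded(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 10_000)
        lib = build_library([_locus("c", 2000, 2020),
                             _locus("c", 2420, 2440)], {"c": seq})
        assert lib == []  # 400 nt apart -> 350 nt windows overlap

    def test_mononucleotide_excluded(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 5000)
        lib = build_library([_locus("c", 2000, 2020, motif="A")], {"c": seq})
        assert lib == []

    def test_locus_out_of_bounds(self):
        with pytest.raises(ValueError):
            build_library([_locus("c", 90, 120)], {"c": "ACGT" * 25})


class TestSelfUniqueness:
    def test_random_flanks_all_retained(self, library_sim):
        loci, _ = exclude_compounds(scan_genome(library_sim.sequences))
        lib = build_library(loci, library_sim.sequences)
        retained, discarded = self_uniqueness_filter(lib)
        assert discarded == []
        assert len(retained) == len(lib)

    def test_identical_flanks_both_discarded(self):
        rng = np.random.default_rng(3)
        flank = random_dna(rng, 2000)
        # same flanked neighbourhood on two chromosomes
        seqs = {"c1": flank[:350] + "AG" * 10 + flank[350:700],
                "c2": flank[:350] + "AG" * 10 + flank[350:700]}
        lib = build_library([_locus("c1", 350, 370),
                             _locus("c2", 350, 370)], seqs)
        retained, discarded = self_uniqueness_filter(lib)
        assert retained == [] and len(discarded) == 2

    def test_single_entry_retained(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 2000)
        lib = build_library([_locus("c", 900, 920)], {"c": seq})
        retained, _ = self_uniqueness_filter(lib)
        assert len(retained) == 1


class TestScenarios:
    def test_identity_scenario_all_conserved_one_position(self, library_sim):
        loci, _ = exclude_compounds(scan_genome(library_sim.sequences))
        lib = build_library(loci, library_sim.sequences, source_genome="P")
        lib, _ = self_uniqueness_filter(lib)
        records = map_conservation(lib, lib)
        assert all(r.status == "conserved" for r in records)
        assert all(len(r.positions) == 1 for r in records)
        props = conservation_proportions(records)
        defined = props[props.defined & (props.motif_length != "all")]
        assert (defined.proportion == 1.0).all()

    def test_unrelated_subject_all_lost(self, library_sim):
        loci, _ = exclude_compounds(scan_genome(library_sim.sequences))
        lib = build_library(loci, library_sim.sequences, source_genome="P")
        other = generate_genome(SimulationConfig(
            seed=99, n_chromosomes=1, chromosome_length=40000,
            planted_loci_per_chromosome=40, min_locus_spacing=720))
        o_loci, _ = exclude_compounds(scan_genome(other.sequences))
        o_lib = build_library(o_loci, other.sequences, source_genome="O")
        records = map_conservation(lib[:30], o_lib)
        assert all(r.status == "lost" for r in records)

    def test_wgd_duplication_two_positions(self, library_sim):
        """The same progenitor evolved into both subgenomes: each conserved
        locus should be recovered at two physical positions."""
        tet = evolve_tetraploid(library_sim, library_sim, EvolutionScenario(
            loss_probability={k: 0.0 for k in range(1, 7)},
            flank_substitution_rate=0.005), seed=41)
        q_loci, _ = exclude_compounds(scan_genome(library_sim.sequences))
        q_lib = build_library(q_loci, library_sim.sequences,
                              source_genome="P")
        q_lib, _ = self_uniqueness_filter(q_lib)
        s_loci, _ = exclude_compounds(scan_genome(tet.sequences))
        s_lib = build_library(s_loci, tet.sequences, source_genome="T")
        records = map_conservation(q_lib, s_lib)
        conserved = [r for r in records if r.status == "conserved"]
        assert len(conserved) / len(records) >= 0.95
        two_pos = sum(len(r.positions) == 2 for r in conserved)
        assert two_pos / len(conserved) >= 0.95

    def test_loss_rates_recovered_within_binomial_interval(self, library_sim):
        scenario = EvolutionScenario(
            loss_probability={1: 0.0, 2: 0.8, 3: 0.1, 4: 0.1, 5: 0.1,
                              6: 0.1})
        other = generate_genome(SimulationConfig(
            seed=55, n_chromosomes=1, chromosome_length=20000,
            planted_loci_per_chromosome=10, min_locus_spacing=720))
        tet = evolve_tetraploid(library_sim, other, scenario, seed=56)
        q_loci, _ = exclude_compounds(scan_genome(library_sim.sequences))
        q_lib = build_library(q_loci, library_sim.sequences,
                              source_genome="P")
        q_lib, _ = self_uniqueness_filter(q_lib)
        sub = {c: s for c, s in tet.sequences.items()
               if c.startswith("A_T")}
        s_loci, _ = exclude_compounds(scan_genome(sub))
        s_lib = build_library(s_loci, tet.sequences, source_genome="T")
        records = map_conservation(q_lib, s_lib)
        # verdicts must match the simulator's truth exactly
        truth = {(c.chromosome, c.start, c.end): c.survived
                 for c in tet.conservation_truth if c.subgenome == "A_T"}
        wrong = sum((r.status == "conserved") != truth[_truth_key(r.locus_id)]
                    for r in records)
        assert wrong == 0
        props = conservation_proportions(records).set_index("motif_length")
        for k, loss in ((2, 0.8), (3, 0.1), (5, 0.1)):
            row = props.loc[str(k)]
            n = int(row.conserved + row.lost)
            lo, hi = stats.binom.ppf([0.005, 0.995], n, 1 - loss)
            assert lo <= row.conserved <= hi


def test_tabular_adapter_roundtrip(tmp_path):
    """Outfmt-6-style rows parse into hits with the same filter semantics
    as in-repo search results."""
    from ssrevol.align import AlignmentParams, passes_filters
    from ssrevol.conserve import read_tabular_hits
    path = tmp_path / "hits.tsv"
    path.write_text(
        "q1\ts1\t95.0\t700\t35\t0\t1\t700\t1001\t1700\t1e-200\t1200\n"
        "q1\ts2\t65.0\t700\t245\t0\t1\t700\t5001\t5700\t1e-50\t300\n"
        "q2\ts1\t100.0\t100\t0\t0\t1\t100\t900\t801\t1e-40\t190\n")
    hits = read_tabular_hits(path, {"q1": 700, "q2": 700})
    assert set(hits) == {"q1", "q2"}
    params = AlignmentParams()
    h_good, h_low_id = hits["q1"]
    assert passes_filters(h_good, params)
    assert not passes_filters(h_low_id, params)       # identity 65 < 70
    assert not passes_filters(hits["q2"][0], params)  # cover 100/700 < 50
    assert hits["q2"][0].strand == "-"
    assert (hits["q2"][0].subject_start, hits["q2"][0].subject_end) == \
        (800, 900)


class TestProportions:
    def _rec(self, k, status):
        return ConservationRecord("id", "AG", k, status)

    def test_all_conserved(self):
        records = [self._rec(k, "conserved") for k in (2, 3, 4, 5, 6)]
        props = conservation_proportions(records)
        assert (props[props.defined].proportion == 1.0).all()

    def test_empty_class_flagged_undefined(self):
        records = [self._rec(2, "conserved"), self._rec(2, "lost")]
        props = conservation_proportions(records).set_index("motif_length")
        assert props.loc["6"].defined == False  # noqa: E712
        assert np.isnan(props.loc["6"].proportion)
        assert props.loc["2"].proportion == 0.5

    def test_ambiguous_excluded_from_denominator(self):
        records = [self._rec(3, "conserved"), self._rec(3, "ambiguous"),
                   self._rec(3, "lost"), self._rec(3, "conserved")]
        props = conservation_proportions(records).set_index("motif_length")
        assert props.loc["3"].proportion == pytest.approx(2 / 3)
        assert props.loc["3"].ambiguous == 1
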