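import numpy as np
import pandas as pd
import pytest

import fatemap as fm
from fatemap.calling import (
    PeakProfile,
    PeakTriplicate,
    _expected_visible_changes,
    call_genotype_matrix,
    read_peak_table,
)
from fatemap.genotypes import GenotypeMatrix


def _trip(peaks):
    """Three identical replicates from one peak list."""
    p = PeakProfile(peaks)
    return PeakTriplicate((p, p, p))


class TestCallLocusGenotype:
    def test_homozygote_when_runner_up_gap_small(self):
        # |I2H - I3H| = 2000 <= 1e4 -> homozygote at the top size
        trip = _trip([(106, 30000), (105, 5000), (104, 3000)])
        call = fm.call_locus_genotype(trip)
        assert (call.allele_a, call.allele_b) == (106, 106)

    def test_heterozygote_when_gap_and_ratio_met(self):
        # |26000 - 4000| >= 1e4 and 26000 > 0.8 * 30000
        trip = _trip([(106, 30000), (105, 26000), (104, 4000)])
        call = fm.call_locus_genotype(trip)
        assert {call.allele_a, call.allele_b} == {106, 105}

    def test_in_between_pattern_is_ambiguous_with_top_allele(self):
        # gap met but 16000 < 0.8 * 30000: neither rule fires
        trip = _trip([(106, 30000), (105, 16000), (104, 2000)])
        call = fm.call_locus_genotype(trip)
        assert call.status == "ambiguous"
        assert call.allele_a == 106 and call.allele_b is None

    def test_irreproducible_triplicates_are_ambiguous(self):
        hom = PeakProfile([(106, 30000), (105, 5000), (104, 3000)])
        het = PeakProfile([(106, 30000), (105, 26000), (104, 4000)])
        call = fm.call_locus_genotype(PeakTriplicate((hom, het, hom)))
        assert call.status == "ambiguous"
        assert call.allele_a == 106  # top allele agreed across replicates

    def test_short_profiles_padded_with_sentinels(self):
        call = fm.call_locus_genotype(_trip([(106, 30000)]))
        assert (call.allele_a, call.allele_b) == (106, 106)

    def test_empty_replicate_is_ambiguous(self):
        empty = PeakProfile([])
        call = fm.call_locus_genotype(PeakTriplicate((empty, empty, empty)))
        assert (call.allele_a, call.allele_b) == (None, None)


class TestParentalAssignment:
    def _matrix(self, cells):
        frame = pd.DataFrame(
            {"L1": cells}, index=[f"c{i}" for i in range(len(cells))]
        )
        return GenotypeMatrix.from_frame(frame)

    def test_uniform_heterozygotes_give_two_founders(self):
        m = self._matrix(["106/103"] * 4)
        oriented, founders = fm.assign_parental_alleles(m)
        assert set(founders.loc["L1"]) == {106, 103}
        summary = fm.identify_somatic_mutations(
            oriented, fm.consensus_genotype(oriented)
        )
        assert summary.per_clone["n_mutant_alleles"].sum() == 0

    def test_single_mutation_detected_against_founders(self):
        m = self._matrix(["106/103", "107/103", "106/103"])
        oriented, founders = fm.assign_parental_alleles(m)
        summary = fm.identify_somatic_mutations(
            oriented, fm.consensus_genotype(oriented)
        )
        assert summary.per_clone["n_mutant_alleles"].sum() == 1
        assert summary.per_clone.loc["c1", "n_mutant_alleles"] == 1

    def test_homozygous_locus_single_founder(self):
        m = self._matrix(["106/106", "106/106"])
        _, founders = fm.assign_parental_alleles(m)
        assert tuple(founders.loc["L1"]) == (106, 106)

    def test_all_missing_locus_flagged(self):
        m = self._matrix(["X/X", "X/X"])
        _, founders = fm.assign_parental_alleles(m)
        assert tuple(founders.loc["L1"]) == (-1, -1)

    def test_orientation_aligns_slots(self):
        m = self._matrix(["106/103", "103/106", "106/103"])
        oriented, _ = fm.assign_parental_alleles(m)
        col = oriented.alleles[:, 0, 0]
        assert len(set(col.tolist())) == 1  # all slot-0 alleles on one founder


class TestConsensus:
    def test_identical_rows_are_idempotent(self, tiny_matrix):
        sub = tiny_matrix.select_clones(["a"])
        cons = fm.consensus_genotype(sub)
        assert np.array_equal(cons, tiny_matrix.genotype_of("a"))

    def test_modal_allele_wins(self):
        cells = ["106/106"] * 5 + ["105/105"] * 2
        frame = pd.DataFrame({"L1": cells}, index=[f"c{i}" for i in range(7)])
        cons = fm.consensus_genotype(GenotypeMatrix.from_frame(frame))
        assert tuple(cons[0]) == (106, 106)

    def test_tie_breaks_to_smaller_length(self):
        cells = ["106/106"] * 3 + ["105/105"] * 3
        frame = pd.DataFrame({"L1": cells}, index=[f"c{i}" for i in range(6)])
        cons = fm.consensus_genotype(GenotypeMatrix.from_frame(frame))
        assert tuple(cons[0]) == (105, 105)

    def test_all_missing_stays_missing(self):
        frame = pd.DataFrame({"L1": ["X/X", "X/X"]}, index=["a", "b"])
        cons = fm.consensus_genotype(GenotypeMatrix.from_frame(frame))
        assert tuple(cons[0]) == (-1, -1)


class TestSomaticMutations:
    def test_reference_against_itself_is_zero(self, small_lineage):
        matrix = small_lineage.matrix_complete
        ref = matrix.genotype_of(matrix.clone_ids[0])
        sub = matrix.select_clones([matrix.clone_ids[0]])
        summary = fm.identify_somatic_mutations(sub, ref)
        assert summary.per_clone["n_mutant_alleles"].sum() == 0
        assert summary.mean_fraction_mutated == 0.0

    def test_fraction_counts_loci(self):
        frame = pd.DataFrame(
            {f"L{j}": ["106/106"] for j in range(110)}, index=["ref"]
        )
        m = GenotypeMatrix.from_frame(frame)
        ref = m.genotype_of("ref").copy()
        mutated = ref.copy()
        mutated[:3, 0] += 1  # three mutated loci
        m2 = GenotypeMatrix(
            np.stack([mutated]), ["c"], list(m.locus_ids)
        )
        summary = fm.identify_somatic_mutations(m2, ref)
        assert summary.per_clone.loc["c", "n_mutated_loci"] == 3
        assert summary.per_clone.loc["c", "fraction_mutated"] == pytest.approx(3 / 110)


class TestMutationRate:
    def test_simple_ratio_arithmetic(self):
        # 264 visible new mutations over 12 subclones x 20 doublings x 110
        # loci gives the quoted 0.010 rate
        rng = np.random.default_rng(0)
        parent = np.full((110, 2), 100, dtype=np.int32)
        rows, ids = [parent], ["parent"]
        per = 264 // 12
        for k in range(12):
            g = parent.copy()
            loci = rng.choice(110, size=per, replace=False)
            g[loci, 0] += 1
            rows.append(g)
            ids.append(f"s{k}")
        m = GenotypeMatrix(np.stack(rows), ids, [f"L{j}" for j in range(110)])
        est = fm.estimate_mutation_rate(m, doublings=20, cancellation_correction=False)
        assert est.rate_raw == pytest.approx(264 / 26400)

    def test_recovers_simulated_rate(self):
        hits = 0
        for seed in range(20):
            m = fm.simulate_subclone_experiment(
                fm.SubcloneExperimentConfig(mu=0.012, seed=seed)
            )
            est = fm.estimate_mutation_rate(m, doublings=20)
            if abs(est.rate - 0.012) <= 3 * est.se:
                hits += 1
        assert hits >= 18

    def test_correction_inverts_expected_visible_changes(self):
        mu, d = 0.012, 20
        visible = _expected_visible_changes(mu, d)
        assert visible < mu * d  # cancellation shortens
        assert visible == pytest.approx(mu * d, rel=0.10)

    def test_zero_usable_loci_raises(self):
        frame = pd.DataFrame({"L1": ["X/X", "X/X"]}, index=["parent", "s1"])
        m = GenotypeMatrix.from_frame(frame)
        with pytest.raises(ValueError, match="usable"):
            fm.estimate_mutation_rate(m, doublings=20)


class TestPeakTable:
    def test_round_trip_through_tsv(self, tmp_path):
        rows = []
        for rep in range(3):
            for size, inten in [(106, 30000), (105, 26000), (100, 500)]:
                rows.append(("c1", "L1", rep, size, inten))
        pd.DataFrame(
            rows, columns=["clone", "locus", "replicate", "size", "intensity"]
        ).to_csv(tmp_path / "peaks.tsv", sep="\t", index=False)
        trips = read_peak_table(tmp_path / "peaks.tsv")
        matrix = call_genotype_matrix(trips)
        call = matrix.call("c1", "L1")
        assert {call.allele_a, call.allele_b} == {106, 105}
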