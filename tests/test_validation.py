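"""Structure / motif / SNP validation comparisons and their nulls."""

import numpy as np
import pytest

from corrmut.seqdata import ContentError, MotifAnnotation, SNPRecord
from corrmut.synthetic_data import (
    PlantedPair,
    SimulationConfig,
    make_toy_structure,
    simulate_paired_alignment,
)
from corrmut.validation import (
    add_one_pvalue,
    aggregate_motif_overlap,
    consistent_overlap,
    distance_enrichment,
    fscore,
    motif_overlap,
    random_subset_pvalue,
    randomize_positions_pvalue,
    shuffle_pairing_null,
    snp_overlap,
)


class TestRandomSubsetPvalue:
    def test_observed_below_every_replicate(self, rng):
        p, _ = random_subset_pvalue(
            rng.normal(size=200), 10, np.mean, observed=-100.0, reps=50, seed=0
        )
        assert p == 1.0

    def test_observed_above_every_replicate(self):
        p, _ = random_subset_pvalue(
            np.zeros(100), 10, np.mean, observed=1.0, reps=1000, seed=0
        )
        assert p == pytest.approx(1 / 1001)

    def test_null_calibration_uniform(self, rng):
        """Statistic drawn from the null gives super-uniform p-values."""
        pool = rng.normal(size=120)
        hits = 0
        trials = 500
        for _ in range(trials):
            obs = float(np.mean(rng.choice(pool, size=8, replace=False)))
            p, _ = random_subset_pvalue(
                pool, 8, np.mean, obs, reps=100, rng=rng
            )
            hits += p <= 0.05
        assert hits / trials <= 0.07

    def test_subset_larger_than_background_is_error(self):
        with pytest.raises(ContentError):
            random_subset_pvalue(np.zeros(5), 10, np.mean, 0.0, reps=10, seed=0)


class TestDistanceEnrichment:
    def _planted(self, seed=0):
        planted = [PlantedPair(3, 17, "intra"), PlantedPair(8, 25, "intra"),
                   PlantedPair(12, 33, "intra"), PlantedPair(20, 38, "intra")]
        toy = make_toy_structure(40, planted, seed=seed)
        pairs = [(("P", p.pos1), ("P", p.pos2)) for p in planted]
        return toy, pairs

    def test_all_pairs_in_contact_gives_fraction_one(self):
        toy, pairs = self._planted()
        res = distance_enrichment(pairs, toy.distances, reps=20, seed=0)
        assert res[0].observed_fraction == 1.0

    def test_background_identity(self):
        """Evaluating the full background set reproduces the background fraction."""
        toy, _ = self._planted()
        all_pairs = [
            (("P", i), ("P", j)) for i in range(1, 41) for j in range(i + 1, 41)
        ]
        res = distance_enrichment(all_pairs, toy.distances, reps=5, seed=0)
        assert res[0].observed_fraction == pytest.approx(res[0].background_fraction)

    def test_planted_contacts_significant(self):
        toy, pairs = self._planted(seed=2)
        res = distance_enrichment(pairs, toy.distances, reps=1000, seed=1)
        for e in res:
            assert e.observed_fraction > e.background_fraction
            assert e.p_value <= 0.01

    def test_unmappable_pairs_counted_and_dropped(self):
        toy, pairs = self._planted()
        res = distance_enrichment(
            pairs + [(("P", 500), ("P", 600))], toy.distances, reps=5, seed=0
        )
        assert res[0].n_unmapped == 1 and res[0].n_evaluated == 4

    def test_no_mappable_pairs_is_error(self):
        toy, _ = self._planted()
        with pytest.raises(ContentError):
            distance_enrichment([(("P", 500), ("P", 600))], toy.distances, reps=5)


class TestShufflePairingNull:
    def test_shuffling_destroys_planted_signal(self):
        cfg = SimulationConfig(
            seed=9, n_species=50, length=30,
            planted_pairs=[PlantedPair(5, 12, "inter", 1.0),
                           PlantedPair(18, 25, "inter", 1.0)],
        )
        pa = simulate_paired_alignment(cfg)
        obs, null, _ = shuffle_pairing_null(
            pa, reps=40, seed=2, statistic="n_pairs"
        )
        assert obs >= 2
        assert null.mean() < obs  # shuffling loses most detections
        obs_r, _, p = shuffle_pairing_null(
            pa, reps=40, seed=2, statistic="max_r"
        )
        assert obs_r > 0.9
        assert p <= 0.05

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(seed=9, n_species=35, length=20)
        pa = simulate_paired_alignment(cfg)
        r1 = shuffle_pairing_null(pa, reps=10, seed=5, statistic="max_r")
        r2 = shuffle_pairing_null(pa, reps=10, seed=5, statistic="max_r")
        assert np.array_equal(r1[1], r2[1]) and r1[2] == r2[2]


class TestMotifOverlap:
    def test_fscore_from_reported_coverages(self):
        assert fscore(0.55, 0.39) == pytest.approx(0.46, abs=0.005)

    @pytest.mark.parametrize("a,b,expected", [(1.0, 1.0, 1.0), (0.0, 0.7, 0.0)])
    def test_fscore_edges(self, a, b, expected):
        assert fscore(a, b) == expected

    def test_fscore_bounded_by_arithmetic_mean(self, rng):
        for _ in range(50):
            a, b = rng.uniform(0, 1, size=2)
            assert fscore(a, b) == fscore(b, a)
            assert fscore(a, b) <= (a + b) / 2 + 1e-12

    def test_position_level_coverages(self):
        motifs = [MotifAnnotation("m1", "P", 10, 14)]  # 5 motif positions
        cm = [("P", 10), ("P", 12), ("P", 50), ("P", 60)]
        res = motif_overlap(cm, motifs)
        assert res.coverage_motif == pytest.approx(2 / 5)
        assert res.coverage_cm == pytest.approx(2 / 4)

    def test_empty_motif_set_is_error(self):
        with pytest.raises(ContentError):
            motif_overlap([("P", 1)], [])

    def test_aggregate_pools_counts(self):
        m1 = [MotifAnnotation("m1", "P", 1, 2)]
        m2 = [MotifAnnotation("m2", "Q", 1, 4)]
        res = aggregate_motif_overlap([
            ([("P", 1), ("P", 2)], m1),      # 2/2 motif, 2/2 cm
            ([("Q", 9)], m2),                # 0/4 motif, 0/1 cm
        ])
        assert res.coverage_motif == pytest.approx(2 / 6)
        assert res.coverage_cm == pytest.approx(2 / 3)


class TestConsistentOverlap:
    MOTIFS = [
        MotifAnnotation("ma", "X", 10, 20, "mb"),
        MotifAnnotation("mb", "Y", 30, 40, "ma"),
    ]

    def test_molecule_matched_containment(self):
        hits = consistent_overlap(
            [("ip1", (("X", 15), ("Y", 35)))], self.MOTIFS
        )
        assert hits[("ma", "mb")] == {"ip1"}

    def test_one_position_outside_is_not_consistent(self):
        hits = consistent_overlap(
            [("ip1", (("X", 15), ("Y", 99)))], self.MOTIFS
        )
        assert hits[("ma", "mb")] == set()

    def test_count_over_interaction_pairs(self):
        """One motif pair consistent in four different interaction pairs."""
        cm = [
            (f"ip{k}", (("X", 10 + k), ("Y", 30 + k))) for k in range(4)
        ] + [("ip9", (("X", 5), ("Y", 35)))]
        hits = consistent_overlap(cm, self.MOTIFS)
        assert len(hits[("ma", "mb")]) == 4

    def test_single_molecule_motif_pair_is_error(self):
        bad = [
            MotifAnnotation("ma", "X", 1, 5, "mb"),
            MotifAnnotation("mb", "X", 8, 9, "ma"),
        ]
        with pytest.raises(ContentError):
            consistent_overlap([], bad)


class TestRandomizePositions:
    def test_saturating_motifs_give_p_near_one(self):
        motifs = [MotifAnnotation("m", "P", 1, 50)]
        cm = [(("P", 3), ("P", 30))]
        f, p, null = randomize_positions_pvalue(
            cm, {"P": 50}, motifs, reps=200, seed=0
        )
        assert f == null.max() == null.min()  # F invariant under randomization
        assert p == 1.0

    def test_exact_match_sparse_motifs_significant(self):
        motifs = [MotifAnnotation(f"m{i}", "P", 10 * i, 10 * i + 1)
                  for i in range(1, 5)]
        cm = [(("P", 10), ("P", 20)), (("P", 30), ("P", 40)),
              (("P", 11), ("P", 21)), (("P", 31), ("P", 41))]
        f, p, _ = randomize_positions_pvalue(
            cm, {"P": 500}, motifs, reps=1000, seed=0
        )
        assert f == 1.0
        assert p < 0.01

    def test_shared_position_replaced_consistently(self, rng):
        # a position occurring in two pairs maps to one random position:
        # the randomized position multiset always has exactly 3 members
        motifs = [MotifAnnotation("m", "P", 1, 5)]
        cm = [(("P", 7), ("P", 8)), (("P", 7), ("P", 9))]
        _, _, null = randomize_positions_pvalue(
            cm, {"P": 10}, motifs, reps=100, seed=1
        )
        # with consistent replacement F can only take values from 3 distinct
        # positions out of 10; inconsistent replacement would allow 4
        assert set(np.round(null, 6)) <= {
            round(fscore(k / 5, k / 3), 6) for k in range(4)
        }


class TestSnpOverlap:
    def test_reported_interacting_fraction(self):
        """19 overlapping / 207 non-overlapping non-synonymous SNPs -> 8.4%."""
        cm = {("P", i) for i in range(1, 20)}
        snps = [SNPRecord("P", i, "non-synonymous") for i in range(1, 20)]
        snps += [SNPRecord("P", 1000 + i, "non-synonymous") for i in range(207)]
        res = snp_overlap(snps, cm)
        assert res.counts["non-synonymous"] == (19, 207)
        assert res.fraction("non-synonymous") * 100 == pytest.approx(8.4, abs=0.05)

    def test_reported_noninteracting_fraction(self):
        """74 / 581 -> 11.3%."""
        cm = {("P", i) for i in range(1, 75)}
        snps = [SNPRecord("P", i, "non-synonymous") for i in range(1, 75)]
        snps += [SNPRecord("P", 2000 + i, "non-synonymous") for i in range(581)]
        res = snp_overlap(snps, cm)
        assert res.fraction("non-synonymous") * 100 == pytest.approx(11.3, abs=0.05)

    def test_counts_conserved_per_class(self, rng):
        cm = {("P", int(i)) for i in rng.integers(1, 50, size=10)}
        snps = [
            SNPRecord("P", int(rng.integers(1, 100)),
                      "synonymous" if i % 2 else "non-synonymous")
            for i in range(40)
        ]
        res = snp_overlap(snps, cm)
        for cls in ("synonymous", "non-synonymous"):
            assert sum(res.counts[cls]) == 20

    def test_zero_snps_fraction_undefined(self):
        res = snp_overlap([], {("P", 1)})
        assert res.fraction("synonymous") is None


def test_add_one_pvalue_bounds():
    assert add_one_pvalue(np.array([1.0, 2.0]), 3.0) == pytest.approx(1 / 3)
    assert add_one_pvalue(np.array([1.0, 2.0]), 0.0) == 1.0
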