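"""The coevolution statistic: variability vectors, correlations, groups."""

import math

import numpy as np
import pytest

from corrmut.caps_engine import (
    blosum_matrix,
    correlated_groups,
    correlation_matrix,
    default_min_pairs,
    detect_correlated_pairs,
    poisson_distance,
    site_pair_correlation,
    site_variability_vector,
)
from corrmut.seqdata import AMINO_ACIDS, ContentError, encode_rows
from corrmut.synthetic_data import PlantedPair, SimulationConfig, simulate_family

from conftest import make_family


class TestPoissonDistance:
    def test_closed_forms(self):
        assert poisson_distance("ACDE", "ACDE") == 0.0
        assert poisson_distance("ACDE", "ACKR") == pytest.approx(math.log(2))

    def test_saturated_pair_is_error(self):
        with pytest.raises(ContentError):
            poisson_distance("AC", "DE")

    def test_gap_columns_excluded(self):
        # comparable columns: (A,A) and (D,E) -> p = 0.5
        assert poisson_distance("A-D", "AEE") == pytest.approx(math.log(2))


class TestSiteVariability:
    def test_constant_column_centers_to_zero(self):
        vec = site_variability_vector(["ARR", "ARR", "ARR"], 1)
        assert np.allclose(vec.values, 0.0)

    def test_hand_computed_blosum62_column(self):
        # residues (A, A, V): raw scores {4, 0, 0}, centered {8/3, -4/3, -4/3}
        vec = site_variability_vector(["AX", "AX", "VX"], 1)
        assert np.allclose(sorted(vec.values), [-4 / 3, -4 / 3, 8 / 3])
        assert np.isclose(np.nanmean(vec.values), 0.0)

    def test_gapped_row_removes_its_pairs(self):
        vec = site_variability_vector(["AR", "-R", "AR", "VR"], 1)
        ii, jj = vec.pair_index
        gone = (ii == 1) | (jj == 1)
        assert np.all(~np.isfinite(vec.values[gone]))
        assert np.all(np.isfinite(vec.values[~gone]))

    def test_time_correction_keeps_constant_column_zero(self):
        rows = ["ACDEF", "AKDEF", "ACREF"]  # column 1 constant, others vary
        vec = site_variability_vector(rows, 1, time_correction=True)
        assert np.allclose(vec.values[np.isfinite(vec.values)], 0.0)


class TestCorrelation:
    def _vec(self, values):
        from corrmut.caps_engine import SiteVariabilityVector
        v = np.asarray(values, dtype=float)
        n = len(v)
        return SiteVariabilityVector(1, v, (np.arange(n), np.arange(n)))

    def test_perfect_and_anti_correlation(self):
        x = self._vec(np.arange(12.0))
        assert site_pair_correlation(x, x, min_pairs=2) == pytest.approx(1.0)
        y = self._vec(-np.arange(12.0))
        assert site_pair_correlation(x, y, min_pairs=2) == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self, rng):
        x = self._vec(rng.normal(size=1000))
        y = self._vec(rng.normal(size=1000))
        assert abs(site_pair_correlation(x, y, min_pairs=2)) < 0.15

    def test_constant_restriction_skipped(self):
        x = self._vec(np.zeros(20))
        y = self._vec(np.arange(20.0))
        assert site_pair_correlation(x, y, min_pairs=2) is None

    def test_small_overlap_skipped(self):
        x = self._vec([1.0, 2.0, np.nan, np.nan])
        y = self._vec([1.0, 2.0, 3.0, 4.0])
        assert site_pair_correlation(x, y, min_pairs=10) is None

    def test_engine_matches_bruteforce_oracle(self, rng):
        """Engine correlations equal per-pair np.corrcoef to < 1e-12."""
        from corrmut.caps_engine import _variability_matrix

        worst = 0.0
        for _ in range(50):
            n_rows = int(rng.integers(5, 12))
            n_cols = int(rng.integers(4, 10))
            rows = [
                "".join(rng.choice(list(AMINO_ACIDS + "-"), size=n_cols))
                for _ in range(n_rows)
            ]
            enc = encode_rows(rows)
            V = _variability_matrix(enc, max_gap_frac=1.0)
            R, N = correlation_matrix(V, min_pairs=2)
            for i in range(n_cols):
                for j in range(i + 1, n_cols):
                    common = np.isfinite(V[i]) & np.isfinite(V[j])
                    if common.sum() < 2:
                        continue
                    x, y = V[i][common], V[j][common]
                    if np.ptp(x) == 0 or np.ptp(y) == 0:
                        assert not np.isfinite(R[i, j])
                        continue
                    oracle = np.corrcoef(x, y)[0, 1]
                    worst = max(worst, abs(R[i, j] - oracle))
        assert worst < 1e-12


class TestDetect:
    def test_identical_rows_give_empty_output(self):
        aln = make_family(["ACDEFGHIKL"] * 12)
        assert detect_correlated_pairs(aln, "intra") == []

    def test_planted_pairs_recovered(self, planted_family):
        cfg, fam = planted_family
        pairs = detect_correlated_pairs(fam, "intra", cutoff=0.4)
        found = {(p.col_a, p.col_b) for p in pairs}
        for planted in cfg.planted_pairs:
            assert (planted.pos1, planted.pos2) in found
        # engine r agrees with a brute-force correlation of the two columns
        from corrmut.caps_engine import _variability_matrix
        V = _variability_matrix(encode_rows(fam.sequences()))
        for p in pairs:
            oracle = np.corrcoef(V[p.col_a - 1], V[p.col_b - 1])[0, 1]
            assert p.r == pytest.approx(oracle, abs=1e-12)

    def test_raising_cutoff_never_adds_pairs(self, planted_family):
        _, fam = planted_family
        low = {(p.col_a, p.col_b) for p in detect_correlated_pairs(fam, cutoff=0.4)}
        high = {(p.col_a, p.col_b) for p in detect_correlated_pairs(fam, cutoff=0.6)}
        assert high <= low

    def test_column_permutation_equivariance(self, planted_family):
        _, fam = planted_family
        perm = np.random.default_rng(7).permutation(fam.length)
        permuted = make_family(
            ["".join(s[c] for c in perm) for s in fam.sequences()],
            family_id=fam.family_id,
        )
        base = {
            frozenset((p.col_a, p.col_b)): round(p.r, 9)
            for p in detect_correlated_pairs(fam, cutoff=0.4)
        }
        # new column k (1-based) holds old column perm[k-1] + 1
        moved = {
            frozenset((int(perm[p.col_a - 1]) + 1, int(perm[p.col_b - 1]) + 1)):
            round(p.r, 9)
            for p in detect_correlated_pairs(permuted, cutoff=0.4)
        }
        assert base == moved

    def test_inter_mode_scans_cross_block_only(self):
        cfg = SimulationConfig(
            seed=5, n_species=50, length=30,
            planted_pairs=[PlantedPair(4, 21, "inter", 1.0)],
        )
        from corrmut.synthetic_data import simulate_paired_alignment
        pa = simulate_paired_alignment(cfg)
        pairs = detect_correlated_pairs(pa, "inter", time_correction=False)
        assert all(p.mol_a == "A" and p.mol_b == "B" for p in pairs)
        assert (4, 21) in {(p.col_a, p.col_b) for p in pairs}

    def test_determinism(self, planted_family):
        _, fam = planted_family
        a = detect_correlated_pairs(fam, cutoff=0.4)
        b = detect_correlated_pairs(fam, cutoff=0.4)
        assert [(p.col_a, p.col_b, p.r) for p in a] == [
            (p.col_a, p.col_b, p.r) for p in b
        ]


class TestGroups:
    def _pair(self, a, b):
        from corrmut.caps_engine import CorrelatedPair
        return CorrelatedPair("X", a, "X", b, 0.5, 100, "intra")

    def test_transitive_connectivity(self):
        groups = correlated_groups([self._pair(1, 2), self._pair(2, 3)])
        assert len(groups) == 1
        assert groups[0].positions == frozenset({("X", 1), ("X", 2), ("X", 3)})

    def test_disjoint_components(self):
        groups = correlated_groups([self._pair(1, 2), self._pair(5, 6)])
        assert len(groups) == 2

    def test_empty_input(self):
        assert correlated_groups([]) == []


def test_default_min_pairs_rule():
    assert default_min_pairs(6) == 10
    assert default_min_pairs(1770) == 885
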