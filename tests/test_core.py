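"""Genotype coding, map functions and heritability accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qtsmap import (
    AdditiveTerm,
    EpistaticTerm,
    GeneticMap,
    GenotypeMatrix,
    QTSEffectSet,
    code_genotypes,
    partition_heritability,
    recombination_fraction,
    ril_recombination_fraction,
)
from qtsmap.core import decode_genotypes

from conftest import make_genotypes


class TestCodeGenotypes:
    def test_majority_allele_coded_plus_one(self):
        raw = pd.DataFrame({"m1": ["GG", "GG", "GG", "AA"]}, index=list("abcd"))
        G = code_genotypes(raw)
        assert list(G.values[:, 0]) == [1.0, 1.0, 1.0, -1.0]
        assert G.markers.loc[0, "allele_high"] == "G"

    def test_heterozygote_coded_zero_and_missing_nan(self):
        raw = pd.DataFrame({"m1": ["GG", "GA", "NA", "AA"]}, index=list("abcd"))
        G = code_genotypes(raw)
        col = G.values[:, 0]
        assert col[1] == 0.0
        assert np.isnan(col[2])

    def test_frequency_tie_broken_lexicographically(self):
        raw = pd.DataFrame({"m1": ["GG", "AA"]}, index=list("ab"))
        G = code_genotypes(raw)
        # A < G, so AA is the +1 homozygote under the tie rule
        assert G.column("m1")[1] == 1.0

    def test_more_than_two_alleles_raises(self):
        raw = pd.DataFrame({"bad": ["GG", "AA", "TT"]}, index=list("abc"))
        with pytest.raises(ValueError, match="bad"):
            code_genotypes(raw)

    def test_monomorphic_marker_excluded(self, caplog):
        raw = pd.DataFrame(
            {"mono": ["GG", "GG", "GG"], "ok": ["GG", "AA", "GG"]}, index=list("abc")
        )
        G = code_genotypes(raw)
        assert list(G.marker_ids) == ["ok"]

    def test_round_trip_recovers_homozygous_calls(self):
        raw = pd.DataFrame(
            {"m1": ["GG", "AA", "GG", "GG"], "m2": ["CC", "CC", "TT", "CC"]},
            index=list("abcd"),
        )
        G = code_genotypes(raw)
        back = decode_genotypes(G)
        pd.testing.assert_frame_equal(back, raw)


class TestMapFunctions:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.0, 0.0), (1e4, 0.5), (50.0, 0.5 * (1 - np.exp(-1.0)))],
    )
    def test_haldane_values(self, d, expected):
        assert recombination_fraction(d) == pytest.approx(expected, abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            recombination_fraction(-1.0)

    @given(st.floats(min_value=0.0, max_value=500.0), st.floats(min_value=1e-6, max_value=100.0))
    @settings(max_examples=50, derandomize=True)
    def test_haldane_strictly_increasing_and_bounded(self, d, delta):
        r1, r2 = recombination_fraction(d), recombination_fraction(d + delta)
        assert 0.0 <= r1 < 0.5 + 1e-12
        assert r2 > r1

    @pytest.mark.parametrize("r,expected", [(0.0, 0.0), (0.5, 0.5), (0.25, 1.0 / 3.0)])
    def test_ril_fraction_values(self, r, expected):
        assert ril_recombination_fraction(r) == pytest.approx(expected, abs=1e-12)

    def test_ril_fraction_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ril_recombination_fraction(0.6)

    @given(st.floats(min_value=1e-6, max_value=0.5 - 1e-6))
    @settings(max_examples=50, derandomize=True)
    def test_ril_fraction_exceeds_single_meiosis(self, r):
        assert ril_recombination_fraction(r) >= r

    def test_ril_fixation_matches_selfing_simulation(self, rng):
        """Brute-force repeated selfing to fixation reproduces R = 2r/(1+2r)."""
        r, n = 0.25, 20000
        # haplotypes of each individual at two loci, start F1: AB / ab
        h1 = np.tile([1, 1], (n, 1))
        h2 = np.tile([0, 0], (n, 1))
        for _ in range(40):
            fixed = (h1 == h2).all(axis=1)
            seg = ~fixed
            if not seg.any():
                break
            m = seg.sum()

            def gamete(k):
                start = rng.integers(0, 2, k)
                rec = rng.random(k) < r
                g = np.empty((k, 2), dtype=int)
                g[:, 0] = np.where(start == 0, h1[seg][np.arange(k), 0], h2[seg][np.arange(k), 0])
                second = np.where(rec, 1 - start, start)
                g[:, 1] = np.where(second == 0, h1[seg][np.arange(k), 1], h2[seg][np.arange(k), 1])
                return g

            h1[seg], h2[seg] = gamete(m), gamete(m)
        recombinant = (h1[:, 0] != h1[:, 1]).mean()
        expect = ril_recombination_fraction(r)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(recombinant - expect) < 3 * se


class TestEffectSetValidation:
    def test_pair_must_be_ordered(self):
        with pytest.raises(ValueError, match="ordered"):
            EpistaticTerm("m9", "m1", 1.0, np.zeros(2))

    def test_sum_to_zero_enforced(self):
        with pytest.raises(ValueError, match="sum-to-zero"):
            QTSEffectSet(
                additive=[AdditiveTerm("m1", 1.0, np.array([1.0, 1.0]))], n_env=2
            )

    def test_sum_to_zero_can_be_disabled(self):
        eff = QTSEffectSet(
            additive=[AdditiveTerm("m1", 1.0, np.array([1.0, 1.0]))],
            n_env=2,
            sum_to_zero=False,
        )
        assert eff.additive[0].ae[0] == 1.0

    def test_duplicate_pair_rejected(self):
        pair = lambda: EpistaticTerm("m1", "m2", 1.0, np.zeros(2))  # noqa: E731
        with pytest.raises(ValueError, match="duplicate"):
            QTSEffectSet(epistatic=[pair(), pair()], n_env=2)


class TestPartitionHeritability:
    def test_single_additive_closed_form(self, balanced_genotypes):
        a, s2 = 1.5, 2.0
        eff = QTSEffectSet(
            additive=[AdditiveTerm("m0", a, np.zeros(1))], sigma2_eps=s2, n_env=1
        )
        rep = partition_heritability(eff, balanced_genotypes)
        expect = 100.0 * a**2 / (a**2 + s2)
        assert rep.components.loc[0, "h2_pct"] == pytest.approx(expect, rel=1e-12)

    def test_zero_effects_zero_components(self, balanced_genotypes):
        eff = QTSEffectSet(
            additive=[AdditiveTerm("m0", 0.0, np.zeros(2))], sigma2_eps=1.0, n_env=2
        )
        rep = partition_heritability(eff, balanced_genotypes)
        assert (rep.components["h2_pct"] == 0).all()
        assert rep.total_h2_pct == 0.0

    def test_accounting_identity(self, balanced_genotypes):
        eff = QTSEffectSet(
            mu=3.0,
            additive=[
                AdditiveTerm("m0", -0.9, np.array([0.4, -0.4])),
                AdditiveTerm("m3", 0.5, np.array([-0.2, 0.2])),
            ],
            epistatic=[EpistaticTerm("m1", "m5", 0.7, np.array([0.3, -0.3]))],
            sigma2_eps=1.3,
            n_env=2,
        )
        rep = partition_heritability(eff, balanced_genotypes)
        assert rep.total_h2_pct == pytest.approx(rep.components["h2_pct"].sum(), abs=1e-9)
        assert 0 <= rep.total_h2_pct <= 100
        assert rep.total_h2_pct >= rep.components["h2_pct"].max()

    def test_invariant_under_line_relabeling(self, balanced_genotypes, rng):
        eff = QTSEffectSet(
            additive=[AdditiveTerm("m2", 1.1, np.array([0.5, -0.5]))],
            sigma2_eps=0.8,
            n_env=2,
        )
        base = partition_heritability(eff, balanced_genotypes)
        perm = rng.permutation(balanced_genotypes.n_lines)
        G2 = GenotypeMatrix(
            balanced_genotypes.line_ids[perm],
            balanced_genotypes.markers,
            balanced_genotypes.values[perm],
        )
        other = partition_heritability(eff, G2)
        assert other.total_h2_pct == pytest.approx(base.total_h2_pct, abs=1e-12)

    def test_zero_total_variance_rejected(self, balanced_genotypes):
        eff = QTSEffectSet(sigma2_eps=0.0, n_env=1)
        with pytest.raises(ValueError, match="zero"):
            partition_heritability(eff, balanced_genotypes)


class TestContainers:
    def test_map_requires_sorted_positions(self):
        bad = pd.DataFrame(
            {"marker": ["a", "b"], "chrom": ["1", "1"], "pos_cm": [5.0, 1.0]}
        )
        with pytest.raises(ValueError, match="non-decreasing"):
            GeneticMap(bad)

    def test_map_read_write_round_trip(self, small_map, tmp_path):
        path = tmp_path / "map.tsv"
        small_map.write(path)
        again = GeneticMap.read(path)
        pd.testing.assert_frame_equal(again.table, small_map.table)

    def test_het_ceiling_enforced(self):
        X = np.array([[1.0, 0.0], [-1.0, 1.0]])
        markers = pd.DataFrame(
            {"marker": ["a", "b"], "chrom": "1", "pos_cm": [0.0, 1.0],
             "allele_high": "A", "allele_low": "B"}
        )
        with pytest.raises(ValueError, match="heterozygote"):
            GenotypeMatrix(["l1", "l2"], markers, X, max_het_fraction=0.0)

    def test_invalid_codes_rejected(self):
        X = np.array([[2.0], [1.0]])
        markers = pd.DataFrame(
            {"marker": ["a"], "chrom": "1", "pos_cm": [0.0],
             "allele_high": "A", "allele_low": "B"}
        )
        with pytest.raises(ValueError, match="coded"):
            GenotypeMatrix(["l1", "l2"], markers, X)

    def test_make_genotypes_helper(self, balanced_genotypes):
        assert balanced_genotypes.n_lines == 60
        assert abs(balanced_genotypes.values.mean()) < 1e-12
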