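"""QTL scan against a brute-force likelihood oracle, thresholds, intervals."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xqtl import qtl
from xqtl.qtl import LRS_CAP
from xqtl.simdata import simulate_ri_genotypes, simulate_trait, uniform_marker_map
from xqtl.types import MarkerMap, QTLSpec, StrainGenotypes

from conftest import two_group_lrs_oracle


def tiny_panel(calls: list[str], n_markers: int = 1) -> StrainGenotypes:
    n = len(calls)
    table = pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(n_markers)],
            "chrom": ["1"] * n_markers,
            "pos_cM": np.arange(n_markers, dtype=float),
            "pos_Mb": np.arange(n_markers, dtype=float),
        }
    )
    arr = np.tile(np.array(calls, dtype="<U1")[:, None], (1, n_markers))
    return StrainGenotypes(
        strains=[f"S{i}" for i in range(n)], markers=MarkerMap(table), calls=arr
    )


class TestMarkerRegression:
    def test_constant_trait_zero_lrs(self):
        geno = tiny_panel(["B"] * 5 + ["D"] * 5, n_markers=3)
        y = pd.Series(2.0, index=geno.strains)
        scan = qtl.marker_regression_scan(y, geno)
        assert (scan.table["LRS"] == 0).all()

    def test_perfect_fit_capped_and_flagged(self):
        geno = tiny_panel(["B"] * 4 + ["D"] * 4)
        y = pd.Series(geno.additive[:, 0], index=geno.strains)
        scan = qtl.marker_regression_scan(y, geno)
        assert scan.table["LRS"].iloc[0] == LRS_CAP
        assert scan.table["flag"].iloc[0] == "perfect_fit"

    def test_monomorphic_marker_flagged(self):
        geno = tiny_panel(["B"] * 6)
        y = pd.Series(np.arange(6.0), index=geno.strains)
        scan = qtl.marker_regression_scan(y, geno)
        assert scan.table["LRS"].iloc[0] == 0.0
        assert scan.table["additive_effect"].iloc[0] == 0.0
        assert scan.table["flag"].iloc[0] == "monomorphic"

    def test_two_group_jitter_matches_oracle_and_half_difference(self):
        rng = np.random.default_rng(77)
        geno = tiny_panel(["B"] * 10 + ["D"] * 10)
        y_vals = np.r_[np.zeros(10), np.ones(10)] + rng.normal(0, 0.01, 20)
        y = pd.Series(y_vals, index=geno.strains)
        scan = qtl.marker_regression_scan(y, geno)
        a = scan.table["additive_effect"].iloc[0]
        d_mean = y_vals[10:].mean()
        b_mean = y_vals[:10].mean()
        assert a == pytest.approx((d_mean - b_mean) / 2, rel=1e-12)
        assert a == pytest.approx(0.5, abs=0.02)
        oracle = two_group_lrs_oracle(y_vals, geno.calls[:, 0])
        assert scan.table["LRS"].iloc[0] == pytest.approx(oracle, rel=0.01)

    def test_scan_equals_oracle_on_random_panels(self):
        rng = np.random.default_rng(5)
        for rep in range(20):
            n = int(rng.integers(6, 21))
            calls = rng.choice(["B", "D"], size=n)
            if len(set(calls)) < 2:
                calls[0] = "B" if calls[0] == "D" else "D"
            geno = tiny_panel(list(calls))
            y_vals = rng.normal(size=n)
            y = pd.Series(y_vals, index=geno.strains)
            scan = qtl.marker_regression_scan(y, geno)
            oracle = two_group_lrs_oracle(y_vals, np.array(calls))
            assert scan.table["LRS"].iloc[0] == pytest.approx(oracle, rel=1e-8)

    def test_fewer_than_three_strains_rejected(self):
        geno = tiny_panel(["B", "D"])
        y = pd.Series([0.0, 1.0], index=geno.strains)
        with pytest.raises(ValueError, match=">= 3 strains"):
            qtl.marker_regression_scan(y, geno)

    @settings(max_examples=30, deadline=None)
    @given(
        alpha=st.floats(0.1, 10.0),
        beta=st.floats(-5.0, 5.0),
        flip=st.booleans(),
    )
    def test_affine_invariance_and_allele_swap(self, alpha, beta, flip):
        """LRS is invariant to y -> alpha*y + beta; swapping B<->D flips the
        sign of the additive effect and leaves LRS unchanged."""
        rng = np.random.default_rng(99)
        calls = list("BBBDDBDD")
        geno = tiny_panel(calls)
        y_vals = rng.normal(size=8)
        y = pd.Series(y_vals, index=geno.strains)
        base = qtl.marker_regression_scan(y, geno)
        if flip:
            swapped = ["B" if c == "D" else "D" for c in calls]
            other = qtl.marker_regression_scan(y, tiny_panel(swapped))
            assert other.table["LRS"].iloc[0] == pytest.approx(
                base.table["LRS"].iloc[0], rel=1e-9
            )
            assert other.table["additive_effect"].iloc[0] == pytest.approx(
                -base.table["additive_effect"].iloc[0], rel=1e-9
            )
        else:
            scaled = qtl.marker_regression_scan(alpha * y + beta, geno)
            assert scaled.table["LRS"].iloc[0] == pytest.approx(
                base.table["LRS"].iloc[0], rel=1e-9, abs=1e-9
            )


class TestLrsToLod:
    @pytest.mark.parametrize(
        "lrs, lod",
        [(0.0, 0.0), (2 * np.log(10), 1.0), (20.54, 20.54 / (2 * np.log(10)))],
    )
    def test_conversion(self, lrs, lod):
        assert qtl.lrs_to_lod(lrs) == pytest.approx(lod, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            qtl.lrs_to_lod(-1.0)


class TestPermutationThreshold:
    def test_threshold_between_order_statistics(self, panel_80, planted_trait):
        y, _ = planted_trait
        thr = qtl.permutation_threshold(y, panel_80, n_perm=100, alpha=0.05, seed=1)
        s = np.sort(thr.max_lrs)
        assert s[94] <= thr.threshold_lrs <= s[95]

    def test_threshold_is_quantile_of_retained_distribution(self, panel_80, planted_trait):
        y, _ = planted_trait
        thr = qtl.permutation_threshold(y, panel_80, n_perm=200, alpha=0.1, seed=2)
        assert thr.threshold_lrs == pytest.approx(np.quantile(thr.max_lrs, 0.9))

    def test_bad_alpha_rejected(self, panel_80, planted_trait):
        y, _ = planted_trait
        with pytest.raises(ValueError):
            qtl.permutation_threshold(y, panel_80, n_perm=100, alpha=0.6, seed=3)

    def test_seed_reproducible(self, panel_80, planted_trait):
        y, _ = planted_trait
        a = qtl.permutation_threshold(y, panel_80, n_perm=100, seed=4)
        b = qtl.permutation_threshold(y, panel_80, n_perm=100, seed=4)
        assert np.array_equal(a.max_lrs, b.max_lrs)


class TestSupportInterval:
    def scan_from_lod(self, lods: list[float]) -> qtl.QTLScan:
        m = len(lods)
        table = pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(m)],
                "chrom": ["1"] * m,
                "pos_cM": np.arange(m, dtype=float),
                "pos_Mb": np.arange(m, dtype=float),
                "LOD": lods,
                "LRS": np.asarray(lods) * 2 * np.log(10),
                "additive_effect": 0.0,
                "flag": "",
            }
        )
        from xqtl.types import QTLScan

        return QTLScan(table=table, trait_id="t", n_strains=20)

    def test_flat_profile_spans_chromosome(self):
        scan = self.scan_from_lod([3.0] * 5)
        iv = qtl.support_interval(scan, "m0", drop_lod=1.5)
        assert (iv.start_Mb, iv.end_Mb) == (0.0, 4.0)

    def test_sharp_peak_spans_flanking_markers(self):
        scan = self.scan_from_lod([0.0, 5.0, 0.0])
        iv = qtl.support_interval(scan, "m1", drop_lod=1.5)
        assert (iv.start_Mb, iv.end_Mb) == (0.0, 2.0)

    def test_triangular_profile_matches_exhaustive_search(self):
        lods = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 4.0, 3.0, 2.0, 1.0, 0.0]
        scan = self.scan_from_lod(lods)
        iv = qtl.support_interval(scan, "m5", drop_lod=1.5)
        # exhaustive: first marker below peak-1.5 walking out from the peak
        cut = 5.0 - 1.5
        left = max(i for i in range(5) if lods[i] < cut)
        right = min(i for i in range(6, 11) if lods[i] < cut)
        assert (iv.start_Mb, iv.end_Mb) == (float(left), float(right))

    def test_non_peak_marker_rejected(self):
        scan = self.scan_from_lod([0.0, 5.0, 0.0])
        with pytest.raises(ValueError, match="not the chromosome-wide"):
            qtl.support_interval(scan, "m0")


class TestClassifyEqtl:
    gene = pd.Series({"chrom": "2", "start": 22.77, "end": 22.88})

    def test_peak_inside_gene_is_cis(self):
        assert qtl.classify_eqtl("2", 22.8, self.gene) == "cis"

    def test_other_chromosome_is_trans(self):
        assert qtl.classify_eqtl("3", 22.8, self.gene) == "trans"

    @pytest.mark.parametrize("pos, expected", [(27.78, "cis"), (27.99, "trans")])
    def test_window_boundary(self, pos, expected):
        # gene end 22.88; 4.9 Mb away -> cis, 5.11 Mb away -> trans at window 5
        assert qtl.classify_eqtl("2", pos, self.gene, cis_window_Mb=5.0) == expected


class TestPlantedRecovery:
    def test_peak_near_causal_marker(self, small_map):
        """With h2 = 0.5 and 80 strains the scan peak lands within 10 cM of
        the causal marker in at least 90 of 100 simulations."""
        hits = 0
        for rep in range(100):
            geno = simulate_ri_genotypes(80, small_map, seed=3000 + rep)
            y = simulate_trait(geno, QTLSpec("m1_015", 1.0, 0.5), seed=4000 + rep)
            scan = qtl.marker_regression_scan(y, geno)
            peak = scan.peak()
            causal = small_map.table.set_index("marker_id").loc["m1_015"]
            if peak["chrom"] == causal["chrom"] and abs(peak["pos_cM"] - causal["pos_cM"]) <= 10:
                hits += 1
        assert hits >= 90
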