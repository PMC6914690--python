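"""GATES: SNP assignment, LD, effective test counts, Simes equivalence."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xqtl import gates
from xqtl.simdata import LDBlock, simulate_ld_panel
from xqtl.types import GeneAnnotation, GeneSNPSet, GWASSummary, LDReference


def make_gss(p_values, snp_ids=None) -> GeneSNPSet:
    p = np.asarray(p_values, float)
    ids = np.asarray(snp_ids if snp_ids is not None else [f"rs{i}" for i in range(len(p))])
    return GeneSNPSet(
        gene_id="G", snp_ids=ids, pos_bp=np.arange(len(p)), p_values=p, window_kb=0.0
    )


def simes(p: np.ndarray) -> float:
    p = np.sort(p)
    m = len(p)
    return float(np.min(m * p / np.arange(1, m + 1)))


class TestAssignSnps:
    def annotation(self, rows):
        return GeneAnnotation(
            pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "start", "end"]),
            species="human",
            units="bp",
        )

    def gwas(self, positions, chrom="10"):
        return GWASSummary(
            pd.DataFrame(
                {
                    "SNP": [f"rs{i}" for i in range(len(positions))],
                    "CHR": chrom,
                    "BP": positions,
                    "A1": "A",
                    "A2": "G",
                    "P": 0.5,
                }
            )
        )

    def test_boundary_snp_included_closed_interval(self):
        ann = self.annotation([("G1", "G1", "10", 100_000, 120_000)])
        g = self.gwas([100_000 - 10_000])  # exactly at start - window
        sets = gates.assign_snps(g, ann, window_kb=10)
        assert len(sets) == 1 and sets[0].snp_ids.tolist() == ["rs0"]

    def test_no_snp_in_any_gene(self):
        ann = self.annotation([("G1", "G1", "10", 100, 200)])
        assert gates.assign_snps(self.gwas([10_000]), ann) == []

    def test_matches_exhaustive_double_loop(self):
        rows = [
            ("G1", "G1", "10", 100, 300),
            ("G2", "G2", "10", 250, 500),
            ("G3", "G3", "11", 100, 300),
        ]
        ann = self.annotation(rows)
        positions = [90, 150, 260, 450, 600]
        g = self.gwas(positions)
        g.table.loc[4, "CHR"] = "11"
        g.table.loc[4, "BP"] = 200
        window = 20 / 1000  # 20 bp as kb
        got = {
            s.gene_id: set(s.snp_ids.tolist())
            for s in gates.assign_snps(g, ann, window_kb=window)
        }
        expected: dict = {}
        for gid, _, chrom, start, end in rows:
            for i, (snp_chrom, bp) in enumerate(zip(g.table["CHR"], g.table["BP"])):
                if str(snp_chrom) == chrom and start - 20 <= bp <= end + 20:
                    expected.setdefault(gid, set()).add(f"rs{i}")
        assert got == expected

    def test_empty_gwas_rejected(self):
        ann = self.annotation([("G1", "G1", "10", 100, 200)])
        empty = GWASSummary(
            pd.DataFrame(columns=["SNP", "CHR", "BP", "A1", "A2", "P"])
        )
        with pytest.raises(ValueError, match="empty"):
            gates.assign_snps(empty, ann)


class TestLdCorrelation:
    def test_duplicated_snp_perfect_correlation(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [1, 1]])
        panel = LDReference(
            snp_ids=np.array(["a", "b"]), chrom=np.array(["1", "1"]),
            pos_bp=np.array([1, 2]), dosages=d,
        )
        R = gates.ld_correlation(panel, ["a", "b"])
        assert R[0, 1] == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        panel = simulate_ld_panel(5000, [LDBlock(1, 0.0) for _ in range(6)], seed=21)
        R = gates.ld_correlation(panel, panel.snp_ids.tolist())
        assert np.abs(R[np.triu_indices(6, 1)]).max() <= 0.05

    def test_single_snp(self):
        panel = simulate_ld_panel(100, [LDBlock(1, 0.0)], seed=22)
        R = gates.ld_correlation(panel, [panel.snp_ids[0]])
        assert R.shape == (1, 1) and R[0, 0] == 1.0

    def test_missing_snp_rejected_with_ids(self):
        panel = simulate_ld_panel(50, [LDBlock(2, 0.0)], seed=23)
        with pytest.raises(KeyError, match="rs_nope"):
            gates.ld_correlation(panel, ["rs_nope"])


class TestEffectiveNumber:
    def test_identity_matrix(self):
        assert gates.effective_number(np.ones(10)) == 10.0

    def test_perfect_ld_collapses_to_one(self):
        lam = np.r_[10.0, np.zeros(9)]
        assert gates.effective_number(lam) == 1.0

    def test_two_snps_partial_correlation(self):
        # p-value correlation 0.6: eigenvalues 1.6 and 0.4, Me = 2 - 0.6
        lam = np.linalg.eigvalsh(np.array([[1.0, 0.6], [0.6, 1.0]]))
        assert gates.effective_number(lam) == pytest.approx(1.4)

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            gates.effective_number(np.array([2.0, -0.5]))


class TestGatesPvalue:
    def test_single_snp_pass_through(self):
        """One assigned SNP: the gene p equals the SNP p (the published
        candidate's gene-level p of 0.0117 is exactly this pass-through)."""
        res = gates.gates_pvalue(make_gss([0.0117]), np.eye(1))
        assert res.p_gene == 0.0117 and res.me == 1.0

    def test_perfect_ld_returns_min_p(self):
        p = [0.2, 0.04, 0.6]
        res = gates.gates_pvalue(make_gss(p), np.ones((3, 3)))
        assert res.p_gene == pytest.approx(0.04) and res.me == pytest.approx(1.0)

    def test_independent_snps_equal_simes(self):
        p = np.array([0.01, 0.02, 0.3, 0.5, 0.9])
        res = gates.gates_pvalue(make_gss(p), np.eye(5))
        assert res.p_gene == pytest.approx(0.05, abs=1e-12)
        assert res.p_gene == pytest.approx(simes(p), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_identity_ld_equals_simes_property(self, data):
        m = data.draw(st.integers(1, 50))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        p = rng.uniform(1e-6, 1.0, size=m)
        res = gates.gates_pvalue(make_gss(p), np.eye(m))
        assert res.p_gene == pytest.approx(simes(p), abs=1e-12)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(31)
        m = 8
        A = rng.normal(size=(m, m))
        R = np.corrcoef(A)
        p = rng.uniform(0.001, 1.0, size=m)
        ids = np.array([f"rs{i}" for i in range(m)])
        base = gates.gates_pvalue(make_gss(p, ids), R)
        perm = rng.permutation(m)
        shuffled = gates.gates_pvalue(
            make_gss(p[perm], ids[perm]), R[np.ix_(perm, perm)]
        )
        assert shuffled.p_gene == pytest.approx(base.p_gene, rel=1e-12)
        assert shuffled.me == pytest.approx(base.me, rel=1e-12)

    def test_prefix_me_bounds_via_result(self):
        rng = np.random.default_rng(32)
        for _ in range(10):
            m = int(rng.integers(2, 12))
            A = rng.normal(size=(m, m + 3))
            R = np.corrcoef(A)
            p = rng.uniform(0.001, 1.0, size=m)
            res = gates.gates_pvalue(make_gss(p), R)
            assert 1.0 <= res.me <= m
            # p_gene <= Me * min(p) since Me(1) = 1
            assert res.p_gene <= res.me * p.min() + 1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gates.gates_pvalue(make_gss([0.1, 0.2]), np.eye(3))


class TestGeneBasedScan:
    def test_planted_signal_detected_and_null_genes_flat(self):
        panel = simulate_ld_panel(400, [LDBlock(5, 0.5) for _ in range(4)], seed=41)
        ann = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_id": [f"G{i}" for i in range(4)],
                    "symbol": [f"G{i}" for i in range(4)],
                    "chrom": "10",
                    "start": [1_000_000 + 25_000 * i for i in range(4)],
                    "end": [1_000_000 + 25_000 * i + 20_000 for i in range(4)],
                }
            ),
            species="human",
            units="bp",
        )
        from xqtl.simdata import simulate_gwas_summary

        gwas = simulate_gwas_summary(panel, ann, {"rs000003": 6.0}, seed=42)
        out = gates.gene_based_scan(gwas, panel, ann)
        sig = out.set_index("gene")["p_gates"]
        assert sig["G0"] < 1e-4
        assert (sig.drop("G0") > 1e-4).all()
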