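"""RPKM, BH-FDR, differential-gene filters, rich factors and 2^-ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycoflav.expression import (
    GeneRecord,
    PathwayMap,
    bh_fdr,
    ddct,
    ddct_table,
    flag_degs,
    rich_factor,
    rpkm,
    rpkm_table,
)
from glycoflav.simulate import SimulationConfig, make_count_table, make_qpcr_table


class TestRPKM:
    def test_closed_form(self):
        assert rpkm(1000, 1000, 10**6) == pytest.approx(1000.0)

    def test_zero_counts(self):
        assert rpkm(0, 500, 10**6) == 0.0

    @given(st.integers(1, 10**6), st.integers(1, 10**5), st.integers(1, 10**9))
    def test_matches_hand_formula(self, counts, length, lib):
        assert rpkm(counts, length, lib) == pytest.approx(
            counts / (length / 1e3) / (lib / 1e6), rel=1e-12
        )

    def test_linearity(self):
        assert rpkm(20, 100, 10**6) == pytest.approx(2 * rpkm(10, 100, 10**6))
        assert rpkm(10, 200, 10**6) == pytest.approx(rpkm(10, 100, 10**6) / 2)
        assert rpkm(10, 100, 2 * 10**6) == pytest.approx(rpkm(10, 100, 10**6) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)

    def test_table_uses_per_sample_library_sizes(self):
        genes = [GeneRecord("g1", 1000, (100, 200)), GeneRecord("g2", 500, (900, 800))]
        table = rpkm_table(genes)
        assert table.loc["g1", "s1"] == pytest.approx(1e9 * 100 / (1000 * 1000.0))
        assert table.loc["g2", "s2"] == pytest.approx(1e9 * 800 / (1000 * 500.0))


def _brute_bh(p):
    """Textbook step-up: q_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order):
        q[i] = min(min(m * p[order[j]] / (j + 1) for j in range(rank_pos, m)), 1.0)
    return q


class TestBHFDR:
    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37]) == pytest.approx([0.37])

    def test_all_equal_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_brute_force_step_up(self, p):
        assert bh_fdr(p) == pytest.approx(_brute_bh(p), abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15), st.randoms())
    def test_order_invariance(self, p, rnd):
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        shuffled = [p[i] for i in idx]
        q = bh_fdr(p)
        q_shuffled = bh_fdr(shuffled)
        assert [q[i] for i in idx] == pytest.approx(list(q_shuffled), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(17)
        p = rng.uniform(size=200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_ref)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestFlagDegs:
    def _one(self, **kw):
        row = {"gene_id": "g", "log2fc": 0.0, "pvalue": 0.5, "fdr": 0.5}
        row.update(kw)
        return flag_degs([row])[0]

    def test_fold_change_exactly_two_passes_global(self):
        assert self._one(log2fc=1.0, fdr=0.01).sig_global is True

    def test_lfc_exactly_one_fails_pathway_criterion(self):
        assert self._one(log2fc=1.0, pvalue=0.01).sig_aa is False

    def test_strictly_above_one_passes_pathway_criterion(self):
        assert self._one(log2fc=1.01, pvalue=0.01).sig_aa is True

    def test_high_fdr_blocks_global(self):
        assert self._one(log2fc=5.0, fdr=0.2).sig_global is False

    def test_downregulation_symmetric(self):
        assert self._one(log2fc=-1.5, fdr=0.01).sig_global is True

    def test_fdr_computed_when_absent(self):
        recs = [{"gene_id": f"g{i}", "log2fc": 2.0, "pvalue": p}
                for i, p in enumerate([0.01, 0.02, 0.03, 0.04])]
        out = flag_degs(recs)
        assert all(d.fdr == pytest.approx(0.04) for d in out)

    def test_flag_counts_monotone_in_thresholds(self):
        rng = np.random.default_rng(23)
        recs = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(300)],
            "log2fc": rng.normal(0, 2, 300),
            "pvalue": rng.uniform(size=300),
        })
        base = sum(d.sig_global for d in flag_degs(recs, fc_min=2, fdr_max=0.05))
        tighter_fc = sum(d.sig_global for d in flag_degs(recs, fc_min=4, fdr_max=0.05))
        tighter_fdr = sum(d.sig_global for d in flag_degs(recs, fc_min=2, fdr_max=0.01))
        assert tighter_fc <= base and tighter_fdr <= base


class TestRichFactor:
    def test_full_overlap(self):
        pmap = PathwayMap.from_pairs([("p1", "g1"), ("p1", "g2")])
        df = rich_factor({"g1", "g2"}, pmap)
        assert df.loc[0, "rich_factor"] == pytest.approx(1.0)

    def test_definition_ratio(self):
        pairs = [("p1", f"g{i}") for i in range(50)]
        pmap = PathwayMap.from_pairs(pairs)
        df = rich_factor({f"g{i}" for i in range(5)}, pmap)
        assert df.loc[0, "rich_factor"] == pytest.approx(0.1)

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(31)
        genes = [f"g{i}" for i in range(200)]
        pairs = [(f"p{k}", g) for k in range(10)
                 for g in rng.choice(genes, size=rng.integers(5, 40), replace=False)]
        pmap = PathwayMap.from_pairs(pairs)
        degs = set(rng.choice(genes, size=60, replace=False))
        df = rich_factor(degs, pmap).set_index("pathway_id")
        for pid, members in pmap.pathways.items():
            assert df.loc[pid, "rich_factor"] == pytest.approx(
                len(degs & members) / len(members)
            )
            assert df.loc[pid, "deg_count"] == len(degs & members)

    def test_sorted_by_rich_factor_desc(self):
        pmap = PathwayMap.from_pairs([("a", "g1"), ("a", "g2"), ("b", "g3")])
        df = rich_factor({"g3"}, pmap)
        assert list(df["pathway_id"]) == ["b", "a"]

    def test_optional_hypergeometric_tail(self):
        pmap = PathwayMap.from_pairs([("p", f"g{i}") for i in range(10)]
                                     + [("q", f"h{i}") for i in range(10)])
        df = rich_factor({f"g{i}" for i in range(10)}, pmap, hypergeometric=True)
        assert "pvalue" in df.columns
        assert df.set_index("pathway_id").loc["p", "pvalue"] < 0.01


class TestDdct:
    def test_all_equal_is_one(self):
        assert ddct(20, 20, 20, 20) == pytest.approx(1.0)

    def test_minus_one_doubles(self):
        # ddCt = (18-20) - (19-20) = -1 -> 2^1 = 2
        assert ddct(18, 20, 19, 20) == pytest.approx(2.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct(float("nan"), 20, 20, 20)

    def test_noiseless_eightfold(self):
        table = make_qpcr_table(SimulationConfig(seed=0, ct_noise_sd=0.0), true_fold=8.0)
        rel = ddct_table(table)["relative_expression"]
        assert np.allclose(rel, 8.0)

    def test_noisy_recovery_within_ten_percent(self):
        table = make_qpcr_table(SimulationConfig(seed=3, ct_noise_sd=0.1), true_fold=8.0)
        rel = ddct_table(table)["relative_expression"].mean()
        assert rel == pytest.approx(8.0, rel=0.1)


class TestSyntheticCounts:
    def test_planted_lfc_recovered_at_scale(self):
        sim = make_count_table(SimulationConfig(seed=2), n_genes=3000, n_de=300, lfc=1.0)
        obs = sim["stats"].set_index("gene_id").loc[sorted(sim["true_de"]), "log2fc"]
        assert obs.mean() == pytest.approx(1.0, abs=0.1)

    def test_null_false_positive_rate(self):
        sim = make_count_table(SimulationConfig(seed=3), n_genes=2000, n_de=0)
        degs = flag_degs(sim["stats"], aa_p_max=0.05, aa_lfc_min=0.0)
        # with no planted effect the p<0.05 rate stays near alpha
        rate = sum(d.pvalue < 0.05 for d in degs) / len(degs)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 2000)
        # and the fold-change-gated global criterion flags almost nothing
        assert sum(d.sig_global for d in degs) / len(degs) <= 0.01
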