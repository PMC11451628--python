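import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from psynmap.de import (DEResult, PseudobulkMatrix, aggregate_pseudobulk,
                        consensus_degs, nb_wald_de, percentile_matched_subset,
                        sc_glm_vs_hsnca, size_factors)
from psynmap.errors import AllZeroUnitError
from psynmap.expression import lognormalize
from psynmap.io import CountMatrix


def _pb(counts, groups, gene_ids=None):
    counts = np.asarray(counts, dtype=np.int64)
    meta = pd.DataFrame({"psyn_group": groups, "n_cells": 100})
    return PseudobulkMatrix(meta, counts,
                            gene_ids or [f"g{j}" for j in range(counts.shape[1])])


class TestAggregate:
    def _cells(self, n, sample="s1", group="psynPos", cell_type="A"):
        return pd.DataFrame({
            "cell_id": [f"{sample}_{group}_{i}" for i in range(n)],
            "sample_id": sample, "psyn_group": group, "cell_type": cell_type})

    def test_exact_sums_and_conservation(self, counts_builder):
        cells = pd.concat([self._cells(2), self._cells(3, group="psynNeg")],
                          ignore_index=True)
        mat = np.arange(10).reshape(5, 2)
        cm = counts_builder(mat, cell_ids=cells.cell_id.tolist())
        pb = aggregate_pseudobulk(cm, cells, min_cells=1)
        assert pb.counts.sum() == mat.sum()
        pos = pb.meta.psyn_group == "psynPos"
        assert pb.counts[pos.to_numpy()].tolist() == [[mat[:2, 0].sum(), mat[:2, 1].sum()]]

    def test_min_cells_drops_unit(self, counts_builder):
        cells = pd.concat([self._cells(4), self._cells(12, group="psynNeg")],
                          ignore_index=True)
        cm = counts_builder(np.ones((16, 2), dtype=int),
                            cell_ids=cells.cell_id.tolist())
        with pytest.warns(UserWarning):
            pb = aggregate_pseudobulk(cm, cells, min_cells=10)
        assert pb.meta.psyn_group.tolist() == ["psynNeg"]

    def test_negative_probes_excluded(self, counts_builder):
        cells = self._cells(3)
        cm = counts_builder(np.ones((3, 2), dtype=int),
                            cell_ids=cells.cell_id.tolist(),
                            panel=["base", "negative_probe"],
                            species=["mouse", "control"])
        pb = aggregate_pseudobulk(cm, cells, min_cells=1)
        assert pb.gene_ids == ["g0"]


class TestSizeFactors:
    def test_identical_units(self):
        pb = _pb([[10, 20, 5], [10, 20, 5]], ["a", "b"])
        assert np.allclose(size_factors(pb), [1.0, 1.0])

    def test_doubled_unit_ratio_two(self):
        pb = _pb([[10, 20, 5], [20, 40, 10]], ["a", "b"])
        s = size_factors(pb)
        assert s[1] / s[0] == pytest.approx(2.0)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(0)
        pb = _pb(rng.poisson(50, size=(6, 30)), list("aaabbb"))
        assert np.exp(np.mean(np.log(size_factors(pb)))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_unit_rejected(self):
        with pytest.raises(AllZeroUnitError):
            size_factors(_pb([[0, 0], [1, 2]], ["a", "b"]))

    def test_matches_independent_median_of_ratios(self):
        """Cross-check against the DESeq2 median-of-ratios implementation."""
        from pydeseq2.preprocessing import deseq2_norm
        rng = np.random.default_rng(1)
        counts = rng.poisson(rng.uniform(5, 200, size=30), size=(8, 30))
        counts[4:] *= 3  # depth imbalance
        pb = _pb(counts, list("aaaabbbb"))
        mine = size_factors(pb)
        _, theirs = deseq2_norm(pd.DataFrame(counts))
        theirs = np.asarray(theirs, dtype=float).ravel()
        theirs = theirs / np.exp(np.mean(np.log(theirs)))  # same normalization
        assert np.allclose(mine, theirs, rtol=1e-10)


class TestNbWaldDE:
    def test_duplicated_units_exact_null(self):
        unit = np.array([17, 3, 250, 41])
        pb = _pb(np.tile(unit, (6, 1)), list("aaabbb"))
        res = nb_wald_de(pb, pb.meta.psyn_group, "a", "b")
        assert np.allclose(res.table.log2FC, 0.0)
        assert np.allclose(res.table.p_raw, 1.0)

    def test_log2fc_antisymmetry(self):
        rng = np.random.default_rng(2)
        pb = _pb(rng.poisson(100, size=(8, 25)), list("aaaabbbb"))
        fwd = nb_wald_de(pb, pb.meta.psyn_group, "a", "b")
        rev = nb_wald_de(pb, pb.meta.psyn_group, "b", "a")
        assert np.allclose(fwd.table.log2FC, -rev.table.log2FC, atol=1e-10)
        assert np.allclose(fwd.table.p_raw, rev.table.p_raw, atol=1e-12)

    def test_separated_gene_flagged_with_pseudocount_lfc(self):
        counts = np.ones((4, 2), dtype=int) * 50
        counts[:2, 1] = 0  # gene g1 all-zero in reference group
        counts[2:, 1] = 20
        pb = _pb(counts, list("aabb"))
        res = nb_wald_de(pb, pb.meta.psyn_group, "a", "b")
        rec = res.table.loc["g1"]
        assert rec.separated
        assert np.isnan(rec.p_raw)
        assert rec.log2FC > 0

    def test_true_effect_recovered(self):
        rng = np.random.default_rng(3)
        lam = np.full((8, 50), 300.0)
        lam[4:, :5] *= 2.0  # log2FC = 1 in 5 genes
        y = rng.poisson(rng.gamma(1 / 0.02, 0.02 * lam))
        pb = _pb(y, list("aaaabbbb"))
        res = nb_wald_de(pb, pb.meta.psyn_group, "a", "b")
        assert res.table.log2FC[:5].mean() == pytest.approx(1.0, abs=0.15)
        assert res.table.significant[:5].all()
        assert not res.table.significant[5:].any()


class TestPercentileSubset:
    def test_enumerable_example(self):
        values = np.arange(1, 101, dtype=float)
        status = np.where(np.arange(100) % 2 == 0, "positive", "negative")
        ids = np.array([f"c{v:.0f}" for v in values])
        neg_high, pos_low = percentile_matched_subset(ids, status, values)
        hi = np.percentile(values, 75)   # 75.25 under linear interpolation
        lo = np.percentile(values, 25)   # 25.75
        assert hi == pytest.approx(75.25) and lo == pytest.approx(25.75)
        want_neg = {f"c{int(v)}" for v, s in zip(values, status)
                    if s == "negative" and v > hi}
        want_pos = {f"c{int(v)}" for v, s in zip(values, status)
                    if s == "positive" and v < lo}
        assert set(neg_high) == want_neg
        assert set(pos_low) == want_pos

    def test_all_negative_gives_empty_positive_subset(self):
        ids = np.array(["a", "b", "c", "d"])
        status = np.array(["negative"] * 4)
        neg_high, pos_low = percentile_matched_subset(ids, status, [1.0, 2, 3, 4])
        assert pos_low == []
        assert neg_high == ["d"]

    def test_subset_means_ordered(self):
        rng = np.random.default_rng(4)
        values = rng.exponential(2, 500)
        status = rng.choice(["positive", "negative"], 500)
        ids = np.arange(500).astype(str)
        neg_high, pos_low = percentile_matched_subset(ids, status, values)
        if neg_high and pos_low:
            vals = pd.Series(values, index=ids)
            assert vals[pos_low].mean() < vals[neg_high].mean()


class TestConsensus:
    def _res(self, cell_type, fdr, lfc):
        table = pd.DataFrame({"log2FC": [lfc], "fdr": [fdr], "separated": [False]},
                             index=pd.Index(["g"], name="gene"))
        return DEResult(table, contrast="x", cell_type=cell_type)

    def test_two_types_same_direction_retained(self):
        out = consensus_degs([self._res("A", 0.01, 1.0), self._res("B", 0.02, 0.5)])
        assert out.gene.tolist() == ["g"]
        assert out.direction.tolist() == ["up"]

    def test_opposite_directions_excluded(self):
        out = consensus_degs([self._res("A", 0.01, 1.0), self._res("B", 0.01, -1.0)])
        assert out.empty

    def test_single_type_excluded(self):
        out = consensus_degs([self._res("A", 0.01, 1.0), self._res("B", 0.5, 1.0)])
        assert out.empty


class TestScGlm:
    def test_constant_zero_gene_skipped(self, counts_builder):
        n = 30
        rng = np.random.default_rng(5)
        mat = np.column_stack([rng.poisson(10, (n, 3)), rng.poisson(5, n),
                               np.zeros(n, dtype=int)])
        cm = counts_builder(mat, gene_ids=["a", "b", "c", "hSNCA", "dead"],
                            species=["mouse"] * 3 + ["human", "mouse"])
        norm = lognormalize(cm)
        res = sc_glm_vs_hsnca(cm, norm, np.ones(n, bool), ["dead", "a"])
        assert res.table.loc["dead", "family"] == "none"
        assert not res.table.loc["dead", "converged"]
        assert np.isnan(res.table.loc["dead", "q"])
        assert np.isfinite(res.table.loc["a", "p_raw"])

    def test_minimum_cell_requirement(self, counts_builder):
        cm = counts_builder(np.ones((10, 2), dtype=int), gene_ids=["hSNCA", "g"],
                            species=["human", "mouse"])
        norm = lognormalize(cm)
        with pytest.raises(ValueError):
            sc_glm_vs_hsnca(cm, norm, np.ones(10, bool), ["g"])

    def test_slope_recovered_within_ci(self):
        rng = np.random.default_rng(6)
        n = 2000
        hk = rng.poisson(12.0, size=(n, 24))
        hs = rng.poisson(rng.gamma(15, 1.0, n))
        base_genes = [f"hk{i}" for i in range(24)] + ["hSNCA"]
        base = np.column_stack([hk, hs])
        cm_base = CountMatrix([f"c{i}" for i in range(n)], base_genes,
                              sp.csr_matrix(base),
                              np.array(["base"] * 25, dtype=object),
                              np.array(["mouse"] * 24 + ["human"], dtype=object))
        norm = lognormalize(cm_base)
        x = norm.gene("hSNCA")
        lib = norm.library_size
        b = 0.5
        mu = np.exp(np.log(lib) + np.log(2.0 / lib.mean()) - b * x.mean() + b * x)
        y = rng.poisson(rng.gamma(1 / 0.3, 0.3 * mu))
        cm = CountMatrix([f"c{i}" for i in range(n)], base_genes + ["target"],
                         sp.csr_matrix(np.column_stack([base, y])),
                         np.array(["base"] * 25 + ["custom"], dtype=object),
                         np.array(["mouse"] * 24 + ["human", "mouse"], dtype=object))
        res = sc_glm_vs_hsnca(cm, norm, np.ones(n, bool), ["target"])
        rec = res.table.loc["target"]
        assert rec.slope - 1.96 * rec.se <= b <= rec.slope + 1.96 * rec.se
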