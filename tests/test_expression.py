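import numpy as np
import pandas as pd
import pytest

from psynmap.errors import (EmptyGroupError, NoSharedGenesError,
                            ZeroLibrarySizeError)
from psynmap.expression import (NormalizedMatrix, ReferenceProfiles,
                                assign_cell_types, average_expression,
                                depth_profile, lognormalize,
                                make_reference_profiles,
                                per_gene_cross_modality_regression,
                                profile_similarity, scale_genes)
from psynmap.io import UNASSIGNED
from psynmap.synth import reference_profiles_from_params


def _norm(values, gene_ids=None, lib=None):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
        gene_ids=gene_ids or [f"g{j}" for j in range(values.shape[1])],
        values=values, scale_factor=1e4,
        library_size=lib if lib is not None else np.full(values.shape[0], 100.0))


class TestLognormalize:
    def test_stated_formula(self, counts_builder):
        cm = counts_builder([[10, 90]])
        norm = lognormalize(cm, scale_factor=1e4)
        assert norm.values[0, 0] == pytest.approx(np.log(1 + 1000), abs=1e-4)

    def test_zero_count_maps_to_zero(self, counts_builder):
        cm = counts_builder([[0, 5]])
        assert lognormalize(cm).values[0, 0] == 0.0

    def test_invariant_to_cell_count_doubling(self, counts_builder):
        a = lognormalize(counts_builder([[3, 7, 10]]))
        b = lognormalize(counts_builder([[6, 14, 20]]))
        assert np.allclose(a.values, b.values)

    def test_negative_probes_excluded(self, counts_builder):
        cm = counts_builder([[10, 90, 900]],
                            panel=["base", "base", "negative_probe"],
                            species=["mouse", "mouse", "control"])
        norm = lognormalize(cm)
        assert norm.gene_ids == ["g0", "g1"]
        assert norm.library_size[0] == 100  # probe counts not in the library
        assert norm.values[0, 0] == pytest.approx(np.log(1 + 1000), abs=1e-4)

    def test_zero_library_raises(self, counts_builder):
        cm = counts_builder([[0, 3]], panel=["base", "negative_probe"],
                            species=["mouse", "control"])
        with pytest.raises(ZeroLibrarySizeError):
            lognormalize(cm)


class TestScaleGenes:
    def test_perfect_covariate_fit_zeroes_gene(self):
        cov = np.array([1.0, 2.0, 3.0, 4.0])
        norm = _norm(np.column_stack([2 * cov + 1, [0, 1, 0, 1]]))
        scaled = scale_genes(norm, covariate=cov)
        assert np.allclose(scaled[:, 0], 0.0)

    def test_two_cell_zscore(self):
        scaled = scale_genes(_norm([[0.0], [2.0]]))
        assert np.allclose(scaled[:, 0], [-0.70710678, 0.70710678])

    def test_constant_gene_all_zeros(self):
        scaled = scale_genes(_norm([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert np.all(scaled[:, 0] == 0)
        assert not np.isnan(scaled).any()


class TestAverageExpression:
    def test_single_cell_group(self):
        avg = average_expression(_norm([[np.log(2)]]), ["a"])
        assert avg.loc["a", "g0"] == pytest.approx(1.0)

    def test_hand_mean(self):
        avg = average_expression(_norm([[np.log(2)], [np.log(4)]]), ["a", "a"])
        assert avg.loc["a", "g0"] == pytest.approx(2.0)

    def test_zero_gene_zero_in_all_groups(self):
        avg = average_expression(_norm([[0.0], [0.0]]), ["a", "b"])
        assert (avg["g0"] == 0).all()

    def test_permutation_invariant_within_groups(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 2, size=(10, 3))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        perm = np.concatenate([rng.permutation(5), 5 + rng.permutation(5)])
        a = average_expression(_norm(vals), groups)
        b = average_expression(_norm(vals[perm]), groups[perm])
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            average_expression(_norm([[1.0]]), ["a", "b"])


class TestAssignCellTypes:
    def _reference(self):
        return ReferenceProfiles(
            ["T1", "T2"], ["g0", "g1", "g2", "g3"],
            np.array([[1.0, -1.0, 1.0, -1.0], [-1.0, 1.0, -1.0, 1.0]]))

    def test_exact_match(self):
        vals = np.array([[2.0, 0.0, 2.0, 0.0], [0.0, 2.0, 0.0, 2.0],
                         [2.0, 0.0, 2.0, 0.0]])
        labels = assign_cell_types(_norm(vals), self._reference(), min_r=0.2)
        assert labels.tolist() == ["T1", "T2", "T1"]

    def test_uncorrelated_unassigned(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 4))
        ref = ReferenceProfiles(["T1"], ["g0", "g1", "g2", "g3"],
                                np.array([[1.0, -1.0, 1.0, -1.0]]))
        labels = assign_cell_types(_norm(vals), ref, min_r=0.999)
        assert (labels == UNASSIGNED).all()

    def test_too_few_shared_genes(self):
        ref = ReferenceProfiles(["T1"], ["x", "y", "g0"], np.array([[1.0, -1.0, 0.5]]))
        with pytest.raises(NoSharedGenesError):
            assign_cell_types(_norm(np.zeros((3, 2))), ref)

    def test_synthetic_recovery_at_default_params(self, default_study):
        from psynmap.io import qc_and_filter
        _, cm = qc_and_filter(default_study.counts)
        norm = lognormalize(cm)
        ref = reference_profiles_from_params(default_study.truth.params)
        labels = assign_cell_types(norm, ref)
        truth = default_study.truth.cells.set_index("cell_id").true_type
        acc = np.mean([l == truth[c] for l, c in zip(labels, cm.cell_ids)])
        assert acc >= 0.95


class TestProfileSimilarity:
    def test_self_similarity_diagonal_one(self):
        from psynmap.synth import GenerativeParams
        ref = reference_profiles_from_params(GenerativeParams())
        sim = profile_similarity(ref, ref)
        assert np.allclose(np.diag(sim.to_numpy()), 1.0)

    def test_anticorrelated_profiles(self):
        a = ReferenceProfiles(["T"], ["g0", "g1", "g2"], np.array([[1.0, 0.0, -1.0]]))
        b = ReferenceProfiles(["U"], ["g0", "g1", "g2"], np.array([[-1.0, 0.0, 1.0]]))
        assert profile_similarity(a, b).loc["T", "U"] == pytest.approx(-1.0)

    def test_independent_syntheses_diagonal_dominant(self, default_study):
        from psynmap.synth import GenerativeParams, generate_study
        other = generate_study(GenerativeParams(n_samples_per_genotype=1, seed=99))
        norm_a = lognormalize(default_study.counts)
        norm_b = lognormalize(other.counts)
        ref_a = make_reference_profiles(norm_a, default_study.truth.cells.true_type)
        ref_b = make_reference_profiles(norm_b, other.truth.cells.true_type)
        sim = profile_similarity(ref_a, ref_b).to_numpy()
        diag = np.diag(sim)
        off = sim[~np.eye(len(sim), dtype=bool)]
        assert diag.mean() > off.mean()


class TestCrossModalityRegression:
    def test_identity_gives_unit_r2(self):
        rng = np.random.default_rng(2)
        a = pd.DataFrame(rng.normal(size=(4, 3)), index=list("wxyz"),
                         columns=["g0", "g1", "g2"])
        res = per_gene_cross_modality_regression(a, a)
        assert np.allclose(res.r2, 1.0)
        assert np.allclose(res.slope, 1.0)

    def test_constant_gene_flagged(self):
        a = pd.DataFrame({"g0": [1.0, 1.0, 1.0], "g1": [0.0, 1.0, 2.0]},
                         index=list("xyz"))
        b = pd.DataFrame({"g0": [0.0, 1.0, 2.0], "g1": [0.0, 1.0, 2.0]},
                         index=list("xyz"))
        res = per_gene_cross_modality_regression(a, b)
        assert res.loc["g0", "degenerate"]
        assert np.isnan(res.loc["g0", "slope"])
        assert not res.loc["g1", "degenerate"]

    def test_r2_decreases_with_noise(self):
        rng = np.random.default_rng(3)
        a = pd.DataFrame(rng.normal(size=(8, 40)), index=[f"t{i}" for i in range(8)])
        a.columns = [f"g{j}" for j in range(40)]
        means = []
        for sigma in (0.1, 1.0, 3.0):
            b = a + rng.normal(0, sigma, size=a.shape)
            res = per_gene_cross_modality_regression(a, b)
            means.append(res.r2.mean())
        assert means[0] > means[1] > means[2]


class TestDepthProfile:
    AXIS = ((0.0, 0.0), (0.0, 1.0))  # depth along +y

    def _cells(self, ys, types):
        from psynmap.io import CellRecord
        out = []
        for k, (y, t) in enumerate(zip(ys, types)):
            verts = np.array([[0, y - 1], [2, y - 1], [2, y + 1], [0, y + 1]])
            c = CellRecord(f"c{k}", "s1", "tg", "M", "cortex", (1.0, y), verts)
            c.cell_type = t
            out.append(c)
        return out

    def test_single_depth_single_bin(self):
        cells = self._cells([10, 10, 10, 0, 100], ["A", "A", "A", "B", "B"])
        prof = depth_profile(cells, self.AXIS, n_bins=5)
        row = prof.loc["A"].to_numpy()
        assert row.sum() == pytest.approx(1.0)
        assert (row > 0).sum() == 1

    def test_uniform_type_flat_profile(self):
        rng = np.random.default_rng(4)
        ys = rng.uniform(0, 100, 4000)
        cells = self._cells(ys, ["A"] * 4000)
        prof = depth_profile(cells, self.AXIS, n_bins=4)
        assert np.allclose(prof.loc["A"], 0.25, atol=0.03)

    def test_rows_sum_to_one(self, default_study):
        sample = [c for c in default_study.cells if c.sample_id == "tg1"]
        types = default_study.truth.cells.set_index("cell_id").true_type
        labels = [types[c.cell_id] for c in sample]
        prof = depth_profile(sample, self.AXIS, n_bins=10, labels=labels)
        assert np.allclose(prof.sum(axis=1), 1.0)

    def test_banded_types_peak_in_their_band(self, default_study):
        """Layer-banded generation leaves each type's modal depth in its band."""
        sample = [c for c in default_study.cells if c.sample_id == "tg1"]
        types = default_study.truth.cells.set_index("cell_id").true_type
        labels = [types[c.cell_id] for c in sample]
        prof = depth_profile(sample, self.AXIS, n_bins=10, labels=labels)
        params = default_study.truth.params
        for t, (lo, hi), _ in params.region_layout:
            if t == "InN":
                continue  # spread across the full depth
            peak_bin = prof.loc[t].to_numpy().argmax()
            center = (peak_bin + 0.5) / 10
            assert lo - 0.1 <= center <= hi + 0.1
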