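import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ixprofile.io_formats import ExpressionMatrix
from ixprofile.ixp import (IxpParams, gaussian_influence, group_average_profile,
                           integrate_profile, transform_dataset)
from ixprofile.network import GeneWeights
from ixprofile.reorder import NodeOrdering


def uniform_weights(genes):
    return GeneWeights(w={g: 1.0 for g in genes}, mode="uniform")


def identity_ordering(genes):
    return NodeOrdering(position={g: i + 1 for i, g in enumerate(genes)},
                        method="random")


def brute_force_profile(expr, ordering, weights, sigma, missing=0.0):
    """Independent double-loop evaluation of the Gaussian superposition."""
    n = ordering.n
    out = np.zeros(n)
    for i in range(1, n + 1):
        for g, p in ordering.position.items():
            x = expr.get(g, missing)
            k = 1.0 if (sigma == 0 and i == p) else (
                0.0 if sigma == 0 else np.exp(-((i - p) ** 2) / (2 * sigma ** 2)))
            out[i - 1] += weights.w[g] * x * k
    return out


class TestGaussianInfluence:
    @pytest.mark.parametrize("delta,sigma,expected", [
        (0, 3.7, 1.0),
        (2, 2, np.exp(-0.5)),
        (5, 0, 0.0),
        (0, 0, 1.0),
    ])
    def test_closed_form(self, delta, sigma, expected):
        assert gaussian_influence(delta, sigma) == pytest.approx(expected)

    def test_array_input(self):
        out = gaussian_influence(np.array([0, 1, 2]), 1.0)
        np.testing.assert_allclose(out, [1.0, np.exp(-0.5), np.exp(-2.0)])

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_influence(1, -1.0)


class TestIntegrateProfile:
    def test_delta_kernel_identity(self):
        genes = ["A", "B", "C"]
        f = integrate_profile({"A": 1.0, "B": 0.0, "C": 0.0},
                              identity_ordering(genes), uniform_weights(genes),
                              IxpParams(r=0.0))
        np.testing.assert_array_equal(f, [1.0, 0.0, 0.0])

    def test_single_peak_closed_form(self):
        genes = ["A", "B", "C"]
        f = integrate_profile({"A": 1.0, "B": 0.0, "C": 0.0},
                              identity_ordering(genes), uniform_weights(genes),
                              IxpParams(r=0.1, base_bandwidth=10.0))  # sigma = 1
        np.testing.assert_allclose(f, [1.0, np.exp(-0.5), np.exp(-2.0)])

    def test_new_peak_of_coordinated_weak_genes(self):
        """Three closely ordered weak genes form a peak exceeding the
        off-position influence of a single strong gene (sigma = 1)."""
        genes = [f"G{i}" for i in range(5)]
        ordering = identity_ordering(genes)
        weights = uniform_weights(genes)
        params = IxpParams(r=0.1, base_bandwidth=10.0)  # sigma = 1
        weak = {"G0": 0.0, "G1": 0.4, "G2": 0.4, "G3": 0.4, "G4": 0.0}
        strong = {"G0": 1.0, "G1": 0.0, "G2": 0.0, "G3": 0.0, "G4": 0.0}
        f_weak = integrate_profile(weak, ordering, weights, params)
        f_strong = integrate_profile(strong, ordering, weights, params)
        np.testing.assert_allclose(
            f_weak, brute_force_profile(weak, ordering, weights, 1.0))
        trio_center = f_weak[2]
        assert trio_center == pytest.approx(0.4 * (1 + 2 * np.exp(-0.5)))
        assert trio_center > 0.88 > f_strong[1:].max()  # strongest off-peak value

    def test_matches_brute_force_on_random_input(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(8)]
        perm = rng.permutation(8)
        ordering = NodeOrdering(
            position={g: int(p) + 1 for g, p in zip(genes, perm)}, method="random")
        weights = GeneWeights(w={g: float(rng.uniform(0.1, 1)) for g in genes},
                              mode="degree")
        expr = {g: float(rng.normal()) for g in genes[:6]}  # two genes missing
        params = IxpParams(r=0.35, base_bandwidth=10.0)
        np.testing.assert_allclose(
            integrate_profile(expr, ordering, weights, params),
            brute_force_profile(expr, ordering, weights, params.sigma))

    def test_extraneous_expression_genes_ignored(self):
        genes = ["A", "B"]
        f = integrate_profile({"A": 1.0, "ZZ": 99.0}, identity_ordering(genes),
                              uniform_weights(genes), IxpParams(r=0.0))
        np.testing.assert_array_equal(f, [1.0, 0.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=6),
           st.lists(st.floats(-5, 5), min_size=6, max_size=6),
           st.floats(-3, 3), st.floats(-3, 3),
           st.floats(0, 0.9))
    def test_linearity(self, xs, ys, a, b, r):
        genes = [f"G{i}" for i in range(6)]
        ordering = identity_ordering(genes)
        weights = uniform_weights(genes)
        params = IxpParams(r=r)
        fx = integrate_profile(dict(zip(genes, xs)), ordering, weights, params)
        fy = integrate_profile(dict(zip(genes, ys)), ordering, weights, params)
        combo = {g: a * x + b * y for g, x, y in zip(genes, xs, ys)}
        np.testing.assert_allclose(
            integrate_profile(combo, ordering, weights, params),
            a * fx + b * fy, atol=1e-9)


def make_em(values, genes, samples, labels=None):
    em_labels = None if labels is None else pd.Series(labels, index=samples)
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=samples),
                            labels=em_labels)


class TestTransformDataset:
    def test_r0_reduction_is_exact_permutation(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(7)]
        em = make_em(rng.normal(size=(7, 4)), genes, [f"S{j}" for j in range(4)])
        perm = rng.permutation(7)
        ordering = NodeOrdering(
            position={g: int(p) + 1 for g, p in zip(genes, perm)}, method="random")
        fm = transform_dataset(em, ordering, uniform_weights(genes),
                               IxpParams(r=0.0), normalization="none")
        expected = np.zeros((4, 7))
        for gi, g in enumerate(genes):
            expected[:, ordering.position[g] - 1] = em.values.loc[g]
        np.testing.assert_array_equal(fm.values.to_numpy(), expected)

    def test_identical_samples_identical_features(self):
        genes = ["A", "B", "C"]
        em = make_em(np.tile([[1.0], [2.0], [3.0]], 2), genes, ["S1", "S2"])
        fm = transform_dataset(em, identity_ordering(genes), uniform_weights(genes),
                               IxpParams(r=0.5))
        np.testing.assert_array_equal(fm.values.loc["S1"], fm.values.loc["S2"])

    def test_constant_gene_zero_after_z(self):
        genes = ["A", "B"]
        em = make_em([[5.0, 5.0], [1.0, 2.0]], genes, ["S1", "S2"])
        fm = transform_dataset(em, identity_ordering(genes), uniform_weights(genes),
                               IxpParams(r=0.0), normalization="per_gene_z")
        np.testing.assert_array_equal(fm.values[1].to_numpy(), [0.0, 0.0])

    def test_no_shared_genes_error(self):
        em = make_em([[1.0]], ["ZZZ"], ["S1"])
        with pytest.raises(ValueError, match="shared"):
            transform_dataset(em, identity_ordering(["A", "B"]),
                              uniform_weights(["A", "B"]), IxpParams())

    def test_permutation_equivariance(self):
        """Consistently relabeling genes leaves the feature matrix unchanged."""
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(6)]
        values = rng.normal(size=(6, 3))
        samples = ["S1", "S2", "S3"]
        ordering = identity_ordering(genes)
        weights = GeneWeights(w={g: float(rng.uniform(0.2, 1)) for g in genes},
                              mode="degree")
        params = IxpParams(r=0.4)
        fm = transform_dataset(make_em(values, genes, samples), ordering,
                               weights, params)
        relabel = {g: f"X{g}" for g in genes}
        fm2 = transform_dataset(
            make_em(values, [relabel[g] for g in genes], samples),
            NodeOrdering(position={relabel[g]: p for g, p in ordering.position.items()},
                         method="random"),
            GeneWeights(w={relabel[g]: w for g, w in weights.w.items()}, mode="degree"),
            params)
        np.testing.assert_array_equal(fm.values.to_numpy(), fm2.values.to_numpy())

    def test_total_variation_smoothing_monotonicity(self):
        """On 20 random profiles: the smoothed profile's total variation per
        unit kernel mass is non-increasing in r (2% slack for boundary
        discretization), and never exceeds the raw profile's TV."""
        from ixprofile.ixp import position_kernel
        rng = np.random.default_rng(21)
        n = 30
        genes = [f"G{i}" for i in range(n)]
        ordering = identity_ordering(genes)
        weights = uniform_weights(genes)
        for _ in range(20):
            em = make_em(rng.normal(size=(n, 1)), genes, ["S1"])
            tv, tv_norm = [], []
            for r in [0.0, 0.1, 0.3, 0.5, 0.7, 0.9]:
                params = IxpParams(r=r)
                row = transform_dataset(em, ordering, weights, params).values.to_numpy()[0]
                mass = position_kernel(n, params.sigma)[n // 2].sum()
                tv.append(np.abs(np.diff(row)).sum())
                tv_norm.append(tv[-1] / mass)
            assert all(t <= tv[0] + 1e-9 for t in tv[1:])
            assert all(tv_norm[i + 1] <= 1.02 * tv_norm[i] + 1e-9
                       for i in range(len(tv_norm) - 1))

    def test_provenance_recorded(self):
        genes = ["A", "B"]
        em = make_em([[1.0], [2.0]], genes, ["S1"])
        fm = transform_dataset(em, identity_ordering(genes), uniform_weights(genes),
                               IxpParams(r=0.2), normalization="per_gene_z")
        assert fm.provenance["r"] == 0.2
        assert fm.provenance["normalization"] == "per_gene_z"


class TestGroupAverageProfile:
    def test_examples(self):
        genes = ["A", "B"]
        em = make_em([[0.0, 2.0], [2.0, 0.0]], genes, ["S1", "S2"],
                     labels=[0, 1])
        fm = transform_dataset(em, identity_ordering(genes), uniform_weights(genes),
                               IxpParams(r=0.0))
        avg = group_average_profile(fm, em.labels)
        np.testing.assert_array_equal(avg[0], [0.0, 2.0])
        np.testing.assert_array_equal(avg[1], [2.0, 0.0])
        both = pd.Series([0, 0], index=["S1", "S2"])
        np.testing.assert_array_equal(group_average_profile(fm, both)[0], [1.0, 1.0])

    def test_unlabeled_sample_error(self):
        genes = ["A"]
        em = make_em([[1.0]], genes, ["S1"])
        fm = transform_dataset(em, identity_ordering(genes), uniform_weights(genes),
                               IxpParams())
        with pytest.raises(ValueError, match="unlabeled"):
            group_average_profile(fm, pd.Series({"OTHER": 0}))
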