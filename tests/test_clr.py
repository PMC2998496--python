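"""B-spline MI estimation and CLR scoring against independent oracles."""

import numpy as np
import pytest

from hepnet.clr import (
    CLRParameters,
    DegenerateProfile,
    bspline_weights,
    clr_scores,
    collapse_probes,
    infer_network,
    mi_matrix,
    mutual_information,
    threshold_network,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles


def deboor_basis(z, n_bins, order):
    """Cox-de Boor recursion evaluated pointwise (textbook form)."""
    k = order - 1
    top = n_bins - k
    t = np.concatenate([np.zeros(k), np.arange(top + 1, dtype=float), np.full(k, top)])
    t_full = np.concatenate([t, [t[-1]]])  # pad for index safety

    def B(i, deg, x):
        if deg == 0:
            # half-open bins, closed at the domain end
            if t[i] <= x < t[i + 1]:
                return 1.0
            if x == top and t[i] < t[i + 1] and t[i + 1] == top:
                return 1.0
            return 0.0
        out = 0.0
        if t[i + deg] > t[i]:
            out += (x - t[i]) / (t[i + deg] - t[i]) * B(i, deg - 1, x)
        if t_full[i + deg + 1] > t[i + 1]:
            out += (t_full[i + deg + 1] - x) / (t_full[i + deg + 1] - t[i + 1]) * B(
                i + 1, deg - 1, x
            )
        return out

    return np.array([[B(i, k, x) for i in range(n_bins)] for x in z])


def hard_bin_mi(x, y, n_bins):
    """Plug-in MI from equal-width hard binning (bits)."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def bins(v):
        lo, hi = v.min(), v.max()
        idx = np.floor((v - lo) / (hi - lo) * n_bins).astype(int)
        return np.clip(idx, 0, n_bins - 1)

    bx, by = bins(x), bins(y)
    joint = np.zeros((n_bins, n_bins))
    for a, b in zip(bx, by):
        joint[a, b] += 1
    joint /= len(x)
    px, py = joint.sum(1), joint.sum(0)

    def H(p):
        p = p[p > 0]
        return -(p * np.log2(p)).sum()

    return H(px) + H(py) - H(joint.ravel())


class TestBsplineWeights:
    def test_partition_of_unity(self, rng):
        x = rng.normal(size=500)
        for order in (1, 2, 3):
            w = bspline_weights(x, 10, order)
            assert w.shape == (500, 10)
            assert (w >= 0).all()
            assert np.allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_order_one_is_hard_binning(self, rng):
        x = rng.uniform(size=200)
        w = bspline_weights(x, 10, 1)
        assert set(np.unique(w)) <= {0.0, 1.0}
        lo, hi = x.min(), x.max()
        expected = np.clip(np.floor((x - lo) / (hi - lo) * 10).astype(int), 0, 9)
        assert (np.argmax(w, axis=1) == expected).all()

    def test_order_three_matches_de_boor_recursion(self, rng):
        x = rng.normal(size=120)
        w = bspline_weights(x, 10, 3)
        lo, hi = x.min(), x.max()
        z = (x - lo) / (hi - lo) * (10 - 2)
        ref = deboor_basis(z, 10, 3)
        assert np.allclose(w, ref, atol=1e-10)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateProfile):
            bspline_weights(np.ones(10), 10, 3)


class TestMutualInformation:
    def test_symmetry(self, rng):
        p = CLRParameters()
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert mutual_information(x, y, p) == pytest.approx(
            mutual_information(y, x, p), abs=1e-12
        )

    def test_self_mi_order_one_equals_hard_binned_entropy(self, rng):
        x = rng.normal(size=300)
        p = CLRParameters(spline_order=1)
        got = mutual_information(x, x, p)
        lo, hi = x.min(), x.max()
        idx = np.clip(np.floor((x - lo) / (hi - lo) * 10).astype(int), 0, 9)
        counts = np.bincount(idx, minlength=10) / len(x)
        counts = counts[counts > 0]
        assert got == pytest.approx(-(counts * np.log2(counts)).sum(), abs=1e-12)

    def test_independent_uniforms_near_zero(self):
        rng = np.random.default_rng(7)
        x, y = rng.uniform(size=10_000), rng.uniform(size=10_000)
        assert mutual_information(x, y, CLRParameters()) < 0.05

    def test_affine_invariance(self, rng):
        p = CLRParameters()
        x, y = rng.normal(size=80), rng.normal(size=80)
        base = mutual_information(x, y, p)
        for a, b in ((2.5, -1.0), (0.3, 7.0)):
            assert mutual_information(a * x + b, y, p) == pytest.approx(base, abs=1e-10)

    def test_constant_input_gives_zero(self, rng):
        assert mutual_information(np.ones(50), rng.normal(size=50), CLRParameters()) == 0.0

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            mutual_information(rng.normal(size=5), rng.normal(size=6), CLRParameters())


class TestMIMatrix:
    def test_duplicated_rows_share_self_mi(self, rng):
        vals = rng.normal(size=(4, 30))
        vals[1] = vals[0]
        mi = mi_matrix(make_matrix(vals, scale="log2"), CLRParameters())
        assert mi.values[0, 1] == pytest.approx(mi.values[0, 0], abs=1e-10)

    def test_invariant_to_sample_permutation(self, rng):
        vals = rng.normal(size=(5, 40))
        p = CLRParameters()
        m1 = mi_matrix(make_matrix(vals, scale="log2"), p)
        perm = rng.permutation(40)
        m2 = mi_matrix(make_matrix(vals[:, perm], scale="log2"), p)
        assert np.allclose(m1.values, m2.values, atol=1e-12)

    def test_matches_looped_pairwise_calls(self, rng):
        vals = rng.normal(size=(5, 25))
        p = CLRParameters()
        mi = mi_matrix(make_matrix(vals, scale="log2"), p)
        for i in range(5):
            for j in range(5):
                assert mi.values[i, j] == pytest.approx(
                    mutual_information(vals[i], vals[j], p), abs=1e-10
                )


class TestCLRScores:
    def test_flat_background_gives_zero_scores(self):
        from hepnet.clr import MIMatrix

        G = 5
        vals = np.full((G, G), 0.2)
        np.fill_diagonal(vals, 1.0)
        s = clr_scores(MIMatrix([f"g{i}" for i in range(G)], vals, CLRParameters()))
        off = s.scores[~np.eye(G, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_score_matrix_symmetric(self, rng):
        vals = rng.normal(size=(8, 40))
        s = clr_scores(mi_matrix(make_matrix(vals, scale="log2"), CLRParameters()))
        assert np.allclose(s.scores, s.scores.T, atol=1e-12)

    def test_single_elevated_pair_matches_row_statistics(self, rng):
        from hepnet.clr import MIMatrix

        G = 10
        base = rng.uniform(0.1, 0.12, size=(G, G))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 2.0)
        base[2, 7] = base[7, 2] = 0.9
        p = CLRParameters()
        s = clr_scores(MIMatrix([f"g{i}" for i in range(G)], base, p))
        # oracle: z from each endpoint's off-diagonal mean/population sd
        def z(i, j):
            bg = np.delete(base[i], i)
            return max(0.0, (base[i, j] - bg.mean()) / bg.std())

        assert s.scores[2, 7] == pytest.approx(
            np.sqrt(z(2, 7) ** 2 + z(7, 2) ** 2), rel=1e-10
        )

    def test_fewer_than_three_genes_rejected(self, rng):
        from hepnet.clr import MIMatrix

        with pytest.raises(ValueError):
            clr_scores(MIMatrix(["a", "b"], np.eye(2), CLRParameters()))


class TestThreshold:
    def _scores(self, values):
        from hepnet.clr import CLRScores

        G = values.shape[0]
        return CLRScores(
            [f"g{i}" for i in range(G)], values, np.zeros_like(values), values, CLRParameters()
        )

    def test_inclusive_boundary(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 2.5
        v[0, 2] = v[2, 0] = 1.9
        v[1, 2] = v[2, 1] = 2.0
        net = threshold_network(self._scores(v))
        assert net.n_edges == 2
        assert net.edge_set() == {frozenset(("g0", "g1")), frozenset(("g1", "g2"))}

    def test_cutoff_zero_keeps_positive_pairs(self, rng):
        v = np.abs(rng.normal(size=(4, 4))) + 0.1
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        net = threshold_network(self._scores(v), CLRParameters(z_cutoff=0.0))
        assert net.n_edges == 6

    def test_cutoff_above_max_gives_empty(self, rng):
        v = np.abs(rng.normal(size=(4, 4)))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        net = threshold_network(self._scores(v), CLRParameters(z_cutoff=1e6))
        assert net.n_edges == 0
        assert net.nodes == set()


class TestPipelineEquivalences:
    def test_order_one_clr_equals_hard_binned_brute_force(self, rng):
        """Full pipeline with spline order 1 reproduces a from-scratch
        hard-binned implementation on a 50x20 fixture."""
        vals = rng.normal(size=(50, 20))
        p = CLRParameters(spline_order=1)
        mi = mi_matrix(make_matrix(vals, scale="log2"), p)
        G = 50
        ref = np.zeros((G, G))
        for i in range(G):
            for j in range(i, G):
                ref[i, j] = ref[j, i] = hard_bin_mi(vals[i], vals[j], 10)
        assert np.allclose(mi.values, ref, atol=1e-12)
        # and the z-standardization agrees with a direct recomputation
        s = clr_scores(mi)
        mean = np.array([np.delete(ref[i], i).mean() for i in range(G)])
        sd = np.array([np.delete(ref[i], i).std() for i in range(G)])
        zi = np.maximum((ref - mean[:, None]) / sd[:, None], 0.0)
        assert np.allclose(s.scores, np.sqrt(zi**2 + zi.T**2) * ~np.eye(G, dtype=bool), atol=1e-10)

    def test_permutation_destroys_edge_evidence(self, rng):
        """Independently shuffling each gene's samples wipes out the MI that
        the inferred network's edges rest on: permuted MI scored against the
        original background statistics retains almost no edges."""
        from hepnet.simulate import SimulationConfig, generate_truth_networks, simulate_expression
        from hepnet.expression import normalize_chain

        # module-dense panel: the regime where the z >= 2 threshold is
        # informative (every gene's background has genuine spread)
        cfg = SimulationConfig(seed=3, n_genes=60, n_tfs=7, targets_per_tf=7,
                               n_compendium_conditions=120)
        ta, _ = generate_truth_networks(cfg)
        m, _ = simulate_expression(ta, cfg, design="compendium", system="a")
        norm, _ = normalize_chain(m)
        p = CLRParameters()
        mi = mi_matrix(norm, p)
        net = threshold_network(clr_scores(mi), p)
        assert net.n_edges > 10  # strong signal present
        # permute each gene's samples independently and re-estimate MI
        vals = norm.values.to_numpy().copy()
        for g in range(vals.shape[0]):
            rng.shuffle(vals[g])
        mi_perm = mi_matrix(make_matrix(vals, gene_ids=norm.gene_ids, scale="log2"), p)
        # score permuted MI against the *original* background model
        G = len(mi.gene_ids)
        off = mi.values[~np.eye(G, dtype=bool)].reshape(G, G - 1)
        mean, sd = off.mean(axis=1), off.std(axis=1)
        z = np.maximum((mi_perm.values - mean[:, None]) / sd[:, None], 0.0)
        scores = np.sqrt(z**2 + z.T**2)
        pos = {g: i for i, g in enumerate(mi.gene_ids)}
        surviving = sum(
            1
            for e in net.edge_set()
            if scores[pos[min(e)], pos[max(e)]] >= p.z_cutoff
        )
        assert surviving < 0.05 * net.n_edges


class TestCollapseProbes:
    def test_max_variance_probe_wins(self, rng):
        vals = np.array([[1.0, 1.1, 0.9], [0.0, 5.0, -5.0], [2.0, 2.0, 2.0]])
        m = make_matrix(vals, gene_ids=["p1", "p2", "p3"], scale="log2")
        out = collapse_probes(m, {"p1": "GENE", "p2": "GENE", "p3": "OTHER"})
        assert sorted(out.gene_ids) == ["GENE", "OTHER"]
        assert np.allclose(out.values.loc["GENE"], vals[1])
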