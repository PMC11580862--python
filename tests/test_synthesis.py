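import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abmkf.macrostate import MacroVector
from abmkf.synthesis import (
    NeighborhoodModel,
    QuantizationConfig,
    build_neighborhood_model,
    largest_remainder,
    one_hot_decode,
    one_hot_encode,
    pair_ensembles,
    quantize_error_diffuse,
    rescale_molecular,
    rescale_onehot,
    simple_synthesis_viral,
    spatial_synthesis_viral,
)
from abmkf.viral import (
    INFECTED,
    MolecularField,
    default_viral_schema,
    init_viral,
    step_viral,
    summarize_viral,
)

L1_ONLY = QuantizationConfig(l1=1.0, l2=0.0, l3=0.0)


def _is_stable(match, d2):
    """No blocking pair: no (post i, pred j) both preferring each other."""
    n = len(match)
    partner_of_post = match.post_to_pred
    partner_of_pred = match.pred_to_post
    for i in range(n):
        for j in range(n):
            if partner_of_post[i] == j:
                continue
            i_prefers = (d2[i, j], j) < (d2[i, partner_of_post[i]], partner_of_post[i])
            j_prefers = (d2[i, j], i) < (d2[partner_of_pred[j], j], partner_of_pred[j])
            if i_prefers and j_prefers:
                return False
    return True


class TestPairEnsembles:
    def test_identical_point_sets_identity(self, rng):
        pts = rng.standard_normal((8, 3))
        match = pair_ensembles(pts, pts)
        assert np.array_equal(match.post_to_pred, np.arange(8))

    def test_two_point_dominant_pairing(self):
        pred = np.array([[0.0], [10.0]])
        post = np.array([[0.1], [9.9]])
        match = pair_ensembles(pred, post)
        assert match.post_to_pred.tolist() == [0, 1]

    @settings(deadline=None, max_examples=40)
    @given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=10_000))
    def test_no_blocking_pairs(self, n, seed):
        r = np.random.default_rng(seed)
        pred = r.standard_normal((n, 2))
        post = r.standard_normal((n, 2))
        match = pair_ensembles(pred, post)
        d2 = ((post[:, None, :] - pred[None, :, :]) ** 2).sum(axis=-1)
        assert _is_stable(match, d2)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pair_ensembles(rng.standard_normal((3, 2)), rng.standard_normal((4, 2)))


class TestLargestRemainder:
    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=1, max_value=8))
    def test_sum_preserved(self, seed, k):
        r = np.random.default_rng(seed)
        total = int(r.integers(0, 200))
        vals = r.dirichlet(np.ones(k)) * total
        out = largest_remainder(vals, total=total)
        assert out.sum() == total
        assert (out >= 0).all()
        assert (np.abs(out - vals) < 1.0 + 1e-9).all()

    def test_integer_input_is_identity(self):
        assert np.array_equal(largest_remainder([3.0, 5.0, 0.0]), [3, 5, 0])


class TestOneHot:
    def test_basis_mapping(self):
        grid = np.array([[0, 1], [4, 2]])
        f = one_hot_encode(grid, 5)
        assert np.array_equal(f[0, 0], [1, 0, 0, 0, 0])
        assert np.array_equal(f[0, 1], [0, 1, 0, 0, 0])
        assert np.array_equal(one_hot_decode(f), grid)

    def test_site_sum_is_count_vector(self, rng):
        grid = rng.integers(0, 5, size=(9, 7))
        f = one_hot_encode(grid, 5)
        tally = np.bincount(grid.ravel(), minlength=5)
        assert np.array_equal(f.sum(axis=(0, 1)), tally)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            one_hot_encode(np.array([[5]]), 5)


class TestRescaleOnehot:
    def test_identity_counts(self, rng):
        grid = rng.integers(0, 3, size=(4, 4))
        counts = np.bincount(grid.ravel(), minlength=3)
        f = one_hot_encode(grid, 3)
        assert np.allclose(rescale_onehot(f, counts, counts), f)

    def test_componentwise_scaling(self, rng):
        grid = rng.integers(0, 2, size=(4, 4))
        counts = np.bincount(grid.ravel(), minlength=2).astype(float)
        new = np.array([counts[0] * 2, counts.sum() - counts[0] * 2])
        f = one_hot_encode(grid, 2)
        out = rescale_onehot(f, counts, new)
        assert np.allclose(out[..., 0], f[..., 0] * 2)

    def test_site_sums_hit_target(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 6))
            grid = rng.integers(0, k, size=(5, 5))
            counts = np.bincount(grid.ravel(), minlength=k)
            new = largest_remainder(rng.dirichlet(np.ones(k)) * 25, total=25)
            out = rescale_onehot(one_hot_encode(grid, k), counts, new)
            assert np.allclose(out.sum(axis=(0, 1)), new, atol=1e-9)

    def test_absent_category_spreads_uniformly(self):
        grid = np.zeros((2, 2), dtype=int)
        out = rescale_onehot(one_hot_encode(grid, 2), [4, 0], [3, 1])
        assert np.allclose(out[..., 1], 0.25)
        assert np.allclose(out.sum(axis=(0, 1)), [3, 1])

    def test_total_mismatch_rejected(self):
        grid = np.zeros((2, 2), dtype=int)
        with pytest.raises(ValueError):
            rescale_onehot(one_hot_encode(grid, 2), [4, 0], [4, 1])


class TestQuantizeErrorDiffuse:
    def test_onehot_fixed_point(self, rng):
        grid = rng.integers(0, 5, size=(6, 6))
        counts = np.bincount(grid.ravel(), minlength=5)
        out = quantize_error_diffuse(one_hot_encode(grid, 5), counts, L1_ONLY, None, rng)
        assert np.array_equal(out, grid)

    def test_two_site_l1_minimal_labeling(self, rng):
        # 1x2 lattice: the L1-minimal feasible labeling is (cat0, cat1)
        field = np.array([[[0.6, 0.4], [0.4, 0.6]]])
        out = quantize_error_diffuse(field, np.array([1, 1]), L1_ONLY, None, rng)
        assert out.tolist() == [[0, 1]]

    def test_random_fields_counts_exact(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 6))
            field = rng.random((5, 5, k))
            target = largest_remainder(rng.dirichlet(np.ones(k)) * 25, total=25)
            out = quantize_error_diffuse(field, target, L1_ONLY, None, rng)
            assert np.array_equal(np.bincount(out.ravel(), minlength=k), target)

    def test_mass_conserved_mid_pass(self, rng):
        for _ in range(10):
            k = int(rng.integers(2, 5))
            grid = rng.integers(0, k, size=(5, 5))
            counts = np.bincount(grid.ravel(), minlength=k)
            tgt = largest_remainder(rng.dirichlet(np.ones(k)) * 25, total=25)
            f = rescale_onehot(one_hot_encode(grid, k), counts, tgt)
            _, det = quantize_error_diffuse(
                f, tgt, L1_ONLY, None, rng, return_details=True
            )
            assert np.allclose(det["mass_trace"], det["mass_trace"][0], atol=1e-9)

    def test_attains_bruteforce_minimum_small_lattices(self, rng):
        """With the neighborhood terms off, the quantization error matches
        exhaustive enumeration over feasible labelings on tiny lattices."""
        for _ in range(25):
            w, h = (int(v) for v in rng.integers(1, 4, size=2))
            k = int(rng.integers(2, 5))
            grid = rng.integers(0, k, size=(w, h))
            counts = np.bincount(grid.ravel(), minlength=k)
            tgt = largest_remainder(rng.dirichlet(np.ones(k)) * w * h, total=w * h)
            field = rescale_onehot(one_hot_encode(grid, k), counts, tgt)
            out = quantize_error_diffuse(field, tgt, L1_ONLY, None, rng)
            cost = ((np.eye(k)[out] - field) ** 2).sum()

            flat = field.reshape(-1, k)
            best = np.inf
            for lab in itertools.product(range(k), repeat=w * h):
                if np.any(np.bincount(lab, minlength=k) != tgt):
                    continue
                c = sum(((np.eye(k)[c_] - flat[i]) ** 2).sum() for i, c_ in enumerate(lab))
                best = min(best, c)
            assert cost <= best + 1e-9

    def test_infeasible_targets_rejected(self, rng):
        field = rng.random((3, 3, 2))
        with pytest.raises(ValueError):
            quantize_error_diffuse(field, np.array([5, 5]), L1_ONLY, None, rng)
        with pytest.raises(ValueError):
            quantize_error_diffuse(field, np.array([-1, 10]), L1_ONLY, None, rng)


class TestNeighborhoodModel:
    def test_uniform_grid_equal_queries(self):
        grid = np.zeros((4, 4), dtype=int)
        fld = np.zeros((4, 4))
        model = NeighborhoodModel.fit([grid], [fld])
        interior = np.zeros(9, dtype=int)
        p_interior = model.probability(interior, 0.0)
        assert p_interior == model.probability(interior.copy(), 0.0)

    def test_unseen_config_finite(self):
        grid = np.zeros((4, 4), dtype=int)
        model = NeighborhoodModel.fit([grid], [np.zeros((4, 4))])
        weird = np.full(9, 3)
        assert np.isfinite(model.neg_log_prob(weird, 123.0))
        assert model.neg_log_prob(weird, 123.0) > model.neg_log_prob(np.zeros(9, dtype=int), 0.0)

    def test_frequencies_match_direct_counting(self):
        grid = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [2, 2, 0, 0], [2, 2, 0, 0]]
        )
        fld = np.zeros((4, 4))
        model = NeighborhoodModel.fit([grid], [fld])
        # count the interior patch at (1,1) by hand
        patch = grid[0:3, 0:3].ravel()
        key = (tuple(patch), 0)
        direct = 0
        padded = np.pad(grid, 1, constant_values=-1)
        for x in range(4):
            for y in range(4):
                if tuple(padded[x : x + 3, y : y + 3].ravel()) == key[0]:
                    direct += 1
        assert model.counts[key] == direct
        assert model.total == 16

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            NeighborhoodModel.fit([], [])
        with pytest.raises(ValueError):
            build_neighborhood_model([])


class TestRescaleMolecular:
    def test_identity_and_zero(self, rng):
        fld = MolecularField("x", rng.random((5, 5)))
        same = rescale_molecular(fld, fld.total)
        assert np.allclose(same.values, fld.values)
        zero = rescale_molecular(fld, 0.0)
        assert zero.total == 0.0

    def test_total_hits_target(self, rng):
        fld = MolecularField("x", rng.random((5, 5)))
        out = rescale_molecular(fld, 42.0)
        assert out.total == pytest.approx(42.0, rel=1e-9)

    def test_spatial_correlation_preserved(self, rng):
        fld = MolecularField("x", rng.random((8, 8)) + 0.1)
        out = rescale_molecular(fld, 7.5)
        r = np.corrcoef(fld.values.ravel(), out.values.ravel())[0, 1]
        assert r == pytest.approx(1.0)

    def test_zero_to_positive_is_uniform(self):
        fld = MolecularField("x", np.zeros((4, 4)))
        out = rescale_molecular(fld, 8.0)
        assert np.allclose(out.values, 0.5)


def _shifted_target(micro, rng, schema):
    mv = summarize_viral(micro, schema)
    vals = mv.values.copy()
    epi = vals[4:9]
    move = min(5, int(epi[0]))
    epi[0] -= move
    epi[1] += move
    vals[3] = max(0.0, vals[3] * rng.uniform(0.5, 1.5))
    vals[12] = rng.integers(0, 5)
    return MacroVector(schema, vals)


class TestViralSynthesis:
    @pytest.fixture
    def schema(self, viral_params):
        return default_viral_schema(viral_params.n_sites)

    def test_simple_fixed_point_changes_nothing(self, hotspot_micro, schema, rng):
        target = summarize_viral(hotspot_micro, schema)
        out = simple_synthesis_viral(target, hotspot_micro, rng)
        assert np.array_equal(out.epithelium, hotspot_micro.epithelium)
        assert np.array_equal(out.endothelium, hotspot_micro.endothelium)

    def test_simple_minimality_single_swap(self, hotspot_micro, schema, rng):
        target = summarize_viral(hotspot_micro, schema)
        vals = target.values.copy()
        vals[schema.index("epi_healthy")] -= 1
        vals[schema.index("epi_infected")] += 1
        out = simple_synthesis_viral(MacroVector(schema, vals), hotspot_micro, rng)
        assert (out.epithelium != hotspot_micro.epithelium).sum() == 1

    @pytest.mark.parametrize("algorithm", ["simple", "spatial"])
    def test_macro_consistency(self, hotspot_micro, schema, rng, algorithm):
        for _ in range(20):
            target = _shifted_target(hotspot_micro, rng, schema)
            if algorithm == "simple":
                out = simple_synthesis_viral(target, hotspot_micro, rng)
            else:
                out = spatial_synthesis_viral(target, hotspot_micro, rng=rng)
            got = summarize_viral(out, schema).values
            assert np.array_equal(got[4:], target.values[4:])  # counts exact
            assert np.allclose(got[:4], target.values[:4], rtol=1e-9, atol=1e-9)

    def test_spatial_identity_target_fixed_point(self, hotspot_micro, schema, rng):
        target = summarize_viral(hotspot_micro, schema)
        out = spatial_synthesis_viral(target, hotspot_micro, cfg=L1_ONLY, rng=rng)
        assert np.array_equal(out.epithelium, hotspot_micro.epithelium)

    def test_spatial_preserves_hotspots_better(self, hotspot_micro, schema):
        """Modest count shifts: spatially aware synthesis creates no more
         8-connected infected components than random relabeling (paired)."""
        from scipy import ndimage

        struct = np.ones((3, 3))
        wins = 0
        trials = 20
        for i in range(trials):
            r = np.random.default_rng(500 + i)
            target = _shifted_target(hotspot_micro, r, schema)
            simple = simple_synthesis_viral(target, hotspot_micro, r)
            spatial = spatial_synthesis_viral(target, hotspot_micro, rng=r)
            _, n_simple = ndimage.label(simple.epithelium == INFECTED, structure=struct)
            _, n_spatial = ndimage.label(spatial.epithelium == INFECTED, structure=struct)
            wins += n_spatial <= n_simple
        assert wins >= 0.9 * trials

    def test_spatial_with_neighborhood_model(self, viral_params, hotspot_micro, schema, rng):
        models = build_neighborhood_model([hotspot_micro])
        target = _shifted_target(hotspot_micro, rng, schema)
        out = spatial_synthesis_viral(
            target, hotspot_micro, cfg=QuantizationConfig(), models=models, rng=rng
        )
        got = summarize_viral(out, schema).values
        assert np.array_equal(got[4:], target.values[4:])
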