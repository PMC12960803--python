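"""Consensus rules against brute-force oracles and simulation properties."""

import itertools

import numpy as np
import pytest

from lcfusion.consensus import (
    ConsensusModel,
    consensus_accco,
    consensus_rf,
    consensus_wv,
    encode_rf_features,
    fit_weights,
)
from lcfusion.raster import CategoricalRaster, GridSpec
from lcfusion.synthetic import (
    SyntheticConfig,
    corrupt,
    default_ensemble_confusions,
    generate_truth,
    sample_labeled_points,
)

NODATA = 0


# ---------------------------------------------------------------------------
# independent brute-force scorers (pure python, per pixel)
# ---------------------------------------------------------------------------

def brute_wv(votes, f1, classes):
    """Weighted-vote winner for one pixel; `votes` may contain None."""
    if all(v is None for v in votes):
        return None
    best = None
    for c in classes:  # ascending: lowest code wins exact ties
        score = sum(f1[d][classes.index(c)] for d, v in enumerate(votes) if v == c)
        support = sum(1 for v in votes if v == c)
        key = (score, support)
        if best is None or key > best[0]:
            best = (key, c)
    return best[1]


def brute_accco(votes, cond, classes):
    if all(v is None for v in votes):
        return None
    best = None
    for c in classes:
        k = classes.index(c)
        score = 0.0
        support = 0
        for d, v in enumerate(votes):
            if v is None:
                continue
            a = classes.index(v)
            if v == c:
                score += cond[d][k][k]
                support += 1
            else:
                score -= cond[d][a][k]
        key = (score, support)
        if best is None or key > best[0]:
            best = (key, c)
    return best[1]


def maps_from_patterns(patterns, n_datasets, classes):
    """One-row rasters whose columns enumerate the vote patterns."""
    n = len(patterns)
    grid = GridSpec(origin_x=0, origin_y=10, dx=10, dy=10, nrows=1, ncols=n, crs="t")
    maps = []
    for d in range(n_datasets):
        vals = np.array(
            [[NODATA if p[d] is None else p[d] for p in patterns]], dtype=np.int32
        )
        maps.append(
            CategoricalRaster(values=vals, grid=grid, nodata=NODATA,
                              class_domain=frozenset(classes))
        )
    return maps


def random_model(n_datasets, classes, rng):
    c = len(classes)
    f1 = rng.uniform(0.05, 1.0, size=(n_datasets, c))
    cond = []
    for _ in range(n_datasets):
        m = rng.dirichlet(np.ones(c) * 0.8, size=c)
        cond.append(m)
    return ConsensusModel(
        classes=tuple(classes),
        dataset_names=tuple(f"m{d}" for d in range(n_datasets)),
        f1_weights=f1,
        cond_conf=cond,
        cond_conf_col=[m / m.sum(axis=0, keepdims=True) for m in cond],
    )


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_datasets,n_classes", [(2, 2), (3, 3), (2, 4), (4, 2)])
    def test_wv_and_accco_match_brute_force(self, n_datasets, n_classes, rng):
        classes = list(range(1, n_classes + 1))
        patterns = list(itertools.product(classes + [None], repeat=n_datasets))
        maps = maps_from_patterns(patterns, n_datasets, classes)
        for _ in range(3):
            model = random_model(n_datasets, classes, rng)
            wv = consensus_wv(maps, model).values[0]
            ac = consensus_accco(maps, model).values[0]
            f1_list = model.f1_weights.tolist()
            cond_list = [m.tolist() for m in model.cond_conf]
            for i, p in enumerate(patterns):
                exp_wv = brute_wv(list(p), f1_list, classes)
                exp_ac = brute_accco(list(p), cond_list, classes)
                assert wv[i] == (NODATA if exp_wv is None else exp_wv), p
                assert ac[i] == (NODATA if exp_ac is None else exp_ac), p

    def test_equal_weights_reduce_to_majority_vote(self, rng):
        # WV with all-equal weights == plain majority with the tie rule
        for n_datasets, n_classes in [(2, 2), (3, 3), (4, 4)]:
            classes = list(range(1, n_classes + 1))
            patterns = list(itertools.product(classes + [None], repeat=n_datasets))
            maps = maps_from_patterns(patterns, n_datasets, classes)
            model = ConsensusModel(
                classes=tuple(classes),
                dataset_names=tuple(f"m{d}" for d in range(n_datasets)),
                f1_weights=np.full((n_datasets, n_classes), 0.5),
                cond_conf=[np.full((n_classes, n_classes), 1 / n_classes)] * n_datasets,
            )
            got = consensus_wv(maps, model).values[0]
            for i, p in enumerate(patterns):
                votes = [v for v in p if v is not None]
                if not votes:
                    assert got[i] == NODATA
                    continue
                counts = {c: votes.count(c) for c in set(votes)}
                top = max(counts.values())
                expected = min(c for c, n in counts.items() if n == top)
                assert got[i] == expected, p


class TestInvariants:
    def test_unanimity_and_identity(self, rng):
        classes = list(range(1, 5))
        model = random_model(3, classes, rng)
        grid = GridSpec(origin_x=0, origin_y=20, dx=10, dy=10, nrows=2, ncols=2, crs="t")
        vals = np.array([[3, 3], [3, 3]], dtype=np.int32)
        r = CategoricalRaster(values=vals, grid=grid, nodata=NODATA,
                              class_domain=frozenset(classes))
        # D=1 identity (AccCo needs a positive diagonal to return the input)
        ident = ConsensusModel(
            classes=tuple(classes), dataset_names=("m0",),
            f1_weights=model.f1_weights[:1],
            cond_conf=[np.eye(4)], cond_conf_col=[np.eye(4)],
        )
        assert (consensus_wv([r], ident).values == vals).all()
        assert (consensus_accco([r], ident).values == vals).all()
        # unanimity across three maps with positive diagonal weights
        diag_model = ConsensusModel(
            classes=tuple(classes), dataset_names=("a", "b", "c"),
            f1_weights=rng.uniform(0.2, 1.0, size=(3, 4)),
            cond_conf=[np.eye(4)] * 3, cond_conf_col=[np.eye(4)] * 3,
        )
        assert (consensus_wv([r, r, r], diag_model).values == vals).all()
        assert (consensus_accco([r, r, r], diag_model).values == vals).all()

    def test_permutation_invariance(self, rng):
        classes = list(range(1, 4))
        patterns = list(itertools.product(classes + [None], repeat=3))
        maps = maps_from_patterns(patterns, 3, classes)
        model = random_model(3, classes, rng)
        perm = [2, 0, 1]
        maps_p = [maps[i] for i in perm]
        model_p = ConsensusModel(
            classes=model.classes,
            dataset_names=tuple(model.dataset_names[i] for i in perm),
            f1_weights=model.f1_weights[perm],
            cond_conf=[model.cond_conf[i] for i in perm],
            cond_conf_col=[model.cond_conf_col[i] for i in perm],
        )
        np.testing.assert_array_equal(
            consensus_wv(maps, model).values, consensus_wv(maps_p, model_p).values
        )
        np.testing.assert_array_equal(
            consensus_accco(maps, model).values, consensus_accco(maps_p, model_p).values
        )


class TestFitWeights:
    def _ensemble(self, seed=0, shape=(96, 96), n_classes=4, n_points=5000):
        cfg = SyntheticConfig(seed=seed, shape=shape, n_classes=n_classes, smoothness=4.0)
        truth = generate_truth(cfg)
        rng = np.random.default_rng(seed + 50)
        confs = []
        for d in range(3):
            m = np.full((n_classes, n_classes), 0.0)
            diag = rng.uniform(0.75, 0.95, size=n_classes)
            for c in range(n_classes):
                m[c, c] = diag[c]
                m[c, np.arange(n_classes) != c] = (1 - diag[c]) / (n_classes - 1)
            confs.append(m)
        maps = [corrupt(truth, m, seed=seed + 100 + d) for d, m in enumerate(confs)]
        sample = sample_labeled_points(truth, n_points, seed=seed + 7)
        return truth, maps, confs, sample

    def test_perfect_map_gets_unit_f1_row(self):
        truth, maps, confs, sample = self._ensemble()
        model = fit_weights([truth] + maps, sample, {1: 1.0})
        np.testing.assert_allclose(model.f1_weights[0], 1.0)

    def test_refit_is_deterministic(self):
        _, maps, _, sample = self._ensemble()
        a = fit_weights(maps, sample, {1: 1.0})
        b = fit_weights(maps, sample, {1: 1.0})
        np.testing.assert_array_equal(a.f1_weights, b.f1_weights)

    def test_cond_conf_recovers_generator_rows(self):
        # fitted row-normalized confusion close to the population one at n=5000
        truth, maps, confs, sample = self._ensemble(seed=4)
        model = fit_weights(maps, sample, {1: 1.0})
        classes = sorted(truth.class_domain)
        for d, conf in enumerate(confs):
            # population conditional q(ref|mapped) from the realized pair
            joint = np.zeros((len(classes), len(classes)))
            for i, ci in enumerate(classes):
                for j, cj in enumerate(classes):
                    joint[i, j] = np.sum((maps[d].values == ci) & (truth.values == cj))
            q_pop = joint / joint.sum(axis=1, keepdims=True)
            assert np.abs(model.cond_conf[d] - q_pop).max() < 0.03

    def test_never_mapped_class_flagged_empty(self):
        truth, maps, confs, sample = self._ensemble()
        # blank out class 4 in the first map
        values = maps[0].values.copy()
        values[values == 4] = 1
        maps[0] = maps[0].with_values(values)
        model = fit_weights(maps, sample, {1: 1.0})
        assert model.empty_rows[0][3]
        assert model.f1_weights[0][3] == 0.0

    def test_serialization_round_trip(self, tmp_path):
        _, maps, _, sample = self._ensemble()
        model = fit_weights(maps, sample, {1: 1.0})
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ConsensusModel.from_json(path)
        np.testing.assert_allclose(back.f1_weights, model.f1_weights)
        np.testing.assert_allclose(back.cond_conf[1], model.cond_conf[1])


class TestRfEncoding:
    def test_stated_example(self):
        # D=2, C=3, votes (2,3), F1 rows (0.5,0.6,0.7)/(0.3,0.4,0.9)
        classes = (1, 2, 3)
        grid = GridSpec(origin_x=0, origin_y=10, dx=10, dy=10, nrows=1, ncols=1, crs="t")
        m1 = CategoricalRaster(values=np.array([[2]], dtype=np.int32), grid=grid,
                               nodata=NODATA, class_domain=frozenset(classes))
        m2 = CategoricalRaster(values=np.array([[3]], dtype=np.int32), grid=grid,
                               nodata=NODATA, class_domain=frozenset(classes))
        model = ConsensusModel(
            classes=classes, dataset_names=("a", "b"),
            f1_weights=np.array([[0.5, 0.6, 0.7], [0.3, 0.4, 0.9]]),
            cond_conf=[np.eye(3)] * 2, cond_conf_col=[np.eye(3)] * 2,
        )
        feats = encode_rf_features([m1, m2], model)
        np.testing.assert_allclose(feats[0], [0, 0.6, 0, 0, 0, 0.9])

    def test_all_nodata_pixel_zero_vector_and_block_structure(self, rng):
        classes = (1, 2, 3)
        grid = GridSpec(origin_x=0, origin_y=10, dx=10, dy=10, nrows=1, ncols=4, crs="t")
        v1 = np.array([[1, 0, 2, 3]], dtype=np.int32)
        v2 = np.array([[0, 0, 1, 1]], dtype=np.int32)
        maps = [CategoricalRaster(values=v, grid=grid, nodata=NODATA,
                                  class_domain=frozenset(classes)) for v in (v1, v2)]
        model = random_model(2, list(classes), rng)
        feats = encode_rf_features(maps, model)
        assert (feats[1] == 0).all()  # fully nodata pixel
        # exactly one nonzero per contributing dataset block
        for i, (a, b) in enumerate(zip(v1[0], v2[0])):
            assert (feats[i, :3] != 0).sum() == (1 if a != NODATA else 0)
            assert (feats[i, 3:] != 0).sum() == (1 if b != NODATA else 0)


class TestConsensusRf:
    def test_same_seed_identical_map(self):
        cfg = SyntheticConfig(seed=2, shape=(48, 48), n_classes=4, smoothness=4.0)
        truth = generate_truth(cfg)
        confs = default_ensemble_confusions(n_datasets=2, n_classes=4) + (np.eye(4),)
        maps = [corrupt(truth, m, seed=10 + d) for d, m in enumerate(confs)]
        sample = sample_labeled_points(truth, 800, seed=3)
        model = fit_weights(maps, sample, {1: 1.0})
        train = sample_labeled_points(truth, 500, seed=4)
        a = consensus_rf(maps, model, train, seed=9, n_trees=50)
        b = consensus_rf(maps, model, train, seed=9, n_trees=50)
        np.testing.assert_array_equal(a.values, b.values)

    def test_small_training_class_raises(self):
        cfg = SyntheticConfig(seed=2, shape=(32, 32), n_classes=3, smoothness=3.0)
        truth = generate_truth(cfg)
        maps = [corrupt(truth, np.eye(3), seed=1)]
        sample = sample_labeled_points(truth, 200, seed=3)
        model = fit_weights(maps, sample, {1: 1.0})
        train = sample_labeled_points(truth, 100, seed=4)
        pts = train.points
        keep = pts.index[pts.final_label != 2][:50].union(pts.index[pts.final_label == 2][:1])
        train.points = pts.loc[keep]
        with pytest.raises(ValueError, match="fewer than 2"):
            consensus_rf(maps, model, train, seed=0, n_trees=10)

    def test_rf_with_perfect_member_matches_that_member(self):
        # noiseless truth among the inputs: RF consensus OA >= that map's OA
        cfg = SyntheticConfig(seed=6, shape=(64, 64), n_classes=4, smoothness=4.0)
        truth = generate_truth(cfg)
        noisy = corrupt(truth, np.full((4, 4), 0.25) + 0.0 * np.eye(4), seed=1)
        maps = [truth, noisy]
        sample = sample_labeled_points(truth, 1500, seed=2)
        model = fit_weights(maps, sample, {1: 1.0})
        train = sample_labeled_points(truth, 800, seed=3)
        rf = consensus_rf(maps, model, train, seed=0, n_trees=100)
        held = sample_labeled_points(truth, 2000, seed=5)
        row, col = rf.grid.locate(held.points.x.to_numpy(), held.points.y.to_numpy())
        oa_rf = (rf.values[row, col] == held.points.final_label.to_numpy()).mean()
        oa_truth = 1.0
        assert oa_rf >= oa_truth - 0.02
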