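"""Dempster-Shafer uncertainty, mean-field adjustment, SNGP behavior."""
import math

import numpy as np
import pytest

from segclr import calibrate_threshold, dempster_shafer, mean_field_adjust
from segclr.classify import train_resnet2
from segclr.sngp import auroc, fit_sngp


def scalar_ds(h, k):
    return k / (k + sum(math.exp(v) for v in h))


class TestDempsterShafer:
    @pytest.mark.parametrize("k", [2, 3, 4, 10])
    def test_zero_logits_give_half(self, k):
        assert dempster_shafer(np.zeros(k)) == pytest.approx(0.5)

    def test_plug_in_example(self):
        u = dempster_shafer(np.log([2.0, 2.0]))
        assert u == pytest.approx(1 / 3)

    def test_monotone_decreasing_in_each_logit(self):
        rng = np.random.default_rng(0)
        h = rng.standard_normal(4)
        base = dempster_shafer(h)
        for i in range(4):
            h2 = h.copy()
            h2[i] += 0.5
            assert dempster_shafer(h2) < base

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            k = int(rng.integers(2, 8))
            h = rng.uniform(-5, 5, k)
            assert dempster_shafer(h) == pytest.approx(scalar_ds(h, k),
                                                       abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            dempster_shafer(np.array([np.inf, 0.0]))


class TestMeanField:
    def test_lambda_zero_identity(self):
        h = np.array([[1.0, -2.0, 0.5]])
        np.testing.assert_allclose(mean_field_adjust(h, np.array([3.0]), 0.0), h)

    def test_zero_variance_identity(self):
        h = np.array([[1.0, -2.0]])
        np.testing.assert_allclose(mean_field_adjust(h, np.array([0.0])), h)

    def test_plug_in_example(self):
        assert mean_field_adjust(np.array([1.0]), np.array([3.0]),
                                 1.0)[0] == pytest.approx(0.5)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            h = float(rng.uniform(-4, 4))
            var = float(rng.uniform(0, 10))
            lam = float(rng.uniform(0, 3))
            expect = h / math.sqrt(1 + lam * var)
            got = mean_field_adjust(np.array([h]), np.array([var]), lam)[0]
            assert got == pytest.approx(expect, abs=1e-12)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            mean_field_adjust(np.array([1.0]), np.array([-1.0]))


class TestThresholdCalibration:
    def test_perfectly_separated(self):
        u = np.array([0.1, 0.2, 0.8, 0.9])
        t, f1 = calibrate_threshold(u, [False, False, True, True])
        assert 0.2 < t < 0.8
        assert f1 == pytest.approx(1.0)

    def test_hand_set_matches_exhaustive_scan(self):
        u = np.array([0.1, 0.4, 0.3, 0.9])
        y = np.array([False, False, True, True])
        t, f1 = calibrate_threshold(u, y)
        # exhaustive oracle over all cut points
        best = -1.0
        for cut in np.linspace(0, 1, 1001):
            pred = u > cut
            tp = (pred & y).sum()
            fp = (pred & ~y).sum()
            fn = (~pred & y).sum()
            d = 2 * tp + fp + fn
            best = max(best, 2 * tp / d if d else 0.0)
        assert f1 == pytest.approx(best)

    def test_beats_any_fixed_quantile(self):
        rng = np.random.default_rng(3)
        u = np.concatenate([rng.beta(2, 5, 50), rng.beta(5, 2, 50)])
        y = np.repeat([False, True], 50)
        t, f1 = calibrate_threshold(u, y)
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            cut = np.quantile(u, q)
            pred = u > cut
            tp = (pred & y).sum()
            fp = (pred & ~y).sum()
            fn = (~pred & y).sum()
            d = 2 * tp + fp + fn
            assert f1 >= (2 * tp / d if d else 0.0) - 1e-12

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(np.full(4, 0.3), [True, False, True, False])


def blobs(rng, k=3, n=60, dim=8, spread=0.15):
    centers = rng.standard_normal((k, dim)) * 2.5
    x = np.concatenate([c + spread * rng.standard_normal((n, dim))
                        for c in centers])
    y = np.repeat([f"c{i}" for i in range(k)], n)
    return x, y, centers


class TestSNGPClassifier:
    def test_accuracy_close_to_plain_resnet2(self):
        """In-distribution accuracy within 0.02 of the unconstrained
        ResNet-2 across 5 seeds."""
        deltas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x, y, _ = blobs(rng)
            half = np.arange(len(x)) % 2 == 0
            sngp = fit_sngp(x[half], y[half], seed=seed, epochs=40,
                            rff_dim=256)
            plain = train_resnet2(x[half], y[half], seed=seed, epochs=40)
            acc_s = (sngp.predict(x[~half]) == y[~half]).mean()
            acc_p = (plain.predict(x[~half]) == y[~half]).mean()
            deltas.append(acc_p - acc_s)
        assert np.mean(deltas) <= 0.02

    def test_variance_grows_far_from_data(self):
        rng = np.random.default_rng(0)
        x, y, centers = blobs(rng)
        model = fit_sngp(x, y, seed=0, epochs=40, rff_dim=256)
        in_var = model.predict_uncertainty(x).variance
        far = centers.mean(axis=0) + 10 * x.std() * rng.standard_normal(
            (50, x.shape[1]))
        far_var = model.predict_uncertainty(far).variance
        assert np.median(far_var) > np.median(in_var)

    def test_refit_same_seed_identical(self):
        rng = np.random.default_rng(1)
        x, y, _ = blobs(rng, n=30)
        a = fit_sngp(x, y, seed=4, epochs=10, rff_dim=128)
        b = fit_sngp(x, y, seed=4, epochs=10, rff_dim=128)
        qa = a.predict_uncertainty(x)
        qb = b.predict_uncertainty(x)
        np.testing.assert_array_equal(qa.adjusted_logits, qb.adjusted_logits)
        np.testing.assert_array_equal(qa.uncertainty, qb.uncertainty)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_sngp(np.zeros((10, 4)), ["a"] * 10)

    def test_held_out_blob_class_is_more_uncertain(self):
        rng = np.random.default_rng(2)
        x, y, _ = blobs(rng)
        in_mask = y != "c2"
        model = fit_sngp(x[in_mask], y[in_mask], seed=0, epochs=40,
                         rff_dim=256)
        u_in = model.predict_uncertainty(x[in_mask]).uncertainty
        u_out = model.predict_uncertainty(x[~in_mask]).uncertainty
        assert np.median(u_out) > np.median(u_in)
        assert auroc(np.concatenate([u_in, u_out]),
                     np.repeat([False, True], [in_mask.sum(),
                                               (~in_mask).sum()])) >= 0.8


class _OracleOODClassifier:
    """Perfect in-distribution predictions; u = 0 in-dist, 1 for OOD.

    Inputs encode their class index in dimension 0; out-of-distribution
    rows carry the marker 99."""

    class_names = ["c0", "c1"]

    def predict_uncertainty(self, x):
        from segclr.sngp import UncertaintyOutput

        idx = np.round(np.atleast_2d(x)[:, 0]).astype(int)
        logits = np.zeros((len(idx), 2))
        logits[idx == 0, 0] = 5.0
        logits[idx != 0, 1] = 5.0
        u = np.where(idx == 99, 0.9, 0.1)
        return UncertaintyOutput(self.class_names, logits, np.zeros(len(idx)),
                                 logits, u, 0.0)


def _ood_inputs(rng, cells_per_class=6, per_cell=10):
    emb, labels, cell_ids = [], [], []
    cid = 0
    for c in range(2):
        for _ in range(cells_per_class):
            block = np.column_stack([np.full(per_cell, c, float),
                                     rng.standard_normal(per_cell)])
            emb.append(block)
            labels += [f"c{c}"] * per_cell
            cell_ids += [cid] * per_cell
            cid += 1
    ood = np.column_stack([np.full(30, 99.0), rng.standard_normal(30)])
    return np.concatenate(emb), np.array(labels), np.array(cell_ids), ood


class TestOODProtocol:
    def test_oracle_uncertainties_give_perfect_f1(self):
        from segclr.sngp import ood_protocol

        rng = np.random.default_rng(0)
        emb, labels, cell_ids, ood = _ood_inputs(rng)
        res = ood_protocol(emb, labels, cell_ids, ood, n_folds=3, seed=0,
                           classifier_factory=lambda x, y, s: _OracleOODClassifier())
        assert res.mean_f1 == pytest.approx(1.0)
        assert res.auroc == pytest.approx(1.0)
        assert all(0.1 < t < 0.9 for t in res.thresholds)

    def test_threshold_one_never_rejects(self):
        from segclr.sngp import OOD_CLASS, ood_protocol

        rng = np.random.default_rng(1)
        emb, labels, cell_ids, ood = _ood_inputs(rng)
        res = ood_protocol(emb, labels, cell_ids, ood, n_folds=3, seed=0,
                           classifier_factory=lambda x, y, s: _OracleOODClassifier(),
                           threshold_override=1.0)
        k = res.class_names.index(OOD_CLASS)
        assert all(f[k] == 0.0 for f in res.fold_f1)

    def test_sngp_beats_plain_resnet2_on_held_out_class(self, aggregated):
        """Cross-validated OOD F1: distance-aware SNGP rejects the held-out
        glia class better than the plain ResNet-2 with logit-only
        uncertainty."""
        from segclr.classify import train_resnet2
        from segclr.sngp import PlainUncertaintyAdapter, ood_protocol

        x, y, segs = aggregated["x"], aggregated["y"], aggregated["segment"]
        in_mask = y != "glia"
        sngp_res = ood_protocol(
            x[in_mask], y[in_mask], segs[in_mask], x[~in_mask], n_folds=4,
            seed=0, classifier_factory=lambda xx, yy, s: fit_sngp(
                xx, yy, seed=s, epochs=40, rff_dim=256))
        plain_res = ood_protocol(
            x[in_mask], y[in_mask], segs[in_mask], x[~in_mask], n_folds=4,
            seed=0, classifier_factory=lambda xx, yy, s: PlainUncertaintyAdapter(
                train_resnet2(xx, yy, seed=s, epochs=40)))
        assert sngp_res.mean_f1 > plain_res.mean_f1
        assert sngp_res.auroc > plain_res.auroc


def test_merged_cell_uncertainty_map(world, emb_store, aggregated):
    """A segment made by merging two cells of different classes (an
    agglomeration-style merge error joining them at their closest point)
    shows higher per-node uncertainty on the out-of-distribution branch
    than on the in-distribution trunk."""
    from segclr import merge_segments
    from segclr.store import EmbeddingStore

    lab = dict(zip(world.labels.cells.segment_id,
                   world.labels.cells.class_name))
    exc = [s for s in emb_store.segment_ids if lab[s] == "excitatory"]
    glia = [s for s in emb_store.segment_ids if lab[s] == "glia"]
    keep, merge = exc[0], glia[0]
    merged = merge_segments(world, keep, merge)
    sk = merged.skeletons[keep]
    # train on excitatory/inhibitory aggregated embeddings only
    mask = aggregated["y"] != "glia"
    model = fit_sngp(aggregated["x"][mask], aggregated["y"][mask], seed=0,
                     epochs=40, rff_dim=256)
    # per-node embeddings keep each cell's own masked views; node ids of the
    # merged-in cell are offset exactly as in the merged skeleton
    offset = max(world.skeletons[keep].node_ids) + 1
    store2 = EmbeddingStore(dim=emb_store.dim)
    trunk_nodes = sorted(emb_store.node_index[keep])
    branch_nodes = sorted(emb_store.node_index[merge])
    for node in trunk_nodes:
        store2.add_rows(keep, [sk.coords(node)],
                        emb_store.embedding_of_node(keep, node)[None],
                        node_ids=[node])
    for node in branch_nodes:
        store2.add_rows(keep, [sk.coords(node + offset)],
                        emb_store.embedding_of_node(merge, node)[None],
                        node_ids=[node + offset])
    u_trunk = [float(model.predict_uncertainty(
        store2.aggregate(sk, n, 5000.0).mean_vector[None]).uncertainty[0])
        for n in trunk_nodes]
    u_branch = [float(model.predict_uncertainty(
        store2.aggregate(sk, n + offset, 5000.0).mean_vector[None])
        .uncertainty[0]) for n in branch_nodes]
    assert u_trunk and u_branch
    assert np.median(u_branch) > np.median(u_trunk)
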