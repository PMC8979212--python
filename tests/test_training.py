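"""Training recipe: loss oracle values, poly schedule, augmentation
behaviour, gradient accumulation and fold bookkeeping."""

import numpy as np
import pytest

from gtvcascade import (AugmentSpec, BinaryMask, ImageVolume, NetworkSpec,
                        PipelineConfig, TrainSpec, augment, build_network,
                        crossval, fine_tune, fold_assignment, initialize,
                        loss, loss_and_grad, lr_at, train_stage)
from gtvcascade.network import _sigmoid


def micro_config(**train_overrides):
    """A deliberately small configuration for fast optimization tests."""
    train = TrainSpec(augment=AugmentSpec(), **train_overrides)
    return PipelineConfig(
        stage1_patch=(16, 16, 8), stage1_stride=(8, 8, 4), stage2_patch=(12, 8, 8),
        stage1_network=NetworkSpec.for_stage(1, levels=2, base_features=4),
        stage2_network=NetworkSpec.for_stage(2, levels=2, base_features=4),
        train=train,
    )


def micro_cases(n=3, shape=(24, 24, 12), seed=0):
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        img = rng.normal(0, 1, shape).astype(np.float32)
        gt = np.zeros(shape, np.uint8)
        c = [int(rng.integers(8, s - 8)) if s > 16 else s // 2 for s in shape]
        gt[c[0]-3:c[0]+3, c[1]-3:c[1]+3, c[2]-2:c[2]+2] = 1
        img[gt.astype(bool)] += 4.0
        cases.append((ImageVolume(img), BinaryMask(gt)))
    return cases


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        label = (np.random.default_rng(0).random((8, 8, 8)) < 0.4).astype(float)
        pred = np.clip(label, 1e-7, 1 - 1e-7)
        assert loss(pred, label, eps=1e-5) < 1e-3

    def test_half_foreground_hand_values(self):
        # pred = 0.5 everywhere, label = exactly half foreground:
        # CE = ln 2; soft Dice = (2*(N/4)+eps)/(N+eps) ~ 0.5 -> Dice loss 0.5
        n = 8 * 8 * 8
        label = np.zeros(n)
        label[: n // 2] = 1.0
        pred = np.full(n, 0.5)
        expected = np.log(2) + 0.5
        assert loss(pred.reshape(8, 8, 8), label.reshape(8, 8, 8)) == pytest.approx(
            expected, abs=1e-4)

    def test_monotone_toward_label(self):
        rng = np.random.default_rng(3)
        label = (rng.random((6, 6, 6)) < 0.3).astype(float)
        values = []
        for t in np.linspace(0.0, 0.9, 5):
            pred = 0.5 + t * (label - 0.5)
            values.append(loss(pred, label))
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_grad_consistent_with_value(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(1, 6, 6, 6))
        y = (rng.random((1, 6, 6, 6)) < 0.3).astype(float)
        val, dz = loss_and_grad(z, y)
        assert val == pytest.approx(loss(_sigmoid(z)[0], y[0]), abs=1e-6)
        eps = 1e-6
        d = rng.normal(size=z.shape)
        num = (loss_and_grad(z + eps * d, y)[0] - loss_and_grad(z - eps * d, y)[0]) / (2 * eps)
        assert num == pytest.approx(float((dz * d).sum()), rel=1e-4)

    def test_ce_symmetric_dice_not_under_label_swap(self):
        rng = np.random.default_rng(6)
        y = (rng.random((6, 6, 6)) < 0.3).astype(float)
        p = np.clip(rng.random((6, 6, 6)), 0.01, 0.99)
        # CE is invariant under swapping foreground/background of both
        ce = lambda pred, lab: -np.mean(lab * np.log(pred) + (1 - lab) * np.log(1 - pred))
        assert ce(p, y) == pytest.approx(ce(1 - p, 1 - y))
        # the Dice term (hence the total) is not
        assert loss(p, y) != pytest.approx(loss(1 - p, 1 - y), abs=1e-3)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        y = (rng.random(200) < 0.3).astype(float)
        p = np.clip(rng.random(200), 0.01, 0.99)
        perm = rng.permutation(200)
        assert loss(p.reshape(8, 5, 5), y.reshape(8, 5, 5)) == pytest.approx(
            loss(p[perm].reshape(8, 5, 5), y[perm].reshape(8, 5, 5)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss(np.zeros((4, 4, 4)), np.zeros((4, 4, 2)))


class TestLrSchedule:
    SPEC = TrainSpec()

    def test_published_endpoints_and_midpoint(self):
        assert lr_at(0, self.SPEC) == pytest.approx(0.01)
        assert lr_at(120, self.SPEC) == 0.0
        assert lr_at(60, self.SPEC) == pytest.approx(0.01 * 0.5**0.9)

    def test_matches_formula_at_all_epochs(self):
        for e in range(121):
            assert lr_at(e, self.SPEC) == 0.01 * (1 - e / 120) ** 0.9

    def test_strictly_decreasing(self):
        vals = [lr_at(e, self.SPEC) for e in range(121)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_at(121, self.SPEC)
        with pytest.raises(ValueError):
            lr_at(-1, self.SPEC)


class TestAugment:
    def _patch(self, shape=(24, 24, 12)):
        grids = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
        c = [s // 2 for s in shape]
        rho = sum(((g - ci) / a) ** 2 for g, ci, a in zip(grids, c, (8, 8, 4)))
        label = (rho <= 1).astype(np.float32)
        patch = (label * 3 + np.random.default_rng(0).normal(0, 0.1, shape)
                 ).astype(np.float32)[None]
        return patch, label

    def test_all_disabled_is_identity(self):
        patch, label = self._patch()
        spec = AugmentSpec(gate_p=0.0)
        p2, l2 = augment(patch, label, spec, np.random.default_rng(0))
        assert np.array_equal(p2, patch) and np.array_equal(l2, label)

    def test_rotation_approximately_preserves_label_volume(self):
        patch, label = self._patch()
        spec = AugmentSpec(scale_range=(1.0, 1.0), elastic_alpha=0.0,
                           rotation_deg=(10.0, 10.0), noise_gaussian_sigma_max=0.0,
                           noise_uniform_limit=0.0, flip=False, gate_p=1.0)
        rng = np.random.default_rng(1)
        p2, l2 = augment(patch, label, spec, rng)
        assert l2.sum() == pytest.approx(label.sum(), rel=0.10)
        assert set(np.unique(l2)) <= {0.0, 1.0}

    def test_noise_leaves_label_untouched(self):
        patch, label = self._patch()
        spec = AugmentSpec(scale_range=(1.0, 1.0), elastic_alpha=0.0,
                           rotation_deg=(0.0, 0.0), flip=False, gate_p=1.0)
        p2, l2 = augment(patch, label, spec, np.random.default_rng(2))
        assert np.array_equal(l2, label)
        assert not np.array_equal(p2, patch)  # noise hit the image

    def test_seeded_reproducibility(self):
        patch, label = self._patch()
        spec = AugmentSpec()
        a = augment(patch, label, spec, np.random.default_rng(9))
        b = augment(patch, label, spec, np.random.default_rng(9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestOptimization:
    def test_accumulation_two_equals_one_on_duplicates(self):
        # averaging gradients over two identical samples must reproduce the
        # single-sample update exactly
        cfg = micro_config()
        cases = micro_cases(1)
        x, y = cases[0][0].data, cases[0][1].data.astype(np.float32)
        nets = {}
        for accum in (1, 2):
            net = initialize(build_network(cfg.stage1_network), seed=11)
            opt_params = net.parameters()
            from gtvcascade.training import SGD
            opt = SGD(opt_params, momentum=0.9)
            for _ in range(accum):
                logits = net.forward_logits(x[:, :16, :16, :8], train=False)
                _, dz = loss_and_grad(logits, y[:16, :16, :8])
                net.backward(dz / accum)
            opt.step(0.01)
            nets[accum] = {name: p.data.copy() for name, p in net.parameters()}
        for name in nets[1]:
            np.testing.assert_allclose(nets[1][name], nets[2][name], atol=1e-6)

    def test_training_reduces_loss(self):
        cfg = micro_config(patches_per_case=2)
        net = initialize(build_network(cfg.stage1_network), seed=1)
        res = train_stage(net, micro_cases(3), cfg, stage=1, seed=2, epochs=8,
                          use_augment=False)
        assert res.history[-1] < res.history[0]

    def test_training_bitwise_deterministic(self):
        cfg = micro_config(patches_per_case=1)
        results = []
        for _ in range(2):
            net = initialize(build_network(cfg.stage2_network), seed=3)
            train_stage(net, micro_cases(2), cfg, stage=2, seed=4, epochs=2)
            results.append({name: p.data.copy() for name, p in net.parameters()})
        for name in results[0]:
            assert np.array_equal(results[0][name], results[1][name])

    def test_empty_cohort_rejected(self):
        cfg = micro_config()
        net = build_network(cfg.stage1_network)
        with pytest.raises(ValueError):
            train_stage(net, [], cfg, stage=1)


class TestFolds:
    def test_partition_law_n10_k5(self):
        folds = fold_assignment(10, 5, seed=0)
        sizes = np.bincount(folds, minlength=5)
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_balance_n257_k5(self):
        sizes = sorted(np.bincount(fold_assignment(257, 5, seed=1)).tolist())
        assert sizes == [51, 51, 51, 51, 53] or sizes == [51, 51, 51, 52, 52]

    def test_same_seed_same_assignment(self):
        assert np.array_equal(fold_assignment(20, 5, 7), fold_assignment(20, 5, 7))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            fold_assignment(3, 5, 0)

    def test_crossval_tests_every_case_once(self):
        cases = list(range(11))
        seen = []

        def runner(train, test, fold):
            assert set(train).isdisjoint(test)
            seen.extend(test)
            return [(fold, t) for t in test]

        folds, pooled = crossval(cases, 5, seed=3, runner=runner)
        assert sorted(seen) == cases
        assert len(pooled) == 11


class TestFineTune:
    def test_split_arithmetic_70_30(self):
        cfg = micro_config()
        net = initialize(build_network(cfg.stage2_network), seed=0)
        res = fine_tune(net, micro_cases(40, seed=1), cfg, stage=2, seed=5, epochs=0)
        assert len(res.train_indices) == 28
        assert len(res.test_indices) == 12
        assert set(res.train_indices).isdisjoint(res.test_indices)

    def test_zero_epochs_leaves_weights_unchanged(self):
        cfg = micro_config()
        net = initialize(build_network(cfg.stage2_network), seed=0)
        before = {name: p.data.copy() for name, p in net.parameters()}
        res = fine_tune(net, micro_cases(10), cfg, stage=2, seed=6, epochs=0)
        assert res.history == []
        for name, p in net.parameters():
            assert np.array_equal(before[name], p.data)

    def test_domain_shift_recovery(self):
        """Fine-tuning on a shifted phantom domain (weaker tumor contrast,
        stronger noise) must not segment the new domain's hold-out cases
        worse than direct transfer of the source-domain network."""
        from gtvcascade import (PhantomSpec, PipelineConfig, generate_cohort,
                                sample_patch_stage2)
        from gtvcascade.cascade import ROIBox, gt_centroid, stage2_infer
        from gtvcascade.preprocessing import (compute_foreground_stats,
                                              normalize, preprocess_case)

        cfg = PipelineConfig.tiny(seed=0, patches_per_case=1)

        def prep(cohort):
            prepped = [preprocess_case(c.volume, cfg.target_spacing, gt=c.gt)
                       for c in cohort]
            stats = compute_foreground_stats([p[0] for p in prepped],
                                             [p[1] for p in prepped])
            return [(normalize(v, stats), g) for v, _, g in prepped]

        src = prep(generate_cohort(PhantomSpec.desk(), 8, seed=21))
        # the shifted domain is genuinely harder: half the contrast, heavier
        # noise and a more diffuse boundary (a plain intensity offset would be
        # removed exactly by the first instance-norm layer)
        shifted_spec = PhantomSpec.desk(tumor_contrast_hu=30.0, noise_sigma_hu=50.0,
                                        boundary_softness=0.25)
        new = prep(generate_cohort(shifted_spec, 10, seed=22))

        net = initialize(build_network(cfg.stage2_network), seed=5)
        train_stage(net, src, cfg, stage=2, seed=6, epochs=6)

        def dice_on(cases, model):
            out = []
            for vol, gt in cases:
                roi = ROIBox(gt_centroid(gt), cfg.stage2_patch)
                scores = stage2_infer(model, vol, roi).data
                _, label = sample_patch_stage2(vol, gt, cfg.stage2_patch,
                                               (0, 0, 0), np.random.default_rng(0))
                pred = scores >= 0.5
                out.append(2 * (pred & (label > 0)).sum()
                           / max(pred.sum() + label.sum(), 1))
            return float(np.median(out))

        res = fine_tune(net, new, cfg, stage=2, seed=7, epochs=10)
        holdout = [new[i] for i in res.test_indices]
        fine_tuned = dice_on(holdout, net)

        direct_net = initialize(build_network(cfg.stage2_network), seed=5)
        train_stage(direct_net, src, cfg, stage=2, seed=6, epochs=6)
        direct = dice_on(holdout, direct_net)
        assert fine_tuned >= direct
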