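"""Coverage labelling, input fusion, cutoff selection, constraint assembly."""

import numpy as np
import pytest

from pleuraseg import discriminator as dm
from pleuraseg import metrics
from pleuraseg.errors import ParameterError, TrainingError
from pleuraseg.training import TrainConfig


def oracle_select_cutoff(scores, labels, target, step):
    """Exhaustive sweep over the full grid, smallest passing point."""
    n = int(round(1 / step))
    best = None
    for g in range(n + 1):
        cutoff = round(g * step, 10)
        pred = np.asarray(scores) >= cutoff
        neg = np.asarray(labels) == 0
        spec = np.sum(~pred & neg) / neg.sum()
        if spec >= target:
            best = cutoff
            break
    return best


class TestCoverage:
    def test_all_ones_full_coverage(self, rng):
        lesion = rng.random((8, 8)) < 0.3
        lesion[0, 0] = True
        assert dm.coverage_rate(np.ones((8, 8), bool), lesion) == 1.0

    def test_disjoint_zero(self):
        c = np.zeros((4, 4), bool)
        c[:2] = True
        lesion = np.zeros((4, 4), bool)
        lesion[3] = True
        assert dm.coverage_rate(c, lesion) == 0.0

    def test_partial_hand_count(self):
        lesion = np.zeros((4, 4), bool)
        lesion[0, :4] = True
        c = np.zeros((4, 4), bool)
        c[0, :3] = True
        assert dm.coverage_rate(c, lesion) == pytest.approx(0.75)

    def test_empty_lesion_rejected(self):
        with pytest.raises(ParameterError):
            dm.coverage_rate(np.ones((4, 4), bool), np.zeros((4, 4), bool))


class TestLabel:
    @pytest.mark.parametrize(
        "R,tau,expected", [(1.0, 0.99, 1), (0.5, 0.99, 0), (0.99, 0.99, 1)]
    )
    def test_boundary_convention(self, R, tau, expected):
        assert dm.label(R, tau) == expected


class TestFuseInput:
    def test_channel_order_and_product(self, rng):
        img = rng.random((8, 8))
        c = (rng.random((8, 8)) > 0.5).astype(float)
        fused = dm.fuse_input(img, c)
        assert fused.shape == (3, 8, 8)
        assert np.array_equal(fused[0], img)
        assert np.array_equal(fused[1], c)
        assert np.array_equal(fused[2], img * c)

    def test_all_ones_constraint_third_channel_equals_image(self, rng):
        img = rng.random((6, 6))
        fused = dm.fuse_input(img, np.ones((6, 6)))
        assert np.array_equal(fused[2], fused[0])

    def test_all_zero_constraint(self, rng):
        fused = dm.fuse_input(rng.random((6, 6)), np.zeros((6, 6)))
        assert not fused[1].any() and not fused[2].any()


class TestSelectCutoff:
    def test_smallest_passing_grid_point(self):
        res = dm.select_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.8, 0.01)
        assert res.cutoff == pytest.approx(0.21)
        assert res.rates.specificity == 1.0
        assert res.attained

    def test_target_zero_keeps_everything(self):
        res = dm.select_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.0, 0.01)
        assert res.cutoff == 0.0
        assert res.rates.sensitivity == 1.0

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            scores = rng.random(20)
            labels = rng.integers(0, 2, 20)
            if labels.sum() in (0, 20):
                continue
            for target in (0.5, 0.8, 0.95):
                res = dm.select_cutoff(scores, labels, target, 0.01)
                assert res.cutoff == pytest.approx(
                    oracle_select_cutoff(scores, labels, target, 0.01)
                )

    def test_identical_cutoffs_for_adjacent_targets(self):
        """Nearby specificity targets can resolve to the same cutoff."""
        scores = [0.05, 0.95, 0.9, 0.85]
        labels = [0, 1, 1, 1]
        r1 = dm.select_cutoff(scores, labels, 0.85, 0.01)
        r2 = dm.select_cutoff(scores, labels, 0.90, 0.01)
        assert r1.cutoff == r2.cutoff

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            dm.select_cutoff([0.2, 0.8], [1, 1], 0.8, 0.01)


class TestAssemble:
    def test_reject_all_gives_all_ones(self, rng):
        cons = [rng.random((6, 6)) > 0.5 for _ in range(4)]
        out, kept = dm.assemble_constraints(cons, [0.1, 0.2, 0.3, 0.4], cutoff=1.01)
        assert not kept.any()
        assert out.all()

    def test_keep_all_unchanged(self, rng):
        cons = [rng.random((6, 6)) > 0.5 for _ in range(4)]
        out, kept = dm.assemble_constraints(cons, [0.5] * 4, cutoff=0.0)
        assert kept.all()
        for i in range(4):
            assert np.array_equal(out[i], cons[i])

    def test_mixed_fixture(self, rng):
        cons = [rng.random((6, 6)) > 0.5 for _ in range(5)]
        scores = [0.9, 0.1, 0.8, 0.2, 0.7]
        out, kept = dm.assemble_constraints(cons, scores, cutoff=0.5)
        assert list(kept) == [True, False, True, False, True]
        assert out[1].all() and out[3].all()
        assert np.array_equal(out[0], cons[0])

    def test_cutoff_monotonicity(self, rng):
        cons = [rng.random((6, 6)) > 0.5 for _ in range(10)]
        scores = rng.random(10)
        kept_counts = [
            dm.assemble_constraints(cons, scores, cutoff=c)[1].sum()
            for c in (0.0, 0.3, 0.6, 0.9, 1.01)
        ]
        assert kept_counts == sorted(kept_counts, reverse=True)


class TestTrainDiscriminator:
    def _fixture(self, rng, n=40, size=32):
        """Linearly separable: unreliable constraints are tiny off-centre
        boxes, reliable ones large centred boxes (strong channel signature)."""
        inputs, labels = [], []
        for i in range(n):
            img = rng.random((size, size)) * 0.3 + 0.3
            c = np.zeros((size, size))
            if i % 2:
                c[4:28, 4:28] = 1.0
                labels.append(1)
            else:
                c[:6, :6] = 1.0
                labels.append(0)
            inputs.append(dm.fuse_input(img, c))
        return np.array(inputs, dtype=np.float32), np.array(labels)

    def test_separable_fixture_high_auroc(self, rng):
        x, y = self._fixture(rng)
        cfg = dm.DiscriminatorConfig(
            classifier_base=4, classifier_depth=1,
            train=TrainConfig(max_epochs=12, batch_size=4, seed=0),
        )
        _, scores, _ = dm.train_discriminator(x[:28], y[:28], x[28:], y[28:], cfg)
        assert metrics.auroc(scores, y[28:]) > 0.9

    def test_deterministic_scores(self, rng):
        x, y = self._fixture(rng, n=16)
        cfg = dm.DiscriminatorConfig(
            classifier_base=4, classifier_depth=1,
            train=TrainConfig(max_epochs=4, batch_size=4, seed=1),
        )
        _, s1, _ = dm.train_discriminator(x[:12], y[:12], x[12:], y[12:], cfg)
        _, s2, _ = dm.train_discriminator(x[:12], y[:12], x[12:], y[12:], cfg)
        assert np.array_equal(s1, s2)

    def test_label_noise_gives_chance_auroc(self, rng):
        """Labels independent of (diverse) inputs -> AUROC near 0.5.

        Each sample gets its own random constraint box so nothing learned on
        the training split can generalise; the band is ~3 null standard
        deviations for 30 validation samples.
        """
        n, size = 90, 32
        inputs = []
        for _ in range(n):
            img = rng.random((size, size)) * 0.3 + 0.3
            c = np.zeros((size, size))
            y0, x0 = rng.integers(0, 16, 2)
            h, w = rng.integers(6, 16, 2)
            c[y0 : y0 + h, x0 : x0 + w] = 1.0
            inputs.append(dm.fuse_input(img, c))
        x = np.array(inputs, dtype=np.float32)
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        cfg = dm.DiscriminatorConfig(
            classifier_base=4, classifier_depth=1,
            train=TrainConfig(max_epochs=6, batch_size=4, seed=2),
        )
        _, scores, _ = dm.train_discriminator(x[:60], y[:60], x[60:], y[60:], cfg)
        assert abs(metrics.auroc(scores, y[60:]) - 0.5) < 0.3

    def test_single_class_rejected(self, rng):
        x, y = self._fixture(rng, n=8)
        with pytest.raises(TrainingError):
            dm.train_discriminator(x[:4], np.ones(4), x[4:], y[4:])


class TestDegrade:
    def test_flags_match_fraction_and_coverage_drops(self, rng):
        from pleuraseg.phantom import PhantomConfig, generate_phantom

        cfg = PhantomConfig(image_size=64, seed=3)
        samples = [generate_phantom(cfg, i) for i in range(10)]
        cons = [s.lungspace_mask for s in samples]
        out, bad = dm.degrade_constraints(cons, 0.3, seed=4)
        assert bad.sum() == 3
        for i, s in enumerate(samples):
            r = dm.coverage_rate(out[i], s.lesion_mask)
            if not bad[i]:
                assert r == 1.0
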