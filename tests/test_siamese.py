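"""Siamese z-distance network: pair construction, weight sharing,
degenerate training, distribution summaries."""

import numpy as np
import pytest
from scipy import stats
from scipy.signal import find_peaks

from flowpheno.beadnet import summarize_displacements
from flowpheno.siamese import (SiameseConfig, _forward_pairs, build_nets,
                               choose_reference, flow_displacement_distribution,
                               make_pair_dataset, predict_distance,
                               train_siamese)
from flowpheno.synth import ZStack
from flowpheno.train import ConvergenceRule


def _stack(n_slices=5, spacing=0.25, size=16, seed=0):
    rng = np.random.default_rng(seed)
    labels = (np.arange(n_slices) - n_slices // 2) * spacing
    return ZStack(rng.random((n_slices, size, size)).astype(np.float32),
                  0.25, spacing, labels)


class TestPairDataset:
    def test_target_arithmetic(self):
        """Slices 10 and 4 at 0.25 µm spacing are +1.5 µm apart."""
        stack = _stack(n_slices=12)
        rng = np.random.default_rng(0)
        pairs = make_pair_dataset([stack], 200, rng)
        for p in pairs:
            assert p.target == pytest.approx((p.slice_a - p.slice_b) * 0.25)
        by_idx = {(p.slice_a, p.slice_b): p.target for p in pairs}
        if (10, 4) in by_idx:
            assert by_idx[(10, 4)] == pytest.approx(1.5)

    def test_equal_slices_give_zero_target(self):
        stack = _stack()
        pairs = make_pair_dataset([stack], 100, np.random.default_rng(1))
        for p in pairs:
            if p.slice_a == p.slice_b:
                assert p.target == 0.0

    def test_exhaustive_five_slice_antisymmetry(self):
        """All 25 ordered pairs of a 5-slice stack reproduce the
        antisymmetric target matrix computed by brute force."""
        stack = _stack(n_slices=5)
        expected = np.array([[(a - b) * 0.25 for b in range(5)]
                             for a in range(5)])
        assert np.allclose(expected, -expected.T)
        pairs = make_pair_dataset([stack], 500, np.random.default_rng(2))
        seen = {(p.slice_a, p.slice_b) for p in pairs}
        assert seen == {(a, b) for a in range(5) for b in range(5)}
        for p in pairs:
            assert p.target == pytest.approx(expected[p.slice_a, p.slice_b])

    def test_single_slice_stack_contributes_zero_targets(self):
        pairs = make_pair_dataset([_stack(n_slices=1)], 10,
                                  np.random.default_rng(3))
        assert all(p.target == 0.0 for p in pairs)


class TestWeightSharing:
    def test_identical_inputs_embed_identically(self):
        """The two siamese paths are the same module: embeddings of equal
        inputs are exactly equal."""
        nets = build_nets(SiameseConfig(widths=(4, 8, 16)).to_dict(),
                          np.random.default_rng(0))
        x = np.random.default_rng(1).random((6, 16, 16)).astype(np.float32)
        both = np.concatenate([x, x], axis=0)[:, None]
        emb = nets["embed"].forward(both, train=False)
        assert np.array_equal(emb[:6], emb[6:])


class TestTraining:
    def test_zero_target_dataset_collapses_predictions(self):
        """Stacks whose labels are all zero distance: predictions collapse
        to ~0 (validation MAE < 0.1 µm)."""
        stacks = [ZStack(np.random.default_rng(s).random((5, 16, 16)
                                                         ).astype(np.float32),
                         0.25, 1e-9, np.zeros(5)) for s in range(6)]
        # spacing ~0 => all pair targets ~0
        cfg = SiameseConfig(widths=(4, 8, 16), pairs_per_stack=16, seed=0,
                            learning_rate=1e-3,
                            convergence=ConvergenceRule(max_epochs=8,
                                                        patience=8))
        model = train_siamese(stacks, cfg)
        x = stacks[0].slices
        pred = predict_distance(model, x, x[0])
        assert np.abs(pred).mean() < 0.1

    def test_same_seed_reruns_identical(self):
        stacks = [_stack(seed=s) for s in range(5)]
        cfg = SiameseConfig(widths=(4, 8, 16), pairs_per_stack=8, seed=9,
                            convergence=ConvergenceRule(max_epochs=2,
                                                        patience=2))
        m1 = train_siamese(stacks, cfg)
        m2 = train_siamese(stacks, cfg)
        assert m1.log == m2.log

    def test_batch_mode_preserves_order(self, siamese_recovery):
        model = siamese_recovery["model"]
        stack = siamese_recovery["test_stacks"][0]
        ref = stack.slices[20]
        batch = predict_distance(model, stack.slices[:10], ref)
        single = [float(predict_distance(model, s, ref))
                  for s in stack.slices[:10]]
        assert np.allclose(batch, single, atol=1e-5)

    def test_shape_mismatch_rejected(self, siamese_recovery):
        with pytest.raises(ValueError):
            predict_distance(siamese_recovery["model"],
                             np.zeros((4, 48, 48), np.float32),
                             np.zeros((32, 32), np.float32))

    def test_self_distance_near_zero(self, siamese_recovery):
        """predict_distance(x, x) stays within one slice spacing of zero
        for a trained model."""
        stack = siamese_recovery["test_stacks"][1]
        x = stack.slices[20]
        assert abs(float(predict_distance(siamese_recovery["model"], x, x))) \
            < 0.25

    def test_soft_antisymmetry(self, siamese_recovery):
        """Mean |(d(a,b) + d(b,a)) / 2| on held-out pairs is well below one
        slice spacing times two."""
        assert siamese_recovery["antisymmetry_residual"] < 0.5


class TestFlowDistribution:
    def test_reference_choice_picks_sharpest(self, siamese_recovery):
        stack = siamese_recovery["test_stacks"][0]
        idx = choose_reference(stack.slices)
        assert abs(idx - 20) <= 2        # near the focal slice

    def test_median_centring_and_cdf_mass(self, siamese_recovery):
        """Crops at known z drawn from N(0, 1 µm): the median-centred
        fraction within 2.5 µm approaches the analytic normal mass
        (~0.9876)."""
        model = siamese_recovery["model"]
        from flowpheno.experiments import make_cell_stacks
        stacks = make_cell_stacks(12, 555)
        rng = np.random.default_rng(4)
        crops, ref = [], None
        for st_ in stacks:
            ref = st_.slices[20] if ref is None else ref
            for _ in range(10):
                z = rng.normal(0.0, 1.0)
                idx = int(np.clip(round(20 + z / st_.spacing), 0, 40))
                crops.append(st_.slices[idx])
        summary = flow_displacement_distribution(model, np.stack(crops), ref)
        assert summary.counts.sum() == len(crops)
        expected = stats.norm.cdf(2.5) - stats.norm.cdf(-2.5)
        assert summary.fraction_within(2.5) >= expected - 0.05

    def test_bimodal_distribution_recovers_two_modes(self, siamese_recovery):
        """A constructed two-population input yields a two-peaked
        median-centred histogram."""
        model = siamese_recovery["model"]
        stacks = siamese_recovery["test_stacks"]
        crops = []
        for st_ in stacks:
            crops.extend([st_.slices[8]] * 3 + [st_.slices[32]] * 3)
        summary = flow_displacement_distribution(model, np.stack(crops),
                                                 stacks[0].slices[20])
        smoothed = np.convolve(summary.counts, [1, 2, 1], mode="same")
        peaks, _ = find_peaks(smoothed,
                              height=0.25 * smoothed.max(), distance=3)
        assert len(peaks) == 2

    def test_empty_input_rejected(self, siamese_recovery):
        with pytest.raises(ValueError):
            flow_displacement_distribution(siamese_recovery["model"],
                                           np.zeros((0, 48, 48)),
                                           np.zeros((48, 48)))
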