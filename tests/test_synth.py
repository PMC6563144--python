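"""Synthetic imaging: blur law, determinism, ground truth conservation,
through-focus sign identifiability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flowpheno.detect import laplacian_sharpness
from flowpheno.synth import (CellPhantom, FlowSequenceSpec, OpticalModel,
                             ZStackSpec, generate_flow_sequence,
                             generate_zstack, make_z_sampler, render_phantom,
                             sample_phantom)


class TestOpticalModel:
    def test_blur_scale_at_focus_equals_sigma0(self):
        opt = OpticalModel(sigma0=1.0, defocus_slope=0.8)
        assert opt.blur_sigma(0.0) == 1.0

    def test_blur_scale_grows_linearly_with_defocus(self):
        opt = OpticalModel(sigma0=1.0, defocus_slope=0.8)
        assert opt.blur_sigma(2.0) == pytest.approx(2.6)
        assert opt.blur_sigma(-2.0) == pytest.approx(2.6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            OpticalModel(sigma0=0.0)
        with pytest.raises(ValueError):
            OpticalModel(noise_std=-0.1)
        with pytest.raises(ValueError):
            OpticalModel(sigma0=float("nan"))


class TestPhantoms:
    def test_sizes_outside_cell_range_rejected(self):
        with pytest.raises(ValueError):
            CellPhantom("round", {"radius": 1.0})      # 2 um diameter
        with pytest.raises(ValueError):
            CellPhantom("rod", {"length": 14.0, "width": 3.0})

    def test_bead_default_diameter_is_6_um(self, rng):
        ph = sample_phantom("bead", rng, (48, 48))
        assert ph.characteristic_size() == pytest.approx(6.0)

    @pytest.mark.parametrize("species", ["round", "budding", "rod", "lemon"])
    def test_shapes_render_dark_edged_objects(self, species, rng):
        opt = OpticalModel(noise_std=0.0)
        ph = sample_phantom(species, rng, (48, 48))
        img = render_phantom(ph, opt, (48, 48)).pixels
        assert img.min() < opt.background - 0.1      # dark edge ring
        assert img.shape == (48, 48)


class TestRenderDeterminism:
    def test_identical_seed_gives_bitwise_identical_frames(self, optics,
                                                           centered_round):
        a = render_phantom(centered_round, optics, (48, 48), seed=42)
        b = render_phantom(centered_round, optics, (48, 48), seed=42)
        assert np.array_equal(a.pixels, b.pixels)

    def test_frame_too_small_for_blur_support_rejected(self, optics):
        ph = CellPhantom("round", {"radius": 2.0}, 0.0, (3.5, 3.5), 5.0)
        with pytest.raises(ValueError):
            render_phantom(ph, optics, (8, 8))


class TestZStacks:
    def test_41_slices_span_plus_minus_5_um(self, optics, centered_round):
        spec = ZStackSpec(41, 0.25, (48, 48), seed=1)
        stack = generate_zstack(centered_round, optics, spec)
        assert stack.z_labels[0] == pytest.approx(-5.0)
        assert stack.z_labels[20] == pytest.approx(0.0)
        assert stack.z_labels[-1] == pytest.approx(5.0)

    def test_single_slice_stack_equals_render(self, optics, centered_round):
        spec = ZStackSpec(1, 0.25, (48, 48), seed=3, focal_index=0)
        stack = generate_zstack(centered_round, optics, spec)
        direct = render_phantom(centered_round, optics, (48, 48),
                                rng=np.random.default_rng(3))
        assert np.array_equal(stack.slices[0], direct.pixels)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sharpness_argmax_at_focal_slice(self, seed, centered_round):
        """Brute-force sharpness scan over slices localises the focal
        plane, with and without the asymmetry term."""
        for asym in (0.0, 0.3):
            opt = OpticalModel(asym_strength=asym)
            stack = generate_zstack(centered_round, opt,
                                    ZStackSpec(41, 0.25, (48, 48), seed=seed))
            scores = [laplacian_sharpness(s) for s in stack.slices]
            assert int(np.argmax(scores)) == 20

    def test_blur_monotonicity_without_asymmetry(self, centered_round):
        """With asym_strength = 0 and no noise, sharpness never increases
        with |z| (tested on a grid)."""
        opt = OpticalModel(asym_strength=0.0, noise_std=0.0)
        vals = []
        for z in np.linspace(0.0, 5.0, 11):
            ph = CellPhantom("round", {"radius": 3.0}, 0.0, (23.5, 23.5),
                             float(z))
            vals.append(laplacian_sharpness(render_phantom(ph, opt,
                                                           (48, 48)).pixels))
        assert all(np.diff(vals) <= 1e-12)

    def test_sign_identifiability_margin(self):
        """With asym_strength != 0 the dark-ring depth differs between +z
        and -z by a clear margin — the cue that makes signed regression
        possible."""
        opt = OpticalModel(asym_strength=0.3, noise_std=0.0)
        for z in (1.0, 2.0, 3.0):
            pos = render_phantom(CellPhantom("round", {"radius": 3.0}, 0.0,
                                             (23.5, 23.5), z), opt,
                                 (48, 48)).pixels
            neg = render_phantom(CellPhantom("round", {"radius": 3.0}, 0.0,
                                             (23.5, 23.5), -z), opt,
                                 (48, 48)).pixels
            assert neg.min() - pos.min() > 0.05


class TestFlowSequence:
    def test_zero_event_rate_gives_cell_free_frames(self, optics):
        spec = FlowSequenceSpec(n_frames=20, event_rate=0.0, seed=5,
                                frame_size=(64, 64))
        frames, truth = generate_flow_sequence(spec, optics)
        assert len(frames) == 20
        assert not truth["has_cell"].any()

    def test_pure_mixture_yields_single_species(self, optics):
        spec = FlowSequenceSpec(n_frames=30, event_rate=1.0,
                                species_mixture={"round": 1.0},
                                frame_size=(64, 64), seed=6)
        _, truth = generate_flow_sequence(spec, optics)
        assert (truth.loc[truth.has_cell, "species"] == "round").all()

    def test_species_counts_match_seeded_replay(self, optics):
        """The species draws match an independent replay of the same
        seeded sampler."""
        spec = FlowSequenceSpec(n_frames=200, event_rate=1.0,
                                species_mixture={"round": 0.5, "rod": 0.5},
                                frame_size=(64, 64), seed=11)
        _, truth = generate_flow_sequence(spec, optics)
        replay = np.random.default_rng(11)
        replay.random(200)                          # event coin flips
        names = list(spec.species_mixture)
        draws = replay.choice(2, size=200, p=[0.5, 0.5])
        expected = [names[i] for i in draws]
        assert list(truth["species"]) == expected

    def test_ground_truth_row_per_frame(self, optics):
        spec = FlowSequenceSpec(n_frames=37, seed=8, frame_size=(64, 64))
        frames, truth = generate_flow_sequence(spec, optics)
        assert len(truth) == 37
        assert list(truth["frame"]) == list(range(37))
        assert truth["has_cell"].sum() == sum(
            1 for _, r in truth.iterrows() if r["species"] != "")

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            FlowSequenceSpec(species_mixture={"round": 0.7, "rod": 0.7})
        with pytest.raises(ValueError):
            FlowSequenceSpec(species_mixture={"round": 1.5, "rod": -0.5})

    def test_determinism_bitwise(self, optics):
        spec = FlowSequenceSpec(n_frames=10, seed=9, frame_size=(64, 64))
        f1, t1 = generate_flow_sequence(spec, optics)
        f2, t2 = generate_flow_sequence(spec, optics)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.pixels, b.pixels)
        pd.testing.assert_frame_equal(t1, t2)


class TestZSamplers:
    @given(st.floats(-3, 3), st.floats(0.1, 2))
    @settings(max_examples=20, deadline=None)
    def test_normal_sampler_moments(self, mean, std):
        sampler = make_z_sampler({"kind": "normal", "mean": mean, "std": std})
        draws = sampler(np.random.default_rng(0), 4000)
        assert abs(draws.mean() - mean) < 4 * std / np.sqrt(4000) + 1e-9
        assert abs(draws.std() - std) < 0.1 * std + 1e-9

    def test_constant_and_bimodal(self):
        c = make_z_sampler({"kind": "constant", "value": 1.5})
        assert np.all(c(np.random.default_rng(0), 5) == 1.5)
        b = make_z_sampler({"kind": "bimodal", "means": [-3, 3],
                            "stds": [0.1, 0.1]})
        draws = b(np.random.default_rng(1), 1000)
        assert (draws < 0).any() and (draws > 0).any()
        assert not ((-1 < draws) & (draws < 1)).any()
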