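"""Ground-truth machinery: sharpness, coefficient search, stitching."""

from __future__ import annotations

import numpy as np
import pytest

from octadc.gtruth import (
    DepthBands,
    build_dataset,
    estimate_optimal_coeff,
    partition_depth_bands,
    sharpness_score,
    stitch_ground_truth,
)
from octadc.recon import build_compensation_stack, reconstruct_bscan
from octadc.sim import (
    DispersionSpec,
    Layer,
    LayeredSample,
    NoiseModel,
    simulate_volume,
)


class TestSharpnessScore:
    def test_impulse_vs_uniform_closed_form(self):
        impulse = np.zeros((10, 1))
        impulse[4, 0] = 3.0
        assert sharpness_score(impulse) == pytest.approx(1.0)
        uniform = np.full((25, 1), 2.0)
        assert sharpness_score(uniform) == pytest.approx(1.0 / 25.0)

    def test_scale_invariance(self, rng):
        img = rng.random((16, 8))
        assert sharpness_score(7.3 * img) == pytest.approx(sharpness_score(img), rel=1e-12)

    def test_all_zero_band_scores_zero(self):
        assert sharpness_score(np.zeros((8, 4))) == 0.0

    def test_matched_band_scores_higher_than_mismatched(self, grid, single_layer_frame_factory):
        frame = single_layer_frame_factory(a2=20.0)
        row = round(200.0 / grid.depth_pitch_um)
        band = (row - 12, row + 12)
        matched = sharpness_score(reconstruct_bscan(frame, 20.0).image, band)
        mismatched = sharpness_score(reconstruct_bscan(frame, -10.0).image, band)
        assert matched > mismatched

    def test_band_bounds_validated(self):
        with pytest.raises(ValueError):
            sharpness_score(np.ones((8, 4)), (4, 12))


class TestEstimateOptimalCoeff:
    SWEEP = (-40.0, 40.0, 5.0)

    def _frame(self, a2, factory):
        return factory(a2=a2)

    @pytest.mark.parametrize("a2", [30.0, 0.0, -25.0])
    def test_recovers_injected_coefficient(self, grid, single_layer_frame_factory, a2):
        frame = single_layer_frame_factory(a2=a2)
        row = round(200.0 / grid.depth_pitch_um)
        est = estimate_optimal_coeff(frame, (row - 15, row + 15), self.SWEEP)
        assert est == pytest.approx(a2, abs=self.SWEEP[2])

    def test_single_point_sweep_returned(self, single_layer_frame_factory):
        est = estimate_optimal_coeff(single_layer_frame_factory(), (40, 80), (7.0, 7.0, 5.0))
        assert est == 7.0

    def test_flat_landscape_returns_midpoint(self, single_layer_frame_factory, caplog):
        import logging
        from dataclasses import replace

        frame = single_layer_frame_factory()
        # an empty band far from any signal has a flat (noise-floor) landscape
        zero = replace(frame, fringes=np.zeros_like(frame.fringes) + 1.0)
        with caplog.at_level(logging.WARNING, logger="octadc.gtruth"):
            est = estimate_optimal_coeff(zero, (100, 120), (-40.0, 40.0, 10.0))
        assert est == 0.0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_recovery_rate_over_random_layers(self, source, grid):
        """>= 95% of random layers recovered within one sweep step."""
        sweep = (-40.0, 40.0, 5.0)
        rng = np.random.default_rng(77)
        hits = 0
        n = 20
        for _ in range(n):
            a2 = rng.uniform(-30.0, 30.0)
            dz = rng.uniform(120.0, 320.0)
            r = rng.uniform(0.3, 0.9)
            # lateral slope so the layer survives background subtraction
            sample = LayeredSample(
                (Layer(dz, r, DispersionSpec(a2=a2)),),
                lateral_profile=np.linspace(0.0, 5.0, 8),
            )
            frame = simulate_volume(
                sample, 1, 8, noise_model=NoiseModel(additive_sigma=0.01),
                rng_seed=int(rng.integers(2**31)), source=source, grid=grid,
            )[0]
            row = round(dz / grid.depth_pitch_um)
            band = (max(row - 15, 0), min(row + 15, grid.n_pixels // 2))
            est = estimate_optimal_coeff(frame, band, sweep)
            hits += abs(est - a2) <= sweep[2]
        assert hits / n >= 0.95


class TestPartitionDepthBands:
    def test_equal_partition(self):
        bands = partition_depth_bands(5, 250)
        assert bands.bands == ((0, 50), (50, 100), (100, 150), (150, 200), (200, 250))

    def test_remainder_rows_go_to_last_band(self):
        assert partition_depth_bands(3, 10).bands == ((0, 3), (3, 6), (6, 10))

    def test_single_full_depth_band(self):
        assert partition_depth_bands(1, 128).bands == ((0, 128),)

    def test_explicit_boundaries(self):
        bands = partition_depth_bands(3, 100, [30, 60])
        assert bands.bands == ((0, 30), (30, 60), (60, 100))

    def test_bad_explicit_boundaries_rejected(self):
        with pytest.raises(ValueError):
            partition_depth_bands(3, 100, [60, 30])
        with pytest.raises(ValueError):
            DepthBands(((0, 10), (12, 20)))


class TestLayerAwareBands:
    def test_boundaries_between_detected_layers(self, source, grid):
        from octadc.gtruth import layer_aware_bands

        sample = LayeredSample(
            (Layer(100.0, 0.8), Layer(300.0, 0.8)),
            lateral_profile=np.linspace(0.0, 3.0, 8),
        )
        frame = simulate_volume(sample, 1, 8, rng_seed=6, source=source, grid=grid)[0]
        bscan = reconstruct_bscan(frame)
        bands = layer_aware_bands(bscan, 2)
        row1 = 100.0 / grid.depth_pitch_um
        row2 = 300.0 / grid.depth_pitch_um
        boundary = bands.bands[0][1]
        assert row1 < boundary < row2

    def test_falls_back_to_equal_partition_without_peaks(self):
        from octadc.gtruth import layer_aware_bands
        from octadc.recon import BScan

        flat = BScan(np.ones((40, 8)))
        bands = layer_aware_bands(flat, 4)
        assert bands.bands == partition_depth_bands(4, 40).bands


class TestStitchGroundTruth:
    def _stack(self, factory, n=2):
        return build_compensation_stack(factory(), -30, 30, n) if n > 1 else None

    def test_single_channel_identity_bit_exact(self, single_layer_frame_factory):
        stack = build_compensation_stack(single_layer_frame_factory(), -30, 30, 1)
        out = stitch_ground_truth(stack, partition_depth_bands(1, stack.shape[0]))
        np.testing.assert_array_equal(out.image, stack.bscans[0].image)

    def test_two_band_halves_bit_exact(self, single_layer_frame_factory):
        frame = single_layer_frame_factory()
        stack = build_compensation_stack(frame, -30, 30, 3)
        z = stack.shape[0]
        # three equal bands from the three channels
        bands = partition_depth_bands(3, z)
        out = stitch_ground_truth(stack, bands)
        for i, (lo, hi) in enumerate(bands):
            np.testing.assert_array_equal(out.image[lo:hi], stack.bscans[i].image[lo:hi])

    def test_stitch_idempotence_for_identical_channels(self, single_layer_frame_factory):
        b = reconstruct_bscan(single_layer_frame_factory())
        from octadc.recon import CompensationStack

        stack = CompensationStack((-10.0, 0.0, 10.0), (b, b, b))
        out = stitch_ground_truth(stack, partition_depth_bands(3, b.shape[0]))
        np.testing.assert_array_equal(out.image, b.image)

    def test_feathering_blends_across_seams(self, single_layer_frame_factory):
        frame = single_layer_frame_factory()
        stack = build_compensation_stack(frame, -30, 30, 3)
        bands = partition_depth_bands(3, stack.shape[0])
        hard = stitch_ground_truth(stack, bands, feather=0)
        soft = stitch_ground_truth(stack, bands, feather=4)
        assert np.any(hard.image != soft.image)

    def test_size_mismatch_rejected(self, single_layer_frame_factory):
        stack = build_compensation_stack(single_layer_frame_factory(), -30, 30, 5)
        with pytest.raises(ValueError):
            stitch_ground_truth(stack, partition_depth_bands(3, stack.shape[0]))

    def test_stitched_sharpness_dominates_per_band(self, source, grid):
        """Channel i matched in band i => stitched image is at least as sharp
        as every channel within each band."""
        z = grid.n_pixels // 2
        bands = partition_depth_bands(5, z)
        coeffs = np.linspace(-30, 30, 5)
        layers = []
        for (lo, hi), c in zip(bands, coeffs):
            dz = (lo + hi) / 2.0 * grid.depth_pitch_um
            layers.append(Layer(dz, 0.6, DispersionSpec(a2=float(c))))
        sample = LayeredSample(tuple(layers))
        frame = simulate_volume(sample, 1, 8, rng_seed=2, source=source, grid=grid)[0]
        stack = build_compensation_stack(frame, -30, 30, 5)
        stitched = stitch_ground_truth(stack, bands)
        for band in bands:
            s_stitched = sharpness_score(stitched.image, band)
            for b in stack.bscans:
                assert s_stitched >= sharpness_score(b.image, band) - 1e-12


class TestBuildDataset:
    def _volumes(self, source, grid, n_volumes=3, bscans=2):
        sample = LayeredSample(
            (Layer(100.0, 0.5, DispersionSpec(a2=-15.0)), Layer(300.0, 0.5, DispersionSpec(a2=15.0)))
        )
        return [
            simulate_volume(
                sample, bscans, 16, noise_model=NoiseModel(additive_sigma=0.02),
                rng_seed=v, source=source, grid=grid, volume_index=v,
            )
            for v in range(n_volumes)
        ]

    def test_volume_wise_split(self, source, grid):
        vols = self._volumes(source, grid)
        bands = partition_depth_bands(5, grid.n_pixels // 2)
        pairs = build_dataset(vols, 5, (-30, 30), bands, n_train_volumes=2)
        by_volume = {}
        for p in pairs:
            by_volume.setdefault(p.meta["volume_index"], set()).add(p.split)
        assert all(len(splits) == 1 for splits in by_volume.values())
        assert sum(p.split == "test" for p in pairs) == 2

    def test_single_channel_input_against_five_channel_target(self, source, grid):
        vols = self._volumes(source, grid, n_volumes=2)
        bands = partition_depth_bands(5, grid.n_pixels // 2)
        pairs1 = build_dataset(vols, 1, (-30, 30), bands, n_train_volumes=1)
        pairs5 = build_dataset(vols, 5, (-30, 30), bands, n_train_volumes=1)
        assert pairs1[0].inputs.shape[0] == 1
        # the target is the N=5-derived ground truth regardless of input count
        np.testing.assert_array_equal(pairs1[0].target, pairs5[0].target)

    def test_deterministic_rebuild(self, source, grid):
        vols = self._volumes(source, grid, n_volumes=2)
        bands = partition_depth_bands(5, grid.n_pixels // 2)
        a = build_dataset(vols, 3, (-30, 30), bands, n_train_volumes=1)
        b = build_dataset(vols, 3, (-30, 30), bands, n_train_volumes=1)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.inputs, pb.inputs)
            np.testing.assert_array_equal(pa.target, pb.target)

    def test_too_few_volumes_rejected(self, source, grid):
        vols = self._volumes(source, grid, n_volumes=1)
        bands = partition_depth_bands(5, grid.n_pixels // 2)
        with pytest.raises(ValueError):
            build_dataset(vols, 5, (-30, 30), bands, n_train_volumes=1)
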