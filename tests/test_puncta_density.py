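"""Puncta detection, colocalization, and density aggregation."""

import numpy as np
import pandas as pd
import pytest

from inhibpipe import (
    DetectionParams,
    ImagingGenConfig,
    PunctaSet,
    analyze_stack,
    colocalize,
    detect_puncta,
    generate_stack,
    per_animal_summary,
    subtract_background,
)
from inhibpipe.puncta_density import match_puncta

VOXEL = (0.10, 0.10, 0.14)


class TestSubtractBackground:
    def test_constant_image_goes_to_zero(self):
        img = np.full((20, 50, 50), 7.0)
        out = subtract_background(img, VOXEL)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_punctum_on_gradient_preserved(self):
        cfg = ImagingGenConfig(stack_size_um=(10, 10, 3), density_vgat=0.0,
                               poisson_noise=False, read_noise_sd=0.0,
                               background=0.0, seed=0)
        stack, _, _ = generate_stack(cfg)
        img = stack.channels["VGAT"]
        from inhibpipe.synth_imaging import _render_puncta

        _render_puncta(img, np.array([[5.0, 5.0, 1.5]]), VOXEL, (0.12, 0.35), 100.0)
        gradient = np.linspace(0, 30, img.shape[2])[None, None, :]
        out = subtract_background(img + gradient, VOXEL)
        assert out.max() == pytest.approx(100.0, rel=0.10)

    def test_blank_noisy_image_near_zero_mean(self):
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(20.0, 4.0, (20, 60, 60)), 0, None)
        out = subtract_background(img, VOXEL)
        assert abs(out.mean()) < 4.0


class TestDetectPuncta:
    def test_blank_stack_empty_set(self):
        cfg = ImagingGenConfig(stack_size_um=(10, 10, 3), density_vgat=0.0)
        stack, _, _ = generate_stack(cfg)
        img = subtract_background(stack.channels["VGAT"], VOXEL)
        detected = detect_puncta(img, VOXEL)
        assert len(detected) == 0

    def test_well_separated_puncta_high_recall_precision(self):
        # ~100 puncta in 30 x 30 x 7 um: mean spacing >> PSF, nominal SNR 10
        cfg = ImagingGenConfig(stack_size_um=(30, 30, 7), density_vgat=100 / 6300,
                               frac_double=0.0, seed=7)
        stack, truth, _ = generate_stack(cfg)
        img = subtract_background(stack.channels["VGAT"], VOXEL)
        detected = detect_puncta(img, VOXEL)
        matches = match_puncta(detected, truth["VGAT"], 0.3)
        recall = len(matches) / len(truth["VGAT"])
        precision = len(matches) / len(detected)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_crowded_count_within_15pct(self):
        cfg = ImagingGenConfig(stack_size_um=(30, 30, 7), density_vgat=0.34,
                               frac_double=0.0, seed=8)
        stack, truth, _ = generate_stack(cfg)
        img = subtract_background(stack.channels["VGAT"], VOXEL)
        detected = detect_puncta(img, VOXEL)
        assert len(detected) == pytest.approx(len(truth["VGAT"]), rel=0.15)

    def test_translation_equivariance(self):
        cfg = ImagingGenConfig(stack_size_um=(20, 20, 5), density_vgat=0.08,
                               poisson_noise=False, read_noise_sd=0.0, seed=9)
        stack, _, _ = generate_stack(cfg)
        img = stack.channels["VGAT"]
        shift = (2, 5, 7)  # voxels in (z, y, x)
        shifted = np.roll(img, shift, axis=(0, 1, 2))
        a = detect_puncta(img, VOXEL)
        b = detect_puncta(shifted, VOXEL)
        vz, vy, vx = 0.14, 0.10, 0.10
        offset = np.array([shift[2] * vx, shift[1] * vy, shift[0] * vz])
        moved = a.centroids + offset
        # np.roll wraps puncta across the boundary, so the property only
        # holds for detections that stay in the interior after the shift
        size = np.array([20.0, 20.0, 5.0])
        margin = 1.0
        interior = np.all((a.centroids > margin) & (moved < size - margin), axis=1)
        assert interior.sum() >= 20
        m = match_puncta(PunctaSet(moved[interior], "x"), b, 0.05)
        assert len(m) >= 0.9 * interior.sum()


class TestColocalize:
    def test_close_pair_is_double_positive(self):
        vgat = PunctaSet(np.array([[1.0, 1.0, 1.0]]), "VGAT")
        other = PunctaSet(np.array([[1.2, 1.0, 1.0]]), "CB1")  # 0.2 um apart
        res = colocalize(vgat, other, stack_volume_um3=100.0, coloc_radius_um=0.3)
        assert res.n_double == 1
        assert res.pct_double == 100.0

    def test_disjoint_sets_zero_density(self):
        vgat = PunctaSet(np.array([[1.0, 1.0, 1.0]]), "VGAT")
        other = PunctaSet(np.array([[5.0, 5.0, 3.0]]), "CB1")
        res = colocalize(vgat, other, 100.0)
        assert res.density_double == 0.0

    def test_each_partner_used_once(self):
        # two VGAT puncta near one channel-2 punctum: only one match
        vgat = PunctaSet(np.array([[1.0, 1.0, 1.0], [1.1, 1.0, 1.0]]), "VGAT")
        other = PunctaSet(np.array([[1.05, 1.0, 1.0]]), "CB1")
        res = colocalize(vgat, other, 100.0)
        assert res.n_double == 1

    def test_zero_vgat_undefined_pct(self):
        vgat = PunctaSet(np.empty((0, 3)), "VGAT")
        other = PunctaSet(np.array([[1.0, 1.0, 1.0]]), "CB1")
        res = colocalize(vgat, other, 100.0)
        assert res.density_vgat == 0.0
        assert np.isnan(res.pct_double)

    def test_shrinking_radius_monotone(self, rng):
        vgat = PunctaSet(rng.uniform(0, 10, (80, 3)), "VGAT")
        other = PunctaSet(rng.uniform(0, 10, (60, 3)), "CB1")
        counts = [
            colocalize(vgat, other, 1000.0, r).n_double
            for r in (0.6, 0.45, 0.3, 0.15, 0.05)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        for r in (0.6, 0.3, 0.05):
            res = colocalize(vgat, other, 1000.0, r)
            assert res.density_double <= res.density_vgat


class TestEndToEnd:
    def test_planted_density_and_fraction_recovered(self):
        """Moderate-density stack: density within 15 %, fraction within 5 pts."""
        cfg = ImagingGenConfig(stack_size_um=(25, 25, 6), density_vgat=0.14,
                               frac_double=0.51, seed=21)
        stack, truth, _ = generate_stack(cfg)
        res, _, _ = analyze_stack(stack)
        assert res.density_vgat == pytest.approx(0.14, rel=0.15)
        assert res.density_double == pytest.approx(0.14 * 0.51, rel=0.15)
        assert res.pct_double == pytest.approx(51.0, abs=5.0)


class TestPerAnimalSummary:
    def _table(self):
        rows = []
        for animal, base in (("a1", 0.04), ("a2", 0.06)):
            for k in range(12):
                rows.append({"animal_id": animal, "genotype": "Eu",
                             "density_vgat": 0.14, "density_double": base + 0.001 * k,
                             "pct_double": 30.0 + k})
        return pd.DataFrame(rows)

    def test_identical_stacks_mean_equals_each(self):
        table = pd.DataFrame(
            [{"animal_id": "a1", "density_vgat": 0.1, "density_double": 0.05,
              "pct_double": 50.0}] * 12
        )
        out = per_animal_summary(table)
        assert out.loc[0, "pct_double"] == 50.0

    def test_mean_equals_brute_force_average(self):
        table = self._table()
        out = per_animal_summary(table).set_index("animal_id")
        for animal in ("a1", "a2"):
            sub = table[table.animal_id == animal]
            assert out.loc[animal, "density_double"] == pytest.approx(
                sub["density_double"].mean()
            )

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            per_animal_summary(pd.DataFrame({"animal_id": ["a"]}))
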