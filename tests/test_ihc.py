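"""Colour deconvolution, bulb counting, and IgG percent-area quantification."""
import numpy as np
import pytest

from headkin import (
    IHCField,
    IHCFieldSpec,
    StainMatrix,
    app_count,
    color_deconvolve,
    igg_percent_area,
    simulate_ihc_field,
    threshold_from_reference,
)
from headkin.errors import InvalidSpecError, InvalidStainsError, InvalidThresholdError
from headkin.ihc_quant import mix_stains, od_to_rgb, rgb_to_od


def dab_level(od):
    """Inverted 8-bit rendering of a DAB optical density."""
    return 255.0 * (1.0 - 10.0 ** (-od))


class TestColorDeconvolve:
    def test_white_image_zero_od(self):
        rgb = np.full((8, 8, 3), 255, dtype=np.uint8)
        res = color_deconvolve(rgb)
        for name in ("hematoxylin", "dab", "residual"):
            assert np.max(np.abs(res.od[name])) < 0.01

    def test_mix_unmix_round_trip(self):
        conc = np.zeros((4, 4, 3))
        conc[..., 1] = 0.8  # pure DAB
        rgb = mix_stains(conc, StainMatrix.hdab())
        res = color_deconvolve(rgb)  # float image: no quantization error
        assert np.allclose(res.od["dab"], 0.8, atol=1e-6)
        assert np.allclose(res.od["hematoxylin"], 0.0, atol=1e-6)
        assert np.allclose(res.od["residual"], 0.0, atol=1e-6)

    def test_round_trip_dense_od(self, rng):
        conc = rng.uniform(0.0, 3.0, size=(16, 16, 3))
        stains = StainMatrix.hdab()
        back = color_deconvolve(mix_stains(conc, stains), stains)
        for i, name in enumerate(("hematoxylin", "dab", "residual")):
            assert np.max(np.abs(back.od[name] - conc[..., i])) < 1e-6

    def test_stain_label_permutation(self):
        stains = StainMatrix.hdab()
        conc = np.zeros((4, 4, 3))
        conc[..., 0] = 0.5  # hematoxylin
        swapped = StainMatrix(stains.matrix[[1, 0, 2]])
        rgb = mix_stains(conc, stains)
        res = color_deconvolve(rgb, swapped)
        # hematoxylin content now lands in the swapped matrix's second row
        assert np.allclose(res.od["dab"], 0.5, atol=1e-6)
        assert np.allclose(res.od["hematoxylin"], 0.0, atol=1e-6)

    def test_singular_matrix_rejected(self):
        v = np.array([0.5, 0.6, 0.62])
        with pytest.raises(InvalidStainsError):
            StainMatrix(np.vstack([v, v, np.array([0.1, 0.2, 0.3])]))

    def test_vectors_match_published_hdab(self):
        # cross-check against scikit-image's Ruifrok-Johnston H-DAB rows
        from skimage.color import rgb_from_hdx

        ours = StainMatrix.hdab().matrix
        theirs = rgb_from_hdx[:2] / np.linalg.norm(rgb_from_hdx[:2], axis=1, keepdims=True)
        assert np.allclose(ours[:2], theirs, atol=1e-6)

    def test_od_transform_inverse(self, rng):
        I = rng.uniform(0, 255, size=(5, 5, 3))
        assert np.allclose(od_to_rgb(rgb_to_od(I)), I, atol=1e-9)


class TestAppCount:
    def test_recovers_truth_count(self):
        field = simulate_ihc_field(IHCFieldSpec(n_bulbs=12, noise_sd=0.0, seed=1))
        res = app_count(field, threshold=100.0)
        assert res.count == 12

    def test_blank_field(self):
        field = simulate_ihc_field(IHCFieldSpec(n_bulbs=0, noise_sd=0.0, seed=1))
        assert app_count(field, threshold=100.0).count == 0

    def test_two_population_threshold(self):
        """12 bulbs, 4 of them fainter than threshold -> count 8."""
        bright = simulate_ihc_field(IHCFieldSpec(n_bulbs=8, dab_od=0.8, noise_sd=0.0, seed=2))
        faint = simulate_ihc_field(IHCFieldSpec(n_bulbs=4, dab_od=0.3, noise_sd=0.0, seed=3))
        # merge: darkest stain wins pixel-wise (disjoint fields in practice)
        rgb = np.minimum(bright.rgb, faint.rgb)
        field = IHCField(rgb, bright.microns_per_pixel)
        thr = (dab_level(0.3) + dab_level(0.8)) / 2.0
        assert app_count(field, threshold=thr).count == 8
        low = dab_level(0.3) - 20.0
        assert app_count(field, threshold=low).count == 12

    def test_count_monotone_in_threshold(self):
        field = simulate_ihc_field(IHCFieldSpec(n_bulbs=15, noise_sd=0.0, seed=4))
        counts = [app_count(field, thr).count for thr in (210.0, 150.0, 100.0, 60.0)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_invalid_threshold(self):
        field = simulate_ihc_field(IHCFieldSpec(n_bulbs=1, seed=0))
        with pytest.raises(InvalidThresholdError):
            app_count(field, threshold=300.0)

    def test_size_filter_excludes_confluent_patch(self):
        """A large confluent stained patch (far above bulb scale) must be
        dropped by the equivalent-diameter filter while bulbs survive."""
        base = simulate_ihc_field(IHCFieldSpec(n_bulbs=6, noise_sd=0.0, seed=5))
        conc = np.zeros(base.rgb.shape[:2] + (3,))
        conc[..., 0] = 0.25
        conc[..., 1] = np.where(base.truth["bulb_mask"], 0.8, 0.0)
        conc[5:105, 300:400, 1] = 0.8  # 200 x 200 um square, eq diam ~226 um
        rgb = np.clip(np.round(mix_stains(conc, StainMatrix.hdab())), 0, 255).astype(np.uint8)
        field = IHCField(rgb, base.microns_per_pixel)
        res = app_count(field, threshold=100.0, size_filter_um=(2.0, 50.0))
        assert res.count == 6


class TestIgGPercentArea:
    def test_blank_fields_zero(self):
        fields = [simulate_ihc_field(IHCFieldSpec(n_bulbs=0, noise_sd=0.0, seed=s))
                  for s in range(6)]
        assert igg_percent_area(fields, threshold=100.0) == 0.0

    def test_saturated_fields_hundred(self):
        fields = [
            simulate_ihc_field(IHCFieldSpec(n_bulbs=0, igg_fraction=1.0, noise_sd=0.0, seed=s))
            for s in range(6)
        ]
        assert igg_percent_area(fields, threshold=100.0) == pytest.approx(100.0)

    def test_mean_of_ground_truth_fractions(self):
        fracs = (0.1, 0.2, 0.3, 0.1, 0.2, 0.3)
        fields = [
            simulate_ihc_field(IHCFieldSpec(n_bulbs=0, igg_fraction=f, noise_sd=0.0, seed=s))
            for s, f in enumerate(fracs)
        ]
        pct = igg_percent_area(fields, threshold=100.0)
        assert pct == pytest.approx(20.0, abs=0.5)

    def test_area_additive_over_disjoint_regions(self):
        a = simulate_ihc_field(IHCFieldSpec(n_bulbs=0, igg_fraction=0.15, noise_sd=0.0, seed=7))
        mask_a = a.truth["igg_mask"]
        # carve a disjoint second region on a fresh blank field
        blank = simulate_ihc_field(IHCFieldSpec(n_bulbs=0, noise_sd=0.0, seed=8))
        h, w = mask_a.shape
        mask_b = np.zeros_like(mask_a)
        mask_b[: h // 4, : w // 2] = True
        mask_b &= ~mask_a
        from headkin.ihc_quant import mix_stains, StainMatrix

        conc = np.zeros((h, w, 3))
        conc[..., 0] = 0.25
        conc[..., 1] = np.where(mask_a | mask_b, 0.8, 0.0)
        rgb = np.clip(np.round(mix_stains(conc, StainMatrix.hdab())), 0, 255).astype(np.uint8)
        field = IHCField(rgb, a.microns_per_pixel)
        pct_union = igg_percent_area([field], threshold=100.0)
        expected = 100.0 * (mask_a.sum() + mask_b.sum()) / mask_a.size
        assert pct_union == pytest.approx(expected, abs=0.05)

    def test_empty_collection_rejected(self):
        with pytest.raises(InvalidSpecError):
            igg_percent_area([], threshold=100.0)

    def test_non_six_count_warns(self, caplog):
        fields = [simulate_ihc_field(IHCFieldSpec(n_bulbs=0, seed=0))]
        with caplog.at_level("WARNING", logger="headkin.ihc_quant"):
            igg_percent_area(fields, threshold=100.0)
        assert any("6 images" in rec.message for rec in caplog.records)


class TestThresholdFromReference:
    def test_minimum_definition(self):
        assert threshold_from_reference([180.0, 140.0, 200.0]) == 140.0

    def test_single_pixel(self):
        assert threshold_from_reference([167.0]) == 167.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidSpecError):
            threshold_from_reference([])

    def test_separates_two_populations_at_zero_noise(self):
        field = simulate_ihc_field(
            IHCFieldSpec(n_bulbs=10, dab_od=0.8, background_od=0.1, noise_sd=0.0, seed=6)
        )
        dab = field.dab_intensity()
        bulb_vals = dab[field.truth["bulb_mask"]]
        bg_vals = dab[~field.truth["bulb_mask"]]
        thr = threshold_from_reference(bulb_vals, bg_vals)
        assert np.all(bulb_vals >= thr)
        assert np.all(bg_vals < thr)

    def test_recovery_over_noisy_fields(self):
        """Exact count recovery on >= 95% of noisy synthetic fields
        (30-field spot check; the 100-field sweep runs in acceptance)."""
        exact = 0
        rng = np.random.default_rng(0)
        for seed in range(30):
            n_bulbs = int(rng.integers(0, 41))
            field = simulate_ihc_field(
                IHCFieldSpec(n_bulbs=n_bulbs, noise_sd=4.0, seed=seed)
            )
            if app_count(field, threshold=100.0).count == n_bulbs:
                exact += 1
        assert exact >= int(0.95 * 30)
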