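import numpy as np
import pytest

from spermtopo.imaging import (
    ChannelMap,
    ConfigError,
    SegmentationParams,
    SpotParams,
    assign_basal_end,
    detect_spots,
    measure_if_intensity,
    segment_nuclei,
)


def make_map(**kw):
    roles = {0: "nuclear", 1: "fish:4", 2: "if:5mC", 3: "if:5hmC"}
    return ChannelMap(roles=roles, **kw)


def draw_ellipse(img, center_px, L_px, l_px, theta, value):
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    dx = xx - center_px[0]
    dy = yy - center_px[1]
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / (L_px / 2)
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / (l_px / 2)
    img[u**2 + v**2 <= 1] += value
    return img


class TestChannelMap:
    def test_requires_one_nuclear(self):
        with pytest.raises(ConfigError, match="nuclear"):
            ChannelMap(roles={0: "fish:4"})

    def test_duplicate_if_rejected(self):
        with pytest.raises(ConfigError):
            ChannelMap(roles={0: "nuclear", 1: "if:5mC", 2: "if:5mC"})

    def test_fish_lookup(self):
        cmap = make_map()
        assert cmap.fish_channels() == {"4": 1}
        assert cmap.if_channel("5hmC") == 3

    def test_json_roundtrip(self, tmp_path):
        cmap = make_map(pixel_size_um=0.2)
        p = tmp_path / "channels.json"
        p.write_text(cmap.to_json())
        back = ChannelMap.from_json(p)
        assert back == cmap


class TestSegmentNuclei:
    def test_blank_image(self):
        img = np.full((256, 256), 100.0)
        assert segment_nuclei(img, make_map()) == []

    def test_three_ellipses_fitted(self):
        # three disjoint 6.0 x 3.5 um ellipses at 0.1 um/px
        img = np.full((512, 512), 100.0)
        for cx, cy, th in [(100, 100, 0.3), (300, 150, 1.2), (200, 400, 2.0)]:
            draw_ellipse(img, (cx, cy), 60, 35, th, 4000.0)
        nuclei = segment_nuclei(img, make_map())
        assert len(nuclei) == 3
        for nuc in nuclei:
            assert nuc.major_um == pytest.approx(6.0, rel=0.05)
            assert nuc.minor_um == pytest.approx(3.5, rel=0.05)

    def test_border_clipped_excluded(self):
        img = np.full((256, 256), 100.0)
        draw_ellipse(img, (5, 128), 60, 35, 0.0, 4000.0)  # clipped at left edge
        assert segment_nuclei(img, make_map()) == []
        kept = segment_nuclei(
            img, make_map(), SegmentationParams(exclude_border=False, min_solidity=0.0)
        )
        assert len(kept) == 1 and kept[0].touches_border

    def test_debris_filtered_by_area(self):
        img = np.full((256, 256), 100.0)
        draw_ellipse(img, (128, 128), 12, 10, 0.0, 4000.0)  # ~1 um^2 speck
        assert segment_nuclei(img, make_map()) == []

    def test_channel_stack_input(self):
        stack = np.full((4, 256, 256), 100.0)
        draw_ellipse(stack[0], (128, 128), 60, 35, 0.5, 4000.0)
        assert len(segment_nuclei(stack, make_map())) == 1


class TestAssignBasalEnd:
    @staticmethod
    def _nucleus():
        img = np.full((256, 256), 100.0)
        draw_ellipse(img, (128, 128), 60, 35, 0.0, 4000.0)
        (nuc,) = segment_nuclei(img, make_map())
        return nuc

    def test_hint_selects_nearer_endpoint(self):
        nuc = self._nucleus()
        e1, e2 = nuc.endpoints_um
        geom = assign_basal_end(nuc, hint_um=tuple(e1 + [0.2, 0.1]))
        assert np.allclose(geom.basal_point, e1, atol=0.3)
        assert geom.qc_pass

    def test_no_hint_flags_ambiguous(self):
        nuc = self._nucleus()
        geom = assign_basal_end(nuc, None)
        assert nuc.axis_ambiguous and not geom.qc_pass

    def test_equidistant_hint_rejected(self):
        nuc = self._nucleus()
        with pytest.raises(ValueError, match="equidistant"):
            assign_basal_end(nuc, hint_um=tuple(nuc.center_um))


class TestDetectSpots:
    @staticmethod
    def _scene(rng, spot_positions_px, amplitude=8000.0, sigma_px=1.5):
        stack = np.full((4, 256, 256), 100.0)
        draw_ellipse(stack[0], (128, 128), 60, 35, 0.0, 4000.0)
        yy, xx = np.mgrid[0:256, 0:256]
        for cx, cy in spot_positions_px:
            stack[1] += amplitude * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2)
            )
        noisy = rng.poisson(stack).astype(float)
        return noisy

    def test_no_signal_channel(self, rng):
        img = self._scene(rng, [])
        nuclei = segment_nuclei(img, make_map())
        assert detect_spots(img, 1, make_map(), nuclei) == []

    def test_single_spot_subpixel(self, rng):
        img = self._scene(rng, [(130.4, 126.7)])
        nuclei = segment_nuclei(img, make_map())
        (spot,) = detect_spots(img, 1, make_map(), nuclei, chromosome="4")
        assert spot.chromosome == "4"
        # within 0.5 px of ground truth
        assert abs(spot.centroid[0] / 0.1 - 130.4) < 0.5
        assert abs(spot.centroid[1] / 0.1 - 126.7) < 0.5

    def test_two_separated_spots(self, rng):
        img = self._scene(rng, [(120, 128), (140, 128)])  # 20 px >> 3 sigma
        nuclei = segment_nuclei(img, make_map())
        spots = detect_spots(img, 1, make_map(), nuclei)
        assert len(spots) == 2

    def test_spot_outside_nucleus_discarded(self, rng):
        img = self._scene(rng, [(30, 30)])  # far from the ellipse
        nuclei = segment_nuclei(img, make_map())
        assert detect_spots(img, 1, make_map(), nuclei) == []


class TestMeasureIfIntensity:
    def test_uniform_image_zero(self):
        img = np.full((4, 256, 256), 100.0)
        draw_ellipse(img[0], (128, 128), 60, 35, 0.0, 4000.0)
        nuclei = segment_nuclei(img, make_map())
        assert measure_if_intensity(img, 2, nuclei[0], nuclei) == pytest.approx(0.0)

    def test_amplitude_recovered(self, rng):
        img = np.full((4, 256, 256), 100.0)
        draw_ellipse(img[0], (128, 128), 60, 35, 0.0, 4000.0)
        draw_ellipse(img[2], (128, 128), 60, 35, 0.0, 1000.0)
        noisy = rng.poisson(img).astype(float)
        nuclei = segment_nuclei(noisy, make_map())
        val = measure_if_intensity(noisy, 2, nuclei[0], nuclei)
        assert val == pytest.approx(1000.0, rel=0.02)

    def test_amplitude_ratio(self, rng):
        img = np.full((4, 512, 512), 100.0)
        draw_ellipse(img[0], (128, 128), 60, 35, 0.0, 4000.0)
        draw_ellipse(img[0], (380, 380), 60, 35, 1.0, 4000.0)
        draw_ellipse(img[2], (128, 128), 60, 35, 0.0, 800.0)
        draw_ellipse(img[2], (380, 380), 60, 35, 1.0, 1600.0)
        noisy = rng.poisson(img).astype(float)
        nuclei = segment_nuclei(noisy, make_map())
        assert len(nuclei) == 2
        vals = sorted(measure_if_intensity(noisy, 2, n, nuclei) for n in nuclei)
        assert vals[1] / vals[0] == pytest.approx(2.0, rel=0.05)

    def test_empty_mask_rejected(self):
        img = np.full((256, 256), 100.0)
        from spermtopo.imaging import SegmentedNucleus

        nuc = SegmentedNucleus(
            mask=np.zeros((256, 256), bool), center_um=(0, 0), major_um=6,
            minor_um=3.5, axis_direction=(1, 0), touches_border=False,
        )
        with pytest.raises(ValueError, match="empty"):
            measure_if_intensity(img, 0, nuc, [nuc])


class TestRenderedSceneRoundTrip:
    def test_segment_count_matches_truth(self, rendered_scene):
        image, cmap, truth, _ = rendered_scene
        nuclei = segment_nuclei(image, cmap)
        assert len(nuclei) == (truth["record"] == "cell").sum()

    def test_spot_recall_precision(self, rendered_scene):
        image, cmap, truth, _ = rendered_scene
        nuclei = segment_nuclei(image, cmap)
        truth_sigs = truth[truth["record"] == "signal"]
        tp = fp = 0
        n_truth = len(truth_sigs)
        for chrom, ch_idx in cmap.fish_channels().items():
            spots = detect_spots(image, ch_idx, cmap, nuclei, chromosome=chrom)
            expected = truth_sigs[truth_sigs["chromosome"] == chrom]
            for spot in spots:
                d = np.hypot(
                    expected["x_um"] - spot.centroid[0], expected["y_um"] - spot.centroid[1]
                )
                if len(d) and d.min() < 0.3:  # 3 px
                    tp += 1
                else:
                    fp += 1
        recall = tp / n_truth
        precision = tp / (tp + fp) if tp + fp else 0.0
        assert recall >= 0.95
        assert precision >= 0.95

    def test_if_intensities_match_truth(self, rendered_scene):
        image, cmap, truth, _ = rendered_scene
        nuclei = segment_nuclei(image, cmap)
        cells = truth[truth["record"] == "cell"]
        for nuc in nuclei:
            d = np.hypot(cells["x_um"] - nuc.center_um[0], cells["y_um"] - nuc.center_um[1])
            row = cells.iloc[int(np.argmin(d))]
            measured = measure_if_intensity(image, cmap.if_channel("5mC"), nuc, nuclei)
            assert measured == pytest.approx(row["i_5mC"], rel=0.05)
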