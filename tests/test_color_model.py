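import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcta.color_model import (
    Status,
    assign_hues,
    compute_resultants,
    hsl_to_rgb,
    hue_of,
    resultant,
    saturation_of,
    unit_vector,
)
from mcta.config import ChannelDef
from mcta.preprocess import ProcessedTable


def make_channels(emissions, hues=None):
    return [
        ChannelDef(index=j + 1, source_column=j + 1, label=f"c{j + 1}",
                   emission_nm=e, background=0.0,
                   hue_deg=None if hues is None else hues[j])
        for j, e in enumerate(emissions)
    ]


class TestAssignHues:
    def test_four_channels_quarter_spacing(self):
        chans = assign_hues(make_channels([520, 578, 675, 774]))
        assert [c.hue_deg for c in chans] == [0.0, 90.0, 180.0, 270.0]

    def test_fifteen_channels_24_degree_spacing(self):
        chans = assign_hues(make_channels([500 + 10 * j for j in range(15)]))
        hues = sorted(c.hue_deg for c in chans)
        steps = np.diff(hues)
        np.testing.assert_allclose(steps, 24.0)

    def test_tie_broken_by_lower_index(self):
        chans = assign_hues(make_channels([660, 660]))
        assert chans[0].hue_deg < chans[1].hue_deg

    def test_emission_order_not_config_order(self):
        chans = assign_hues(make_channels([774, 520]))
        assert chans[0].hue_deg == 180.0  # longest emission gets the later hue
        assert chans[1].hue_deg == 0.0

    def test_explicit_hue_override_kept(self):
        chans = make_channels([520, 578], hues=[300.0, None])
        assign_hues(chans)
        assert chans[0].hue_deg == 300.0


class TestUnitVector:
    @pytest.mark.parametrize(
        "hue,expected",
        [
            (0.0, (1.0, 0.0)),
            (90.0, (0.0, 1.0)),
            (240.0, (-0.5, -math.sqrt(3) / 2)),
        ],
    )
    def test_exact_angles(self, hue, expected):
        x, y = unit_vector(hue)
        assert x == pytest.approx(expected[0], abs=1e-12)
        assert y == pytest.approx(expected[1], abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(hue=st.floats(0, 360, exclude_max=True))
    def test_unit_length(self, hue):
        x, y = unit_vector(hue)
        assert math.hypot(x, y) == pytest.approx(1.0, abs=1e-12)


class TestResultant:
    def test_single_channel(self):
        rx, ry, mag = resultant([0.0, 5.0], [0.0, 90.0], {2})
        assert rx == pytest.approx(0.0, abs=1e-12)
        assert ry == pytest.approx(5.0)
        assert mag == pytest.approx(5.0)

    def test_symmetric_pair_midpoint(self):
        rx, ry, _ = resultant([2.0, 2.0], [0.0, 90.0], {1, 2})
        assert hue_of(rx, ry) == pytest.approx(45.0)

    def test_three_four_five(self):
        # hand trigonometry oracle: I=(3,4) at 0/90 deg -> (3,4), |.|=5, 53.130 deg
        rx, ry, mag = resultant([3.0, 4.0], [0.0, 90.0], {1, 2})
        assert (rx, ry) == (pytest.approx(3.0), pytest.approx(4.0))
        assert mag == pytest.approx(5.0)
        assert hue_of(rx, ry) == pytest.approx(math.degrees(math.atan2(4, 3)))
        assert hue_of(rx, ry) == pytest.approx(53.130, abs=1e-3)

    def test_channels_outside_set_ignored(self):
        rx, ry, _ = resultant([3.0, 999.0], [0.0, 90.0], {1})
        assert (rx, ry) == (pytest.approx(3.0), pytest.approx(0.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            resultant([1.0], [0.0, 90.0], {1})

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            resultant([1.0], [0.0], set())

    @settings(max_examples=50, deadline=None)
    @given(
        intensities=st.lists(st.floats(0.01, 1e4), min_size=2, max_size=6),
        c=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, intensities, c):
        n = len(intensities)
        hues = [360.0 * j / n for j in range(n)]
        full = set(range(1, n + 1))
        rx1, ry1, m1 = resultant(intensities, hues, full)
        rx2, ry2, m2 = resultant([c * v for v in intensities], hues, full)
        # abs term covers the cancellation-degenerate case (magnitude ~ 0)
        assert m2 == pytest.approx(
            c * m1, rel=1e-9, abs=1e-11 * c * max(intensities)
        )
        h1, h2 = hue_of(rx1, ry1), hue_of(rx2, ry2)
        if h1 is not None and m1 > 1e-6:
            diff = abs(h1 - h2) % 360.0
            assert min(diff, 360.0 - diff) < 1e-6

    def test_cancellation_roots_of_unity(self):
        for n in (2, 3, 5, 8):
            hues = [360.0 * j / n for j in range(n)]
            intensity = 1234.5
            _, _, mag = resultant([intensity] * n, hues, set(range(1, n + 1)))
            assert mag < 1e-9 * intensity

    def test_convexity_shorter_arc(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            h1, sep = rng.uniform(0, 360), rng.uniform(1, 179)
            h2 = (h1 + sep) % 360.0
            i1, i2 = rng.uniform(0.1, 10, size=2)
            rx, ry, _ = resultant([i1, i2], [h1, h2], {1, 2})
            h = hue_of(rx, ry)
            off = (h - h1) % 360.0  # position along the arc from h1
            assert 0.0 <= off <= sep + 1e-9


class TestHueOf:
    @pytest.mark.parametrize("xy,expected", [((1, 0), 0.0), ((0, -2), 270.0)])
    def test_cardinal(self, xy, expected):
        assert hue_of(*xy) == pytest.approx(expected)

    def test_degenerate_undefined(self):
        assert hue_of(0.0, 0.0) is None


class TestSaturation:
    def test_zero_magnitude(self):
        assert saturation_of(0.0, 10.0) == 0.0

    def test_at_norm_is_one(self):
        assert saturation_of(10.0, 10.0) == 1.0

    def test_clamped_above(self):
        assert saturation_of(20.0, 10.0) == 1.0

    def test_bad_norm(self):
        with pytest.raises(ValueError):
            saturation_of(1.0, 0.0)


class TestHslToRgb:
    @pytest.mark.parametrize(
        "hsl,rgb",
        [
            ((0, 1, 0.5), (255, 0, 0)),
            ((120, 1, 0.5), (0, 255, 0)),
            ((240, 1, 0.5), (0, 0, 255)),
            ((37, 0, 0.5), (128, 128, 128)),
        ],
    )
    def test_reference_colors(self, hsl, rgb):
        assert hsl_to_rgb(*hsl) == rgb

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hsl_to_rgb(0, 1.5, 0.5)
        with pytest.raises(ValueError):
            hsl_to_rgb(0, 0.5, -0.1)


class TestComputeResultants:
    def _run(self, intens, cfg, labels=None):
        n = intens.shape[0]
        processed = ProcessedTable(intensities=intens, compensated=intens.copy())
        if labels is None:
            labels = np.full(n, Status.COLORED, dtype=object)
        return compute_resultants(processed, cfg, labels)

    def test_single_positive_exactness(self, config_builder):
        cfg = config_builder(nc=4)
        assign_hues(cfg.channels)
        intens = np.zeros((4, 4))
        for j in range(4):
            intens[j, j] = 100.0
        recs = self._run(intens, cfg)
        for j, ch in enumerate(cfg.channels):
            assert recs.hue_deg[j] == pytest.approx(ch.hue_deg, abs=1e-9)

    def test_batch_matches_naive_loop(self, config_builder):
        # oracle: per-event scalar loop over the same formula
        cfg = config_builder(nc=5, resultant={1, 3, 5})
        rng = np.random.default_rng(11)
        intens = rng.uniform(0, 1e4, size=(500, 5))
        recs = self._run(intens, cfg)
        hues = np.array([c.hue_deg for c in cfg.channels])
        for i in range(500):
            rx, ry, mag = resultant(intens[i], hues, cfg.resultant)
            assert recs.rx[i] == pytest.approx(rx, rel=1e-12, abs=1e-9)
            assert recs.ry[i] == pytest.approx(ry, rel=1e-12, abs=1e-9)
            assert recs.magnitude[i] == pytest.approx(mag, rel=1e-12, abs=1e-9)

    def test_achromatic_downgrade(self, config_builder):
        cfg = config_builder(nc=4)
        intens = np.zeros((3, 4))
        intens[0] = [1.0, 0, 0, 0]
        recs = self._run(intens, cfg)
        assert recs.status[0] is Status.COLORED
        assert recs.status[1] is Status.ACHROMATIC
        assert np.isnan(recs.hue_deg[1])

    def test_magnitude_pythagoras(self, config_builder):
        cfg = config_builder(nc=3)
        rng = np.random.default_rng(5)
        intens = rng.uniform(0, 100, size=(200, 3))
        recs = self._run(intens, cfg)
        np.testing.assert_allclose(
            recs.magnitude**2, recs.rx**2 + recs.ry**2, rtol=1e-9
        )

    def test_excluded_status_preserved(self, config_builder):
        cfg = config_builder(nc=3)
        intens = np.ones((2, 3))
        labels = np.array([Status.EXCLUDED, Status.COLORED], dtype=object)
        recs = self._run(intens, cfg, labels)
        assert recs.status[0] is Status.EXCLUDED
        assert recs.rgb(0) is None
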