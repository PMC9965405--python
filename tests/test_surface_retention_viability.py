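"""Roughness metrics, gravimetric retention and MTT normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from releasekit import (
    SurfaceProfile,
    corrected_signal,
    generate_plate,
    percent_viability,
    profile_from_image_row,
    retention_mass_loss,
    retention_signed,
    roughness,
    summarize_angles,
    viability_table,
)


class TestRoughness:
    def test_flat_profile(self):
        res = roughness(SurfaceProfile(np.arange(5), np.full(5, 42.0)))
        assert res.ra == 0.0 and res.rms == 0.0
        assert res.mean_line == 42.0

    def test_square_wave(self):
        res = roughness(SurfaceProfile(np.arange(4), [-1.0, 1.0, -1.0, 1.0]))
        assert res.ra == pytest.approx(1.0)
        assert res.rms == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # mean 3, deviations (-2, -1, 0, 3)
        res = roughness(SurfaceProfile(np.arange(4), [1.0, 2.0, 3.0, 6.0]))
        assert res.ra == pytest.approx(1.5)
        assert res.rms == pytest.approx(np.sqrt(3.5), abs=1e-4)  # 1.8708

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_rms_dominates_ra(self, z):
        res = roughness(SurfaceProfile(np.arange(len(z), dtype=float), z))
        assert res.rms >= res.ra >= 0.0 or np.isclose(res.rms, res.ra)

    @given(offset=st.floats(-500, 500), scale=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_offset_invariance_and_linear_scaling(self, offset, scale):
        z = np.array([1.0, 5.0, 2.0, 9.0, 4.0])
        x = np.arange(z.size, dtype=float)
        base = roughness(SurfaceProfile(x, z))
        shifted = roughness(SurfaceProfile(x, z + offset))
        assert shifted.ra == pytest.approx(base.ra, rel=1e-9, abs=1e-9)
        scaled = roughness(SurfaceProfile(x, z * scale))
        assert scaled.ra == pytest.approx(base.ra * scale, rel=1e-9)
        assert scaled.rms == pytest.approx(base.rms * scale, rel=1e-9)

    def test_nonuniform_spacing_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            SurfaceProfile([0.0, 1.0, 3.0], [1.0, 2.0, 3.0])


class TestImageProfile:
    def test_single_row_verbatim(self):
        img = np.arange(12.0).reshape(3, 4)
        profile = profile_from_image_row(img, 1)
        np.testing.assert_array_equal(profile.z, img[1])

    def test_uniform_image_constant_profile(self):
        profile = profile_from_image_row(np.full((5, 8), 7.0), (0, 5))
        assert np.ptp(profile.z) == 0.0
        assert roughness(profile).ra == 0.0

    def test_band_averaging(self):
        img = np.vstack([np.zeros(6), np.full(6, 2.0)])
        profile = profile_from_image_row(img, (0, 2))
        np.testing.assert_array_equal(profile.z, np.ones(6))

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="no rows"):
            profile_from_image_row(np.ones((3, 3)), (1, 1))


class TestRetention:
    @pytest.mark.parametrize("m0, meq, expected", [
        (0.200, 0.314, 57.0),   # mass gain on soaking
        (0.123, 0.123, 0.0),
        (0.200, 0.170, -15.0),  # net mass loss
    ])
    def test_signed_values(self, m0, meq, expected):
        assert retention_signed(m0, meq) == pytest.approx(expected)

    def test_mass_loss_convention_is_negated(self):
        assert retention_mass_loss(0.2, 0.314) == pytest.approx(-57.0)

    def test_antisymmetry_around_equal_masses(self):
        gap = 0.05
        assert retention_signed(0.2, 0.2 + gap) == pytest.approx(
            -retention_signed(0.2, 0.2 - gap))

    @given(scale=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale):
        assert retention_signed(0.2 * scale, 0.314 * scale) == pytest.approx(
            57.0, rel=1e-9)

    def test_nonpositive_dry_mass_rejected(self):
        with pytest.raises(ValueError):
            retention_signed(0.0, 0.1)


class TestAngles:
    def test_replicates(self):
        s = summarize_angles([129] * 5)
        assert s.mean == 129 and s.sd == 0 and s.hydrophobic

    def test_boundary_below_90(self):
        s = summarize_angles([89.0])
        assert s.mean == 89.0 and not s.hydrophobic

    def test_mean_sd(self):
        s = summarize_angles([111.0, 112.0, 113.0])
        assert s.mean == pytest.approx(112.0)
        assert s.sd == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            summarize_angles([181.0])
        with pytest.raises(ValueError):
            summarize_angles([])


class TestViability:
    def test_corrected_signal(self):
        assert corrected_signal(0.8, 0.1) == pytest.approx(0.7)
        assert corrected_signal(0.45, 0.0) == 0.45
        with pytest.warns(UserWarning, match="background exceeds"):
            assert corrected_signal(0.1, 0.2) == pytest.approx(-0.1)
        with pytest.raises(ValueError):
            corrected_signal(-0.1, 0.0)

    def test_identity_and_proportional(self):
        u = [0.6, 0.7, 0.65]
        assert percent_viability(u, u).pct == pytest.approx(100.0)
        t = [0.2 * v for v in u]
        assert percent_viability(t, u).pct == pytest.approx(20.0)
        assert percent_viability([0.0, 0.0], u).pct == 0.0

    def test_scale_invariance(self):
        t, u = [0.3, 0.35], [0.6, 0.7]
        a = percent_viability(t, u)
        b = percent_viability([3.0, 3.5], [6.0, 7.0])
        assert b.pct == pytest.approx(a.pct, rel=1e-12)
        assert b.se == pytest.approx(a.se, rel=1e-12)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            percent_viability([0.5], [0.0, 0.0])

    def test_plate_table_recovers_effects(self):
        plate = generate_plate({"membrane": 1.0, "membrane_querc": 0.2},
                               n_wells=6, seed=11)
        table = viability_table(plate)
        row = table.set_index("group")
        assert row.loc["membrane", "viability_pct"] == pytest.approx(100, abs=15)
        assert row.loc["membrane_querc", "viability_pct"] == pytest.approx(
            20, abs=10)
        assert (table["se_pct"] > 0).all()

    def test_missing_control_raises(self):
        plate = generate_plate({"membrane": 1.0}, seed=1)
        plate = plate[plate["group"] != "untreated"]
        with pytest.raises(ValueError, match="untreated"):
            viability_table(plate)
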