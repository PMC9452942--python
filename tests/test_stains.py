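"""Stain algebra: optical-density transforms, normalization, deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sccnn.errors import DegenerateStainError, InvalidParameterError, SingularStainMatrixError
from sccnn.stains import (
    HE_DEFAULT,
    StainMatrix,
    deconvolution_matrix,
    normalize_stain_matrix,
    od_to_rgb,
    rgb_to_od,
    separate_stains,
)


class TestOpticalDensity:
    def test_full_transmission_gives_zero_od(self):
        assert np.all(rgb_to_od(np.full((2, 2, 3), 255.0)) == 0.0)

    def test_tenth_transmission_gives_unit_od(self):
        od = rgb_to_od(np.full((1, 1, 3), 25.5))
        np.testing.assert_allclose(od, 1.0, atol=1e-12)

    def test_zero_intensity_clamped_to_od_six(self):
        od = rgb_to_od(np.zeros((1, 1, 3)))
        np.testing.assert_allclose(od, 6.0)

    def test_zero_od_gives_incident_intensity(self):
        np.testing.assert_allclose(od_to_rgb(np.zeros((2, 2, 3))), 255.0)

    def test_nonpositive_incident_rejected(self):
        with pytest.raises(InvalidParameterError):
            rgb_to_od(np.ones((1, 1, 3)), incident=0.0)
        with pytest.raises(InvalidParameterError):
            od_to_rgb(np.zeros((1, 1, 3)), incident=-1.0)

    def test_negative_od_rejected(self):
        with pytest.raises(InvalidParameterError):
            od_to_rgb(np.full((1, 1, 3), -0.1))

    def test_float_round_trip(self, rng):
        od = rng.uniform(0.0, 3.0, size=(8, 8, 3))
        back = rgb_to_od(od_to_rgb(od))
        assert np.abs(back - od).max() < 1e-6

    def test_quantized_round_trip_bounded_by_one_grey_level(self):
        # brute force over every 8-bit level above the clamp floor
        levels = np.arange(1, 256, dtype=np.float64)
        od = rgb_to_od(levels[:, None, None].repeat(3, axis=2))
        quantized = np.rint(od_to_rgb(od))
        od_back = rgb_to_od(quantized)
        # worst-case OD step between adjacent grey levels at the dark end
        step = np.log10(2.0 / 1.0)
        assert np.abs(od_back - od).max() <= step


class TestStainMatrix:
    def test_unit_row_unchanged(self):
        m = normalize_stain_matrix(StainMatrix(np.array([[1.0, 0.0, 0.0]])))
        np.testing.assert_allclose(m.rows, [[1, 0, 0]])

    def test_hematoxylin_row_normalization(self):
        m = normalize_stain_matrix(HE_DEFAULT)
        # oracle: divide by sqrt(0.18^2 + 0.20^2 + 0.18^2)
        expected = np.array([0.18, 0.20, 0.18]) / np.sqrt(0.18**2 + 0.20**2 + 0.18**2)
        np.testing.assert_allclose(m.rows[0], expected, atol=5e-5)
        np.testing.assert_allclose(m.rows[0], [0.5560, 0.6178, 0.5560], atol=5e-5)

    def test_eosin_row_normalization(self):
        m = normalize_stain_matrix(HE_DEFAULT)
        expected = np.array([0.01, 0.13, 0.01]) / np.sqrt(0.01**2 + 0.13**2 + 0.01**2)
        np.testing.assert_allclose(m.rows[1], expected, atol=5e-5)
        np.testing.assert_allclose(m.rows[1], [0.0765, 0.9941, 0.0765], atol=5e-5)

    def test_normalization_idempotent(self, rng):
        m = StainMatrix(rng.uniform(0.05, 1.0, size=(2, 3)))
        once = normalize_stain_matrix(m)
        twice = normalize_stain_matrix(once)
        np.testing.assert_allclose(once.rows, twice.rows, atol=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(DegenerateStainError):
            StainMatrix(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]))

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "he.yaml"
        HE_DEFAULT.to_yaml(path)
        loaded = StainMatrix.from_yaml(path)
        np.testing.assert_allclose(loaded.rows, HE_DEFAULT.rows)
        assert loaded.names == HE_DEFAULT.names


class TestDeconvolution:
    def test_identity_matrix_inverts_to_identity(self):
        m = StainMatrix(np.eye(3), normalized=True)
        np.testing.assert_allclose(deconvolution_matrix(m), np.eye(3), atol=1e-12)

    def test_pseudo_inverse_identity_on_stain_space(self, he_normalized):
        d = deconvolution_matrix(he_normalized)
        np.testing.assert_allclose(d @ he_normalized.rows.T, np.eye(2), atol=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_recovers_concentrations_from_od(self, seed):
        # oracle: generic least-squares solve against the pseudo-inverse route
        g = np.random.default_rng(seed)
        rows = g.uniform(0.05, 1.0, size=(2, 3))
        rows[1, 1] += 1.0  # keep the rows well-conditioned
        m = normalize_stain_matrix(StainMatrix(rows))
        c = g.uniform(0.0, 2.0, size=2)
        od = m.rows.T @ c
        recovered = deconvolution_matrix(m) @ od
        lstsq = np.linalg.lstsq(m.rows.T, od, rcond=None)[0]
        np.testing.assert_allclose(recovered, c, atol=1e-9)
        np.testing.assert_allclose(recovered, lstsq, atol=1e-9)

    def test_dependent_rows_rejected(self):
        m = StainMatrix(np.array([[0.6, 0.8, 0.0], [0.3, 0.4, 0.0]]))
        with pytest.raises(SingularStainMatrixError):
            deconvolution_matrix(normalize_stain_matrix(m))

    def test_invariant_to_row_rescaling(self, he_normalized):
        scaled = StainMatrix(HE_DEFAULT.rows * np.array([[3.7], [0.2]]))
        np.testing.assert_allclose(
            deconvolution_matrix(scaled), deconvolution_matrix(he_normalized), atol=1e-12
        )


class TestSeparateStains:
    def test_white_image_gives_zero_concentration(self, he_normalized):
        conc = separate_stains(np.full((4, 4, 3), 255.0), he_normalized)
        np.testing.assert_allclose(conc, 0.0, atol=1e-12)

    def test_forward_backward_round_trip(self, rng, he_normalized):
        true = rng.uniform(0.0, 1.5, size=(16, 16, 2))
        od = true @ he_normalized.rows
        image = od_to_rgb(od)
        recovered = separate_stains(image, he_normalized)
        assert np.abs(recovered - true).max() < 1e-6

    def test_unit_hematoxylin_pixel_maps_to_stain_row_od(self, he_normalized):
        # a pixel with unit hematoxylin and no eosin carries the H row as its OD
        od = np.tensordot(np.array([[[1.0, 0.0]]]), he_normalized.rows, axes=1)
        image = od_to_rgb(od)
        np.testing.assert_allclose(rgb_to_od(image), od, atol=1e-9)
        conc = separate_stains(image, he_normalized)
        np.testing.assert_allclose(conc[0, 0], [1.0, 0.0], atol=1e-9)

    def test_hematoxylin_only_pixel_has_no_eosin(self, he_normalized):
        od = np.tensordot(np.array([[[0.7, 0.0]]]), he_normalized.rows, axes=1)
        conc = separate_stains(od_to_rgb(od), he_normalized)
        assert abs(conc[0, 0, 1]) < 1e-6

    def test_clip_negative_flag(self, he_normalized):
        image = np.full((2, 2, 3), 255.0)
        image[..., 1] = 254.0  # slight green absorption only: negative H possible
        conc = separate_stains(image, he_normalized, clip_negative=True)
        assert conc.min() >= 0.0
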