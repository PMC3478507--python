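"""Folding of dose curves, kerma grids and spectra into coefficients."""

import warnings

import numpy as np
import pytest

from groundshine.decay import NuclideSpectrum, PhotonLine
from groundshine.folding import (
    DoseCurve,
    build_table,
    fold_mono,
    fold_nuclide,
)
from groundshine.transport import KermaGrid


def unit_curve(value=1.0):
    e = np.geomspace(0.01, 3.0, 10)
    return DoseCurve("adult", "icrp103", e, np.full(10, value))


def unit_grid(value=1.0, alphas=(0.0, 5.0)):
    e = np.geomspace(0.01, 3.0, 10)
    alphas = np.asarray(alphas, dtype=float)
    K = np.full((10, alphas.size, 1), value)
    return KermaGrid(e, alphas, [1.0], K, np.zeros_like(K), 1)


class TestFoldMono:
    def test_unit_curve_returns_kerma(self):
        grid = unit_grid(2e-18)
        assert fold_mono(unit_curve(1.0), grid, 0.5, 0.0) == pytest.approx(
            2e-18, rel=1e-12)

    def test_exact_product_at_shared_node(self):
        e = np.geomspace(0.01, 3.0, 10)
        curve = DoseCurve("adult", "icrp103", e, 0.5 + np.linspace(0, 1, 10))
        K = np.linspace(1, 2, 10)[:, None, None] * 1e-17
        grid = KermaGrid(e, [0.0], [1.0], K, np.zeros_like(K), 1)
        i = 4
        assert fold_mono(curve, grid, e[i], 0.0) == pytest.approx(
            curve.values[i] * K[i, 0, 0], rel=1e-12)

    def test_off_node_matches_independent_interpolation(self):
        e = np.geomspace(0.01, 3.0, 10)
        rng = np.random.default_rng(5)
        curve_v = np.exp(rng.uniform(-1, 0.5, 10))
        kv = np.exp(rng.uniform(-40, -39, (10, 2)))
        curve = DoseCurve("adult", "icrp103", e, curve_v)
        grid = KermaGrid(e, [0.0, 5.0], [1.0], kv[:, :, None],
                         np.zeros((10, 2, 1)), 1)
        eq, aq = 0.123, 2.7
        # independent two-step oracle: explicit log-log and linear interpolation
        ev = np.exp(np.interp(np.log(eq), np.log(e), np.log(curve_v)))
        k_at_alpha = kv[:, 0] + (kv[:, 1] - kv[:, 0]) * (aq - 0.0) / 5.0
        kq = np.exp(np.interp(np.log(eq), np.log(e), np.log(k_at_alpha)))
        assert fold_mono(curve, grid, eq, aq) == pytest.approx(
            ev * kq, rel=1e-12)

    def test_out_of_range_is_an_error(self):
        grid = unit_grid()
        with pytest.raises(ValueError):
            fold_mono(unit_curve(), grid, 5.0, 0.0)
        with pytest.raises(ValueError):
            fold_mono(unit_curve(), grid, 0.5, 50.0)


class TestFoldNuclide:
    def test_unit_folding(self):
        spec = NuclideSpectrum("Sy-1", (PhotonLine(0.5, 1.0),))
        out = fold_nuclide(spec, unit_curve(1.0), unit_grid(1.0), 0.0)
        assert out == pytest.approx(3600.0, rel=1e-12)

    def test_linearity_in_yield(self):
        one = NuclideSpectrum("Sy-1", (PhotonLine(0.5, 1.0),))
        halves = NuclideSpectrum("Sy-2", (PhotonLine(0.3, 0.5),
                                          PhotonLine(0.8, 0.5)))
        curve, grid = unit_curve(1.0), unit_grid(1.0)
        assert fold_nuclide(halves, curve, grid, 0.0) == pytest.approx(
            fold_nuclide(one, curve, grid, 0.0), rel=1e-12)

    def test_three_line_hand_sum(self):
        e = np.geomspace(0.01, 3.0, 10)
        curve_v = np.linspace(0.5, 1.5, 10)
        curve = DoseCurve("adult", "icrp103", e, curve_v)
        grid = unit_grid(2e-16)
        lines = ((0.05, 0.2), (0.5, 0.9), (2.0, 0.4))
        spec = NuclideSpectrum("Sy-3", tuple(PhotonLine(*l) for l in lines))
        expected = 3600.0 * sum(
            y * float(curve(en)) * 2e-16 for en, y in lines)
        assert fold_nuclide(spec, curve, grid, 0.0) == pytest.approx(
            expected, rel=1e-12)

    def test_zero_retained_lines_returns_zero_with_warning(self):
        spec = NuclideSpectrum("Sy-4", (PhotonLine(0.005, 1.0),))
        with pytest.warns(UserWarning):
            out = fold_nuclide(spec, unit_curve(), unit_grid(), 0.0)
        assert out == 0.0


class TestBuildTable:
    def test_constant_fixtures_give_closed_form(self):
        spectra = {
            "Sy-1": NuclideSpectrum("Sy-1", (PhotonLine(0.5, 0.7),)),
            "Sy-2": NuclideSpectrum("Sy-2", (PhotonLine(0.2, 0.3),
                                             PhotonLine(1.0, 0.6))),
        }
        table = build_table(spectra, [0.0, 5.0], unit_curve(2.0), unit_grid(1e-17))
        assert table.value("Sy-1", 0.0) == pytest.approx(
            3600.0 * 0.7 * 2.0 * 1e-17, rel=1e-12)
        assert table.value("Sy-2", 5.0) == pytest.approx(
            3600.0 * (0.3 + 0.6) * 2.0 * 1e-17, rel=1e-12)

    def test_depth_monotonicity_propagates_from_kerma(self):
        e = np.geomspace(0.01, 3.0, 10)
        K = np.stack([np.full(10, 1e-16), np.full(10, 4e-17)], axis=1)[:, :, None]
        grid = KermaGrid(e, [0.0, 5.0], [1.0], K, np.zeros_like(K), 1)
        spectra = {"Sy-1": NuclideSpectrum("Sy-1", (PhotonLine(0.6, 1.0),))}
        table = build_table(spectra, [0.0, 5.0], unit_curve(), grid)
        assert table.value("Sy-1", 5.0) <= table.value("Sy-1", 0.0)

    def test_empty_nuclide_list_gives_empty_table(self):
        table = build_table({}, [0.0], unit_curve(), unit_grid())
        assert table.entries.empty
        assert table.nuclides == []

    def test_csv_export_includes_tags(self, tmp_path):
        spectra = {"Sy-1": NuclideSpectrum("Sy-1", (PhotonLine(0.5, 1.0),))}
        table = build_table(spectra, [0.0], unit_curve(), unit_grid())
        path = tmp_path / "table.csv"
        table.to_csv(path)
        text = path.read_text()
        assert "coefficient_Sv_per_h_per_Bq_m2" in text
        assert "adult" in text and "icrp103" in text


def test_dose_curve_validation_and_range():
    e = np.geomspace(0.01, 3.0, 5)
    with pytest.raises(ValueError):
        DoseCurve("adult", "icrp103", e, np.array([1, 1, -1, 1, 1.0]))
    curve = DoseCurve("adult", "icrp103", e, np.ones(5))
    with pytest.raises(ValueError):
        curve(10.0)
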