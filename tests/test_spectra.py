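"""Band extraction: Beer-Lambert conversions, limits, integration, f_exp."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import gaussian_spectrum
from oscbench import spectra as sp
from oscbench.constants import EV_TO_WAVENUMBER, K_F
from oscbench.spectra import Band, Spectrum

GAUSS_AREA = np.sqrt(np.pi / (4 * np.log(2)))


@pytest.mark.parametrize(
    "absorbance,conc,path,expected",
    [(0.0, 1e-5, 1.0, 0.0), (1.0, 1e-5, 1.0, 1.0e5), (0.5, 2.5e-5, 0.5, 4.0e4)],
)
def test_epsilon_from_absorbance(absorbance, conc, path, expected):
    assert sp.epsilon_from_absorbance(absorbance, conc, path) == pytest.approx(expected)


@pytest.mark.parametrize("conc,path", [(0.0, 1.0), (-1e-5, 1.0), (1e-5, 0.0)])
def test_epsilon_from_absorbance_rejects_nonpositive(conc, path):
    with pytest.raises(ValueError):
        sp.epsilon_from_absorbance(1.0, conc, path)


def test_cross_section_conversion():
    assert sp.cross_section_from_epsilon(0.0) == 0.0
    assert sp.cross_section_from_epsilon(1.0) == pytest.approx(3.8235e-21, rel=1e-4)
    assert sp.cross_section_from_epsilon(1e5) == pytest.approx(3.8235e-16, rel=1e-4)
    with pytest.raises(ValueError):
        sp.cross_section_from_epsilon(-1.0)


def test_ev_wavenumber_conversion_constant():
    # CODATA-derived value used for the energy-axis convention
    assert EV_TO_WAVENUMBER == pytest.approx(8065.543937, abs=1e-5)


def test_spectrum_invariants():
    with pytest.raises(ValueError):
        Spectrum("m", "s", [1.0, 2.0], [1.0, 1.0])  # too short
    with pytest.raises(ValueError):
        Spectrum("m", "s", [1.0, 3.0, 2.0], [1.0, 1.0, 1.0])  # not increasing
    with pytest.raises(ValueError):
        Spectrum("m", "s", [1.0, 2.0, 3.0], [1.0, -1.0, 1.0])  # negative eps


def test_band_invariants():
    with pytest.raises(ValueError):
        Band(0, 2000.0, 1000.0, 0.1, 1500.0)
    with pytest.raises(ValueError):
        Band(0, 1000.0, 2000.0, 0.1, 2500.0)  # mean outside window


def test_detect_band_limits_monotone_curve_is_single_band():
    nu = np.linspace(10000, 20000, 501)
    s = Spectrum("m", "s", nu, np.linspace(0.0, 1e4, 501))
    limits = sp.detect_band_limits(s)
    assert limits.tolist() == [nu[0], nu[-1]]


def test_detect_band_limits_two_equal_gaussians():
    s = gaussian_spectrum([30000, 40000], [2000, 2000], [1e4, 1e4], grid_step=2.0)
    limits = sp.detect_band_limits(s)
    interior = limits[1:-1]
    assert len(interior) == 1
    assert abs(interior[0] - 35000.0) <= 2.0  # within one grid step of symmetry point


def test_detect_band_limits_synthetic_three_band(clean_set):
    cfg, spectra, _, truth = clean_set
    for spectrum, mol in zip(spectra, truth.molecules):
        limits = sp.detect_band_limits(spectrum)
        assert len(limits) == len(mol.band_limits)
        for found, true in zip(limits[1:-1], mol.band_limits[1:-1]):
            assert abs(found - true) <= cfg.grid_step


def test_detect_band_limits_rejects_oversized_window():
    s = gaussian_spectrum([30000], [2000], [1e4], grid_step=100.0)
    with pytest.raises(ValueError):
        sp.detect_band_limits(s, smoothing_window=1e9)


def test_integrate_band_rectangle():
    nu = np.arange(9000.0, 12001.0, 1.0)
    eps = np.where((nu >= 10000) & (nu <= 11000), 1e4, 0.0)
    s = Spectrum("m", "s", nu, eps)
    assert sp.integrate_band(s, 10000.0, 11000.0) == pytest.approx(1e7, rel=1e-3)


def test_integrate_band_gaussian_closed_form():
    s = gaussian_spectrum([35000], [3000], [2e4], grid_step=1.0, margin=5.5)
    integral = sp.integrate_band(s, 35000 - 5 * 3000, 35000 + 5 * 3000)
    assert integral == pytest.approx(2e4 * 3000 * GAUSS_AREA, rel=1e-4)


def test_integrate_band_zero_spectrum():
    nu = np.linspace(10000, 20000, 101)
    s = Spectrum("m", "s", nu, np.zeros(101))
    assert sp.integrate_band(s, 12000, 18000) == 0.0


def test_integrate_band_out_of_range():
    s = gaussian_spectrum([35000], [3000], [1e4])
    with pytest.raises(ValueError):
        sp.integrate_band(s, 0.0, 35000.0)


def test_band_oscillator_strength():
    assert sp.band_oscillator_strength(0.0) == 0.0
    assert sp.band_oscillator_strength(1.0 / K_F) == pytest.approx(1.0)
    assert sp.band_oscillator_strength(1e7) == pytest.approx(4.32e-2, rel=1e-2)
    with pytest.raises(ValueError):
        sp.band_oscillator_strength(-1.0)


def test_band_mean_energy_symmetric_gaussian():
    s = gaussian_spectrum([35000], [3000], [1e4])
    assert sp.band_mean_energy(s, 30000, 40000) == pytest.approx(35000, abs=1.0)


def test_band_mean_energy_rectangles():
    nu = np.arange(500.0, 2501.0, 1.0)
    s1 = Spectrum("m", "s", nu, np.where((nu >= 1000) & (nu <= 2000), 5.0, 0.0))
    assert sp.band_mean_energy(s1, 1000, 2000) == pytest.approx(1500, rel=1e-6)
    eps = np.where((nu >= 1000) & (nu <= 1100), 1.0, 0.0) + np.where(
        (nu >= 1900) & (nu <= 2000), 3.0, 0.0
    )
    s2 = Spectrum("m", "s", nu, eps)
    # weighted centroid (1*1050 + 3*1950)/4
    assert sp.band_mean_energy(s2, 900, 2100) == pytest.approx(1725, rel=1e-3)


def test_band_mean_energy_zero_integral_raises():
    nu = np.linspace(1000, 2000, 101)
    s = Spectrum("m", "s", nu, np.zeros(101))
    with pytest.raises(ValueError):
        sp.band_mean_energy(s, 1200, 1800)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(split=st.floats(0.05, 0.95))
def test_band_strength_additive_under_window_split(split):
    s = gaussian_spectrum([35000], [3000], [1.7e4], grid_step=4.0)
    lo, hi = 26000.0, 44000.0
    mid = lo + split * (hi - lo)
    whole = sp.integrate_band(s, lo, hi)
    parts = sp.integrate_band(s, lo, mid) + sp.integrate_band(s, mid, hi)
    assert parts == pytest.approx(whole, rel=1e-12)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    lo=st.floats(27000, 33000),
    width=st.floats(1000, 10000),
    bump_center=st.floats(28000, 42000),
    bump_height=st.floats(0, 5e3),
)
def test_band_strength_monotone_and_mean_inside_window(lo, width, bump_center, bump_height):
    hi = lo + width
    base = gaussian_spectrum([35000], [3000], [1e4], grid_step=4.0)
    bumped = Spectrum(
        "m",
        "s",
        base.wavenumbers,
        base.epsilon
        + bump_height
        * np.exp(-4 * np.log(2) * ((base.wavenumbers - bump_center) / 500.0) ** 2),
    )
    f0 = sp.integrate_band(base, lo, hi)
    f1 = sp.integrate_band(bumped, lo, hi)
    assert f1 >= f0 - 1e-9
    if f1 > 0:
        mean = sp.band_mean_energy(bumped, lo, hi)
        assert lo <= mean <= hi


def test_round_trip_extraction_matches_truth(clean_set):
    cfg, spectra, _, truth = clean_set
    for spectrum, mol in zip(spectra, truth.molecules):
        limits = sp.detect_band_limits(spectrum)
        for k, f_true in enumerate(mol.f_exp):
            f_hat = sp.band_oscillator_strength(
                sp.integrate_band(spectrum, limits[k], limits[k + 1])
            )
            assert f_hat == pytest.approx(f_true, rel=1e-3)


def test_extract_bands_labels_and_count(clean_set):
    _, spectra, _, truth = clean_set
    bands = sp.extract_bands(spectra[0], confidence="VH")
    assert len(bands) == len(truth.molecules[0].f_exp)
    assert all(b.confidence == "VH" for b in bands)
    assert all(b.lo <= b.e_exp <= b.hi for b in bands)


def test_vhhm_filter_membership():
    assert {"VH", "H", "M"} <= sp.VHHM
    assert "L" not in sp.VHHM and "VL" not in sp.VHHM


def test_csv_round_trip(tmp_path):
    s = gaussian_spectrum([30000], [2000], [1e4], grid_step=10.0, molecule_id="azulene")
    path = tmp_path / "azulene.csv"
    import pandas as pd

    pd.DataFrame(
        {"wavenumber_cm-1": s.wavenumbers, "epsilon_M-1cm-1": s.epsilon}
    ).to_csv(path, index=False)
    back = sp.read_spectrum(path)
    assert back.molecule_id == "azulene"
    np.testing.assert_allclose(back.wavenumbers, s.wavenumbers)
    np.testing.assert_allclose(back.epsilon, s.epsilon)


def test_csv_missing_columns(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("a,b\n1,2\n3,4\n5,6\n")
    with pytest.raises(ValueError, match="wavenumber_cm-1"):
        sp.read_spectrum_csv(path)


JCAMP_XYDATA = """##TITLE=test dye
##JCAMP-DX=4.24
##XUNITS=1/CM
##YUNITS=ABSORBANCE
##XFACTOR=1.0
##YFACTOR=100.0
##XYDATA=(X++(Y..Y))
30000 1.0 2.0 3.0
30003 4.0 5.0 6.0
##END=
"""

JCAMP_XYPOINTS = """##TITLE=test dye
##XYPOINTS=(XY..XY)
30000, 100.0; 30010, 200.0
30020, 300.0
##END=
"""


def test_jcamp_xydata(tmp_path):
    path = tmp_path / "dye.jdx"
    path.write_text(JCAMP_XYDATA)
    s = sp.read_spectrum(path)
    assert s.molecule_id == "test dye"
    np.testing.assert_allclose(s.wavenumbers, 30000 + np.arange(6))
    np.testing.assert_allclose(s.epsilon, 100.0 * np.arange(1, 7))


def test_jcamp_xypoints(tmp_path):
    path = tmp_path / "dye.dx"
    path.write_text(JCAMP_XYPOINTS)
    s = sp.read_spectrum(path)
    np.testing.assert_allclose(s.wavenumbers, [30000, 30010, 30020])
    np.testing.assert_allclose(s.epsilon, [100.0, 200.0, 300.0])


def test_band_table_writer(tmp_path):
    bands = {"m1": [Band(0, 1000.0, 2000.0, 0.25, 1500.0, "H")]}
    df = sp.write_band_table(bands, tmp_path / "bands.csv")
    row = df.iloc[0]
    assert row["molecule"] == "m1"
    assert row["e_exp_eV"] == pytest.approx(1500.0 / EV_TO_WAVENUMBER)
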