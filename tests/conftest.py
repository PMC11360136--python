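import numpy as np
import pytest

from oscbench.spectra import Band, Spectrum
from oscbench.synthetic import SyntheticConfig, generate_benchmark_set
from oscbench.transitions import ComputedTransition, TransitionSet
from oscbench.constants import wavenumber_to_ev


def gaussian_spectrum(
    centers, fwhms, peak_heights, grid_step=1.0, margin=6.0, molecule_id="mol"
):
    """Sum-of-Gaussians epsilon curve on a uniform wavenumber grid."""
    centers = np.asarray(centers, float)
    fwhms = np.asarray(fwhms, float)
    lo = centers.min() - margin * fwhms.max()
    hi = centers.max() + margin * fwhms.max()
    nu = np.arange(lo, hi + grid_step, grid_step)
    eps = np.zeros_like(nu)
    for c, w, a in zip(centers, fwhms, np.asarray(peak_heights, float)):
        eps += a * np.exp(-4.0 * np.log(2.0) * ((nu - c) / w) ** 2)
    return Spectrum(molecule_id, "test", nu, eps)


def make_problem(band_windows, transition_energies_cm, strengths, targets, gauge="length"):
    """Small assignment problem from plain numbers (energies in cm^-1)."""
    bands = tuple(
        Band(k, lo, hi, max(t, 0.0), 0.5 * (lo + hi))
        for k, ((lo, hi), t) in enumerate(zip(band_windows, targets))
    )
    order = np.argsort(transition_energies_cm)
    ts = tuple(
        ComputedTransition(
            i + 1,
            wavenumber_to_ev(float(transition_energies_cm[j])),
            float(strengths[j]),
            float(strengths[j]),
            float(strengths[j]),
        )
        for i, j in enumerate(order)
    )
    from oscbench.assignment import AssignmentProblem

    return AssignmentProblem(bands, TransitionSet("mol", "test", ts), tuple(targets), gauge)


@pytest.fixture(scope="session")
def clean_set():
    """Small noise-free synthetic benchmark set (C* = 1.3)."""
    cfg = SyntheticConfig(n_molecules=8, seed=42)
    spectra, tsets, truth = generate_benchmark_set(cfg)
    return cfg, spectra, tsets, truth
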