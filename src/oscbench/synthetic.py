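"""Synthetic benchmark sets with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
molecule's solution spectrum is a sum of well-separated Gaussian band
envelopes, each band fed by a handful of stick transitions whose summed
strength exceeds the apparent experimental band strength by a known
global factor C* (emulating the systematic overestimation of computed
strengths relative to in-solvent measurements, typically 1.1-1.6 for
TD-DFT).  Computed transition energies may carry a systematic
multiplicative shift (electronic-structure methods overestimating
energies by ~10% is the regime in which strict band-limit assignment
breaks down) and Gaussian jitter; rendered intensities may carry
per-band multiplicative amplitude noise, which is what makes extracted
band strengths noisy at the stated coefficient of variation (noise
applied per grid point would average away under integration).

Everything is reproducible from the master seed, with one independent
stream per molecule so a molecule's data do not change when the set is
resized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import K_F, wavenumber_to_ev
from .spectra import Band, Spectrum
from .transitions import ComputedTransition, TransitionSet
from .assignment import AssignmentProblem

__all__ = [
    "SyntheticConfig",
    "MoleculeTruth",
    "SyntheticTruth",
    "generate_benchmark_set",
    "render_spectrum",
    "problems_from_truth",
]

_GAUSS_AREA = float(np.sqrt(np.pi / (4.0 * np.log(2.0))))  # area = A * fwhm * this


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; defaults give a clean, well-separated set."""

    n_molecules: int = 50
    bands_per_molecule: tuple[int, int] = (1, 3)
    transitions_per_band: tuple[int, int] = (1, 3)
    band_center_range: tuple[float, float] = (25000.0, 50000.0)  # cm^-1
    band_fwhm_range: tuple[float, float] = (1500.0, 2500.0)  # cm^-1
    min_band_separation: float = 3.5  # multiples of the larger FWHM
    stick_strength_lognorm: tuple[float, float] = (-1.6, 0.6)  # (mu, sigma) of ln f
    true_scale_c: float = 1.3
    energy_shift_fraction: float = 0.0  # systematic; 0.10 emulates ~10% overestimation
    energy_jitter_sd: float = 0.0  # cm^-1
    epsilon_noise_cv: float = 0.0  # per-band multiplicative amplitude noise
    gauge_spread: float = 0.0  # relative spread of velocity/mixed vs length
    grid_step: float = 1.0  # cm^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")
        if self.true_scale_c <= 0:
            raise ValueError("true_scale_c must be positive")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        for name in ("bands_per_molecule", "transitions_per_band"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be a non-degenerate range >= 1")
        lo, hi = self.band_center_range
        if not lo < hi:
            raise ValueError("band_center_range must be non-degenerate")
        lo, hi = self.band_fwhm_range
        if not 0 < lo <= hi:
            raise ValueError("band_fwhm_range must be positive")


@dataclass(frozen=True)
class MoleculeTruth:
    """Ground truth for one synthetic molecule."""

    molecule_id: str
    band_limits: tuple[float, ...]  # n_bands + 1 boundaries, cm^-1
    band_centers: tuple[float, ...]
    band_fwhm: tuple[float, ...]
    f_exp: tuple[float, ...]  # noise-free apparent strengths
    f_exp_noisy: tuple[float, ...]  # with the rendered amplitude factors
    e_true: tuple[float, ...]  # stick-weighted band energies, cm^-1 (unshifted)
    membership: tuple[tuple[int, ...], ...]  # band -> indices in energy-sorted set
    amplitude_factors: tuple[float, ...]


@dataclass(frozen=True)
class SyntheticTruth:
    config: SyntheticConfig
    molecules: tuple[MoleculeTruth, ...]

    @property
    def true_c(self) -> float:
        return self.config.true_scale_c


def render_spectrum(
    molecule_id: str,
    centers: Sequence[float],
    fwhms: Sequence[float],
    f_exps: Sequence[float],
    grid_step: float = 1.0,
    amplitude_factors: Sequence[float] | None = None,
    margin_fwhm: float = 6.0,
) -> Spectrum:
    """Render Gaussian band envelopes whose areas encode the f_exp values.

    Each band contributes A * exp(-4 ln2 (nu - c)^2 / fwhm^2) with the
    amplitude chosen so the band area equals f_exp / K_F (optionally scaled
    by a per-band noise factor).
    """
    centers = np.asarray(centers, float)
    fwhms = np.asarray(fwhms, float)
    f_exps = np.asarray(f_exps, float)
    factors = (
        np.ones_like(f_exps)
        if amplitude_factors is None
        else np.asarray(amplitude_factors, float)
    )
    lo = float(centers.min() - margin_fwhm * fwhms.max())
    hi = float(centers.max() + margin_fwhm * fwhms.max())
    nu = np.arange(lo, hi + grid_step, grid_step)
    eps = np.zeros_like(nu)
    for c, w, f, s in zip(centers, fwhms, f_exps, factors):
        area = s * f / K_F
        amp = area / (w * _GAUSS_AREA)
        eps += amp * np.exp(-4.0 * np.log(2.0) * ((nu - c) / w) ** 2)
    return Spectrum(molecule_id, "synthetic", nu, np.clip(eps, 0.0, None))


def _sample_centers_fwhms(rng, cfg: SyntheticConfig, n_bands: int):
    """Sample band centers honouring the separation constraint.

    The minimum pairwise gaps are laid down first and the remaining span
    is distributed randomly among the n_bands + 1 slots, so any feasible
    configuration is produced without rejection.
    """
    lo, hi = cfg.band_center_range
    fwhms = rng.uniform(*cfg.band_fwhm_range, size=n_bands)
    min_gaps = [
        cfg.min_band_separation * max(fwhms[i], fwhms[i + 1])
        for i in range(n_bands - 1)
    ]
    slack = (hi - lo) - sum(min_gaps)
    if slack < 0:
        raise ValueError(
            "could not place bands with the requested separation; widen the "
            "center range or reduce band count/FWHM"
        )
    extra = rng.dirichlet(np.ones(n_bands + 1)) * slack
    centers = np.empty(n_bands)
    centers[0] = lo + extra[0]
    for i in range(n_bands - 1):
        centers[i + 1] = centers[i] + min_gaps[i] + extra[i + 1]
    return centers, fwhms


def _true_trough(c0, w0, a0, c1, w1, a1) -> float:
    """Location of the minimum of two Gaussians between their centers."""
    from scipy.optimize import minimize_scalar

    def env(x):
        return a0 * np.exp(-4 * np.log(2) * ((x - c0) / w0) ** 2) + a1 * np.exp(
            -4 * np.log(2) * ((x - c1) / w1) ** 2
        )

    res = minimize_scalar(env, bounds=(c0, c1), method="bounded", options={"xatol": 1e-6})
    return float(res.x)


def generate_benchmark_set(
    config: SyntheticConfig,
) -> tuple[list[Spectrum], list[TransitionSet], SyntheticTruth]:
    """Generate spectra, transition tables and ground truth for a set."""
    spectra: list[Spectrum] = []
    tsets: list[TransitionSet] = []
    truths: list[MoleculeTruth] = []
    for m in range(config.n_molecules):
        rng = np.random.default_rng([config.seed, m])
        mol_id = f"mol{m:03d}"
        n_bands = int(rng.integers(config.bands_per_molecule[0], config.bands_per_molecule[1] + 1))
        centers, fwhms = _sample_centers_fwhms(rng, config, n_bands)

        stick_e: list[float] = []
        stick_f: list[float] = []
        stick_band: list[int] = []
        f_exp = []
        e_true = []
        mu, sigma = config.stick_strength_lognorm
        for k in range(n_bands):
            n_sticks = int(
                rng.integers(config.transitions_per_band[0], config.transitions_per_band[1] + 1)
            )
            es = centers[k] + rng.uniform(-0.25, 0.25, size=n_sticks) * fwhms[k]
            fs = rng.lognormal(mu, sigma, size=n_sticks)
            stick_e.extend(es.tolist())
            stick_f.extend(fs.tolist())
            stick_band.extend([k] * n_sticks)
            total = float(fs.sum())
            f_exp.append(total / config.true_scale_c)
            e_true.append(float((es * fs).sum() / total))

        factors = (
            1.0 + config.epsilon_noise_cv * rng.standard_normal(n_bands)
            if config.epsilon_noise_cv > 0
            else np.ones(n_bands)
        )
        factors = np.clip(factors, 0.05, None)
        spectrum = render_spectrum(
            mol_id, centers, fwhms, f_exp, config.grid_step, factors
        )

        # true band limits: spectrum endpoints plus the analytic troughs of
        # the noise-free envelope between adjacent band centers
        amps = np.asarray(f_exp) / K_F / (fwhms * _GAUSS_AREA)
        limits = [float(spectrum.wavenumbers[0])]
        for k in range(n_bands - 1):
            limits.append(
                _true_trough(
                    centers[k], fwhms[k], amps[k], centers[k + 1], fwhms[k + 1], amps[k + 1]
                )
            )
        limits.append(float(spectrum.wavenumbers[-1]))

        # computed transitions: systematic shift + jitter on stick energies
        e_comp_cm = np.asarray(stick_e) * (1.0 + config.energy_shift_fraction)
        if config.energy_jitter_sd > 0:
            e_comp_cm = e_comp_cm + rng.normal(0.0, config.energy_jitter_sd, size=e_comp_cm.size)
        order = np.argsort(e_comp_cm)
        membership: list[list[int]] = [[] for _ in range(n_bands)]
        transitions = []
        for pos, idx in enumerate(order):
            membership[stick_band[idx]].append(pos)
            fl = float(stick_f[idx])
            if config.gauge_spread > 0:
                fv = max(0.0, fl * (1.0 + config.gauge_spread * rng.standard_normal()))
                fm = max(0.0, fl * (1.0 + 0.5 * config.gauge_spread * rng.standard_normal()))
            else:
                fv = fm = fl
            transitions.append(
                ComputedTransition(
                    pos + 1,
                    wavenumber_to_ev(float(e_comp_cm[idx])),
                    fl,
                    fv,
                    fm,
                )
            )
        tsets.append(TransitionSet(mol_id, "synthetic", tuple(transitions)))
        spectra.append(spectrum)
        truths.append(
            MoleculeTruth(
                mol_id,
                tuple(limits),
                tuple(map(float, centers)),
                tuple(map(float, fwhms)),
                tuple(f_exp),
                tuple(float(f * s) for f, s in zip(f_exp, factors)),
                tuple(e_true),
                tuple(tuple(b) for b in membership),
                tuple(map(float, factors)),
            )
        )
    return spectra, tsets, SyntheticTruth(config, tuple(truths))


def problems_from_truth(
    truth: SyntheticTruth,
    tsets: Sequence[TransitionSet],
    gauge: str = "length",
    noisy: bool = False,
) -> list[AssignmentProblem]:
    """Assignment problems from the ground-truth bands.

    Targets are the (optionally noisy) apparent strengths themselves, i.e.
    the plain-f reference; callers wanting a scaled or solvent-corrected
    target transform the targets afterwards.
    """
    problems = []
    for mol, tset in zip(truth.molecules, tsets):
        f_ref = mol.f_exp_noisy if noisy else mol.f_exp
        bands = tuple(
            Band(k, mol.band_limits[k], mol.band_limits[k + 1], f_ref[k], mol.e_true[k])
            for k in range(len(f_ref))
        )
        problems.append(AssignmentProblem(bands, tset, tuple(f_ref), gauge))
    return problems
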