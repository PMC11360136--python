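"""Experimental absorption spectra and band reduction.

A :class:`Spectrum` holds a digitized molar attenuation curve
``epsilon(nu)`` (M^-1 cm^-1 against wavenumber in cm^-1) for one molecule in
one solvent.  The reduction pipeline locates band limits at local minima of
the (optionally smoothed) curve, integrates each band by the trapezoid rule,
and converts the integral into an apparent oscillator strength

    f_exp = K_F * integral_lo^hi epsilon(nu) d nu

together with the intensity-weighted mean transition energy of the band.
Apparent means: solvent field effects are still folded into the measured
intensity; removing them is the job of :mod:`oscbench.solvent`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .constants import K_F, wavenumber_to_ev

__all__ = [
    "Spectrum",
    "Band",
    "CONFIDENCE_LABELS",
    "VHHM",
    "epsilon_from_absorbance",
    "cross_section_from_epsilon",
    "detect_band_limits",
    "integrate_band",
    "band_oscillator_strength",
    "band_mean_energy",
    "extract_bands",
    "read_spectrum",
    "read_spectrum_csv",
    "read_spectrum_jcamp",
    "write_band_table",
]

CONFIDENCE_LABELS = ("VH", "H", "M", "L", "VL")
#: Confidence labels retained by the default benchmark filter.
VHHM = frozenset({"VH", "H", "M"})


@dataclass(frozen=True)
class Spectrum:
    """A digitized absorption spectrum on a strictly increasing grid."""

    molecule_id: str
    solvent_id: str
    wavenumbers: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        nu = np.asarray(self.wavenumbers, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        object.__setattr__(self, "wavenumbers", nu)
        object.__setattr__(self, "epsilon", eps)
        if nu.ndim != 1 or eps.ndim != 1 or nu.shape != eps.shape:
            raise ValueError("wavenumbers and epsilon must be 1-D of equal length")
        if nu.size < 3:
            raise ValueError("spectrum needs at least 3 grid points")
        if not np.all(np.diff(nu) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(nu)) or not np.all(np.isfinite(eps)):
            raise ValueError("spectrum contains non-finite values")
        if np.any(eps < 0):
            raise ValueError("epsilon values must be non-negative")


@dataclass(frozen=True)
class Band:
    """One experimental band: window, apparent strength, mean energy."""

    band_index: int
    lo: float
    hi: float
    f_exp: float
    e_exp: float  # intensity-weighted mean, cm^-1
    confidence: str = "M"

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("band requires lo < hi")
        if self.f_exp < 0:
            raise ValueError("f_exp must be non-negative")
        if not (self.lo <= self.e_exp <= self.hi):
            raise ValueError("mean energy must lie inside [lo, hi]")
        if self.confidence not in CONFIDENCE_LABELS:
            raise ValueError(f"unknown confidence label {self.confidence!r}")


def epsilon_from_absorbance(
    absorbance: float, concentration: float, path_length: float
) -> float:
    """Beer-Lambert molar attenuation: A / (c * l), in M^-1 cm^-1.

    Parameters are the measured decadic absorbance (dimensionless), the
    molar concentration (mol/L) and the optical path length (cm).
    """
    if concentration <= 0 or path_length <= 0:
        raise ValueError("concentration and path length must be positive")
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    return absorbance / (concentration * path_length)


def cross_section_from_epsilon(epsilon: float) -> float:
    """Absorption cross section (cm^2) from epsilon (M^-1 cm^-1)."""
    if np.any(np.asarray(epsilon) < 0):
        raise ValueError("epsilon must be non-negative")
    from .constants import EPSILON_TO_CROSS_SECTION

    return EPSILON_TO_CROSS_SECTION * epsilon


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(y, pad, mode="edge")  # edge padding keeps endpoints unbiased
    smoothed = np.convolve(padded, kernel, mode="same")
    return smoothed[pad : pad + y.size]


def detect_band_limits(
    spectrum: Spectrum,
    smoothing_window: float = 0.0,
    min_prominence: float = 0.01,
) -> np.ndarray:
    """Locate band boundaries at local minima of the attenuation curve.

    ``smoothing_window`` is a moving-average width in cm^-1 applied to a
    copy of the curve before minima are searched; reported boundaries are
    grid points of the *unsmoothed* spectrum.  ``min_prominence`` is the
    minimum dip prominence as a fraction of the spectrum maximum.  The two
    grid endpoints are always included, so N interior minima yield N+1
    bands.
    """
    nu = spectrum.wavenumbers
    eps = spectrum.epsilon
    step = float(np.median(np.diff(nu)))
    width = int(round(smoothing_window / step)) if smoothing_window > 0 else 0
    if width >= nu.size:
        raise ValueError("smoothing window wider than the spectrum")
    smoothed = _moving_average(eps, width) if width > 1 else eps

    scale = float(np.max(eps))
    if scale <= 0:
        return np.array([nu[0], nu[-1]])
    # minima of eps == peaks of -eps; prominence relative to global max
    idx, _ = find_peaks(-smoothed, prominence=min_prominence * scale)
    boundaries = np.concatenate([[nu[0]], nu[idx], [nu[-1]]])
    return np.unique(boundaries)


def _interp_epsilon(spectrum: Spectrum, x: float) -> float:
    return float(np.interp(x, spectrum.wavenumbers, spectrum.epsilon))


def _window_grid(spectrum: Spectrum, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Grid restricted to [lo, hi] with linearly interpolated endpoints."""
    nu = spectrum.wavenumbers
    if lo >= hi:
        raise ValueError("integration window requires lo < hi")
    if lo < nu[0] or hi > nu[-1]:
        raise ValueError("integration window outside the spectral grid")
    inner = (nu > lo) & (nu < hi)
    xs = np.concatenate([[lo], nu[inner], [hi]])
    ys = np.concatenate(
        [[_interp_epsilon(spectrum, lo)], spectrum.epsilon[inner], [_interp_epsilon(spectrum, hi)]]
    )
    return xs, ys


def integrate_band(spectrum: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of epsilon over [lo, hi] (M^-1 cm^-1 * cm^-1)."""
    xs, ys = _window_grid(spectrum, lo, hi)
    return float(np.trapezoid(ys, xs))


def band_oscillator_strength(integral: float) -> float:
    """Apparent oscillator strength from an integrated band intensity."""
    if integral < 0:
        raise ValueError("band integral must be non-negative")
    return K_F * integral


def band_mean_energy(spectrum: Spectrum, lo: float, hi: float) -> float:
    """Intensity-weighted mean wavenumber of a band (cm^-1)."""
    xs, ys = _window_grid(spectrum, lo, hi)
    denom = np.trapezoid(ys, xs)
    if denom <= 0:
        raise ValueError("band integral is zero; mean energy undefined")
    return float(np.trapezoid(xs * ys, xs) / denom)


def extract_bands(
    spectrum: Spectrum,
    smoothing_window: float = 0.0,
    min_prominence: float = 0.01,
    confidence: str | Sequence[str] = "M",
) -> list[Band]:
    """Full reduction: detect limits, integrate, convert to Band records.

    ``confidence`` may be a single label applied to every band or one label
    per detected band.
    """
    limits = detect_band_limits(spectrum, smoothing_window, min_prominence)
    n_bands = len(limits) - 1
    if isinstance(confidence, str):
        labels = [confidence] * n_bands
    else:
        labels = list(confidence)
        if len(labels) != n_bands:
            raise ValueError(f"expected {n_bands} confidence labels, got {len(labels)}")
    bands = []
    for k in range(n_bands):
        lo, hi = float(limits[k]), float(limits[k + 1])
        integral = integrate_band(spectrum, lo, hi)
        f_exp = band_oscillator_strength(integral)
        e_exp = band_mean_energy(spectrum, lo, hi) if integral > 0 else 0.5 * (lo + hi)
        bands.append(Band(k, lo, hi, f_exp, e_exp, labels[k]))
    return bands


# ---------------------------------------------------------------------------
# I/O


def read_spectrum_csv(path: str | Path, molecule_id: str = "", solvent_id: str = "") -> Spectrum:
    """Read a two-column delimited spectrum.

    Expected header: ``wavenumber_cm-1,epsilon_M-1cm-1`` (any delimiter
    pandas can sniff).  Rows are sorted by wavenumber on ingestion.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        nu_col = cols["wavenumber_cm-1"]
        eps_col = cols["epsilon_m-1cm-1"]
    except KeyError as exc:
        raise ValueError(
            f"{path}: expected columns 'wavenumber_cm-1' and 'epsilon_M-1cm-1'"
        ) from exc
    df = df.sort_values(nu_col)
    return Spectrum(
        molecule_id or path.stem,
        solvent_id,
        df[nu_col].to_numpy(float),
        df[eps_col].to_numpy(float),
    )


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def read_spectrum_jcamp(path: str | Path, molecule_id: str = "", solvent_id: str = "") -> Spectrum:
    """Read a JCAMP-DX spectrum (XYDATA ``(X++(Y..Y))`` or XYPOINTS dialects).

    Only plain AFFN numeric tables are supported, which covers digitized
    UV-vis deposits; compressed (DIFDUP/SQZ) encodings are not.
    XFACTOR/YFACTOR scaling and TITLE metadata are honoured.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    xfactor = yfactor = 1.0
    title = ""
    mode: str | None = None
    xs: list[float] = []
    ys: list[float] = []
    for raw in lines:
        line = raw.split("$$")[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "TITLE":
                title = value
            elif key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            elif key == "XYDATA":
                mode = "xydata"
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "END":
                mode = None
            else:
                mode = None if key not in ("XYDATA", "XYPOINTS") else mode
            continue
        if mode is None:
            continue
        nums = [float(m) for m in _JCAMP_NUM.findall(line)]
        if not nums:
            continue
        if mode == "xydata":
            # (X++(Y..Y)): first number is X of the first Y; subsequent Ys
            # advance by the implied grid step, resolved after reading.
            xs.append(nums[0])
            ys.append(nums[1:])  # type: ignore[arg-type]
        else:  # xypoints: explicit (x, y) pairs
            for x, y in zip(nums[::2], nums[1::2]):
                xs.append(x)
                ys.append(y)  # type: ignore[arg-type]
    if not xs:
        raise ValueError(f"{path}: no XYDATA/XYPOINTS table found")
    if ys and isinstance(ys[0], list):
        nu, eps = _expand_xydata(xs, ys)  # type: ignore[arg-type]
    else:
        nu = np.asarray(xs, float)
        eps = np.asarray(ys, float)
    nu = nu * xfactor
    eps = eps * yfactor
    order = np.argsort(nu)
    return Spectrum(molecule_id or title or path.stem, solvent_id, nu[order], eps[order])


def _expand_xydata(x_starts: list[float], y_rows: list[list[float]]) -> tuple[np.ndarray, np.ndarray]:
    """Expand (X++(Y..Y)) rows: per-row X start, Ys on an implied even grid."""
    if len(x_starts) > 1:
        counts = [len(r) for r in y_rows[:-1]]
        steps = [
            (x_starts[i + 1] - x_starts[i]) / counts[i]
            for i in range(len(x_starts) - 1)
            if counts[i] > 0
        ]
        step = float(np.median(steps))
    else:
        step = 1.0
    nu: list[float] = []
    eps: list[float] = []
    for x0, row in zip(x_starts, y_rows):
        for j, y in enumerate(row):
            nu.append(x0 + j * step)
            eps.append(y)
    return np.asarray(nu), np.asarray(eps)


def read_spectrum(path: str | Path, molecule_id: str = "", solvent_id: str = "") -> Spectrum:
    """Dispatch on extension: ``.jdx``/``.dx`` -> JCAMP, otherwise delimited."""
    suffix = Path(path).suffix.lower()
    if suffix in (".jdx", ".dx", ".jcamp"):
        return read_spectrum_jcamp(path, molecule_id, solvent_id)
    return read_spectrum_csv(path, molecule_id, solvent_id)


def write_band_table(bands: dict[str, list[Band]], path: str | Path) -> pd.DataFrame:
    """Write extracted bands for several molecules as delimited text."""
    rows = []
    for molecule, blist in bands.items():
        for b in blist:
            rows.append(
                {
                    "molecule": molecule,
                    "band_index": b.band_index,
                    "lo": b.lo,
                    "hi": b.hi,
                    "f_exp": b.f_exp,
                    "e_exp_cm-1": b.e_exp,
                    "e_exp_eV": wavenumber_to_ev(b.e_exp),
                    "confidence": b.confidence,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "molecule",
            "band_index",
            "lo",
            "hi",
            "f_exp",
            "e_exp_cm-1",
            "e_exp_eV",
            "confidence",
        ],
    )
    df.to_csv(path, index=False)
    return df
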