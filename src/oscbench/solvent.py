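"""Solvent refractive indexes and cavity-field corrections.

A chromophore dissolved in a solvent of refractive index ``n`` sees an
incident radiation field modified by the dielectric around its cavity, so
the apparent oscillator strength extracted from the solution spectrum is
not directly comparable to a strength computed for the isolated (or
reaction-field-only) molecule.  This module supplies the classical
spherical/ellipsoidal-cavity correction factors that map an apparent
experimental strength onto a reference value,

    reference = C(n) * f_exp

with the factor forms

    C_Chako(n)     = 9 n / (n^2 + 2)^2          (Lorentz local field, sphere)
    C_Shibuya,k(n) = n / [s_k (n^2 - 1) + 1]^2  (ellipsoid, axis k)
    C_AbeL(n)      = 9 n^2 / (n^2 + 2)^2        (Lorentz, Abe's variant)
    C_AbeO(n)      = 9 n^2 / (2 n + 1)^2        (Onsager cavity field)
    C_Schuyer(n)   = (2 n^2 + 1)(n^2 + 1) / (6 n)

plus the elementary prefactors 1/n, 1 and n, and a fixed user constant C.
The Shibuya shape parameter s_k is the depolarization factor along the
transition-moment axis of an ellipsoidal cavity: s_k in [0, 1], the three
axis values summing to 1, with s_k = 1/3 (sphere) recovering Chako's
factor.

The refractive index may be evaluated at the transition frequency from a
dispersion formula (Cauchy or Sellmeier) or held at the sodium-D-line
value n_D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .constants import wavenumber_to_nm

__all__ = [
    "SolventModel",
    "ReferenceMode",
    "REFERENCE_KINDS",
    "refractive_index",
    "correction_factor",
    "apply_reference",
    "check_depolarization_sum",
    "builtin_registry",
    "load_registry",
    "parse_reference_spec",
]

REFERENCE_KINDS = (
    "f_over_n",
    "f_plain",
    "n_times_f",
    "chako",
    "shibuya",
    "abe_lorentz",
    "abe_onsager",
    "schuyer",
    "fixed_c",
)

#: Sodium D line, nm.
SODIUM_D_NM = 589.29


@dataclass(frozen=True)
class SolventModel:
    """Refractive-index model for one solvent.

    ``coefficients`` meaning depends on ``dispersion_form``:

    - ``constant``: (n,)
    - ``cauchy``: (A, B[, C, ...]) with n(lambda) = A + B/lambda^2 + C/lambda^4,
      lambda in nm
    - ``sellmeier``: (B1, C1, B2, C2, ...) with
      n^2 = 1 + sum_i B_i lambda^2 / (lambda^2 - C_i), lambda in nm, C_i in nm^2
    """

    name: str
    n_D: float
    dispersion_form: str = "constant"
    coefficients: tuple[float, ...] = ()
    valid_range_nm: tuple[float, float] = (200.0, 1100.0)

    def __post_init__(self) -> None:
        if self.n_D < 1:
            raise ValueError("n_D must be >= 1")
        if self.dispersion_form not in ("cauchy", "sellmeier", "constant"):
            raise ValueError(f"unknown dispersion form {self.dispersion_form!r}")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    def n_at_wavelength(self, wavelength_nm: float) -> float:
        c = self.coefficients
        if self.dispersion_form == "constant":
            return c[0] if c else self.n_D
        if self.dispersion_form == "cauchy":
            lam2 = wavelength_nm**2
            return sum(coef / lam2**i for i, coef in enumerate(c))
        # sellmeier
        lam2 = wavelength_nm**2
        n2 = 1.0
        for b, cc in zip(c[::2], c[1::2]):
            n2 += b * lam2 / (lam2 - cc)
        return math.sqrt(n2)


@dataclass(frozen=True)
class ReferenceMode:
    """How the experimental strength is transformed into the benchmark target."""

    kind: str
    s_k: float = 1.0 / 3.0  # shibuya only
    c_value: float = 1.0  # fixed_c only
    n_source: str = "dispersion"  # or "n_D"

    def __post_init__(self) -> None:
        if self.kind not in REFERENCE_KINDS:
            raise ValueError(f"unknown reference kind {self.kind!r}")
        if not (0.0 <= self.s_k <= 1.0):
            raise ValueError("shibuya shape parameter s_k must lie in [0, 1]")
        if self.kind == "fixed_c" and self.c_value <= 0:
            raise ValueError("fixed_c requires a positive constant")
        if self.n_source not in ("dispersion", "n_D"):
            raise ValueError("n_source must be 'dispersion' or 'n_D'")


def refractive_index(
    solvent: SolventModel,
    wavenumber: float,
    n_source: str = "dispersion",
    allow_nd_fallback: bool = False,
) -> float:
    """Refractive index at a transition wavenumber (cm^-1).

    With ``n_source='dispersion'`` the solvent's dispersion formula is
    evaluated at the corresponding wavelength; out-of-range wavelengths
    raise unless ``allow_nd_fallback`` substitutes n_D explicitly.
    """
    if n_source == "n_D":
        return solvent.n_D
    lam = wavenumber_to_nm(wavenumber)
    lo, hi = solvent.valid_range_nm
    if not (lo <= lam <= hi):
        if allow_nd_fallback:
            return solvent.n_D
        raise ValueError(
            f"{solvent.name}: wavelength {lam:.1f} nm outside dispersion range "
            f"[{lo}, {hi}] nm"
        )
    return solvent.n_at_wavelength(lam)


def correction_factor(mode: ReferenceMode, n: float) -> float:
    """Multiplicative factor C such that the reference equals C * f_exp."""
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    kind = mode.kind
    if kind == "f_plain":
        return 1.0
    if kind == "f_over_n":
        return 1.0 / n
    if kind == "n_times_f":
        return n
    if kind == "fixed_c":
        return mode.c_value
    if kind == "chako":
        return 9.0 * n / (n**2 + 2.0) ** 2
    if kind == "shibuya":
        return n / (mode.s_k * (n**2 - 1.0) + 1.0) ** 2
    if kind == "abe_lorentz":
        return 9.0 * n**2 / (n**2 + 2.0) ** 2
    if kind == "abe_onsager":
        return 9.0 * n**2 / (2.0 * n + 1.0) ** 2
    if kind == "schuyer":
        return (2.0 * n**2 + 1.0) * (n**2 + 1.0) / (6.0 * n)
    raise ValueError(f"unknown reference kind {kind!r}")  # pragma: no cover


def apply_reference(f_exp: float, mode: ReferenceMode, n: float) -> float:
    """Reference value C(n) * f_exp for one band."""
    if f_exp < 0:
        raise ValueError("f_exp must be non-negative")
    return correction_factor(mode, n) * f_exp


def check_depolarization_sum(s: Sequence[float], tol: float = 1e-9) -> None:
    """Validate a triple of ellipsoid depolarization factors (must sum to 1)."""
    s = tuple(float(x) for x in s)
    if len(s) != 3 or any(not (0.0 <= x <= 1.0) for x in s):
        raise ValueError("need three depolarization factors in [0, 1]")
    if abs(sum(s) - 1.0) > tol:
        raise ValueError(f"depolarization factors sum to {sum(s)}, expected 1")


# ---------------------------------------------------------------------------
# Registry

# Two-term Cauchy coefficients n(lambda) = A + B/lambda^2 (lambda in nm) for
# the solvents of the benchmark, derived from handbook n_D values and visible
# dispersions (n_F - n_C); each reproduces n_D at 589.29 nm by construction.
_HANDBOOK: dict[str, tuple[float, float]] = {
    # name: (n_D at ~20-25 C, n_F - n_C)
    "water": (1.3330, 0.00597),
    "ethanol": (1.3611, 0.00606),
    "carbon_tetrachloride": (1.4601, 0.00949),
    "dioxane": (1.4224, 0.00812),
    "acetonitrile": (1.3442, 0.00593),
    "methanol": (1.3288, 0.00557),
    "cyclohexane": (1.4266, 0.00759),
    "hexane": (1.3749, 0.00646),
    "heptane": (1.3878, 0.00657),
}

# 1/486.13^2 - 1/656.28^2, nm^-2 (hydrogen F and C lines)
_FC_SPAN = 1.0 / 486.13**2 - 1.0 / 656.28**2


def _cauchy_from_handbook(n_d: float, n_f_minus_c: float) -> tuple[float, float]:
    b = n_f_minus_c / _FC_SPAN
    a = n_d - b / SODIUM_D_NM**2
    return a, b


def builtin_registry() -> dict[str, SolventModel]:
    """The nine benchmark solvents as two-term Cauchy models."""
    reg = {}
    for name, (n_d, dfc) in _HANDBOOK.items():
        a, b = _cauchy_from_handbook(n_d, dfc)
        reg[name] = SolventModel(name, n_d, "cauchy", (a, b), (200.0, 1100.0))
    reg["vacuum"] = SolventModel("vacuum", 1.0, "constant", (1.0,), (1.0, 1e9))
    return reg


def load_registry(path: str | Path) -> dict[str, SolventModel]:
    """Load a user solvent registry from a YAML key-value file.

    Each entry maps a solvent name to ``{n_D, form, coefficients,
    valid_range_nm}``; ``form`` defaults to ``constant`` with n = n_D.
    Unknown solvents must be declared here — there is no silent default.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    reg = {}
    for name, entry in raw.items():
        if not isinstance(entry, Mapping) or "n_D" not in entry:
            raise ValueError(f"solvent {name!r}: entry must map and contain n_D")
        reg[name] = SolventModel(
            name,
            float(entry["n_D"]),
            str(entry.get("form", "constant")),
            tuple(entry.get("coefficients", ())) or (float(entry["n_D"]),),
            tuple(entry.get("valid_range_nm", (200.0, 1100.0))),  # type: ignore[arg-type]
        )
    return reg


def parse_reference_spec(spec: str) -> ReferenceMode:
    """Parse a CLI-style reference spec.

    Accepted forms: ``f_over_n``, ``f``, ``nf``, ``chako``, ``abeL``,
    ``abeO``, ``schuyer``, ``shibuya:<s_k>``, ``C:<value>``.
    """
    aliases = {
        "f": "f_plain",
        "f_plain": "f_plain",
        "f_over_n": "f_over_n",
        "nf": "n_times_f",
        "n_times_f": "n_times_f",
        "chako": "chako",
        "abeL": "abe_lorentz",
        "abe_lorentz": "abe_lorentz",
        "abeO": "abe_onsager",
        "abe_onsager": "abe_onsager",
        "schuyer": "schuyer",
    }
    head, _, arg = spec.partition(":")
    if head in aliases:
        return ReferenceMode(aliases[head])
    if head == "shibuya":
        return ReferenceMode("shibuya", s_k=float(arg) if arg else 1.0 / 3.0)
    if head in ("C", "c", "fixed_c"):
        if not arg:
            raise ValueError("fixed-C reference needs a value, e.g. 'C:1.3'")
        return ReferenceMode("fixed_c", c_value=float(arg))
    raise ValueError(f"unknown reference spec {spec!r}")
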