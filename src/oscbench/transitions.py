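"""Computed electronic transitions and per-gauge oscillator strengths.

An excited-state calculation yields, per state, a vertical excitation
energy and transition moments in the dipole-length gauge (position
operator) and dipole-velocity gauge (momentum operator).  The three
oscillator-strength formulations, in atomic units with excitation energy
dE in hartree, are

    f_lg = (2/3) dE |<n|r|0>|^2
    f_vg = (2/3) |<n|p|0>|^2 / dE
    f_mx = (2/3) <n|r|0> . <n|p|0>

For exact wave functions <n|p|0> = dE <n|r|0> and all three coincide; for
approximate wave functions they differ, and the spread is a diagnostic of
wave-function quality (it is large for CIS/TDA, small for RPA-type linear
response).  The mixed form uses the plain real dot product, which makes it
independent of the excitation energy and reduces to the single-gauge
values whenever the exact-limit relation holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import ev_to_hartree

__all__ = [
    "ComputedTransition",
    "TransitionSet",
    "GAUGES",
    "f_length_from_moment",
    "f_velocity_from_moment",
    "f_mixed_from_moments",
    "read_transition_table",
]

GAUGES = ("length", "velocity", "mixed")


def f_length_from_moment(delta_e: float, mu_length: Sequence[float]) -> float:
    """Length-gauge oscillator strength from dE (hartree) and <n|r|0> (a.u.)."""
    if delta_e <= 0:
        raise ValueError("excitation energy must be positive")
    mu = np.asarray(mu_length, dtype=float)
    return (2.0 / 3.0) * delta_e * float(mu @ mu)


def f_velocity_from_moment(delta_e: float, mu_velocity: Sequence[float]) -> float:
    """Velocity-gauge oscillator strength from dE (hartree) and <n|p|0> (a.u.)."""
    if delta_e <= 0:
        raise ValueError("excitation energy must be positive")
    p = np.asarray(mu_velocity, dtype=float)
    return (2.0 / 3.0) * float(p @ p) / delta_e


def f_mixed_from_moments(
    mu_length: Sequence[float], mu_velocity: Sequence[float]
) -> float:
    """Mixed-gauge oscillator strength (2/3) <n|r|0>.<n|p|0>; may be negative."""
    mu = np.asarray(mu_length, dtype=float)
    p = np.asarray(mu_velocity, dtype=float)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(p))):
        raise ValueError("transition moments must be finite")
    return (2.0 / 3.0) * float(mu @ p)


@dataclass(frozen=True)
class ComputedTransition:
    """One excited state: energy (eV) and per-gauge strengths."""

    state_index: int
    energy: float  # eV
    f_length: float
    f_velocity: float
    f_mixed: float
    mu_length: tuple[float, float, float] | None = None
    mu_velocity: tuple[float, float, float] | None = None
    tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state_index < 1:
            raise ValueError("state index must be >= 1")
        if self.energy <= 0:
            raise ValueError("excitation energy must be positive")
        if self.f_length < 0 or self.f_velocity < 0:
            raise ValueError("single-gauge strengths must be non-negative")

    def strength(self, gauge: str) -> float:
        if gauge not in GAUGES:
            raise ValueError(f"unknown gauge {gauge!r}")
        return getattr(self, f"f_{gauge}")

    @classmethod
    def from_moments(
        cls,
        state_index: int,
        energy_ev: float,
        mu_length: Sequence[float],
        mu_velocity: Sequence[float],
        tags: Mapping[str, str] | None = None,
    ) -> "ComputedTransition":
        """Build a transition from its moment vectors, deriving all gauges."""
        de = ev_to_hartree(energy_ev)
        return cls(
            state_index,
            energy_ev,
            f_length_from_moment(de, mu_length),
            f_velocity_from_moment(de, mu_velocity),
            f_mixed_from_moments(mu_length, mu_velocity),
            tuple(float(x) for x in mu_length),  # type: ignore[arg-type]
            tuple(float(x) for x in mu_velocity),  # type: ignore[arg-type]
            tags or {},
        )


@dataclass(frozen=True)
class TransitionSet:
    """Ordered excited states of one molecule from one method."""

    molecule_id: str
    method_id: str
    transitions: tuple[ComputedTransition, ...]

    def __post_init__(self) -> None:
        ts = tuple(sorted(self.transitions, key=lambda t: t.energy))
        object.__setattr__(self, "transitions", ts)
        indices = [t.state_index for t in ts]
        if len(set(indices)) != len(indices):
            raise ValueError("state indices must be unique")

    def __len__(self) -> int:
        return len(self.transitions)

    def __iter__(self):
        return iter(self.transitions)

    def energies(self) -> np.ndarray:
        return np.array([t.energy for t in self.transitions])

    def strengths(self, gauge: str) -> np.ndarray:
        return np.array([t.strength(gauge) for t in self.transitions])


_F_COLS = ("f_length", "f_velocity", "f_mixed")
_MU_COLS = ("mux_len", "muy_len", "muz_len", "mux_vel", "muy_vel", "muz_vel")


def read_transition_table(
    path: str | Path,
    molecule_id: str = "",
    method_id: str = "",
    tags: Mapping[str, str] | None = None,
) -> TransitionSet:
    """Read a delimited transition table into a validated TransitionSet.

    Required columns: ``state, energy_eV`` plus either the three strength
    columns ``f_length, f_velocity, f_mixed`` or the six moment columns
    ``mux_len..muz_vel``; when only moments are present, the per-gauge
    strengths are reconstructed from the moment formulas.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip() for c in df.columns]
    for col in ("state", "energy_eV"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    have_f = all(c in df.columns for c in _F_COLS)
    have_mu = all(c in df.columns for c in _MU_COLS)
    if not have_f and not have_mu:
        raise ValueError(
            f"{path}: need either columns {_F_COLS} or moment columns {_MU_COLS}"
        )
    out: list[ComputedTransition] = []
    for row_no, row in df.iterrows():
        state = int(row["state"])
        energy = float(row["energy_eV"])
        if energy <= 0:
            raise ValueError(f"{path} row {row_no}: non-positive energy {energy}")
        mu_l = tuple(float(row[c]) for c in _MU_COLS[:3]) if have_mu else None
        mu_v = tuple(float(row[c]) for c in _MU_COLS[3:]) if have_mu else None
        if have_f:
            fl, fv, fm = (float(row[c]) for c in _F_COLS)
            if fl < 0 or fv < 0:
                raise ValueError(
                    f"{path} row {row_no}: negative single-gauge strength"
                )
        else:
            de = ev_to_hartree(energy)
            fl = f_length_from_moment(de, mu_l)  # type: ignore[arg-type]
            fv = f_velocity_from_moment(de, mu_v)  # type: ignore[arg-type]
            fm = f_mixed_from_moments(mu_l, mu_v)  # type: ignore[arg-type]
        try:
            out.append(
                ComputedTransition(state, energy, fl, fv, fm, mu_l, mu_v, tags or {})
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {row_no}: {exc}") from exc
    return TransitionSet(molecule_id or path.stem, method_id, tuple(out))
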