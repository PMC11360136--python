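"""Agreement statistics and the iterative scaling-constant optimization.

Given per-band pairs (reference, computed) of oscillator strengths and of
mean transition energies, this module computes the benchmark statistic
suite — mean absolute error, relative MAE against the mean reference,
ordinary least-squares slope/intercept/R^2 of computed on reference, and
three energy-error metrics — and the fixed-point search for the global
scaling constant C relating computed to experimental strengths:

    repeat: targets_k <- C_i * r_k ; reassign bands (improved fit);
            C_{i+1} <- sum(f_comp r) / sum(r^2)          (through-origin OLS)
    until |C_{i+1} - C_i| < tol.

Because the re-assignment step changes which transitions contribute to
each band, the map is only piecewise smooth and can have several fixed
points; the search is therefore run from several starting values
(default 0.7, 1.0, 1.4) and the converged value with the highest R^2
between C * r and f_comp is selected.

Empty-band convention: a band with no assigned transition contributes a
computed strength and computed energy of zero.  A strongly negative mean
energy error therefore signals transitions falling outside the band
limits rather than a systematic red shift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assignment import (
    Assignment,
    AssignmentProblem,
    assign_exact,
    band_e_comp,
    band_f_comp,
    improved_fit,
)
from .constants import wavenumber_to_ev

__all__ = [
    "BenchmarkReport",
    "ScalingResult",
    "mae",
    "relative_mae",
    "linear_fit",
    "energy_metrics",
    "score_problems",
    "benchmark_report",
    "report_from_records",
    "grouped_benchmark",
    "iterate_scaling",
]

GROUP_KEYS = ("symmetry_class", "character", "solvent", "solvent_class", "spectrometer")


def mae(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Mean absolute error between two equal-length sequences."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("sequences must be non-empty and of equal length")
    return float(np.mean(np.abs(a - b)))


def relative_mae(mae_value: float, reference_values: Sequence[float]) -> float:
    """MAE as a percentage of the mean reference strength."""
    ref_mean = float(np.mean(np.asarray(reference_values, dtype=float)))
    if ref_mean <= 0:
        raise ValueError("mean reference must be positive")
    return 100.0 * mae_value / ref_mean


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """OLS of y on x: (slope, intercept, R^2) with R^2 = squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.shape != y.shape:
        raise ValueError("need at least two (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; fit is degenerate")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def energy_metrics(
    e_comp: Sequence[float], e_exp: Sequence[float]
) -> tuple[float, float, float]:
    """(mean |dE|, mean dE, mean E_comp/E_exp); empty bands enter with 0."""
    ec = np.asarray(e_comp, dtype=float)
    ee = np.asarray(e_exp, dtype=float)
    if ec.shape != ee.shape or ec.size == 0:
        raise ValueError("sequences must be non-empty and of equal length")
    if np.any(ee <= 0):
        raise ValueError("experimental energies must be positive")
    return (
        float(np.mean(np.abs(ec - ee))),
        float(np.mean(ec - ee)),
        float(np.mean(ec / ee)),
    )


@dataclass(frozen=True)
class BenchmarkReport:
    """Statistic bundle for one method / gauge / reference / framework."""

    method_id: str
    gauge: str
    reference: str
    framework: str
    n_bands: int
    mae: float
    relative_mae: float  # percent
    slope: float
    intercept: float
    r_squared: float
    mean_abs_de: float  # eV
    mean_de: float  # eV
    mean_e_ratio: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _solve(problem: AssignmentProblem, framework: str) -> Assignment:
    if framework == "exact":
        return assign_exact(problem)
    if framework == "improved":
        return improved_fit(problem)
    raise ValueError(f"unknown framework {framework!r}")


def score_problems(
    problems: Sequence[AssignmentProblem],
    framework: str = "exact",
    labels: Mapping[str, Sequence] | None = None,
) -> pd.DataFrame:
    """Solve every molecule's assignment and tabulate per-band records.

    Returns one row per band with columns ``molecule, band_index, target,
    f_comp, e_exp_eV, e_comp_eV, n_assigned`` plus any extra per-band label
    columns supplied in ``labels``.
    """
    rows = []
    for problem in problems:
        assignment = _solve(problem, framework)
        fc = band_f_comp(problem, assignment)
        ec = band_e_comp(problem, assignment)
        for k, band in enumerate(problem.bands):
            rows.append(
                {
                    "molecule": problem.transitions.molecule_id,
                    "band_index": band.band_index,
                    "target": problem.targets[k],
                    "f_comp": float(fc[k]),
                    "e_exp_eV": wavenumber_to_ev(band.e_exp),
                    "e_comp_eV": float(ec[k]),
                    "n_assigned": len(assignment.assigned[k]),
                }
            )
    df = pd.DataFrame(rows)
    if labels:
        for col, values in labels.items():
            df[col] = list(values)
    return df


def report_from_records(
    records: pd.DataFrame,
    method_id: str = "",
    gauge: str = "",
    reference: str = "",
    framework: str = "",
) -> BenchmarkReport:
    """Compute the full statistic bundle from a scored band table."""
    t = records["target"].to_numpy(float)
    fc = records["f_comp"].to_numpy(float)
    m = mae(fc, t)
    slope, intercept, r2 = linear_fit(t, fc)
    de_abs, de, ratio = energy_metrics(
        records["e_comp_eV"].to_numpy(float), records["e_exp_eV"].to_numpy(float)
    )
    return BenchmarkReport(
        method_id,
        gauge,
        reference,
        framework,
        len(records),
        m,
        relative_mae(m, t),
        slope,
        intercept,
        r2,
        de_abs,
        de,
        ratio,
    )


def benchmark_report(
    problems: Sequence[AssignmentProblem],
    framework: str = "exact",
    method_id: str = "",
    reference: str = "",
) -> BenchmarkReport:
    """Convenience: score a molecule set and report in one call."""
    gauge = problems[0].gauge if problems else ""
    records = score_problems(problems, framework)
    return report_from_records(records, method_id, gauge, reference, framework)


def grouped_benchmark(
    records: pd.DataFrame,
    group_key: str,
    min_group_size: int = 5,
    **report_kwargs,
) -> dict[str, tuple[BenchmarkReport, bool]]:
    """Per-group reports keyed by label; the bool flags undersized groups."""
    if group_key not in records.columns:
        raise ValueError(f"unknown group key {group_key!r}")
    out = {}
    for label, sub in records.groupby(group_key, sort=True):
        out[str(label)] = (
            report_from_records(sub, **report_kwargs),
            len(sub) < min_group_size,
        )
    return out


@dataclass(frozen=True)
class ScalingResult:
    """Outcome of the multi-start iterative scaling search."""

    trajectories: dict[float, list[float]]  # C0 -> iterates (incl. C0)
    converged: dict[float, bool]
    r_squared: dict[float, float]
    selected_c: float
    selected_c0: float
    tol: float
    max_iter: int

    @property
    def any_converged(self) -> bool:
        return any(self.converged.values())


def _pooled_fit(problems: Sequence[AssignmentProblem], c: float) -> tuple[np.ndarray, np.ndarray]:
    """Improved-fit f_comp and base references pooled over molecules at scale c."""
    refs = []
    comps = []
    for problem in problems:
        scaled = replace(problem, targets=tuple(c * t for t in problem.targets))
        assignment = improved_fit(scaled)
        fc = band_f_comp(problem, assignment)
        refs.extend(problem.targets)
        comps.extend(fc.tolist())
    return np.asarray(refs), np.asarray(comps)


def iterate_scaling(
    problems: Sequence[AssignmentProblem],
    c0_list: Sequence[float] = (0.7, 1.0, 1.4),
    tol: float = 1e-4,
    max_iter: int = 100,
) -> ScalingResult:
    """Multi-start fixed-point search for the global scaling constant C.

    ``problems`` carry the *base* (unscaled) reference values as targets;
    each iteration re-runs the improved-fit assignment against C * target
    and updates C by the through-origin least-squares slope of f_comp on
    the base references.  Non-convergence from every start is reported in
    the result, never raised.
    """
    n_bands = sum(len(p.bands) for p in problems)
    if n_bands < 2:
        raise ValueError("need at least two bands pooled across molecules")
    trajectories: dict[float, list[float]] = {}
    converged: dict[float, bool] = {}
    r2s: dict[float, float] = {}
    for c0 in c0_list:
        c = float(c0)
        path = [c]
        ok = False
        for _ in range(max_iter):
            refs, comps = _pooled_fit(problems, c)
            denom = float(refs @ refs)
            if denom == 0:
                break
            c_next = float(comps @ refs) / denom
            path.append(c_next)
            if abs(c_next - c) < tol:
                c = c_next
                ok = True
                break
            c = c_next
        trajectories[float(c0)] = path
        converged[float(c0)] = ok
        # R^2 between C*r and f_comp after a final reassignment at C
        refs, comps = _pooled_fit(problems, c)
        if np.ptp(refs) > 0 and np.ptp(comps) > 0:
            r2s[float(c0)] = float(sps.pearsonr(c * refs, comps)[0] ** 2)
        else:
            r2s[float(c0)] = float("nan")

    # prefer converged starts; among those, highest R^2; ties -> first start
    def key(c0):
        r2 = r2s[c0]
        return (converged[c0], -1.0 if np.isnan(r2) else r2)

    best_c0 = max(trajectories, key=key)
    return ScalingResult(
        trajectories,
        converged,
        r2s,
        trajectories[best_c0][-1],
        best_c0,
        tol,
        max_iter,
    )
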