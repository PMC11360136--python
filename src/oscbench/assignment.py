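"""Assigning computed transitions to experimental bands.

Two frameworks are provided.

**Exact band limits** assigns a computed transition to a band when its
energy lies strictly inside the band's experimental window; transitions on
or outside every window stay unassigned.  Large errors in the computed
excitation energies therefore directly corrupt the strength comparison:
a band can end up empty even though the method placed the right intensity
slightly outside the window.

**Improved fit** treats the band windows as adjustable: it chooses, per
band, an energy-contiguous block of transitions — blocks pairwise
disjoint and ordered consistently with the bands, so no transition is
ever double-counted — minimizing the total absolute deviation

    sum_k | f_comp,k - target_k |

where ``target_k`` is the (solvent-corrected) experimental strength.
This yields a best-case assignment: an upper bound on how well the
method's strengths can agree with experiment under any reasonable
re-drawing of the band limits.  The optimum is found by dynamic
programming over transitions sorted by energy and is verified against an
exhaustive enumeration exposed via ``method='exhaustive'``.

Ties in the objective are resolved in favour of the assignment closest to
the exact-band-limits one (minimal number of transitions whose band
membership differs), then by fewer assigned transitions; residual ties
are broken by the fixed, deterministic scan order of the optimizer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import ev_to_wavenumber
from .spectra import Band
from .transitions import GAUGES, TransitionSet

__all__ = [
    "AssignmentProblem",
    "Assignment",
    "assign_exact",
    "improved_fit",
    "band_f_comp",
    "band_e_comp",
    "objective",
]


@dataclass(frozen=True)
class AssignmentProblem:
    """Bands, transitions and per-band reference targets for one molecule."""

    bands: tuple[Band, ...]
    transitions: TransitionSet
    targets: tuple[float, ...]
    gauge: str = "length"

    def __post_init__(self) -> None:
        bands = tuple(sorted(self.bands, key=lambda b: b.lo))
        object.__setattr__(self, "bands", bands)
        object.__setattr__(self, "targets", tuple(float(t) for t in self.targets))
        if len(self.targets) != len(bands):
            raise ValueError("need exactly one target per band")
        for a, b in itertools.pairwise(bands):
            if a.hi > b.lo:
                raise ValueError("bands must not overlap")
        if self.gauge not in GAUGES:
            raise ValueError(f"unknown gauge {self.gauge!r}")

    @property
    def energies_cm(self) -> np.ndarray:
        """Transition energies on the band axis (cm^-1), sorted ascending."""
        return self.transitions.energies() * ev_to_wavenumber(1.0)

    def strengths(self) -> np.ndarray:
        return self.transitions.strengths(self.gauge)


@dataclass(frozen=True)
class Assignment:
    """Per-band transition blocks produced by either framework."""

    framework: str  # "exact" or "improved"
    assigned: tuple[tuple[int, ...], ...]  # indices into energy-sorted transitions
    windows: tuple[tuple[float, float], ...]  # adjusted [lo', hi'], cm^-1
    unassigned: tuple[int, ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for block in self.assigned:
            if seen & set(block):
                raise ValueError("a transition is assigned to two bands")
            seen |= set(block)
        if seen & set(self.unassigned):
            raise ValueError("a transition is both assigned and unassigned")


def assign_exact(problem: AssignmentProblem) -> Assignment:
    """Strict containment: transition in band k iff lo_k < E < hi_k."""
    e_cm = problem.energies_cm
    blocks: list[tuple[int, ...]] = []
    taken: set[int] = set()
    for band in problem.bands:
        inside = tuple(
            i for i, e in enumerate(e_cm) if band.lo < e < band.hi and i not in taken
        )
        taken |= set(inside)
        blocks.append(inside)
    unassigned = tuple(i for i in range(len(e_cm)) if i not in taken)
    windows = tuple((b.lo, b.hi) for b in problem.bands)
    return Assignment("exact", tuple(blocks), windows, unassigned)


def band_f_comp(
    problem: AssignmentProblem, assignment: Assignment, gauge: str | None = None
) -> np.ndarray:
    """Per-band computed strength: sum of assigned strengths; 0 if empty."""
    f = problem.transitions.strengths(gauge or problem.gauge)
    return np.array([sum(f[i] for i in block) for block in assignment.assigned])


def band_e_comp(
    problem: AssignmentProblem, assignment: Assignment, gauge: str | None = None
) -> np.ndarray:
    """Per-band strength-weighted mean computed energy (eV); 0 if empty.

    A band that received transitions whose strengths sum to zero has no
    defined weighted mean and raises.
    """
    f = problem.transitions.strengths(gauge or problem.gauge)
    e = problem.transitions.energies()
    out = []
    for block in assignment.assigned:
        if not block:
            out.append(0.0)
            continue
        w = sum(f[i] for i in block)
        if w == 0:
            raise ValueError("assigned band has zero total strength; mean undefined")
        out.append(sum(f[i] * e[i] for i in block) / w)
    return np.array(out)


# ---------------------------------------------------------------------------
# Improved fit


def _hull_windows(
    problem: AssignmentProblem, blocks: Sequence[tuple[int, ...]]
) -> tuple[tuple[float, float], ...]:
    e_cm = problem.energies_cm
    windows = []
    for band, block in zip(problem.bands, blocks):
        if block:
            es = [e_cm[i] for i in block]
            windows.append((float(min(es)), float(max(es))))
        else:
            windows.append((band.lo, band.hi))
    return tuple(windows)


def _cost_components(problem: AssignmentProblem):
    """Prefix sums and tie-break bookkeeping shared by both optimizers.

    ``mism_prefix[k][i]`` counts transitions with index < i whose
    exact-band-limits membership differs from band k; ``gap_mismatch[i]``
    is 1 when leaving transition i unassigned contradicts the exact
    assignment.
    """
    f = problem.strengths()
    prefix = np.concatenate([[0.0], np.cumsum(f)])
    exact = assign_exact(problem)
    exact_band: dict[int, int] = {}
    for k, block in enumerate(exact.assigned):
        for i in block:
            exact_band[i] = k
    t_count = len(f)
    k_count = len(problem.bands)
    gap_mismatch = np.array([1 if i in exact_band else 0 for i in range(t_count)])
    mism_prefix = np.zeros((k_count, t_count + 1), dtype=int)
    for k in range(k_count):
        for i in range(t_count):
            mism_prefix[k][i + 1] = mism_prefix[k][i] + (exact_band.get(i) != k)
    return f, prefix, mism_prefix, gap_mismatch


def _segment_cost(prefix, targets, mism_prefix, k, a, b):
    dev = abs((prefix[b] - prefix[a]) - targets[k])
    return (dev, int(mism_prefix[k][b] - mism_prefix[k][a]), b - a)


def _blocks_to_assignment(problem, blocks):
    taken = set().union(*(set(b) for b in blocks)) if blocks else set()
    unassigned = tuple(i for i in range(len(problem.transitions)) if i not in taken)
    return Assignment("improved", tuple(blocks), _hull_windows(problem, blocks), unassigned)


def _improved_fit_dp(problem: AssignmentProblem) -> Assignment:
    f, prefix, mism_prefix, gap_mism = _cost_components(problem)
    targets = problem.targets
    T = len(f)
    K = len(targets)
    ZERO = (0.0, 0, 0)

    def add(u, v):
        return (u[0] + v[0], u[1] + v[1], u[2] + v[2])

    # D[k][j]: best cost with bands 0..k-1 placed and transitions [0, j)
    # fully accounted (in blocks or as gaps).  parent[k][j] records the
    # optimal move for backtracking.
    D = [[None] * (T + 1) for _ in range(K + 1)]
    parent: list[list[tuple]] = [[None] * (T + 1) for _ in range(K + 1)]
    D[0][0] = ZERO
    for j in range(1, T + 1):
        D[0][j] = add(D[0][j - 1], (0.0, int(gap_mism[j - 1]), 0))
        parent[0][j] = ("gap",)
    for k in range(1, K + 1):
        for j in range(0, T + 1):
            best = None
            move = None
            # band k-1's block ends exactly at j (possibly empty, a == j)
            for a in range(0, j + 1):
                if D[k - 1][a] is None:
                    continue
                cand = add(D[k - 1][a], _segment_cost(prefix, targets, mism_prefix, k - 1, a, j))
                if best is None or cand < best:
                    best, move = cand, ("block", a)
            # or transition j-1 stays a gap after band k-1 closed earlier
            if j > 0 and D[k][j - 1] is not None:
                cand = add(D[k][j - 1], (0.0, int(gap_mism[j - 1]), 0))
                if best is None or cand < best:
                    best, move = cand, ("gap",)
            D[k][j] = best
            parent[k][j] = move

    # backtrack
    blocks: list[tuple[int, ...]] = []
    k, j = K, T
    while k > 0:
        move = parent[k][j]
        if move[0] == "gap":
            j -= 1
        else:
            a = move[1]
            blocks.append(tuple(range(a, j)))
            k -= 1
            j = a
    blocks.reverse()
    return _blocks_to_assignment(problem, blocks)


def _improved_fit_exhaustive(problem: AssignmentProblem) -> Assignment:
    """Enumerate every admissible ordered block partition (small instances)."""
    f, prefix, mism_prefix, gap_mism = _cost_components(problem)
    targets = problem.targets
    T = len(f)
    K = len(targets)
    total_gap = int(gap_mism.sum())
    gap_prefix = np.concatenate([[0], np.cumsum(gap_mism)]) if T else np.zeros(1, int)
    best = None
    best_blocks = None

    # choose 0 <= a_0 <= b_0 <= a_1 <= ... <= b_{K-1} <= T
    def recurse(k, start, acc, swallowed, blocks):
        nonlocal best, best_blocks
        if k == K:
            # transitions outside every block are gaps
            cost = (acc[0], acc[1] + total_gap - swallowed, acc[2])
            if best is None or cost < best:
                best, best_blocks = cost, list(blocks)
            return
        for a in range(start, T + 1):
            for b in range(a, T + 1):
                dev, mism, size = _segment_cost(prefix, targets, mism_prefix, k, a, b)
                recurse(
                    k + 1,
                    b,
                    (acc[0] + dev, acc[1] + mism, acc[2] + size),
                    swallowed + int(gap_prefix[b] - gap_prefix[a]),
                    blocks + [tuple(range(a, b))],
                )

    recurse(0, 0, (0.0, 0, 0), 0, [])
    assert best_blocks is not None
    return _blocks_to_assignment(problem, best_blocks)


def improved_fit(problem: AssignmentProblem, method: str = "dp") -> Assignment:
    """Optimal band re-assignment minimizing total |f_comp - target|.

    ``method='dp'`` (default) uses the O(K T^2) dynamic program;
    ``method='exhaustive'`` enumerates all admissible block partitions and
    exists to cross-check the dynamic program on small instances.
    """
    if method == "dp":
        return _improved_fit_dp(problem)
    if method == "exhaustive":
        return _improved_fit_exhaustive(problem)
    raise ValueError(f"unknown method {method!r}")


def objective(problem: AssignmentProblem, assignment: Assignment) -> float:
    """Total absolute deviation sum_k |f_comp,k - target_k|."""
    fc = band_f_comp(problem, assignment)
    return float(np.abs(fc - np.asarray(problem.targets)).sum())
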