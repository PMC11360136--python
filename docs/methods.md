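# Methods

## Band reduction

A spectrum is a strictly increasing wavenumber grid with non-negative
molar attenuation values. Band limits are strict local minima of the
curve, optionally after a moving-average smoothing (window in cm⁻¹,
default off), subject to a prominence threshold expressed as a fraction
of the spectrum maximum (default 1%); the two grid endpoints are always
limits, and reported limits are grid points of the *unsmoothed* data.
Integration is trapezoidal on the native grid with linear interpolation
at off-grid window edges — exact for piecewise-linear digitized data and
exactly additive under window splits. The oscillator-strength conversion
constant K_f = 4ε₀m_ec²ln10/(N_Ae²) (≈4.319×10⁻⁹ mol L⁻¹ cm² for ε in
M⁻¹cm⁻¹ and ν̃ in cm⁻¹) and the energy-axis conversion
1 eV = 8065.5439 cm⁻¹ are computed from `scipy.constants` CODATA values
at import, never hard-coded.

Confidence labels (VH/H/M/L/VL) are carried as metadata; the default
benchmark filter keeps VH∪H∪M. The JCAMP-DX reader supports plain AFFN
`(X++(Y..Y))` and `XYPOINTS` tables (no DIFDUP/SQZ compression), which
covers digitized UV–vis deposits; the native format is two-column
delimited text.

## Gauges

Energies are stored in eV and converted to hartree only inside the
moment formulas. The mixed-gauge strength is the plain real dot product
(2/3)⟨r⟩·⟨p⟩: program packages differ in the precise symmetrized
combination they print, so the implementation fixes the simplest form
that is energy-independent and reduces to both single gauges whenever
⟨p⟩ = ΔE⟨r⟩; that consistency identity, not any one program's
convention, is what the tests assert. Mixed-gauge values may be
negative. Ingestion is from delimited tables (strength columns, or
moment columns from which all three gauges are reconstructed).

## Solvent references

The nine stock solvents (water, ethanol, carbon tetrachloride, dioxane,
acetonitrile, methanol, cyclohexane, hexane, heptane) ship as two-term
Cauchy models n(λ) = A + B/λ², with A and B derived from handbook n_D
values and visible dispersions (n_F − n_C across the hydrogen F/C
lines). Each model reproduces its n_D at 589.29 nm within 0.003 by
construction (gated in the tests). A two-term Cauchy extrapolated into
the deep UV underestimates the true dispersion of strongly absorbing
solvents; users needing accurate n below ~250 nm should supply Sellmeier
coefficients through the YAML registry. Unknown solvents always require
explicit registration — there is no silent default. The default n source
is the dispersion value at the transition frequency; n_D is a switch
(`--n-source nD`), with an explicit opt-in fallback to n_D outside a
model's validity range.

All correction factors equal 1 at n = 1, and the Shibuya family spans
the apparent-to-vacuum ratio from 1/n (s_k = 0) to n³ (s_k = 1) with the
sphere (s_k = 1/3) recovering Chako's factor.

## Assignment

Admissible improved-fit assignments give each band an energy-contiguous
(possibly empty) block of transitions, blocks pairwise disjoint and
ordered like the bands; transitions between and outside blocks stay
unassigned. Blocks may extend arbitrarily far in energy — this is what
lets the optimizer capture transitions computed entirely outside the
experimental limits — but cannot reorder bands, and a wrong energy
ordering of states is deliberately not repaired. The objective is the
per-molecule sum of absolute deviations |f_comp,k − target_k| (bands of
one molecule compete for the same transitions, so per-band independent
minimization would be ill-posed under the no-double-count rule).

The optimum is found by dynamic programming over energy-sorted
transitions, O(bands × transitions²), with lexicographic cost tuples
(objective, mismatch count against the exact-band-limits assignment,
number of assigned transitions) implementing the tie policy: stay
closest to the physically anchored assignment, then assign fewer
transitions; residual ties fall to the deterministic scan order (earlier
block start wins). An exhaustive enumerator over all cut-point choices
is exposed (`method="exhaustive"`) and the test suite checks both
against an independently written brute-force oracle on randomized small
instances. Adjusted windows are reported as the tight energy hull of
each block (the initial window for empty blocks). Empty bands contribute
zero computed strength and zero computed energy; a band assigned
transitions whose strengths sum to zero has no defined mean energy and
raises.

## Scaling iteration

The update rule is the through-origin least-squares slope
C ← Σf_comp·r / Σr² over all pooled bands (the model C·r has no
intercept by construction), with the improved-fit assignment re-run
against C·r each iteration; convergence is |ΔC| < 1e-4 with a 100
iteration cap. Because re-assignment makes the map piecewise smooth, the
iteration can have several fixed points: a start well below the true
constant lets bands shed or swap sticks to chase the small target, and C
can spiral toward a smaller fixed point or zero. The search therefore
runs from 0.7, 1.0 and 1.4 and selects the converged value with the
highest Pearson R² between C·r and f_comp (computed after a final
re-assignment, since R² is invariant under scaling but not under
assignment changes). Non-convergence of every start is flagged in the
result, not raised.

## Synthetic generator

Each molecule gets 1–3 Gaussian band envelopes (FWHM 1500–2500 cm⁻¹,
centers in 20 000–50 000 cm⁻¹ laid out with at least 3.5 FWHM between
centers by distributing the slack left after the minimum gaps), each fed
by 1–3 stick transitions with log-normal strengths (ln f ~ N(−1.6,
0.6²)); the apparent band strength is the stick sum divided by the true
scaling constant C* (default 1.3, the hybrid-functional regime), and the
envelope amplitude encodes it exactly through K_f, so extraction is
invertible. The 3.5-FWHM separation keeps inter-band tail leakage below
the 10⁻³ relative extraction tolerance on a 1 cm⁻¹ grid even for
strength ratios of ~20 between neighbors.

Computed energies are stick energies times (1 + shift) plus optional
Gaussian jitter; a 10% shift at these band positions moves most sticks
across the inter-band troughs, which is the regime where strict
containment visibly fails while the improved fit still recovers the
true membership. Intensity noise is a per-band multiplicative amplitude
factor (1 + cv·z): per-gridpoint noise would average away under
integration, whereas a per-band factor makes the extracted strengths
noisy at the stated coefficient of variation. One `numpy` Generator per
molecule is seeded from (master seed, molecule index), so a molecule's
data are invariant under set resizing and byte-identical across runs.

The generator emulates band envelopes, a global scaling, energy shifts
and intensity noise; it does not emulate vibronic structure, asymmetric
or Fano lineshapes, baseline drift, band overlap stronger than the
separation constraint, or gauge disagreement beyond an optional random
spread. Passing recovery tests therefore demonstrates correctness of the
extraction/assignment/scaling machinery under the stated noise model,
not robustness to strongly overlapping real spectra.

Two recovery regimes deserve note. With one band and one stick per
molecule the scaling iteration has a unique fixed point over the whole
start bracket (keeping the stick always beats dropping it for any C₀
above C*/2), so C* is recovered to 1e-6 from every start — this is the
construction used to validate the iteration itself. With several sticks
per band, low starts can genuinely converge elsewhere; that
start-sensitivity is intrinsic to the method, and the R²-based selection
is what recovers C* there.

## Problem sizes

The validation suite runs 50-molecule sets (≈100 bands) for the
stochastic recovery checks, 1 cm⁻¹ grids where extraction fidelity is
asserted and 5 cm⁻¹ elsewhere, 200 randomized instances (≤12
transitions, ≤3 bands) for the optimality cross-check, and 1000 draws
for the gauge-consistency identity; the whole suite and the acceptance
script each complete in seconds.
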