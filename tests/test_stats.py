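"""Agreement metrics and the iterative scaling-constant search."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from conftest import make_problem
from oscbench.stats import (
    energy_metrics,
    grouped_benchmark,
    iterate_scaling,
    linear_fit,
    mae,
    relative_mae,
    report_from_records,
    score_problems,
)
from oscbench.synthetic import SyntheticConfig, generate_benchmark_set, problems_from_truth


def test_mae_examples_and_symmetry():
    assert mae([0.1, 0.3], [0.1, 0.3]) == 0.0
    assert mae([0.1, 0.3], [0.2, 0.5]) == pytest.approx(0.15)
    assert mae([0.1, 0.3], [0.2, 0.5]) == mae([0.2, 0.5], [0.1, 0.3])
    with pytest.raises(ValueError):
        mae([0.1], [0.1, 0.2])


def test_relative_mae():
    assert relative_mae(0.0, [0.5, 0.5]) == 0.0
    assert relative_mae(0.05, [0.5, 0.5]) == pytest.approx(10.0)
    # scale invariance
    assert relative_mae(0.05 * 3.7, [0.5 * 3.7, 0.5 * 3.7]) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        relative_mae(0.1, [0.0, 0.0])


def test_linear_fit_exact_lines():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    assert linear_fit(x, x) == pytest.approx((1.0, 0.0, 1.0))
    assert linear_fit(x, 2 * x + 1) == pytest.approx((2.0, 1.0, 1.0))


def test_linear_fit_three_point_hand_ols():
    slope, intercept, r2 = linear_fit([1, 2, 3], [1, 2, 2])
    assert slope == pytest.approx(0.5)
    assert intercept == pytest.approx(2.0 / 3.0)
    assert r2 == pytest.approx(0.75)


def test_linear_fit_degenerate():
    with pytest.raises(ValueError):
        linear_fit([1.0, 1.0, 1.0], [1, 2, 3])
    with pytest.raises(ValueError):
        linear_fit([1.0], [1.0])


def test_energy_metrics_identity_and_zero_convention():
    assert energy_metrics([4.0, 5.0], [4.0, 5.0]) == pytest.approx((0.0, 0.0, 1.0))
    # an empty band enters as e_comp = 0: mean error can be negative
    # without any systematic red shift
    de_abs, de, ratio = energy_metrics([4.4, 0.0], [4.0, 5.0])
    assert de_abs == pytest.approx(2.7)
    assert de == pytest.approx(-2.3)
    assert ratio == pytest.approx(0.55)
    with pytest.raises(ValueError):
        energy_metrics([4.0], [0.0])


def test_report_permutation_invariance():
    df = pd.DataFrame(
        {
            "target": [0.1, 0.2, 0.3, 0.4],
            "f_comp": [0.12, 0.25, 0.28, 0.5],
            "e_exp_eV": [4.0, 4.5, 5.0, 5.5],
            "e_comp_eV": [4.1, 4.4, 5.2, 5.6],
        }
    )
    r1 = report_from_records(df)
    r2 = report_from_records(df.iloc[[2, 0, 3, 1]].reset_index(drop=True))
    assert r1.mae == pytest.approx(r2.mae)
    assert r1.relative_mae == pytest.approx(r2.relative_mae)
    assert r1.slope == pytest.approx(r2.slope)
    assert 0.0 <= r1.r_squared <= 1.0
    assert np.isfinite(list(r1.to_dict().values())[4:]).all()


def test_grouped_benchmark_partition_consistency():
    df = pd.DataFrame(
        {
            "target": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
            "f_comp": [0.1, 0.25, 0.28, 0.5, 0.52, 0.7],
            "e_exp_eV": [4.0, 4.5, 5.0, 5.5, 4.2, 4.8],
            "e_comp_eV": [4.1, 4.4, 5.2, 5.6, 4.3, 4.7],
            "solvent": ["w", "w", "w", "e", "e", "e"],
        }
    )
    whole = report_from_records(df)
    groups = grouped_benchmark(df, "solvent", min_group_size=2)
    assert set(groups) == {"w", "e"}
    for label, (rep, flagged) in groups.items():
        sub = df[df["solvent"] == label].reset_index(drop=True)
        assert rep.mae == pytest.approx(report_from_records(sub).mae)
        assert not flagged
    # single group equals ungrouped
    df2 = df.assign(solvent="x")
    only = grouped_benchmark(df2, "solvent")["x"][0]
    assert only.mae == pytest.approx(whole.mae)
    assert only.slope == pytest.approx(whole.slope)
    with pytest.raises(ValueError):
        grouped_benchmark(df, "spectrometer")


def test_iterate_scaling_identity_fixed_point():
    cfg = SyntheticConfig(
        n_molecules=6, seed=21, true_scale_c=1.0,
        bands_per_molecule=(1, 1), transitions_per_band=(1, 1), grid_step=5.0
    )
    _, tsets, truth = generate_benchmark_set(cfg)
    problems = problems_from_truth(truth, tsets)
    res = iterate_scaling(problems)
    for c0, traj in res.trajectories.items():
        assert res.converged[c0]
        assert traj[-1] == pytest.approx(1.0, abs=1e-9)


def test_iterate_scaling_recovers_generating_constant_from_all_starts():
    cfg = SyntheticConfig(
        n_molecules=12, seed=22, true_scale_c=1.3,
        bands_per_molecule=(1, 1), transitions_per_band=(1, 1), grid_step=5.0
    )
    _, tsets, truth = generate_benchmark_set(cfg)
    problems = problems_from_truth(truth, tsets)
    res = iterate_scaling(problems)
    for c0, traj in res.trajectories.items():
        assert res.converged[c0]
        assert abs(traj[-1] - 1.3) < 1e-6
    assert res.selected_c == pytest.approx(1.3, abs=1e-6)


def test_iterate_scaling_multistart_selects_by_r_squared():
    # with several sticks per band a low start can lock onto a smaller
    # fixed point (dropping sticks); selection by R^2 must still pick C*
    cfg = SyntheticConfig(n_molecules=15, seed=23, transitions_per_band=(2, 3), grid_step=5.0)
    _, tsets, truth = generate_benchmark_set(cfg)
    problems = problems_from_truth(truth, tsets)
    res = iterate_scaling(problems)
    assert res.selected_c == pytest.approx(1.3, rel=1e-6)
    assert res.r_squared[res.selected_c0] == pytest.approx(1.0, abs=1e-9)


def test_iterate_scaling_requires_two_bands():
    p = make_problem([(30000, 35000)], [32000.0], [0.2], [0.2])
    with pytest.raises(ValueError):
        iterate_scaling([p])


def test_score_problems_schema(clean_set):
    _, _, tsets, truth = clean_set
    problems = problems_from_truth(truth, tsets)
    df = score_problems(problems, "exact")
    assert {"molecule", "band_index", "target", "f_comp", "e_exp_eV", "e_comp_eV"} <= set(
        df.columns
    )
    assert len(df) == sum(len(m.f_exp) for m in truth.molecules)
    # exact assignment on clean data: f_comp = C* x target everywhere
    np.testing.assert_allclose(df["f_comp"], 1.3 * df["target"], rtol=1e-12)


def test_grouped_scaling_recovers_group_constants():
    # two sub-populations with different true scaling factors
    out = {}
    for label, c_true, seed in (("a", 1.1, 31), ("b", 1.5, 32)):
        cfg = SyntheticConfig(
            n_molecules=8, seed=seed, true_scale_c=c_true, grid_step=5.0
        )
        _, tsets, truth = generate_benchmark_set(cfg)
        problems = problems_from_truth(truth, tsets)
        out[label] = iterate_scaling(problems).selected_c
    assert out["a"] == pytest.approx(1.1, rel=0.02)
    assert out["b"] == pytest.approx(1.5, rel=0.02)
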