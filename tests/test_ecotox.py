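"""Dose-response fitting and immobility endpoints."""

import numpy as np
import pytest

from daphtrack.ecotox import (
    DoseResponseRecord,
    concordance,
    fit_ec50,
    immobility_table,
    read_dose_response_csv,
    write_dose_response_csv,
)
from daphtrack.track import Observation, Trajectory

FPS = 15.0


def _traj(moving: bool, n=400, track_id=1):
    t = Trajectory(track_id)
    for f in range(n):
        u = 5.0 + (1.5 * f if moving else 0.0)
        t.observations.append(Observation(f, (u - 2, 3, 4, 4), (u, 5.0)))
    return t


# ---------------------------------------------------------------------------
# immobility table


def test_all_mobile_gives_zero_immobile():
    chambers = {0.5: (5, [_traj(True, track_id=i) for i in range(5)])}
    (rec,) = immobility_table(chambers, FPS)
    assert rec.n_immobile == 0 and rec.n_total == 5


def test_all_stationary_gives_full_immobility():
    chambers = {2.0: (5, [_traj(False, track_id=i) for i in range(5)])}
    (rec,) = immobility_table(chambers, FPS)
    assert rec.n_immobile == 5


def test_mixed_chambers_match_hand_count():
    trajs = [_traj(True, track_id=1), _traj(False, track_id=2), _traj(False, track_id=3)]
    chambers = {1.0: (5, trajs)}  # 2 untracked animals count as immobile
    (rec,) = immobility_table(chambers, FPS)
    assert rec.n_immobile == 5 - 1
    assert rec.n_immobile + 1 == rec.n_total


def test_mobile_count_exceeding_population_rejected():
    chambers = {1.0: (2, [_traj(True, track_id=i) for i in range(3)])}
    with pytest.raises(ValueError):
        immobility_table(chambers, FPS)


def test_record_validation():
    with pytest.raises(ValueError):
        DoseResponseRecord(1.0, 10, 11)
    with pytest.raises(ValueError):
        DoseResponseRecord(-1.0, 10, 1)


# ---------------------------------------------------------------------------
# EC50 fit


def test_exact_midpoint_ec50():
    records = [(1.0, 10, 0), (2.0, 10, 5), (4.0, 10, 10)]
    fit = fit_ec50(records)
    assert fit.ec50 == pytest.approx(2.0, rel=1e-3)
    assert fit.converged


def test_noiseless_curve_recovers_parameters():
    true_ec50, true_slope = 1.5, 3.0
    concs = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
    n = 10**6
    p = 1.0 / (1.0 + (true_ec50 / concs) ** true_slope)
    records = [(c, n, int(round(pi * n))) for c, pi in zip(concs, p)]
    fit = fit_ec50(records)
    assert fit.ec50 == pytest.approx(true_ec50, rel=1e-4)
    assert fit.slope == pytest.approx(true_slope, rel=1e-3)


def test_fitted_response_is_monotone_and_half_at_ec50():
    records = [(0.5, 20, 2), (1.0, 20, 6), (2.0, 20, 14), (4.0, 20, 19)]
    fit = fit_ec50(records)
    grid = np.linspace(0.1, 10, 200)
    resp = fit.predict(grid)
    assert np.all(np.diff(resp) >= -1e-12)
    assert fit.predict([fit.ec50])[0] == pytest.approx(0.5, abs=1e-9)


def test_scale_equivariance():
    records = [(0.5, 30, 3), (1.0, 30, 10), (2.0, 30, 21), (4.0, 30, 28)]
    fit1 = fit_ec50(records)
    k = 7.5
    fit2 = fit_ec50([(c * k, n, m) for c, n, m in records])
    assert fit2.ec50 == pytest.approx(fit1.ec50 * k, rel=1e-4)
    assert fit2.slope == pytest.approx(fit1.slope, rel=1e-4)


def test_binomial_recovery_within_ten_percent():
    # 6-point assay grid in ~1.4x steps bracketing the expected EC50 (the
    # design a range-finding pre-test yields); median over 5 replicate
    # simulated assays of n=50 animals per concentration
    rng = np.random.default_rng(2024)
    true_ec50, true_slope = 1.5, 3.0
    concs = np.array([0.6, 0.85, 1.2, 1.7, 2.4, 3.4])
    p = 1.0 / (1.0 + (true_ec50 / concs) ** true_slope)
    n = 50
    estimates = []
    for _ in range(5):
        records = [(c, n, int(k)) for c, k in zip(concs, rng.binomial(n, p))]
        estimates.append(fit_ec50(records).ec50)
    assert abs(np.median(estimates) - true_ec50) / true_ec50 <= 0.10


def test_non_crossing_response_rejected():
    records = [(1.0, 10, 0), (2.0, 10, 1), (4.0, 10, 2)]
    with pytest.raises(ValueError, match="50"):
        fit_ec50(records)
    fit = fit_ec50(records, allow_extrapolation=True)
    assert fit.ec50 > 4.0


def test_degenerate_responses_rejected():
    with pytest.raises(ValueError):
        fit_ec50([(1.0, 10, 0), (2.0, 10, 0), (4.0, 10, 0)])
    with pytest.raises(ValueError):
        fit_ec50([(1.0, 10, 0), (2.0, 10, 5)])  # < 3 concentrations


def test_bootstrap_ci_brackets_estimate():
    records = [(0.5, 40, 4), (1.0, 40, 13), (2.0, 40, 28), (4.0, 40, 37)]
    fit = fit_ec50(records, n_bootstrap=50, seed=7)
    assert fit.ci_low is not None and fit.ci_low <= fit.ec50 <= fit.ci_high


def test_probit_link_close_to_logit():
    records = [(0.5, 50, 5), (1.0, 50, 16), (2.0, 50, 35), (4.0, 50, 46)]
    f1 = fit_ec50(records, link="logit")
    f2 = fit_ec50(records, link="probit")
    assert f2.ec50 == pytest.approx(f1.ec50, rel=0.15)


# ---------------------------------------------------------------------------
# concordance


def test_identical_lists_perfect_correlation():
    r2, slope, intercept = concordance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r2 == pytest.approx(1.0)
    assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0)


def test_exact_linear_relationship():
    x = np.array([0.5, 1.0, 1.5, 2.0])
    r2, slope, intercept = concordance(x, 2 * x + 1)
    assert r2 == pytest.approx(1.0)
    assert slope == pytest.approx(2.0) and intercept == pytest.approx(1.0)


def test_concordance_matches_textbook_formula(rng):
    x = rng.uniform(0, 5, 20)
    y = 1.3 * x + rng.normal(0, 0.5, 20)
    r2, slope, intercept = concordance(x, y)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    r2_direct = sxy**2 / (np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    assert r2 == pytest.approx(r2_direct)
    assert slope == pytest.approx(sxy / np.sum((x - x.mean()) ** 2))


def test_zero_variance_undefined():
    assert concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == (None, None, None)


# ---------------------------------------------------------------------------
# CSV round trip


def test_dose_response_csv_round_trip(tmp_path):
    records = [DoseResponseRecord(0.5, 20, 3), DoseResponseRecord(1.0, 20, 11)]
    path = tmp_path / "dr.csv"
    write_dose_response_csv(records, path)
    assert read_dose_response_csv(path) == records
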