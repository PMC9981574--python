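"""Acute-toxicity endpoints from tracked behaviour.

Immobility is the assay endpoint: an animal that stays stationary for
20 s or more counts as affected. Per test concentration the module
builds (concentration, n_total, n_immobile) records and fits a
two-parameter log-logistic dose-response curve by maximum binomial
likelihood:

    P(immobile | c) = 1 / (1 + (ec50 / c) ** slope)

EC50 is the concentration at which the fitted response is exactly 50 %.
The fit uses a deterministic bounded quasi-Newton optimization in
(log ec50, log slope) with fixed starting values, so identical inputs
give identical estimates; confidence intervals come from a seeded
nonparametric bootstrap. A probit link is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from . import behavior


@dataclass(frozen=True)
class DoseResponseRecord:
    """Counts at one test concentration (mg/L or % dilution)."""

    concentration: float
    n_total: int
    n_immobile: int

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not (0 <= self.n_immobile <= self.n_total):
            raise ValueError("0 <= n_immobile <= n_total required")


@dataclass(frozen=True)
class Ec50Fit:
    """Fitted dose-response parameters."""

    ec50: float
    slope: float
    log_likelihood: float
    converged: bool
    link: str = "logit"
    ci_low: float | None = None
    ci_high: float | None = None

    def predict(self, conc) -> np.ndarray:
        """Fitted immobility probability at the given concentrations."""
        return _response(np.asarray(conc, dtype=float), self.ec50, self.slope, self.link)


def _response(conc, ec50, slope, link="logit"):
    conc = np.asarray(conc, dtype=float)
    out = np.zeros_like(conc)
    pos = conc > 0
    with np.errstate(over="ignore"):
        if link == "logit":
            out[pos] = 1.0 / (1.0 + (ec50 / conc[pos]) ** slope)
        elif link == "probit":
            out[pos] = norm.cdf(slope * (np.log(conc[pos]) - np.log(ec50)))
        else:
            raise ValueError(f"unknown link {link!r}")
    return out


def immobility_table(
    trajs_by_concentration: dict[float, tuple[int, list]],
    fps: float,
    window_s: float = 20.0,
    epsilon: float = 0.5,
) -> list[DoseResponseRecord]:
    """Build dose-response records from tracked chambers.

    ``trajs_by_concentration`` maps concentration -> (chamber population,
    trajectories). n_immobile = population - mobile count; a mobile count
    exceeding the stated population signals a tracking error and is
    rejected.
    """
    records = []
    for conc in sorted(trajs_by_concentration):
        n_total, trajs = trajs_by_concentration[conc]
        mobile = behavior.mobile_count(trajs, fps, window_s, epsilon)
        if mobile > n_total:
            raise ValueError(
                f"concentration {conc}: mobile count {mobile} exceeds population {n_total}"
            )
        records.append(DoseResponseRecord(conc, n_total, n_total - mobile))
    return records


def fit_ec50(
    records,
    link: str = "logit",
    allow_extrapolation: bool = False,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> Ec50Fit:
    """Maximum-likelihood two-parameter log-logistic fit.

    Requires at least three distinct positive concentrations and a
    response that actually crosses 50 % (otherwise the EC50 would be an
    extrapolation, refused unless ``allow_extrapolation``). Zero
    concentrations (controls) do not enter the likelihood.
    """
    recs = [r if isinstance(r, DoseResponseRecord) else DoseResponseRecord(*r) for r in records]
    pos = [r for r in recs if r.concentration > 0]
    concs = np.array([r.concentration for r in pos])
    n_tot = np.array([r.n_total for r in pos])
    n_imm = np.array([r.n_immobile for r in pos])
    if len(np.unique(concs)) < 3:
        raise ValueError("need >= 3 distinct positive concentrations")
    frac = n_imm / n_tot
    if np.all(frac == 0) or np.all(frac == 1):
        raise ValueError("responses are all 0 or all 1; dose-response cannot be fitted")
    order = np.argsort(concs)
    f_sorted, c_sorted = frac[order], concs[order]
    crosses = f_sorted.min() < 0.5 < f_sorted.max() or np.any(f_sorted == 0.5)
    if not crosses and not allow_extrapolation:
        raise ValueError(
            "observed response never crosses 50%; EC50 would be an extrapolation "
            "(pass allow_extrapolation=True to force)"
        )

    # start: geometric mean of the concentrations bracketing the 50% crossing
    above = np.nonzero(f_sorted >= 0.5)[0]
    if above.size and above[0] > 0:
        ec50_0 = float(np.sqrt(c_sorted[above[0] - 1] * c_sorted[above[0]]))
    else:
        ec50_0 = float(np.exp(np.mean(np.log(c_sorted))))
    x0 = np.array([np.log(ec50_0), 0.0])  # log slope starts at 0 (slope 1)

    def nll(x):
        ec50, slope = np.exp(x[0]), np.exp(x[1])
        p = _response(concs, ec50, slope, link)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(n_imm * np.log(p) + (n_tot - n_imm) * np.log(1 - p))

    lo, hi = np.log(concs.min()), np.log(concs.max())
    bounds = [(lo - 5.0, hi + 5.0), (np.log(0.05), np.log(30.0))]
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    ec50, slope = float(np.exp(res.x[0])), float(np.exp(res.x[1]))

    ci_low = ci_high = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        estimates = []
        for _ in range(n_bootstrap):
            b_imm = rng.binomial(n_tot, np.clip(n_imm / n_tot, 0, 1))
            def nll_b(x, b=b_imm):
                p = np.clip(_response(concs, np.exp(x[0]), np.exp(x[1]), link), 1e-12, 1 - 1e-12)
                return -np.sum(b * np.log(p) + (n_tot - b) * np.log(1 - p))
            try:
                r = minimize(nll_b, res.x, method="L-BFGS-B", bounds=bounds)
                estimates.append(np.exp(r.x[0]))
            except Exception:
                continue
        if estimates:
            ci_low, ci_high = (float(q) for q in np.percentile(estimates, [2.5, 97.5]))

    return Ec50Fit(
        ec50=ec50,
        slope=slope,
        log_likelihood=float(-res.fun),
        converged=bool(res.success),
        link=link,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def concordance(lab_values, device_values):
    """Squared Pearson correlation and least-squares line between paired
    lab and device measurements.

    Returns (r_squared, slope, intercept); zero variance in either list
    leaves all three None.
    """
    x = np.asarray(lab_values, dtype=float)
    y = np.asarray(device_values, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need paired lists with n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None, None
    from scipy.stats import linregress

    fit = linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope), float(fit.intercept)


def read_dose_response_csv(path) -> list[DoseResponseRecord]:
    """Read a concentration,n_total,n_immobile CSV (header optional)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if lineno == 1 and not _is_number(parts[0]):
                continue  # header
            if len(parts) < 3:
                raise ValueError(f"malformed dose-response line {lineno}")
            records.append(DoseResponseRecord(float(parts[0]), int(parts[1]), int(parts[2])))
    return records


def write_dose_response_csv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("concentration,n_total,n_immobile\n")
        for r in records:
            fh.write(f"{r.concentration},{r.n_total},{r.n_immobile}\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
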