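"""Tethered-flight endurance analysis.

Each queen's total flight time is the sum of her bout durations.  The
quantity of scientific interest is maximum, not typical, performance:
minimum flight times are short for every morphology (any queen can
decline to fly), while the upper envelope of total flight time declines
with abdominal loading.  The envelope is characterized by quantile
regression through the upper quartile (tau = 0.75): the line (b0, b1)
minimizes the check loss

    sum_i rho_tau(y_i - b0 - b1 x_i),   rho_tau(u) = u * (tau - 1[u < 0]),

solved here exactly as a linear program (HiGHS).  An optimal solution
interpolates at least two data points, which is what the exhaustive
point-pair oracle in the test suite exploits.  Slope inference is by a
seeded xy-pairs bootstrap.  OLS and Spearman rank correlations are
computed alongside as central-tendency comparators, with Holm correction
applied across the predictors within each method (explicit family).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog

from .compare import holm_correction
from .io import FlightRecord
from .morphometrics import profile_queen

__all__ = [
    "EnduranceError",
    "QuantileFit",
    "total_flight_time",
    "build_endurance_dataset",
    "exclude_outliers",
    "colony_homogeneity",
    "check_loss",
    "fit_quantile",
    "fit_ols_and_rank",
    "endurance_analysis",
    "PREDICTORS",
]

#: Table-4-style predictors of total flight time
PREDICTORS = ("abdomen_mass", "log_fmr", "wing_loading")


class EnduranceError(ValueError):
    pass


@dataclass(frozen=True)
class QuantileFit:
    tau: float
    slope: float
    intercept: float
    objective: float  # check loss of the returned line
    n: int
    iterations: int
    p_raw: float | None = None
    p_corrected: float | None = None


def total_flight_time(record: FlightRecord) -> float:
    """Sum of all bout durations (s) for one queen."""
    if len(record.bout_durations) < 1:
        raise EnduranceError(f"queen {record.queen_id!r} has no bouts")
    return float(sum(record.bout_durations))


def build_endurance_dataset(flights: Sequence[FlightRecord]) -> pd.DataFrame:
    """Per-queen endurance table: total flight time plus the predictors.

    FMR enters as its natural logarithm (log_fmr), the scale on which it
    is analyzed against flight time.
    """
    rows = []
    for rec in flights:
        if rec.morphometry is None:
            raise EnduranceError(
                f"queen {rec.queen_id!r} lacks post-flight morphometry"
            )
        prof = profile_queen(rec.morphometry)
        rows.append(
            {
                "queen_id": rec.queen_id,
                "colony_id": rec.colony_id,
                "total_flight_time": total_flight_time(rec),
                "abdomen_mass": rec.morphometry.abdomen_mass,
                "log_fmr": math.log(prof.fmr),
                "wing_loading": prof.wing_loading,
                "excluded": False,
                "exclusion_reason": "",
            }
        )
    return pd.DataFrame(rows)


def exclude_outliers(
    dataset: pd.DataFrame,
    enabled: bool = False,
    abs_threshold: float | None = None,
    k_sd: float = 3.0,
) -> pd.DataFrame:
    """Flag (and, only with explicit assent, exclude) light-abdomen outliers.

    A queen is flagged when her abdomen mass falls below ``abs_threshold``
    (mg) or more than ``k_sd`` SDs below the cohort mean — the signature
    of a just-eclosed queen not yet provisioned for her mating flight.
    With ``enabled=False`` (the default) nothing is excluded; flags are
    recorded either way, with reasons.
    """
    out = dataset.copy()
    if out.empty:
        return out
    mass = out["abdomen_mass"].to_numpy(dtype=float)
    mean, sd = mass.mean(), mass.std(ddof=1) if len(mass) > 1 else 0.0
    reasons = []
    for m in mass:
        r = []
        if abs_threshold is not None and m < abs_threshold:
            r.append(f"abdomen mass {m:.3f} mg below threshold {abs_threshold} mg")
        if sd > 0 and m < mean - k_sd * sd:
            r.append(
                f"abdomen mass {m:.3f} mg more than {k_sd} SD below cohort "
                f"mean {mean:.3f} mg"
            )
        reasons.append("; ".join(r))
    out["exclusion_reason"] = reasons
    out["excluded"] = [bool(r) and enabled for r in reasons]
    return out


def colony_homogeneity(
    dataset: pd.DataFrame,
    variables: Sequence[str] = ("total_flight_time",) + PREDICTORS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test whether colonies differ in flight time or any predictor.

    Per variable: one-way ANOVA across colonies when every colony group
    passes a Shapiro-Wilk screen, Kruskal-Wallis otherwise; a pooling
    recommendation (pool when p >= alpha) supports dropping colony
    identity from the final endurance fits.
    """
    data = dataset[~dataset["excluded"]] if "excluded" in dataset else dataset
    colonies = data["colony_id"].unique()
    if len(colonies) < 2:
        raise EnduranceError("need >= 2 colonies")
    rows = []
    for var in variables:
        groups = [
            data.loc[data["colony_id"] == c, var].to_numpy(dtype=float)
            for c in sorted(colonies)
        ]
        normal = all(
            len(g) >= 3 and np.ptp(g) > 0 and stats.shapiro(g).pvalue > alpha
            for g in groups
        )
        if normal:
            test, res = "anova", stats.f_oneway(*groups)
        else:
            test, res = "kruskal_wallis", stats.kruskal(*groups)
        rows.append(
            {
                "variable": var,
                "test": test,
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
                "recommendation": "pool" if res.pvalue >= alpha else "do_not_pool",
            }
        )
    return pd.DataFrame(rows)


def check_loss(
    x: np.ndarray, y: np.ndarray, intercept: float, slope: float, tau: float
) -> float:
    """Asymmetric absolute (check) loss of a line on the data."""
    u = np.asarray(y, dtype=float) - intercept - slope * np.asarray(x, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def fit_quantile(
    x: Sequence[float],
    y: Sequence[float],
    tau: float = 0.75,
    n_boot: int = 0,
    seed: int | np.random.SeedSequence | None = None,
) -> QuantileFit:
    """Quantile regression of y on x by exact linear programming.

    Minimizes the tau check loss over (intercept, slope); with
    ``n_boot > 0`` a seeded xy-pairs bootstrap yields a two-sided
    p-value for the slope (fraction of resampled slopes on the other
    side of zero, with the +1 small-sample correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise EnduranceError("x and y lengths differ")
    if x.size < 3:
        raise EnduranceError("need >= 3 points")
    if not 0 < tau < 1:
        raise EnduranceError("tau must be in (0, 1)")
    if np.ptp(x) == 0:
        raise EnduranceError("degenerate predictor: all x equal")
    b0, b1, iters = _solve_check_loss(x, y, tau)
    fit = QuantileFit(
        tau=tau,
        slope=b1,
        intercept=b0,
        objective=check_loss(x, y, b0, b1, tau),
        n=int(x.size),
        iterations=iters,
    )
    if n_boot > 0:
        fit = replace(fit, p_raw=_bootstrap_slope_p(x, y, tau, n_boot, seed))
    return fit


def _solve_check_loss(x: np.ndarray, y: np.ndarray, tau: float):
    """LP formulation: y_i = b0 + b1 x_i + u_i - v_i, u, v >= 0,
    minimize tau * sum(u) + (1 - tau) * sum(v)."""
    n = x.size
    c = np.concatenate([[0.0, 0.0], np.full(n, tau), np.full(n, 1.0 - tau)])
    a_eq = np.hstack(
        [np.ones((n, 1)), x[:, None], np.eye(n), -np.eye(n)]
    )
    bounds = [(None, None), (None, None)] + [(0.0, None)] * (2 * n)
    res = linprog(c, A_eq=a_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise EnduranceError(f"LP solver failed: {res.message}")
    return float(res.x[0]), float(res.x[1]), int(res.nit)


def _bootstrap_slope_p(x, y, tau, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    n = x.size
    slopes = np.empty(n_boot)
    got = 0
    while got < n_boot:
        idx = rng.integers(0, n, size=n)
        if np.ptp(x[idx]) == 0:
            continue  # resample degenerate in x; redraw
        _, b1, _ = _solve_check_loss(x[idx], y[idx], tau)
        slopes[got] = b1
        got += 1
    n_le = int(np.sum(slopes <= 0.0))
    n_ge = int(np.sum(slopes >= 0.0))
    p = 2.0 * (min(n_le, n_ge) + 1) / (n_boot + 1)
    return float(min(p, 1.0))


def fit_ols_and_rank(
    dataset: pd.DataFrame,
    predictors: Sequence[str] = PREDICTORS,
    response: str = "total_flight_time",
) -> dict[str, pd.DataFrame]:
    """OLS and Spearman comparators for each predictor, Holm per method."""
    data = dataset[~dataset["excluded"]] if "excluded" in dataset else dataset
    y = data[response].to_numpy(dtype=float)
    ols_rows, rank_rows = [], []
    for pred in predictors:
        xv = data[pred].to_numpy(dtype=float)
        if xv.size < 3:
            raise EnduranceError("need >= 3 points")
        lin = stats.linregress(xv, y)
        ols_rows.append(
            {
                "predictor": pred,
                "r_squared": float(lin.rvalue**2),
                "intercept": float(lin.intercept),
                "slope": float(lin.slope),
                "p": float(lin.pvalue),
            }
        )
        sp = stats.spearmanr(xv, y)
        rank_rows.append(
            {"predictor": pred, "r_s": float(sp.statistic), "p": float(sp.pvalue)}
        )
    ols = pd.DataFrame(ols_rows)
    rank = pd.DataFrame(rank_rows)
    ols["p_corrected"] = holm_correction(ols["p"])
    rank["p_corrected"] = holm_correction(rank["p"])
    return {"ols": ols, "spearman": rank}


def endurance_analysis(
    dataset: pd.DataFrame,
    tau: float = 0.75,
    n_boot: int = 0,
    seed: int | None = None,
    predictors: Sequence[str] = PREDICTORS,
) -> dict[str, pd.DataFrame]:
    """Full endurance battery: quantile fits plus OLS/Spearman comparators.

    The quantile table mirrors the maximum-performance analysis (one
    univariate fit per predictor); Holm correction spans the predictors
    within each method (family size = number of predictors).  Child
    bootstrap seeds derive deterministically from ``seed``.
    """
    data = dataset[~dataset["excluded"]] if "excluded" in dataset else dataset
    y = data["total_flight_time"].to_numpy(dtype=float)
    child_seeds = (
        np.random.SeedSequence(seed).spawn(len(predictors))
        if seed is not None
        else [None] * len(predictors)
    )
    q_rows = []
    fits = []
    for pred, child in zip(predictors, child_seeds):
        fit = fit_quantile(
            data[pred].to_numpy(dtype=float), y, tau=tau, n_boot=n_boot, seed=child
        )
        fits.append(fit)
        q_rows.append(
            {
                "predictor": pred,
                "tau": fit.tau,
                "intercept": fit.intercept,
                "slope": fit.slope,
                "objective": fit.objective,
                "n": fit.n,
                "p": fit.p_raw,
            }
        )
    quantile = pd.DataFrame(q_rows)
    if n_boot > 0:
        quantile["p_corrected"] = holm_correction(quantile["p"])
    out = {"quantile": quantile}
    out.update(fit_ols_and_rank(data, predictors=predictors))
    return out
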