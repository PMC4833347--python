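"""Caste-contrast statistics battery.

Two-group comparisons between claustral and parasitic queens are gated
on normality: each group is screened with a Shapiro-Wilk test and the
contrast uses a t-test when both groups pass, a Kruskal-Wallis test
(two groups, tie-corrected) otherwise.  Contrasts are also expressed as
percent differences relative to the parasitic group and as
claustral/parasitic fold differences.  To guard against
pseudoreplication from sampling sisters, every analysis can be repeated
in colony-average mode, treating each colony as one data point.

Per-queen flight indices are regressed on dry abdomen mass separately
within each queen type (OLS), and family-wise error across the four
queen types is controlled per index with the Holm-Bonferroni step-down.
Holm families are always explicit — membership is never inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    trait: str
    group: str
    n: int
    mean: float
    sd: float
    median: float
    iqr_low: float
    iqr_high: float


@dataclass(frozen=True)
class ComparisonResult:
    trait: str
    species: str
    test_used: str  # "t" | "kruskal_wallis" | "degenerate"
    statistic: float
    p_raw: float
    claustral: GroupSummary
    parasitic: GroupSummary
    percent_difference: float  # 100 * (claustral - parasitic) / parasitic
    fold_difference: float  # claustral / parasitic


@dataclass(frozen=True)
class FitResult:
    """One least-squares fit of an index on abdomen mass."""

    response: str
    predictor: str
    group: str
    slope: float
    intercept: float
    r_squared: float
    p_raw: float
    n: int
    p_corrected: float | None = None


def summarize_group(
    values: Sequence[float], trait: str = "", group: str = ""
) -> GroupSummary:
    """Mean/SD and median/IQR (25th-75th percentile, linear interpolation)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ComparisonError("need at least one value")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return GroupSummary(
        trait=trait,
        group=group,
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        median=float(q50),
        iqr_low=float(q25),
        iqr_high=float(q75),
    )


def _normalish(values: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk gate; constant samples count as non-normal."""
    if np.ptp(values) == 0:
        return False
    return stats.shapiro(values).pvalue > alpha


def compare_castes(
    claustral: Sequence[float],
    parasitic: Sequence[float],
    trait: str = "",
    species: str = "",
    alpha_normality: float = 0.05,
    equal_var: bool = False,
    transform=None,
) -> ComparisonResult:
    """Two-group caste contrast with a Shapiro-Wilk normality gate.

    ``transform`` (e.g. ``numpy.log``) is applied before the normality
    screen and the test, mirroring per-trait transforms used to meet
    normality assumptions; percent and fold differences are always on
    the raw scale.  The t-test is Welch by default (``equal_var=True``
    for the pooled-variance variant).
    """
    c = np.asarray(claustral, dtype=float)
    p = np.asarray(parasitic, dtype=float)
    if c.size < 3 or p.size < 3:
        raise ComparisonError(
            "need >= 3 values per group for the normality screen"
        )
    ct = transform(c) if transform is not None else c
    pt = transform(p) if transform is not None else p
    if np.ptp(np.concatenate([ct, pt])) == 0:
        test_used, statistic, p_raw = "degenerate", math.nan, math.nan
    elif _normalish(ct, alpha_normality) and _normalish(pt, alpha_normality):
        res = stats.ttest_ind(ct, pt, equal_var=equal_var)
        test_used, statistic, p_raw = "t", float(res.statistic), float(res.pvalue)
    else:
        res = stats.kruskal(ct, pt)
        test_used = "kruskal_wallis"
        statistic, p_raw = float(res.statistic), float(res.pvalue)
    c_mean, p_mean = float(c.mean()), float(p.mean())
    return ComparisonResult(
        trait=trait,
        species=species,
        test_used=test_used,
        statistic=statistic,
        p_raw=p_raw,
        claustral=summarize_group(c, trait, "claustral"),
        parasitic=summarize_group(p, trait, "parasitic"),
        percent_difference=100.0 * (c_mean - p_mean) / p_mean,
        fold_difference=c_mean / p_mean,
    )


def colony_averages(
    table: pd.DataFrame, colony_col: str = "colony_id"
) -> pd.DataFrame:
    """Collapse a per-queen table to per-colony trait means.

    Non-numeric columns (species, caste, ...) are kept when constant
    within a colony.
    """
    if colony_col not in table.columns:
        raise ComparisonError(f"column {colony_col!r} missing")
    numeric = [
        c for c in table.select_dtypes(include="number").columns if c != colony_col
    ]
    grouped = table.groupby(colony_col, sort=True)
    out = grouped[list(numeric)].mean()
    for col in table.columns:
        if col in numeric or col == colony_col:
            continue
        uniques = grouped[col].agg(lambda s: s.iloc[0] if s.nunique() == 1 else None)
        out[col] = uniques
    return out.reset_index()


def regress_on_abdomen_mass(
    abdomen_mass: Sequence[float],
    response: Sequence[float],
    response_name: str = "",
    group: str = "",
) -> FitResult:
    """OLS of one flight index on dry abdomen mass (two-sided slope p)."""
    x = np.asarray(abdomen_mass, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size < 3:
        raise ComparisonError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ComparisonError("degenerate predictor: all abdomen masses equal")
    if np.ptp(y) == 0:
        # constant response: zero slope, no variance explained
        return FitResult(
            response=response_name,
            predictor="abdomen_mass",
            group=group,
            slope=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            p_raw=1.0,
            n=int(x.size),
        )
    res = stats.linregress(x, y)
    return FitResult(
        response=response_name,
        predictor="abdomen_mass",
        group=group,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_raw=float(res.pvalue),
        n=int(x.size),
    )


def holm_correction(p_values: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjusted p-values, in input order.

    The i-th smallest p (1-based) is multiplied by (m - i + 1), a running
    maximum enforces monotonicity, and results are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ComparisonError("p-values must lie in [0, 1]")
    return [float(v) for v in multipletests(p, method="holm")[1]]


def apply_holm(fits: Sequence[FitResult]) -> list[FitResult]:
    """Holm-correct one explicit family of fits (returned in input order)."""
    corrected = holm_correction([f.p_raw for f in fits])
    return [replace(f, p_corrected=c) for f, c in zip(fits, corrected)]


def morphology_regressions(
    profiles: pd.DataFrame,
    responses: Sequence[str] = ("fmr", "wing_loading", "drag_area"),
) -> pd.DataFrame:
    """Per-queen-type OLS of each index on abdomen mass, Holm per index.

    ``profiles`` must carry species, caste, abdomen_mass and the response
    columns.  Each index forms one Holm family across the queen types
    (m = number of types present).
    """
    rows = []
    for response in responses:
        fits = []
        for (species, caste), grp in profiles.groupby(
            ["species", "caste"], sort=True
        ):
            label = f"{species[0].upper()}{caste[0].upper()}"
            fits.append(
                regress_on_abdomen_mass(
                    grp["abdomen_mass"], grp[response], response, label
                )
            )
        for f in apply_holm(fits):
            rows.append(
                {
                    "response": f.response,
                    "group": f.group,
                    "n": f.n,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "r_squared": f.r_squared,
                    "p": f.p_raw,
                    "p_corrected": f.p_corrected,
                }
            )
    return pd.DataFrame(rows)


def caste_summary_table(profiles: pd.DataFrame, traits: Sequence[str]) -> pd.DataFrame:
    """Group summary table (mean/SD/median/IQR) per species x caste x trait."""
    rows = []
    for (species, caste), grp in profiles.groupby(["species", "caste"], sort=True):
        for trait in traits:
            s = summarize_group(grp[trait].dropna(), trait, caste)
            rows.append(
                {
                    "species": species,
                    "caste": caste,
                    "trait": trait,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "median": s.median,
                    "iqr_low": s.iqr_low,
                    "iqr_high": s.iqr_high,
                }
            )
    return pd.DataFrame(rows)


def caste_contrast_table(
    profiles: pd.DataFrame,
    traits: Sequence[str],
    alpha_normality: float = 0.05,
    transforms: dict | None = None,
) -> pd.DataFrame:
    """Claustral-vs-parasitic contrasts per species for the given traits."""
    transforms = transforms or {}
    rows = []
    for species, grp in profiles.groupby("species", sort=True):
        cla = grp[grp["caste"] == "claustral"]
        par = grp[grp["caste"] == "parasitic"]
        if len(cla) < 3 or len(par) < 3:
            continue
        for trait in traits:
            r = compare_castes(
                cla[trait].dropna(),
                par[trait].dropna(),
                trait=trait,
                species=species,
                alpha_normality=alpha_normality,
                transform=transforms.get(trait),
            )
            rows.append(
                {
                    "species": species,
                    "trait": trait,
                    "test": r.test_used,
                    "statistic": r.statistic,
                    "p": r.p_raw,
                    "claustral_mean": r.claustral.mean,
                    "claustral_sd": r.claustral.sd,
                    "parasitic_mean": r.parasitic.mean,
                    "parasitic_sd": r.parasitic.sd,
                    "percent_difference": r.percent_difference,
                    "fold_difference": r.fold_difference,
                }
            )
    return pd.DataFrame(rows)
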