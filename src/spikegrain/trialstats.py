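"""Validation and field-trial statistics.

Two groups of tools:

* calibration of image-derived grain dimensions against reference caliper
  measurements — ordinary least squares with R^2, and seeded k-fold
  cross-validation of the linear model (per-fold mean absolute error, mean
  squared error, and the root of the mean of the fold MSEs);

* trial statistics for genotype x environment experiments laid out as a
  randomized complete block design with environments as main plots
  (split-plot): the split-plot ANOVA with its two error strata, a plain
  two-way factorial RCBD ANOVA, and Duncan's multiple range test (DMRT)
  letter groupings of means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CalibrationFit",
    "CVReport",
    "DMRTResult",
    "fit_calibration",
    "kfold_cv",
    "anova_split_plot",
    "anova_factorial",
    "dmrt",
    "duncan_critical_range",
]


# --------------------------------------------------------------------------
# calibration + cross-validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of reference measurements on image-derived values."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_calibration(observed, predicted_source) -> CalibrationFit:
    """Least-squares line `observed ~ predicted_source` with R^2.

    ``observed`` are the reference (caliper) values, ``predicted_source``
    the image-derived values (Feret for length, MinFeret for width).
    """
    y = np.asarray(observed, dtype=float)
    x = np.asarray(predicted_source, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the source values")
    res = sps.linregress(x, y)
    # constant response: SST = 0, the flat fit explains nothing (R^2 = 0)
    r2 = float(res.rvalue**2) if math.isfinite(res.rvalue) else 0.0
    return CalibrationFit(slope=float(res.slope),
                          intercept=float(res.intercept),
                          r_squared=r2,
                          n=len(x))


@dataclass
class CVReport:
    """Seeded k-fold cross-validation of a simple linear model."""

    k: int
    fold_assignment: np.ndarray   # fold index per observation
    fold_mae: np.ndarray          # mean |error| per fold
    fold_mse: np.ndarray          # mean squared error per fold
    overall_rmse: float           # sqrt(mean of fold MSEs)
    predictions: np.ndarray       # out-of-fold prediction per observation


def kfold_cv(x, y, k: int = 10, seed: int = 0) -> CVReport:
    """k-fold cross-validation of the line y ~ x.

    Observations are shuffled with the seed and split into k near-equal
    contiguous folds; for each fold the line is fit on the complement and
    the fold is predicted.  Per fold, the mean absolute and mean squared
    prediction errors are recorded; the overall statistic is the square
    root of the average of the fold MSEs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("inputs must have equal length")
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    assignment = np.empty(n, dtype=int)
    predictions = np.empty(n, dtype=float)
    fold_mae = np.empty(k)
    fold_mse = np.empty(k)
    for f, test_idx in enumerate(folds):
        assignment[test_idx] = f
        train = np.setdiff1d(np.arange(n), test_idx)
        slope, intercept = np.polyfit(x[train], y[train], 1)
        pred = intercept + slope * x[test_idx]
        predictions[test_idx] = pred
        err = y[test_idx] - pred
        fold_mae[f] = np.abs(err).mean()
        fold_mse[f] = (err**2).mean()
    return CVReport(k=k, fold_assignment=assignment, fold_mae=fold_mae,
                    fold_mse=fold_mse,
                    overall_rmse=float(np.sqrt(fold_mse.mean())),
                    predictions=predictions)


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------

def _check_balanced(table: pd.DataFrame, factors: list[str]) -> None:
    counts = table.groupby(factors, observed=True).size()
    n_cells = int(np.prod([table[f].nunique() for f in factors]))
    if counts.nunique() != 1 or counts.iloc[0] != 1 or len(counts) != n_cells:
        raise ValueError(
            "unbalanced design: exactly one observation per "
            f"{' x '.join(factors)} cell is required")
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")


def _merge_year_into_block(table: pd.DataFrame) -> pd.DataFrame:
    """Combined multi-year analysis: (year, block) pairs become blocks."""
    if "year" in table.columns and table["year"].nunique() > 1:
        table = table.copy()
        table["block"] = (table["year"].astype(str) + ":"
                          + table["block"].astype(str))
    return table


def _ss(table: pd.DataFrame, value: str, factors: list[str],
        cf: float) -> float:
    g = table.groupby(factors, observed=True)[value]
    return float((g.sum() ** 2 / g.size()).sum() - cf)


def anova_split_plot(
    table: pd.DataFrame,
    value: str = "value",
    block: str = "block",
    environment: str = "environment",
    genotype: str = "genotype",
) -> pd.DataFrame:
    """Split-plot ANOVA: environments are main plots, genotypes subplots.

    Expects a balanced long-format table with one observation per
    block x environment x genotype cell (a ``year`` column, if present with
    more than one level, is folded into the blocks).  Environment (and
    block) are tested against the main-plot error (block x environment);
    genotype and the G x E interaction against the residual.

    Returns a DataFrame indexed by source with columns df, SS, MS, F, p.
    Sources with an undefined F (zero error MS) report NaN.
    """
    table = _merge_year_into_block(table)
    _check_balanced(table, [block, environment, genotype])
    y = table[value].astype(float)
    n = len(table)
    cf = y.sum() ** 2 / n
    ss_total = float((y**2).sum() - cf)

    r = table[block].nunique()
    e = table[environment].nunique()
    g = table[genotype].nunique()

    ss_b = _ss(table, value, [block], cf)
    ss_e = _ss(table, value, [environment], cf)
    ss_be = _ss(table, value, [block, environment], cf) - ss_b - ss_e
    ss_g = _ss(table, value, [genotype], cf)
    ss_ge = _ss(table, value, [environment, genotype], cf) - ss_e - ss_g
    ss_resid = ss_total - ss_b - ss_e - ss_be - ss_g - ss_ge

    rows = {
        "block": (r - 1, ss_b),
        "environment": (e - 1, ss_e),
        "main_plot_error": ((r - 1) * (e - 1), ss_be),
        "genotype": (g - 1, ss_g),
        "genotype:environment": ((g - 1) * (e - 1), ss_ge),
        "residual": (e * (r - 1) * (g - 1), ss_resid),
    }
    out = _assemble_anova(rows, ss_total, n,
                          error_of={"block": "main_plot_error",
                                    "environment": "main_plot_error",
                                    "genotype": "residual",
                                    "genotype:environment": "residual"})
    return out


def anova_factorial(
    table: pd.DataFrame,
    value: str = "value",
    block: str = "block",
    environment: str = "environment",
    genotype: str = "genotype",
) -> pd.DataFrame:
    """Two-way factorial RCBD ANOVA (single error stratum)."""
    table = _merge_year_into_block(table)
    _check_balanced(table, [block, environment, genotype])
    y = table[value].astype(float)
    n = len(table)
    cf = y.sum() ** 2 / n
    ss_total = float((y**2).sum() - cf)

    r = table[block].nunique()
    e = table[environment].nunique()
    g = table[genotype].nunique()

    ss_b = _ss(table, value, [block], cf)
    ss_e = _ss(table, value, [environment], cf)
    ss_g = _ss(table, value, [genotype], cf)
    ss_ge = _ss(table, value, [environment, genotype], cf) - ss_e - ss_g
    ss_resid = ss_total - ss_b - ss_e - ss_g - ss_ge

    rows = {
        "block": (r - 1, ss_b),
        "environment": (e - 1, ss_e),
        "genotype": (g - 1, ss_g),
        "genotype:environment": ((g - 1) * (e - 1), ss_ge),
        "residual": (r * e * g - 1 - (r - 1) - (e - 1) - (g - 1)
                     - (g - 1) * (e - 1), ss_resid),
    }
    return _assemble_anova(rows, ss_total, n,
                           error_of={k: "residual" for k in
                                     ("block", "environment", "genotype",
                                      "genotype:environment")})


def _assemble_anova(rows: dict[str, tuple[int, float]], ss_total: float,
                    n: int, error_of: dict[str, str]) -> pd.DataFrame:
    out = pd.DataFrame(
        {"df": {k: v[0] for k, v in rows.items()},
         "SS": {k: v[1] for k, v in rows.items()}})
    out["MS"] = out["SS"] / out["df"].where(out["df"] > 0)
    out["F"] = np.nan
    out["p"] = np.nan
    for src, err in error_of.items():
        ms_err = out.at[err, "MS"]
        if pd.notna(ms_err) and ms_err > 0:
            f = out.at[src, "MS"] / ms_err
            out.at[src, "F"] = f
            out.at[src, "p"] = sps.f.sf(f, out.at[src, "df"],
                                        out.at[err, "df"])
    out.loc["total"] = [n - 1, ss_total, np.nan, np.nan, np.nan]
    out["df"] = out["df"].astype(int)
    return out


# --------------------------------------------------------------------------
# Duncan's multiple range test
# --------------------------------------------------------------------------

def duncan_critical_range(span: int, df_error: int, mse: float,
                          n_per_group: float, alpha: float = 0.05) -> float:
    """Duncan critical range R_p for comparing means ``span`` ranks apart.

    R_p = q*(alpha_p, p, df) * sqrt(MSE / n), with the protection level
    alpha_p = 1 - (1 - alpha)^(p-1) and q* the studentized-range quantile.
    """
    if span < 2:
        raise ValueError("span must be >= 2")
    q = _q_studentized((1.0 - alpha) ** (span - 1), span, df_error)
    return float(q * math.sqrt(mse / n_per_group))


@lru_cache(maxsize=1024)
def _q_studentized(prob: float, span: int, df_error: int) -> float:
    # scipy's studentized-range ppf is accurate but slow; quantiles only
    # depend on (alpha, span, df), so cache them across comparisons
    return float(sps.studentized_range.ppf(prob, span, df_error))


@dataclass
class DMRTResult:
    """Duncan letter groupings; groups sharing a letter do not differ."""

    groups: pd.DataFrame  # index = group, columns mean, rank, letters
    alpha: float
    mse: float
    df_error: int
    n_per_group: float

    def letters(self) -> dict[str, str]:
        return self.groups["letters"].to_dict()


def dmrt(means: dict[str, float], n_per_group: float, mse: float,
         df_error: int, alpha: float = 0.05) -> DMRTResult:
    """Duncan's multiple range test letter display.

    Means are ranked in descending order; a pair ``span`` ranks apart
    differs significantly when its difference exceeds the Duncan critical
    range R_span.  Letters are built by the insert-and-absorb procedure on
    maximal homogeneous runs of consecutive ranked means (a run is
    homogeneous when *every* pair inside it is non-significant), so groups
    sharing any letter never differ by more than the applicable R_p.
    """
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    if mse <= 0 or df_error < 1 or n_per_group <= 0:
        raise ValueError("invalid mse / df_error / n_per_group")
    names = sorted(means, key=lambda k: -means[k])
    m = np.array([means[k] for k in names])
    g = len(names)
    crit = {p: duncan_critical_range(p, df_error, mse, n_per_group, alpha)
            for p in range(2, g + 1)}

    def significant(i: int, j: int) -> bool:
        return abs(m[i] - m[j]) > crit[abs(j - i) + 1]

    # maximal homogeneous intervals [i, end(i)]
    intervals: list[tuple[int, int]] = []
    for i in range(g):
        end = i
        for j in range(i + 1, g):
            if any(significant(a, j) for a in range(i, j)):
                break
            end = j
        intervals.append((i, end))
    # absorb intervals contained in an earlier one
    maximal: list[tuple[int, int]] = []
    for iv in intervals:
        if not maximal or iv[1] > maximal[-1][1]:
            maximal.append(iv)

    letters = [""] * g
    for letter_idx, (lo, hi) in enumerate(maximal):
        ch = _letter(letter_idx)
        for i in range(lo, hi + 1):
            letters[i] += ch

    out = pd.DataFrame({"mean": m, "rank": np.arange(1, g + 1),
                        "letters": letters}, index=pd.Index(names, name="group"))
    return DMRTResult(groups=out, alpha=alpha, mse=mse, df_error=df_error,
                      n_per_group=n_per_group)


def _letter(i: int) -> str:
    """a, b, ..., z, aa, ab, ... for pathological many-group displays."""
    s = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        s = chr(ord("a") + r) + s
    return s
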