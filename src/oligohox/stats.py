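"""Cohort-level statistics and rule-based genomic/clinical calls.

This module is the single statistics surface used by every other stage:
survival tests (log-rank, Cox proportional hazards with VIF-based collinearity
screening), categorical and continuous tests (Fisher exact, Mann-Whitney U,
Pearson), Benjamini-Hochberg FDR, normality/unimodality checks, and the
rule-based calls for chromosome 15q loss, CDKN2A homozygous deletion and
adjuvant-therapy labelling.

Conventions
-----------
* Survival times are in years, events are booleans (True = death observed).
* All tests delegate to lifelines / scipy / statsmodels; this module only adds
  the contracts (input validation, VIF screening, tie handling policy) that
  the pipeline relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalResult",
    "logrank_test",
    "cox_ph",
    "fisher_exact",
    "mann_whitney",
    "pearson",
    "bh_fdr",
    "dip_statistic",
    "normality_unimodality",
    "call_15q_loss",
    "call_cdkn2a_homdel",
    "label_adjuvant",
]


@dataclass
class SurvivalResult:
    """Outcome of a survival test or Cox fit.

    ``hazard_ratios`` maps covariate name -> (HR, CI low, CI high, p); it is
    empty for the log-rank test.  ``dropped`` maps covariate name -> the VIF
    it had when removed by the collinearity screen.
    """

    statistic: float
    p: float
    n_per_group: dict = field(default_factory=dict)
    hazard_ratios: dict = field(default_factory=dict)
    dropped: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def logrank_test(times, events, groups) -> SurvivalResult:
    """Two-group log-rank test (chi-square with 1 df).

    ``groups`` may hold any two distinct labels; at least one event is
    required overall and both groups must be non-empty.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {len(labels)}")
    a = groups == labels[0]
    if a.all() or (~a).all():
        raise ValueError("one group is empty")
    if not events.any():
        raise ValueError("no events observed")
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return SurvivalResult(
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        n_per_group={str(labels[0]): int(a.sum()), str(labels[1]): int((~a).sum())},
    )


def variance_inflation(design: pd.DataFrame) -> pd.Series:
    """VIF per column via auxiliary OLS regressions (with intercept).

    A column perfectly predicted by the others gets ``inf``.
    """
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    out = {}
    for j, name in enumerate(design.columns):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0.0:
            out[name] = np.inf  # constant column: degenerate by convention
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, dtype=float)


def cox_ph(times, events, covariates: pd.DataFrame, vif_threshold: float = 10.0) -> SurvivalResult:
    """Cox proportional-hazards fit with VIF > threshold covariates dropped.

    Covariates are screened iteratively: while any VIF exceeds the threshold
    the worst offender is removed (and reported), then the model is fit by
    partial likelihood with Efron handling of tied event times.
    """
    cov = covariates.astype(float).copy()
    if cov.shape[1] == 0:
        raise ValueError("no covariates supplied")
    dropped: dict = {}
    while cov.shape[1] > 1:
        vifs = variance_inflation(cov)
        worst = vifs.idxmax()
        if vifs[worst] <= vif_threshold:
            break
        dropped[worst] = float(vifs[worst])
        cov = cov.drop(columns=[worst])
    if cov.shape[1] == 0:
        raise ValueError("all covariates removed by VIF screen")
    events = np.asarray(events, dtype=bool)
    if events.sum() < cov.shape[1]:
        raise ValueError("fewer events than covariates")
    df = cov.copy()
    df["__time"] = np.asarray(times, dtype=float)
    df["__event"] = events.astype(int)
    fitter = CoxPHFitter()
    fitter.fit(df, duration_col="__time", event_col="__event")
    summ = fitter.summary
    hrs = {
        str(name): (
            float(row["exp(coef)"]),
            float(row["exp(coef) lower 95%"]),
            float(row["exp(coef) upper 95%"]),
            float(row["p"]),
        )
        for name, row in summ.iterrows()
    }
    stat = float(fitter.log_likelihood_ratio_test().test_statistic)
    p = float(summ["p"].min())
    return SurvivalResult(
        statistic=stat,
        p=p,
        n_per_group={"n": int(len(df)), "events": int(events.sum())},
        hazard_ratios=hrs,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# categorical / continuous tests
# ---------------------------------------------------------------------------

def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    Two-sided means the enumeration definition: the sum of hypergeometric
    probabilities of all tables (at fixed margins) no more probable than the
    observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and np.any(t != np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative")
    return float(sps.fisher_exact(t.astype(int), alternative="two-sided")[1])


_EXACT_U_CUTOFF = 25


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.  Exact null distribution below a size
    cutoff (both samples <= 25, no ties); normal approximation with tie
    correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= _EXACT_U_CUTOFF and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and its t-transform p; (nan, nan) for degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0.0 or np.std(y) == 0.0:
        return (math.nan, math.nan)
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are passed through as NaN and excluded from the correction.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# normality / unimodality
# ---------------------------------------------------------------------------

def dip_statistic(x) -> float:
    """Dip statistic: sup-distance of the empirical CDF from the nearest
    unimodal CDF (convex left of the mode, concave right of it).

    For each candidate mode position the best convex (resp. concave) fit on
    the left (resp. right) is obtained from the greatest convex minorant
    (least concave majorant) of the ECDF, whose maximal gap, halved, is the
    sup-distance to the convex (concave) cone.  The dip is the minimum over
    mode positions of the larger of the two side distances.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    if n < 4 or xs[0] == xs[-1]:
        return math.nan
    # break exact ties so the hull abscissae are strictly increasing
    if len(np.unique(xs)) < n:
        span = xs[-1] - xs[0]
        xs = xs + np.arange(n) * (span * 1e-9 / n)
    F = (np.arange(1, n + 1) - 0.5) / n

    def _side_dists(px: np.ndarray, py: np.ndarray) -> np.ndarray:
        """dist[j] = sup-distance of (px, py)[0..j] from the convex cone."""
        dists = np.empty(len(px))
        hull: list[int] = []
        for j in range(len(px)):
            while len(hull) >= 2:
                i1, i2 = hull[-2], hull[-1]
                cross = (px[i2] - px[i1]) * (py[j] - py[i1]) - (py[i2] - py[i1]) * (px[j] - px[i1])
                if cross <= 0:
                    hull.pop()
                else:
                    break
            hull.append(j)
            hx = px[hull]
            hy = py[hull]
            gcm = np.interp(px[: j + 1], hx, hy)
            dists[j] = 0.5 * float(np.max(py[: j + 1] - gcm))
        return dists

    left = _side_dists(xs, F)
    # right side: reflect so the LCM problem becomes a GCM problem
    right = _side_dists((-xs)[::-1], (-F)[::-1])[::-1]
    return float(np.min(np.maximum(left, right)))


_DIP_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def normality_unimodality(x, n_null: int = 200, seed: int = 0) -> tuple[float, float]:
    """(Shapiro-Wilk p, dip-test p) for a sample of n >= 8 values.

    The dip p-value is calibrated by Monte Carlo against uniform samples of
    the same size (``n_null`` draws, cached per size/seed).  Constant input
    yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 observations")
    if np.all(x == x[0]):
        return (math.nan, math.nan)
    shapiro_p = float(sps.shapiro(x).pvalue)
    d_obs = dip_statistic(x)
    key = (len(x), n_null, seed)
    if key not in _DIP_NULL_CACHE:
        rng = np.random.default_rng(seed)
        _DIP_NULL_CACHE[key] = np.array(
            [dip_statistic(rng.uniform(size=len(x))) for _ in range(n_null)]
        )
    null = _DIP_NULL_CACHE[key]
    dip_p = float((1 + np.sum(null >= d_obs)) / (1 + len(null)))
    return (shapiro_p, dip_p)


# ---------------------------------------------------------------------------
# rule-based genomic / clinical calls
# ---------------------------------------------------------------------------

def call_15q_loss(gene_loss_flags) -> bool:
    """Arm-level 15q loss: strictly more than half of 15q genes lost."""
    flags = np.asarray(gene_loss_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("no genes on 15q supplied")
    return bool(flags.mean() > 0.5)


def call_cdkn2a_homdel(gistic_scores) -> bool:
    """CDKN2A homozygous deletion: GISTIC score of -2 in >= 2 of 3 call sets."""
    s = np.asarray(gistic_scores)
    if s.shape != (3,):
        raise ValueError("exactly three GISTIC scores required")
    return bool(np.sum(s == -2) >= 2)


ADJUVANT_CUTOFF_DAYS = 244  # 8 months at 30.5 days/month; config-overridable


def label_adjuvant(records: pd.DataFrame, cutoff_days: int = ADJUVANT_CUTOFF_DAYS) -> pd.DataFrame:
    """Per-patient adjuvant chemo / radiotherapy flags from treatment records.

    ``records`` columns: patient_id, modality ('chemo'|'rt'), regimen_label,
    start_day (days since diagnosis, may be NaN), order_index (1 = first
    treatment).  A record is adjuvant if its regimen label is "ADJUVANT", or
    if it started within ``cutoff_days`` of diagnosis and was the first
    treatment administered.  A patient with neither a label nor a start day
    on any record of a modality is left unlabeled (pd.NA), never False.
    """
    need = {"patient_id", "modality", "regimen_label", "start_day", "order_index"}
    if not need.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(need)}")
    if (records["start_day"].dropna() < 0).any():
        raise ValueError("start_day must be non-negative")
    out = {}
    for (pid, modality), grp in records.groupby(["patient_id", "modality"]):
        labeled = grp["regimen_label"].astype("string").str.upper() == "ADJUVANT"
        timed = grp["start_day"].notna()
        if not labeled.any() and not timed.any():
            flag = pd.NA
        else:
            by_time = (
                (grp["start_day"] <= cutoff_days) & (grp["order_index"] == 1)
            ).fillna(False)
            flag = bool((labeled.fillna(False) | by_time).any())
        out.setdefault(pid, {})[f"adjuvant_{modality}"] = flag
    return pd.DataFrame.from_dict(out, orient="index").sort_index()
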