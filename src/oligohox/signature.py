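"""HOXD12 gene-body methylation signature.

The signature is the arithmetic mean of the beta values of the three probes in
the gene body of HOXD12 (cg23130254, cg03964958, cg03371669).  A cohort-level
hypermethylation threshold is the midpoint of the mean signature in the
expression-negative and expression-positive groups; a sample strictly above
the threshold is called hypermethylated.  Probe screening reproduces the
three-way filter used to select the signature probes: each candidate probe
must show an age association, a univariate survival association, and a
multivariate survival association (adjusting for age and grade), all at
p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as cstats
from .core import MethylationMatrix
from .synthetic import SIGNATURE_PROBES

__all__ = [
    "SIGNATURE_PROBES",
    "ProbeScreenResult",
    "correlate_probes_with_expression",
    "screen_probes",
    "signature_value",
    "derive_threshold",
    "truncate4",
    "call_hypermethylation",
    "call_expression_status",
    "signature_calls",
]


@dataclass
class ProbeScreenResult:
    """Per-probe screening report; ``passed`` iff all three p-values < 0.05."""

    table: pd.DataFrame  # columns: age_p, surv_p, multiv_p, passed, reason

    @property
    def passed_probes(self) -> pd.Index:
        return self.table.index[self.table["passed"]]


def correlate_probes_with_expression(
    meth: MethylationMatrix, expression: pd.Series, probes=None
) -> pd.DataFrame:
    """Pearson correlation of each probe's beta with per-sample expression.

    Returns a DataFrame (r, p, n) indexed by probe; degenerate probes (or
    constant expression, or < 3 paired samples) get NaN rather than a silent
    zero.
    """
    probes = meth.probe_ids if probes is None else pd.Index(probes)
    expr = expression.reindex(meth.sample_ids)
    out = []
    for pid in probes:
        b = meth.beta[pid]
        mask = b.notna() & expr.notna()
        n = int(mask.sum())
        if n < 3:
            out.append((math.nan, math.nan, n))
            continue
        r, p = cstats.pearson(b[mask].to_numpy(), expr[mask].to_numpy())
        out.append((r, p, n))
    return pd.DataFrame(out, index=probes, columns=["r", "p", "n"])


def screen_probes(
    meth: MethylationMatrix,
    clinical: pd.DataFrame,
    probes=None,
    alpha: float = 0.05,
) -> ProbeScreenResult:
    """Three-way probe screen: age, univariate survival, multivariate survival.

    Each probe is dichotomized at its cohort median (the same elevated/low
    convention used for expression): the age test is Mann-Whitney between the
    two probe groups, the survival test is log-rank, and the multivariate
    test enters the continuous beta into a Cox model adjusting for age and
    grade.  ``clinical`` must carry age, grade, os_years, os_event.
    """
    probes = meth.probe_ids if probes is None else pd.Index(probes)
    need = {"age", "grade", "os_years", "os_event"}
    if not need.issubset(clinical.columns):
        raise ValueError(f"clinical table must have columns {sorted(need)}")
    clin = clinical.loc[meth.sample_ids]
    rows = []
    for pid in probes:
        b = meth.beta[pid].to_numpy(dtype=float)
        med = np.nanmedian(b)
        hi = b > med
        if hi.all() or (~hi).all():
            rows.append((math.nan, math.nan, math.nan, False, "degenerate"))
            continue
        _, age_p = cstats.mann_whitney(clin["age"][hi], clin["age"][~hi])
        try:
            surv = cstats.logrank_test(clin["os_years"], clin["os_event"], hi)
            surv_p = surv.p
        except ValueError:
            rows.append((age_p, math.nan, math.nan, False, "no-events"))
            continue
        cov = pd.DataFrame(
            {"beta": b, "age": clin["age"].to_numpy(), "grade": clin["grade"].to_numpy()},
            index=clin.index,
        )
        fit = cstats.cox_ph(clin["os_years"], clin["os_event"], cov)
        multiv_p = fit.hazard_ratios["beta"][3] if "beta" in fit.hazard_ratios else math.nan
        passed = bool(age_p < alpha and surv_p < alpha and multiv_p < alpha)
        rows.append((age_p, surv_p, multiv_p, passed, ""))
    table = pd.DataFrame(
        rows, index=probes, columns=["age_p", "surv_p", "multiv_p", "passed", "reason"]
    )
    return ProbeScreenResult(table=table)


def signature_value(sample_betas: pd.Series, probes=SIGNATURE_PROBES) -> float:
    """Mean beta over the three gene-body signature probes for one sample."""
    vals = []
    for pid in probes:
        if pid not in sample_betas.index or pd.isna(sample_betas[pid]):
            raise ValueError(f"signature probe {pid} missing for this sample")
        vals.append(float(sample_betas[pid]))
    return float(np.mean(vals))


def derive_threshold(signatures, expression_status) -> float:
    """Midpoint of the mean signature in the negative and positive groups.

    ``expression_status`` is boolean-like (True = positive/elevated).  Both
    groups must be non-empty.  Full precision is returned; use
    :func:`truncate4` for reporting.
    """
    sig = np.asarray(signatures, dtype=float)
    pos = np.asarray(expression_status, dtype=bool)
    if not pos.any() or pos.all():
        raise ValueError("both status groups must be non-empty")
    mean_neg = float(sig[~pos].mean())
    mean_pos = float(sig[pos].mean())
    return 0.5 * (mean_neg + mean_pos)


def truncate4(x: float) -> float:
    """Truncate (not round) to 4 decimals, the convention used for reporting
    the hypermethylation threshold (0.35775 -> 0.3577)."""
    return math.floor(x * 10_000) / 10_000


def call_hypermethylation(signature: float, threshold: float) -> bool:
    """True iff the signature strictly exceeds the threshold."""
    if not (np.isfinite(signature) and np.isfinite(threshold)):
        raise ValueError("signature and threshold must be finite")
    return bool(signature > threshold)


def call_expression_status(values, gene: str = "HOXD12") -> pd.Series:
    """Elevated/low call per sample: elevated iff TPM strictly above the
    cohort median.  When the median is zero this reduces to 'non-zero'."""
    v = pd.Series(values, dtype=float)
    if (v < 0).any():
        raise ValueError("TPM values must be non-negative")
    med = float(v.median())
    return pd.Series(
        np.where(v > med, "elevated", "low"), index=v.index, name=f"{gene}_status"
    )


def signature_calls(
    meth: MethylationMatrix,
    expression: pd.Series,
    probes=SIGNATURE_PROBES,
) -> pd.DataFrame:
    """Cohort-level convenience wrapper: signature per sample, threshold from
    the expression-status split, and the hyper/hypomethylation call.

    Samples missing any signature probe receive no call (NaN signature,
    <NA> call) rather than an imputed value.
    """
    status = call_expression_status(expression.reindex(meth.sample_ids))
    sigs, calls = [], []
    complete = []
    for sid in meth.sample_ids:
        row = meth.beta.loc[sid]
        try:
            sigs.append(signature_value(row, probes))
            complete.append(True)
        except ValueError:
            sigs.append(math.nan)
            complete.append(False)
    sigs = np.asarray(sigs)
    ok = np.asarray(complete)
    thr = derive_threshold(sigs[ok], (status == "elevated")[ok])
    hyper = pd.array(
        [call_hypermethylation(s, thr) if c else None for s, c in zip(sigs, ok)],
        dtype="boolean",
    )
    return pd.DataFrame(
        {
            "signature": sigs,
            "threshold": thr,
            "threshold_reported": truncate4(thr),
            "hypermethylated": hyper,
            "expression_status": status.to_numpy(),
        },
        index=meth.sample_ids,
    )
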