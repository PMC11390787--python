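"""Pan-HOX methylation: pooling, batch adjustment, consensus clustering.

The analysis pools gene-body probes of HOXA/B/C/D-locus genes across cohorts
(the probe set is the intersection across inputs), adjusts for cohort batch
effects on the logit(beta) scale, and then asks whether samples fall into two
stable methylation clusters.  Stability is assessed by repeating a stochastic
2-D embedding (UMAP with a different random initialization per run) followed
by 2-means clustering of the embedding; per-sample labels are aligned across
runs and a sample's switch frequency is the fraction of runs that disagree
with its majority label.  Samples switching more than 10% of the time are
excluded.  The retained membership drives a probe-level differential
methylation analysis (Welch t on logit(beta), BH-FDR) whose effects are
averaged per HOX gene and per HOX locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from . import stats as cstats
from .core import MethylationMatrix, expit_beta, logit_beta

__all__ = [
    "ConsensusResult",
    "DiffMethResult",
    "pool_hox_body_probes",
    "batch_adjust",
    "align_labels",
    "majority_switch",
    "consensus_cluster",
    "apply_stability_filter",
    "differential_methylation",
]

SWITCH_EXCLUSION = 0.10  # excluded iff switch_freq strictly exceeds this


@dataclass
class ConsensusResult:
    """Per-sample consensus membership with stability diagnostics.

    ``samples`` columns: majority_label ('HOX-high'/'HOX-low'), switch_freq,
    retained.  ``run_labels`` is the aligned 0/1 label matrix
    (samples x runs); label 1 corresponds to HOX-high.
    """

    samples: pd.DataFrame
    run_labels: pd.DataFrame
    params: dict = field(default_factory=dict)


@dataclass
class DiffMethResult:
    probes: pd.DataFrame  # effect (logit-scale mean diff), p, fdr
    genes: pd.DataFrame  # mean effect over member probes
    loci: pd.DataFrame


def pool_hox_body_probes(matrices: list[MethylationMatrix]):
    """Pool cohorts on the intersection of their HOX gene-body probes.

    Returns (pooled MethylationMatrix, batch labels keyed by source matrix
    name).  Raises if no HOX body probe is shared by all inputs.
    """
    if not matrices:
        raise ValueError("at least one matrix required")
    common = None
    for mm in matrices:
        probes = pd.Index(mm.body_probes_for_loci())
        common = probes if common is None else common.intersection(probes)
    if common is None or len(common) == 0:
        raise ValueError("no HOX gene-body probes shared across all inputs")
    common = common.sort_values()
    parts, batches = [], []
    for i, mm in enumerate(matrices):
        name = mm.name if mm.name != "cohort" else f"batch{i}"
        parts.append(mm.beta.loc[:, common])
        batches.extend([name] * len(mm.sample_ids))
    beta = pd.concat(parts, axis=0)
    pooled = MethylationMatrix(
        beta=beta, manifest=matrices[0].manifest.loc[common], name="pooled"
    )
    return pooled, pd.Series(batches, index=beta.index, name="batch")


def batch_adjust(
    pooled: MethylationMatrix,
    batch: pd.Series,
    protected: pd.Series | None = None,
    eps: float = 1e-6,
) -> MethylationMatrix:
    """Location/scale batch adjustment on the logit scale.

    Per probe, each batch's location effect (deviation of the batch mean
    from the grand mean) is removed exactly, and the batch's scale is
    brought to the pooled within-batch scale using an empirical-Bayes
    variance estimate (inverse-gamma moments across probes, ComBat-style).
    Location effects are deliberately not shrunk: the downstream stability
    clustering requires realized between-batch mean differences to vanish,
    and shrinkage would leave each probe's sampling noise in place.  Betas
    are mapped back through the inverse logit, so output stays in (0, 1).
    A single batch is returned unchanged up to the logit round trip.
    """
    batch = batch.loc[pooled.sample_ids]
    levels = pd.unique(batch)
    counts = batch.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"batches with fewer than 2 samples: {bad}")
    if protected is not None:
        confounded = (
            protected.loc[pooled.sample_ids].groupby(batch).nunique().max() == 1
        )
        if confounded and len(levels) > 1:
            warnings.warn(
                "protected covariate is perfectly confounded with batch; "
                "adjustment may remove signal",
                stacklevel=2,
            )
    X = logit_beta(pooled.beta.to_numpy(), eps=eps)
    if len(levels) == 1:
        adj = X
    else:
        adj = X.copy()
        grand = X.mean(axis=0)
        masks = {lev: (batch == lev).to_numpy() for lev in levels}
        # exact per-probe location removal
        for lev, rows in masks.items():
            adj[rows] -= X[rows].mean(axis=0) - grand
        # EB scale equalization toward the pooled within-batch variance
        within = np.vstack([adj[rows].var(axis=0, ddof=1) for rows in masks.values()])
        target = np.maximum(within.mean(axis=0), 1e-12)
        for i, (lev, rows) in enumerate(masks.items()):
            ni = int(rows.sum())
            delta2_hat = np.maximum(within[i] / target, 1e-12)  # variance ratio
            m = delta2_hat.mean()
            v = max(delta2_hat.var(ddof=1), 1e-12)
            a_prior = (2 * v + m**2) / v
            b_prior = (m * v + m**3) / v
            delta2_star = (b_prior + 0.5 * ni * delta2_hat) / (a_prior + ni / 2 - 1)
            delta2_star = np.maximum(delta2_star, 1e-12)
            mu = adj[rows].mean(axis=0)
            adj[rows] = mu + (adj[rows] - mu) / np.sqrt(delta2_star)
    beta_adj = pd.DataFrame(
        expit_beta(adj), index=pooled.sample_ids, columns=pooled.probe_ids
    )
    return MethylationMatrix(beta=beta_adj, manifest=pooled.manifest, name=pooled.name)


def align_labels(labels_run: np.ndarray, labels_reference: np.ndarray) -> np.ndarray:
    """Align a two-cluster labelling with a reference by choosing, of the two
    possible label mappings, the one maximizing agreement."""
    run = np.asarray(labels_run)
    ref = np.asarray(labels_reference)
    if run.shape != ref.shape:
        raise ValueError("label vectors must cover the same samples")
    if len(np.unique(run)) > 2 or len(np.unique(ref)) > 2:
        raise ValueError("alignment is defined for 2 clusters only")
    agree = int((run == ref).sum())
    flipped = 1 - run
    agree_flipped = int((flipped == ref).sum())
    if agree != agree_flipped:
        return run if agree > agree_flipped else flipped
    # tie: both mappings agree equally; break canonically (lexicographically
    # smaller candidate) so alignment is invariant to flipping the input
    for a, b in zip(run, flipped):
        if a != b:
            return run if a < b else flipped
    return run


def majority_switch(aligned_labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Majority label and switch frequency per sample from an aligned
    (samples x runs) 0/1 label matrix.

    The switch frequency is the fraction of runs disagreeing with the
    sample's majority label, so it always lies in [0, 0.5]; an exact tie
    breaks to label 1.
    """
    L = np.asarray(aligned_labels, dtype=int)
    majority = (L.mean(axis=1) >= 0.5).astype(int)
    switch = (L != majority[:, None]).mean(axis=1)
    return majority, switch


def consensus_cluster(
    matrix: MethylationMatrix,
    n_runs: int = 1000,
    base_seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> ConsensusResult:
    """Repeated stochastic embedding + 2-means consensus clustering.

    Each run embeds the beta matrix to 2-D with UMAP (random initialization,
    seed = base_seed + run index) and partitions the embedding by k-means
    with k=2 (10 restarts).  Run labels are aligned to run 0; each sample's
    majority label and switch frequency (fraction of runs disagreeing with
    the majority) are computed, and the >10% switchers are flagged
    non-retained.  Orientation is fixed by the data: HOX-high is the
    majority group with the greater overall mean beta.
    """
    import umap  # deferred: numba JIT import cost

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    X = matrix.beta.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    labels = np.empty((n, n_runs), dtype=int)
    nn = min(n_neighbors, n - 1)
    for r in range(n_runs):
        seed = base_seed + r
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = umap.UMAP(
                n_components=2,
                n_neighbors=nn,
                min_dist=min_dist,
                init="random",
                random_state=seed,
            ).fit_transform(X)
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(emb)
        lab = km.labels_
        labels[:, r] = lab if r == 0 else align_labels(lab, labels[:, 0])
    majority, switch_freq = majority_switch(labels)
    retained = switch_freq <= SWITCH_EXCLUSION

    # orientation: HOX-high = majority group with greater overall mean beta
    mean1 = X[majority == 1].mean() if (majority == 1).any() else -np.inf
    mean0 = X[majority == 0].mean() if (majority == 0).any() else -np.inf
    if mean0 > mean1:
        majority = 1 - majority
        labels = 1 - labels
    names = np.where(majority == 1, "HOX-high", "HOX-low")
    samples = pd.DataFrame(
        {"majority_label": names, "switch_freq": switch_freq, "retained": retained},
        index=matrix.sample_ids,
    )
    run_labels = pd.DataFrame(
        labels, index=matrix.sample_ids, columns=[f"run{r}" for r in range(n_runs)]
    )
    return ConsensusResult(
        samples=samples,
        run_labels=run_labels,
        params={
            "n_runs": n_runs,
            "base_seed": base_seed,
            "n_neighbors": nn,
            "min_dist": min_dist,
            "embedding": "umap",
            "partitioner": "kmeans(k=2, n_init=10)",
        },
    )


def apply_stability_filter(result: ConsensusResult) -> pd.Index:
    """Samples retained by the stability rule (switch_freq <= 0.10; 'more
    than 10%' is a strict exclusion)."""
    s = result.samples
    return s.index[s["switch_freq"] <= SWITCH_EXCLUSION]


def differential_methylation(
    matrix: MethylationMatrix, membership: pd.Series
) -> DiffMethResult:
    """Probe-level Welch t on logit(beta) between the two membership groups.

    The effect is the logit-scale mean difference (group 'HOX-high' minus
    'HOX-low'); per-gene and per-locus summaries are arithmetic means of the
    member-probe effects.  A probe with zero variance in both groups gets
    effect 0 and NaN p.
    """
    membership = membership.loc[matrix.sample_ids]
    groups = pd.unique(membership)
    if len(groups) != 2:
        raise ValueError("membership must have exactly 2 groups")
    hi_name = "HOX-high" if "HOX-high" in set(groups) else groups[0]
    lo_name = [g for g in groups if g != hi_name][0]
    hi = (membership == hi_name).to_numpy()
    if hi.sum() < 2 or (~hi).sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    X = logit_beta(matrix.beta.to_numpy())
    A, B = X[hi], X[~hi]
    effect = A.mean(axis=0) - B.mean(axis=0)
    with np.errstate(all="ignore"):
        t, p = sps.ttest_ind(A, B, axis=0, equal_var=False)
    zero_var = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    effect = np.where(zero_var, 0.0, effect)
    p = np.where(zero_var, np.nan, p)
    fdr = cstats.bh_fdr(p)
    probes = pd.DataFrame(
        {"effect": effect, "p": p, "fdr": fdr}, index=matrix.probe_ids
    )
    gene = matrix.manifest.loc[matrix.probe_ids, "gene"]
    locus = gene.str.slice(0, 4)
    genes = probes["effect"].groupby(gene).mean().to_frame("effect")
    loci = probes["effect"].groupby(locus).mean().to_frame("effect")
    genes["n_probes"] = probes.groupby(gene).size()
    loci["n_probes"] = probes.groupby(locus).size()
    return DiffMethResult(probes=probes, genes=genes, loci=loci)
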