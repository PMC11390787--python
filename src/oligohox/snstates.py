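"""Single-nucleus neoplastic calling and cell-state assignment.

Pipeline: cluster nuclei on normalized expression (PCA + k-means); infer
arm-level relative dosage against reference clusters using meta-cells and a
sliding genomic window (a simplified inferred-copy-number procedure); call a
cluster neoplastic only when the 1p/19q codeletion pattern (1p and 19q lost,
1q and 19p intact) is universal across its meta-cells, non-neoplastic when it
is universally absent, and excluded otherwise; assign cell types to
non-neoplastic clusters by marker panels; score neoplastic nuclei against
cell-state gene programs using bin-matched control genes; and assign each
nucleus the state with the lowest permutation-test FDR when that FDR falls
below 0.05 / (number of states) = 0.0125, otherwise the state "gradient".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import stats as cstats

log = logging.getLogger(__name__)

__all__ = [
    "ArmDosageProfile",
    "cluster_nuclei",
    "normalize_log",
    "infer_arm_dosage",
    "call_compartments",
    "assign_cell_types",
    "relative_program_score",
    "permutation_state_test",
    "assign_state",
    "stemness_lineage_scores",
    "compare_marker_prevalence",
    "annotate_nuclei",
]

STATE_ALPHA = 0.0125  # 0.05 / 4 cell states
STATE_ORDER = ("OPC-like", "Astro-like", "Cycling", "RE")
CODELETION_ARMS = {"loss": ("1p", "19q"), "intact": ("1q", "19p")}

MARKER_PANELS = {
    "neuron": ["RBFOX3"],
    "oligodendrocyte": ["MBP", "MOG", "CNP"],
    "astrocyte": ["SLC1A2", "GFAP", "AQP4", "ALDH1L1"],
    "microglia": ["PTPRC", "CD163", "CD14"],
}


def normalize_log(counts: sparse.spmatrix, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalize each nucleus to ``target_sum`` and log1p."""
    C = counts.tocsr().astype(float)
    totals = np.asarray(C.sum(axis=1)).ravel()
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    X = C.multiply(scale[:, None]).toarray()
    return np.log1p(X)


def cluster_nuclei(
    counts: sparse.spmatrix,
    n_clusters: int = 10,
    n_pcs: int = 30,
    seed: int = 0,
):
    """Cluster nuclei: normalize, log, PCA, k-means.

    All-zero nuclei are dropped (logged).  Returns (labels Series indexed by
    row position of the kept nuclei, 2-D embedding array, kept row mask).
    """
    totals = np.asarray(counts.sum(axis=1)).ravel()
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d all-zero nuclei", n_dropped)
    if keep.sum() < 50:
        raise ValueError("need at least 50 non-empty nuclei")
    X = normalize_log(counts.tocsr()[keep])
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(pcs)
    return km.labels_, pcs[:, :2], keep


@dataclass
class ArmDosageProfile:
    """Arm-level relative dosage per cluster.

    ``meta_scores``: DataFrame (meta-cell x arm) of mean smoothed log-ratios;
    ``meta_cluster``: cluster id per meta-cell; ``cluster_calls``: DataFrame
    (cluster x arm) of 'loss'/'intact'/'gain'; ``codeletion_fraction``:
    per-cluster fraction of meta-cells with the full 1p/19q codeletion
    pattern.
    """

    meta_scores: pd.DataFrame
    meta_cluster: pd.Series
    cluster_calls: pd.DataFrame
    codeletion_fraction: pd.Series
    params: dict = field(default_factory=dict)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    w = min(w, len(x))
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad : pad + len(x)]
    return out


def infer_arm_dosage(
    counts: sparse.spmatrix,
    clusters: np.ndarray,
    reference_clusters,
    features: pd.DataFrame,
    window: int = 51,
    metacell_size: int = 25,
    tau: float = 0.15,
    min_ref_mean: float = 2.0,
    clip: float = 1.5,
    seed: int = 0,
) -> ArmDosageProfile:
    """Windowed arm-level log-ratio dosage against reference clusters.

    Meta-cells are averages of up to ``metacell_size`` nuclei within a
    cluster (random partition, seeded).  Per gene the natural-log ratio of
    meta-cell normalized expression to the reference mean is clipped to
    ±``clip`` and smoothed along genomic order per chromosome with a centered
    moving average of ``window`` genes (shrunk, with a log entry, on arms
    with fewer genes).  The arm score is the mean smoothed value over the
    arm; calls are loss (< -tau), gain (> +tau), else intact.  Genes with a
    reference mean below ``min_ref_mean`` (normalized units) are excluded
    from the ratio, since near-zero denominators carry no dosage signal.
    """
    reference_clusters = list(reference_clusters)
    if not reference_clusters:
        raise ValueError("reference clusters must be non-empty")
    rng = np.random.default_rng(seed)
    feats = features.copy()
    order = feats.sort_values(["chrom", "start"]).index
    gene_pos = {g: i for i, g in enumerate(features.index)}
    col_order = np.array([gene_pos[g] for g in order])

    C = counts.tocsr().astype(float)
    totals = np.asarray(C.sum(axis=1)).ravel()
    scale = np.divide(1e4, totals, out=np.zeros_like(totals), where=totals > 0)
    N = C.multiply(scale[:, None]).toarray()[:, col_order]
    feats = feats.loc[order]

    clusters = np.asarray(clusters)
    meta_profiles, meta_cl = [], []
    for cl in pd.unique(clusters):
        idx = np.flatnonzero(clusters == cl)
        idx = rng.permutation(idx)
        n_groups = max(1, len(idx) // metacell_size)
        for grp in np.array_split(idx, n_groups):
            meta_profiles.append(N[grp].mean(axis=0))
            meta_cl.append(cl)
    M = np.vstack(meta_profiles)
    meta_cl = np.asarray(meta_cl)

    ref_rows = np.isin(meta_cl, reference_clusters)
    if not ref_rows.any():
        raise ValueError("no meta-cells in reference clusters")
    ref_mean = M[ref_rows].mean(axis=0)
    expressed = ref_mean >= min_ref_mean
    if not expressed.any():
        raise ValueError("no gene passes the reference expression floor")

    rel = np.clip(
        np.log((M[:, expressed] + 0.05) / (ref_mean[expressed] + 0.05)), -clip, clip
    )
    # anchor the zero point per gene on the reference meta-cells (cancels
    # pseudocount and composition biases), then re-center each meta-cell by
    # its median log-ratio: library-size normalization inflates the
    # non-deleted arms of dosage-altered cells and the median removes that
    # global shift
    rel = rel - rel[ref_rows].mean(axis=0, keepdims=True)
    rel = rel - np.median(rel, axis=1, keepdims=True)
    sub = feats.loc[expressed]
    arms = sub["arm"].to_numpy()
    arm_names = pd.unique(arms)
    smoothed = np.empty_like(rel)
    for arm in arm_names:
        cols = np.flatnonzero(arms == arm)
        w = min(window, len(cols))
        if w < window:
            log.info("arm %s has %d genes; window shrunk to %d", arm, len(cols), w)
        for i in range(rel.shape[0]):
            smoothed[i, cols] = _moving_average(rel[i, cols], w)

    scores = pd.DataFrame(
        {arm: smoothed[:, arms == arm].mean(axis=1) for arm in arm_names}
    )
    # arm-level recentering: with most arms copy-neutral, the median arm
    # score estimates the residual global offset of each meta-cell
    scores = scores.sub(scores.median(axis=1), axis=0)
    calls_rows = {}
    codel = {}
    meta_codel = _codeletion_mask(scores, tau)
    for cl in pd.unique(meta_cl):
        rows = meta_cl == cl
        mean_scores = scores[rows].mean(axis=0)
        calls_rows[cl] = {
            arm: ("loss" if s < -tau else "gain" if s > tau else "intact")
            for arm, s in mean_scores.items()
        }
        codel[cl] = float(meta_codel[rows].mean())
    return ArmDosageProfile(
        meta_scores=scores,
        meta_cluster=pd.Series(meta_cl, name="cluster"),
        cluster_calls=pd.DataFrame.from_dict(calls_rows, orient="index"),
        codeletion_fraction=pd.Series(codel, name="codeletion_fraction"),
        params={"window": window, "metacell_size": metacell_size, "tau": tau},
    )


def _codeletion_mask(scores: pd.DataFrame, tau: float) -> np.ndarray:
    """Per-meta-cell boolean: 1p and 19q lost AND 1q and 19p intact."""
    ok = np.ones(len(scores), dtype=bool)
    for arm in CODELETION_ARMS["loss"]:
        ok &= (scores[arm] < -tau).to_numpy() if arm in scores else False
    for arm in CODELETION_ARMS["intact"]:
        ok &= (scores[arm].abs() <= tau).to_numpy() if arm in scores else False
    return ok


def call_compartments(profile: ArmDosageProfile, universality: float = 0.95) -> pd.Series:
    """Per-cluster compartment from the codeletion fraction.

    neoplastic if the codeletion pattern holds in >= ``universality`` of the
    cluster's meta-cells, non-neoplastic if in <= 1 - universality, excluded
    otherwise (codeletion evidence not universal either way).
    """
    f = profile.codeletion_fraction
    out = pd.Series("excluded", index=f.index, dtype=object, name="compartment")
    out[f >= universality] = "neoplastic"
    out[f <= 1.0 - universality] = "non-neoplastic"
    return out


def assign_cell_types(
    lognorm: np.ndarray,
    genes: pd.Index,
    clusters: np.ndarray,
    target_clusters=None,
    panels: dict | None = None,
    margin: float = 0.25,
) -> pd.Series:
    """Marker-panel cell typing of clusters.

    Per cluster, each panel's score is the mean (over panel genes present) of
    the cluster-level z-scored mean expression; the argmax panel is assigned
    if it beats the runner-up by ``margin`` (in sd units), else 'unassigned'.
    Missing marker genes are logged, not fatal; all panels absent is an
    error.
    """
    panels = dict(MARKER_PANELS) if panels is None else panels
    clusters = np.asarray(clusters)
    cl_ids = pd.unique(clusters) if target_clusters is None else list(target_clusters)
    gene_loc = {g: i for i, g in enumerate(genes)}
    present_panels = {}
    for name, gene_set in panels.items():
        hit = [g for g in gene_set if g in gene_loc]
        missing = set(gene_set) - set(hit)
        if missing:
            log.info("panel %s missing markers: %s", name, sorted(missing))
        if hit:
            present_panels[name] = hit
    if not present_panels:
        raise ValueError("no marker panel has any gene present")
    # cluster mean expression, scaled per gene by the nucleus-level sd so a
    # near-flat gene cannot produce a large panel score
    all_cl = pd.unique(clusters)
    means = np.vstack([lognorm[clusters == cl].mean(axis=0) for cl in all_cl])
    mu = means.mean(axis=0)
    sd = lognorm.std(axis=0)
    sd[sd == 0] = 1.0
    z = (means - mu) / sd
    zrow = {cl: z[i] for i, cl in enumerate(all_cl)}
    out = {}
    for cl in cl_ids:
        scores = {
            name: float(np.mean([zrow[cl][gene_loc[g]] for g in hit]))
            for name, hit in present_panels.items()
        }
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        if len(ranked) == 1 or ranked[0][1] - ranked[1][1] >= margin:
            out[cl] = ranked[0][0]
        else:
            out[cl] = "unassigned"
    return pd.Series(out, name="cell_type")


# ---------------------------------------------------------------------------
# program scoring and the permutation test
# ---------------------------------------------------------------------------

def _bin_genes(aggregate: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-size expression bins (by rank of aggregate expression)."""
    order = np.argsort(aggregate, kind="stable")
    bins = np.empty(len(aggregate), dtype=int)
    bins[order] = np.minimum(
        (np.arange(len(aggregate)) * n_bins) // len(aggregate), n_bins - 1
    )
    return bins


def relative_program_score(
    lognorm: np.ndarray,
    genes: pd.Index,
    gene_set,
    n_bins: int = 25,
    controls_per_gene: int = 100,
    seed: int = 0,
    _prepared=None,
) -> np.ndarray:
    """Bin-matched relative program score per nucleus.

    Genes are binned into ``n_bins`` bins of aggregate expression; for each
    program gene, ``controls_per_gene`` control genes are drawn from its bin;
    the score is mean centered expression of the program genes minus mean
    centered expression of the controls (centering = subtracting each gene's
    mean across nuclei).
    """
    if _prepared is None:
        _prepared = prepare_scoring(lognorm, genes, n_bins)
    centered, bins, gene_loc = _prepared
    idx = [gene_loc[g] for g in gene_set if g in gene_loc]
    if not idx:
        raise ValueError("gene set has no overlap with features")
    rng = np.random.default_rng(seed)
    ctrl = []
    for gi in idx:
        pool = np.flatnonzero(bins == bins[gi])
        ctrl.append(rng.choice(pool, size=controls_per_gene, replace=True))
    ctrl = np.concatenate(ctrl)
    return centered[:, idx].mean(axis=1) - centered[:, ctrl].mean(axis=1)


def prepare_scoring(lognorm: np.ndarray, genes: pd.Index, n_bins: int = 25):
    """Precompute (centered matrix, bins, gene index) for repeated scoring."""
    centered = lognorm - lognorm.mean(axis=0, keepdims=True)
    bins = _bin_genes(lognorm.mean(axis=0), n_bins)
    gene_loc = {g: i for i, g in enumerate(genes)}
    return centered, bins, gene_loc


def permutation_state_test(
    lognorm: np.ndarray,
    genes: pd.Index,
    program_sets: dict,
    n_perm: int = 100_000,
    n_bins: int = 25,
    controls_per_gene: int = 100,
    seed: int = 0,
    chunk: int = 256,
):
    """Observed score, permutation p and BH-FDR per (nucleus, state).

    Null scores are generated from ``n_perm`` random gene sets matched in
    size and bin composition to the program set (each null score is the
    bin-matched difference-of-means statistic of a random set).  The p-value
    uses the add-one correction p = (1 + #{null >= obs}) / (1 + n_perm), so
    its attainable floor is 1/(n_perm+1) — about 1e-5 at 100,000
    permutations.  FDR is BH across the full nucleus x state grid.

    Returns (scores, pvals, fdrs), each a DataFrame nuclei x states.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    prepared = prepare_scoring(lognorm, genes, n_bins)
    centered, bins, gene_loc = prepared
    n = centered.shape[0]
    rng = np.random.default_rng(seed)
    scores = {}
    pvals = {}
    for state, gene_set in program_sets.items():
        obs = relative_program_score(
            lognorm, genes, gene_set,
            n_bins=n_bins, controls_per_gene=controls_per_gene,
            seed=seed, _prepared=prepared,
        )
        idx = [gene_loc[g] for g in gene_set if g in gene_loc]
        bin_of = bins[idx]
        total = len(idx)
        bin_counts = pd.Series(bin_of).value_counts().to_dict()
        pools = {b: np.flatnonzero(bins == b) for b in bin_counts}
        exceed = np.zeros(n, dtype=np.int64)
        done = 0
        while done < n_perm:
            k = min(chunk, n_perm - done)
            # each permutation draws a random gene set matched in bin
            # composition plus a bin-matched control draw; with-replacement
            # sampling is realized via multinomial count weights per bin
            set_sum = np.zeros((n, k))
            ctrl_sum = np.zeros((n, k))
            for b, c_b in bin_counts.items():
                pool = pools[b]
                probs = np.full(len(pool), 1.0 / len(pool))
                w_set = rng.multinomial(c_b, probs, size=k).T.astype(float)
                w_ctrl = rng.multinomial(
                    c_b * controls_per_gene, probs, size=k
                ).T.astype(float)
                block = centered[:, pool]
                set_sum += block @ w_set
                ctrl_sum += block @ w_ctrl
            null = set_sum / total - ctrl_sum / (total * controls_per_gene)
            exceed += (null >= obs[:, None]).sum(axis=1)
            done += k
        scores[state] = obs
        pvals[state] = (1.0 + exceed) / (1.0 + n_perm)
    scores = pd.DataFrame(scores)
    pvals = pd.DataFrame(pvals)
    flat = cstats.bh_fdr(pvals.to_numpy().ravel())
    fdrs = pd.DataFrame(
        flat.reshape(pvals.shape), index=pvals.index, columns=pvals.columns
    )
    return scores, pvals, fdrs


def assign_state(
    fdrs: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    alpha: float = STATE_ALPHA,
) -> pd.Series:
    """State per nucleus: argmin-FDR state when min FDR < alpha, else
    'gradient'.  FDR ties break by larger observed score, then by the fixed
    state order OPC-like, Astro-like, Cycling, RE."""
    states = [s for s in STATE_ORDER if s in fdrs.columns] + [
        s for s in fdrs.columns if s not in STATE_ORDER
    ]
    F = fdrs[states].to_numpy()
    S = scores[states].to_numpy() if scores is not None else np.zeros_like(F)
    out = []
    for i in range(F.shape[0]):
        fmin = np.nanmin(F[i])
        if not (fmin < alpha):
            out.append("gradient")
            continue
        tied = np.flatnonzero(F[i] == fmin)
        best = tied[np.argmax(S[i, tied])]
        out.append(states[best])
    return pd.Series(out, index=fdrs.index, name="state")


def stemness_lineage_scores(
    lognorm: np.ndarray,
    genes: pd.Index,
    lineage_sets: dict,
    n_bins: int = 25,
    controls_per_gene: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """OC, AC and stemness relative program scores per nucleus, plus the
    lineage differential OC_score - AC_score."""
    prepared = prepare_scoring(lognorm, genes, n_bins)
    out = {}
    for name in ("OC", "AC", "stemness"):
        if name not in lineage_sets:
            raise ValueError(f"lineage set {name!r} not configured")
        out[f"{name}_score"] = relative_program_score(
            lognorm, genes, lineage_sets[name],
            n_bins=n_bins, controls_per_gene=controls_per_gene,
            seed=seed, _prepared=prepared,
        )
    df = pd.DataFrame(out)
    df["lineage_differential"] = df["OC_score"] - df["AC_score"]
    return df


def compare_marker_prevalence(
    marker_active: pd.Series,
    grouping: pd.Series,
    scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Pairwise group contrasts of sparse-marker prevalence (Fisher exact)
    and, optionally, of a per-nucleus score (two-sample t).

    ``marker_active`` is boolean per nucleus; ``grouping`` a categorical per
    nucleus.  Every unordered pair of groups yields one row; empty groups are
    skipped with a log entry.  When the marker is never active anywhere the
    contrast is reported with p = 1.
    """
    active = marker_active.astype(bool)
    groups = [g for g in pd.unique(grouping) if (grouping == g).any()]
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            ina = (grouping == a).to_numpy()
            inb = (grouping == b).to_numpy()
            if ina.sum() == 0 or inb.sum() == 0:
                log.info("skipping empty-group contrast %s vs %s", a, b)
                continue
            k_a, n_a = int(active[ina].sum()), int(ina.sum())
            k_b, n_b = int(active[inb].sum()), int(inb.sum())
            table = [[k_a, n_a - k_a], [k_b, n_b - k_b]]
            p_fisher = cstats.fisher_exact(table)
            if scores is not None:
                from scipy import stats as sps

                t, p_t = sps.ttest_ind(
                    scores[ina].to_numpy(), scores[inb].to_numpy(), equal_var=True
                )
            else:
                t, p_t = np.nan, np.nan
            rows.append(
                (a, b, k_a / n_a, k_b / n_b, p_fisher, float(t), float(p_t))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group_a", "group_b", "prevalence_a", "prevalence_b",
            "fisher_p", "t_stat", "t_p",
        ],
    )


# ---------------------------------------------------------------------------
# end-to-end annotation
# ---------------------------------------------------------------------------

def annotate_nuclei(
    counts: sparse.spmatrix,
    features: pd.DataFrame,
    barcodes: pd.Index,
    program_sets: dict,
    lineage_sets: dict | None = None,
    sparse_marker: str | None = None,
    n_clusters: int = 10,
    n_perm: int = 100_000,
    universality: float = 0.95,
    min_state_count: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Full single-nucleus annotation with one reference-update round.

    Clusters nuclei; takes marker-typed clusters as the initial suspected
    non-neoplastic reference for arm-dosage inference; after the first
    codeletion pass, updates the reference to the clusters called
    non-neoplastic and re-infers once; then scores states for neoplastic
    nuclei, runs the permutation test, and assembles one row per nucleus.
    RE nuclei remain assigned but are flagged for exclusion from downstream
    contrasts when fewer than ``min_state_count`` exist.
    """
    labels, emb, keep = cluster_nuclei(counts, n_clusters=n_clusters, seed=seed)
    kept_counts = counts.tocsr()[keep]
    kept_barcodes = barcodes[keep]
    lognorm = normalize_log(kept_counts)
    genes = features.index

    typed = assign_cell_types(lognorm, genes, labels)
    suspected_ref = [cl for cl, t in typed.items() if t != "unassigned"]
    if not suspected_ref:
        suspected_ref = list(pd.unique(labels))
    profile = infer_arm_dosage(
        kept_counts, labels, suspected_ref, features, seed=seed
    )
    comp = call_compartments(profile, universality=universality)
    updated_ref = [cl for cl, c in comp.items() if c == "non-neoplastic"]
    if updated_ref and set(updated_ref) != set(suspected_ref):
        profile = infer_arm_dosage(
            kept_counts, labels, updated_ref, features, seed=seed
        )
        comp = call_compartments(profile, universality=universality)

    compartment = pd.Series(labels).map(comp).to_numpy()
    out = pd.DataFrame(
        {
            "cluster": labels,
            "compartment": compartment,
            "cell_type": "",
            "state": "",
        },
        index=kept_barcodes,
    )
    non_neo = compartment == "non-neoplastic"
    out.loc[non_neo, "cell_type"] = (
        pd.Series(labels[non_neo]).map(typed).fillna("unassigned").to_numpy()
    )

    neo = compartment == "neoplastic"
    if neo.any():
        scores, pvals, fdrs = permutation_state_test(
            lognorm[neo], genes, program_sets, n_perm=n_perm, seed=seed
        )
        state = assign_state(fdrs, scores)
        out.loc[neo, "state"] = state.to_numpy()
        for s in scores.columns:
            out.loc[neo, f"score_{s}"] = scores[s].to_numpy()
            out.loc[neo, f"fdr_{s}"] = fdrs[s].to_numpy()
        if lineage_sets is not None:
            lin = stemness_lineage_scores(lognorm[neo], genes, lineage_sets, seed=seed)
            for c in lin.columns:
                out.loc[neo, c] = lin[c].to_numpy()
        re_count = int((out.loc[neo, "state"] == "RE").sum())
        out["re_excluded_downstream"] = re_count < min_state_count
    if sparse_marker is not None and sparse_marker in genes:
        gi = genes.get_loc(sparse_marker)
        out["sparse_marker_active"] = np.asarray(
            kept_counts[:, gi].todense()
        ).ravel() > 0
    return out
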