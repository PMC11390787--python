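"""Seeded synthetic cohorts with known planted truth.

Three generators emulate the data shapes the pipeline consumes, so every
downstream stage is testable without consortium downloads:

* :func:`gen_bulk_cohort` — a bulk cohort with a bimodal age distribution, a
  binary expression status (the HOXD12-positive / negative stand-in) that is
  age-enriched via a logistic link and survival-associated with a planted
  hazard ratio, three informative gene-body methylation probes and eleven
  weaker flanking probes.
* :func:`gen_panhox` — a multi-batch pan-HOX gene-body beta matrix with two
  planted methylation clusters (offset concentrated on HOXD probes), optional
  additive batch shifts on the logit scale, and a configurable fraction of
  ambiguous samples placed midway between the clusters.
* :func:`gen_snseq` — single-nucleus gene-level counts with planted arm-level
  dosage loss on 1p/19q in neoplastic nuclei, cell-type marker programs,
  neoplastic cell-state programs, and a sparse marker gene whose detection
  probability depends on cell state (the HOXD12 stand-in).

All generators draw from ``numpy.random.default_rng(seed)`` (PCG64), so an
identical truth object yields byte-identical output across runs and
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .core import MethylationMatrix, logit_beta, expit_beta

SIGNATURE_PROBES = ("cg23130254", "cg03964958", "cg03371669")

HOX_GENES = {
    "HOXA": [f"HOXA{i}" for i in (1, 2, 3, 4, 5, 6, 7, 9, 10, 11, 13)],
    "HOXB": [f"HOXB{i}" for i in (1, 2, 3, 4, 5, 6, 7, 8, 9, 13)],
    "HOXC": [f"HOXC{i}" for i in (4, 5, 6, 8, 9, 10, 11, 12, 13)],
    "HOXD": [f"HOXD{i}" for i in (1, 3, 4, 8, 9, 10, 11, 12, 13)],
}
_LOCUS_ARM = {"HOXA": "7p", "HOXB": "17q", "HOXC": "12q", "HOXD": "2q"}


def _beta_draw(rng: np.random.Generator, mean, concentration: float, size) -> np.ndarray:
    """Beta variates parameterized by (mean, concentration)."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-4, 1 - 1e-4)
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a, b, size=size)


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

@dataclass
class BulkCohortTruth:
    """Planted truth for a bulk methylation/expression/survival cohort.

    Defaults encode the study conditions this generator emulates: a bimodal
    patient-age mixture, a positive-status prevalence rising with age, group
    gene-body beta means of 0.3034 (negative) and 0.4121 (positive), a
    hazard ratio of 9.3 for positive status, and a baseline hazard putting
    the positive-group median survival near 2.6 years.
    """

    n: int = 500
    age_means: tuple[float, float] = (38.0, 55.0)
    age_sds: tuple[float, float] = (7.0, 7.0)
    age_weight: float = 0.55  # weight of the younger component
    pos_logistic_slope: float = 0.12  # per year of age
    pos_logistic_intercept: float = -5.64
    body_beta_means: tuple[float, float] = (0.3034, 0.4121)  # (negative, positive)
    beta_concentration: float = 50.0
    survival_hr: float = 9.3
    baseline_hazard: float = 0.0287  # 1/years; positive-group median OS ~2.6 y
    censor_horizon: float = 15.0  # years of administrative follow-up
    grade3_prob_by_status: tuple[float, float] = (0.35, 0.75)
    seed: int = 0

    def validate(self) -> None:
        for p in (self.age_weight, *self.grade3_prob_by_status):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for m in self.body_beta_means:
            if not 0.0 < m < 1.0:
                raise ValueError(f"beta mean {m} outside (0, 1)")
        if self.survival_hr <= 0:
            raise ValueError("survival_hr must be > 0")
        if self.n < 0:
            raise ValueError("n must be >= 0")


def _bulk_manifest() -> pd.DataFrame:
    """14-probe HOXD12 manifest: 3 gene-body signature probes + 11 others."""
    rows = []
    for i, pid in enumerate(SIGNATURE_PROBES):
        rows.append((pid, "HOXD12", "Body", "2q", 176_964_000 + 100 * i))
    regions = ["TSS1500", "TSS1500", "TSS200", "TSS200", "5UTR", "5UTR", "3UTR",
               "3UTR", "TSS1500", "5UTR", "3UTR"]
    for i, region in enumerate(regions):
        rows.append((f"cgSYN{i:04d}", "HOXD12", region, "2q", 176_960_000 + 100 * i))
    return pd.DataFrame(
        rows, columns=["probe_id", "gene", "region", "chrom_arm", "pos"]
    ).set_index("probe_id")


def gen_bulk_cohort(truth: BulkCohortTruth):
    """Generate (clinical table, methylation matrix, expression table).

    The clinical table carries the planted status in ``true_status`` so tests
    can compare recovered calls against truth; a real cohort would not have
    this column.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    n = truth.n
    manifest = _bulk_manifest()
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")

    comp = rng.uniform(size=n) < truth.age_weight
    age = np.where(
        comp,
        rng.normal(truth.age_means[0], truth.age_sds[0], size=n),
        rng.normal(truth.age_means[1], truth.age_sds[1], size=n),
    )
    age = np.clip(age, 18.0, 90.0)

    logit_p = truth.pos_logistic_intercept + truth.pos_logistic_slope * age
    p_pos = expit_beta(logit_p)
    status = rng.uniform(size=n) < p_pos  # True = positive

    # methylation: signature probes track status; 5 weak probes share a small
    # shift, 6 are status-independent
    neg_m, pos_m = truth.body_beta_means
    beta = np.empty((n, len(manifest)))
    for j, pid in enumerate(manifest.index):
        if pid in SIGNATURE_PROBES:
            means = np.where(status, pos_m, neg_m)
        elif j < len(SIGNATURE_PROBES) + 5:
            base = 0.25 + 0.02 * j
            means = np.where(status, base + 0.02, base)
        else:
            means = np.full(n, 0.25 + 0.015 * j)
        beta[:, j] = _beta_draw(rng, means, truth.beta_concentration, n)

    # expression: negatives are exactly zero TPM; positives log-normal
    expr = np.where(status, np.exp(rng.normal(1.0, 0.6, size=n)), 0.0)

    # survival: exponential with planted HR, administrative censoring
    hazard = truth.baseline_hazard * np.where(status, truth.survival_hr, 1.0)
    with np.errstate(divide="ignore"):
        t_event = rng.exponential(1.0, size=n) / hazard
    os_event = t_event <= truth.censor_horizon
    os_time = np.minimum(t_event, truth.censor_horizon)

    grade3_p = np.where(status, *truth.grade3_prob_by_status[::-1])
    grade = np.where(rng.uniform(size=n) < grade3_p, 3, 2)

    # treatment records: first treatment, sometimes labeled ADJUVANT
    start_day = rng.integers(0, 600, size=n).astype(float)
    labeled = rng.uniform(size=n) < 0.3
    regimen = np.where(labeled, "ADJUVANT", "UNLABELED")
    drug = rng.choice(["temozolomide", "procarbazine", "lomustine"], size=n)

    clinical = pd.DataFrame(
        {
            "age": age,
            "grade": grade,
            "os_years": os_time,
            "os_event": os_event,
            "true_status": np.where(status, "positive", "negative"),
            "therapy_regimen": regimen,
            "drug_name": drug,
            "treatment_start_day": start_day,
            "treatment_order": 1,
        },
        index=sample_ids,
    )
    meth = MethylationMatrix(
        beta=pd.DataFrame(beta, index=sample_ids, columns=manifest.index),
        manifest=manifest,
        name="bulk",
    )
    expression = pd.DataFrame({"HOXD12": expr}, index=sample_ids)
    return clinical, meth, expression


# ---------------------------------------------------------------------------
# pan-HOX multi-batch matrix
# ---------------------------------------------------------------------------

@dataclass
class PanHoxTruth:
    """Planted truth for the pooled pan-HOX gene-body matrix.

    Defaults mirror the pooled-cohort conditions the pipeline targets: 422
    gene-body probes shared across batches and two methylation clusters whose
    separation is concentrated on, but not exclusive to, HOXD probes.
    """

    n_per_batch: tuple[int, ...] = (171, 170, 24)
    n_probes: int = 422
    cluster_shift: float = 0.15  # mean beta offset between clusters
    batch_offsets: tuple[float, ...] = (0.0, 0.0, 0.0)  # logit-scale shifts
    ambiguous_fraction: float = 0.0
    high_fraction: float = 0.5  # prevalence of the HOX-high cluster
    base_mean_range: tuple[float, float] = (0.15, 0.45)
    beta_concentration: float = 80.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.ambiguous_fraction < 1.0:
            raise ValueError("ambiguous_fraction must be in [0, 1)")
        if len(self.batch_offsets) != len(self.n_per_batch):
            raise ValueError("one batch offset per batch required")
        if self.n_probes < 1:
            raise ValueError("need at least one probe")


def panhox_manifest(n_probes: int = 422) -> pd.DataFrame:
    """Manifest of ``n_probes`` HOX gene-body probes, cycling over the four
    loci so every probe maps to exactly one gene and one locus."""
    genes = [g for locus in HOX_GENES for g in HOX_GENES[locus]]
    rows = []
    for i in range(n_probes):
        gene = genes[i % len(genes)]
        locus = gene[:4]
        rows.append((f"cgHOX{i:04d}", gene, "Body", _LOCUS_ARM[locus], 1_000 * i))
    return pd.DataFrame(
        rows, columns=["probe_id", "gene", "region", "chrom_arm", "pos"]
    ).set_index("probe_id")


def gen_panhox(truth: PanHoxTruth):
    """Generate (MethylationMatrix, true labels, batch labels).

    True labels are 'high', 'low', or 'ambiguous' (samples interpolated
    midway between the cluster means).
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    manifest = panhox_manifest(truth.n_probes)
    n = int(sum(truth.n_per_batch))

    base = rng.uniform(*truth.base_mean_range, size=truth.n_probes)
    # per-probe offset: concentrated on HOXD body probes but present elsewhere
    is_hoxd = manifest["gene"].str.startswith("HOXD").to_numpy()
    probe_shift = truth.cluster_shift * np.where(is_hoxd, 1.5, 0.85)
    mean_low = np.clip(base, 0.02, 0.98)
    mean_high = np.clip(base + probe_shift, 0.02, 0.98)

    batch = np.concatenate(
        [np.full(k, f"batch{i}") for i, k in enumerate(truth.n_per_batch)]
    )
    labels = np.where(rng.uniform(size=n) < truth.high_fraction, "high", "low")
    n_amb = int(round(truth.ambiguous_fraction * n))
    amb_idx = rng.choice(n, size=n_amb, replace=False)
    labels = labels.astype(object)
    labels[amb_idx] = "ambiguous"

    means = np.where(
        (labels == "high")[:, None],
        mean_high[None, :],
        mean_low[None, :],
    )
    means[labels == "ambiguous"] = 0.5 * (mean_low + mean_high)
    beta = _beta_draw(rng, means, truth.beta_concentration, (n, truth.n_probes))

    offsets = np.concatenate(
        [np.full(k, off) for off, k in zip(truth.batch_offsets, truth.n_per_batch)]
    )
    if np.any(offsets != 0.0):
        beta = expit_beta(logit_beta(beta) + offsets[:, None])
    beta = np.clip(beta, 1e-6, 1 - 1e-6)

    sample_ids = pd.Index([f"P{i:04d}" for i in range(n)], name="sample_id")
    mm = MethylationMatrix(
        beta=pd.DataFrame(beta, index=sample_ids, columns=manifest.index),
        manifest=manifest,
        name="panhox",
    )
    return (
        mm,
        pd.Series(labels, index=sample_ids, name="true_label"),
        pd.Series(batch, index=sample_ids, name="batch"),
    )


# ---------------------------------------------------------------------------
# single-nucleus counts
# ---------------------------------------------------------------------------

CELL_TYPES = ("neoplastic", "oligodendrocyte", "astrocyte", "neuron", "microglia")
CELL_STATES = ("OPC-like", "Astro-like", "Cycling", "RE", "gradient")

MARKER_GENE_SETS = {
    "neuron": ["RBFOX3"],
    "oligodendrocyte": ["MBP", "MOG", "CNP"],
    "astrocyte": ["SLC1A2", "GFAP", "AQP4", "ALDH1L1"],
    "microglia": ["PTPRC", "CD163", "CD14"],
}


def _default_program_sets() -> dict[str, list[str]]:
    return {
        "OPC-like": [f"OPCP{i:03d}" for i in range(30)],
        "Astro-like": [f"ASTP{i:03d}" for i in range(30)],
        "Cycling": [f"CYCP{i:03d}" for i in range(30)],
        "RE": [f"REP{i:03d}" for i in range(30)],
    }


def _default_lineage_sets() -> dict[str, list[str]]:
    return {
        "OC": [f"OCLIN{i:03d}" for i in range(20)],
        "AC": [f"ACLIN{i:03d}" for i in range(20)],
        "stemness": [f"STEM{i:03d}" for i in range(20)],
    }


@dataclass
class SnTruth:
    """Planted truth for a single-nucleus gene-level count matrix."""

    n_nuclei: int = 3000
    type_proportions: dict = field(
        default_factory=lambda: {
            "neoplastic": 0.60,
            "oligodendrocyte": 0.15,
            "astrocyte": 0.08,
            "neuron": 0.07,
            "microglia": 0.10,
        }
    )
    deleted_arm_dosage: float = 0.5  # 1p/19q multiplicative factor, neoplastic
    state_proportions: dict = field(
        default_factory=lambda: {
            "OPC-like": 0.25,
            "Astro-like": 0.30,
            "Cycling": 0.15,
            "RE": 0.05,
            "gradient": 0.25,
        }
    )
    program_gene_sets: dict = field(default_factory=_default_program_sets)
    marker_gene_sets: dict = field(default_factory=lambda: dict(MARKER_GENE_SETS))
    lineage_gene_sets: dict = field(default_factory=_default_lineage_sets)
    sparse_marker: str = "HOXD12"
    sparse_marker_probs: dict = field(
        default_factory=lambda: {
            "Cycling": 0.15,
            "OPC-like": 0.08,
            "Astro-like": 0.02,
            "RE": 0.02,
            "gradient": 0.02,
            "non-neoplastic": 0.005,
        }
    )
    genes_per_arm: int = 250
    n_background_genes: int = 1200  # neutral-arm genes; keeps the 1p/19q share
    # of the transcriptome near a realistic ~15-20%
    type_profile_sd: float = 0.4  # breadth of each cell type's transcriptome
    # signature over background genes (log scale)
    program_upregulation: float = 4.0
    marker_upregulation: float = 8.0
    mean_depth: float = 4000.0
    dispersion: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for props in (self.type_proportions, self.state_proportions):
            if abs(sum(props.values()) - 1.0) > 1e-8:
                raise ValueError("proportions must sum to 1")
        if not 0.0 < self.deleted_arm_dosage <= 1.0:
            raise ValueError("dosage must be in (0, 1]")
        for name, gene_set in {**self.program_gene_sets, **self.marker_gene_sets}.items():
            if self.sparse_marker in gene_set:
                raise ValueError(f"sparse marker may not appear in set {name!r}")


def _sn_features(truth: SnTruth) -> pd.DataFrame:
    """Feature table: arm-resident genes on 1p/1q/19p/19q plus marker,
    program, lineage and sparse-marker genes on neutral arms."""
    rows = []
    for arm, chrom in (("1p", "1"), ("1q", "1"), ("19p", "19"), ("19q", "19")):
        for i in range(truth.genes_per_arm):
            start = (i + 1) * 10_000 + (0 if arm.endswith("p") else 150_000_000)
            rows.append((f"G{arm}_{i:03d}", chrom, start, start + 5000, arm))
    extra = []
    for gs in truth.marker_gene_sets.values():
        extra.extend(gs)
    for gs in truth.program_gene_sets.values():
        extra.extend(gs)
    for gs in truth.lineage_gene_sets.values():
        extra.extend(gs)
    extra.append(truth.sparse_marker)
    neutral = [("2q", "2"), ("7p", "7"), ("12q", "12"), ("17q", "17")]
    for i, g in enumerate(extra):
        arm, chrom = neutral[i % len(neutral)]
        start = (i + 1) * 20_000
        rows.append((g, chrom, start, start + 5000, arm))
    background = [("3p", "3"), ("4q", "4"), ("5q", "5"), ("6p", "6"),
                  ("8q", "8"), ("10q", "10"), ("11p", "11"), ("14q", "14")]
    for i in range(truth.n_background_genes):
        arm, chrom = background[i % len(background)]
        start = (i + 1) * 15_000
        rows.append((f"BG{i:04d}", chrom, start, start + 5000, arm))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "arm"])
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene in feature construction")
    return df.set_index("gene")


def gen_snseq(truth: SnTruth, features: pd.DataFrame | None = None):
    """Generate (sparse counts nuclei x genes, features, barcodes, truth table).

    Neoplastic nuclei have every gene on 1p and 19q scaled by
    ``deleted_arm_dosage`` before count sampling; program genes are
    upregulated in their state; the sparse marker is nonzero with a
    state-specific probability.  A ``features`` table (gene-indexed, columns
    chrom/start/end/arm) may be supplied; every program gene must then
    appear in it.
    """
    truth.validate()
    for state, gene_set in truth.program_gene_sets.items():
        if state not in truth.state_proportions:
            raise ValueError(f"program set for unknown state {state!r}")
    rng = np.random.default_rng(truth.seed)
    if features is None:
        features = _sn_features(truth)
    for name, gene_set in truth.program_gene_sets.items():
        absent = set(gene_set) - set(features.index)
        if absent:
            raise ValueError(f"program genes absent from features: {sorted(absent)[:3]}")
    genes = features.index
    g = len(genes)
    n = truth.n_nuclei

    types = rng.choice(
        list(truth.type_proportions), size=n, p=list(truth.type_proportions.values())
    )
    states = np.full(n, "", dtype=object)
    neo = types == "neoplastic"
    states[neo] = rng.choice(
        list(truth.state_proportions),
        size=int(neo.sum()),
        p=list(truth.state_proportions.values()),
    )

    base = np.exp(rng.normal(0.0, 0.5, size=g))  # relative baseline per gene
    base[features.index.get_loc(truth.sparse_marker)] = 0.0  # sampled separately

    col = {gname: features.index.get_loc(gname) for gname in genes}
    mult = np.ones((n, g))
    # each cell type carries a broad transcriptome signature over background
    # genes, as real brain cell types do, so clustering does not hinge on a
    # handful of markers
    is_bg = np.asarray(genes.str.startswith("BG"))
    if is_bg.any():
        for ctype in truth.type_proportions:
            profile = np.exp(rng.normal(0.0, truth.type_profile_sd, size=int(is_bg.sum())))
            rows_t = types == ctype
            mult[np.ix_(rows_t, is_bg)] *= profile
    on_del = features["arm"].isin(["1p", "19q"]).to_numpy()
    mult[np.ix_(neo, on_del)] *= truth.deleted_arm_dosage
    for ctype, gene_set in truth.marker_gene_sets.items():
        rows_t = types == ctype
        for gname in gene_set:
            mult[rows_t, col[gname]] *= truth.marker_upregulation
    for state, gene_set in truth.program_gene_sets.items():
        rows_s = states == state
        for gname in gene_set:
            mult[rows_s, col[gname]] *= truth.program_upregulation
    # lineage programs: OC genes up in OPC-like, AC in Astro-like, stemness in
    # Cycling and OPC-like (stem/progenitor phenotype)
    lineage_up = {
        "OC": ["OPC-like"],
        "AC": ["Astro-like"],
        "stemness": ["Cycling", "OPC-like"],
    }
    for lname, up_states in lineage_up.items():
        for gname in truth.lineage_gene_sets.get(lname, []):
            rows_l = np.isin(states, up_states)
            mult[rows_l, col[gname]] *= truth.program_upregulation

    depth = truth.mean_depth * np.exp(rng.normal(0.0, 0.25, size=n))
    profile = base[None, :] * mult
    profile_sum = profile.sum(axis=1, keepdims=True)
    mu = profile / profile_sum * depth[:, None]
    r = 1.0 / truth.dispersion
    counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))

    # sparse marker: Bernoulli activity with a small positive count when on
    p_active = np.where(
        neo,
        pd.Series(states).map(truth.sparse_marker_probs).fillna(0.0).to_numpy(),
        truth.sparse_marker_probs.get("non-neoplastic", 0.0),
    )
    active = rng.uniform(size=n) < p_active
    marker_counts = np.where(active, 1 + rng.poisson(0.3, size=n), 0)
    counts[:, col[truth.sparse_marker]] = marker_counts

    barcodes = pd.Index([f"BC{i:05d}" for i in range(n)], name="barcode")
    annotation = pd.DataFrame(
        {
            "cell_type": types,
            "state": np.where(neo, states, ""),
            "sparse_marker_active": active,
        },
        index=barcodes,
    )
    return sparse.csr_matrix(counts), features, barcodes, annotation
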