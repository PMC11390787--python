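# oligohox

Tools for studying HOX gene-body DNA methylation as a prognostic marker in
oligodendroglioma (IDH-mutant, 1p/19q-codeleted glioma), built for
epigenomics analysts who want the full analysis chain — signature
definition, cohort pooling, stability clustering, single-nucleus cell-state
calling and survival statistics — as tested, reusable functions rather than
one-off scripts.

## What it computes

**Gene-body methylation signature.** For a cohort of Illumina-style beta
values (fraction methylated, β ∈ [0, 1]) the HOXD12 signature of a sample is
the arithmetic mean of its three gene-body probes
(cg23130254, cg03964958, cg03371669):

    s_i = (β_i1 + β_i2 + β_i3) / 3

The cohort threshold is the midpoint of the mean signature in the
expression-negative and expression-positive groups, t = (m− + m+) / 2, and a
sample is called *hypermethylated* iff s_i > t (strictly). Expression status
itself is the median split of TPM values ("elevated" iff above the cohort
median, which reduces to "non-zero" when the median is zero). Candidate
probes are screened by three tests — Mann-Whitney age association and
log-rank survival association on the probe's median split, plus the
continuous beta in a Cox model adjusting for age and grade — all at p < 0.05.

**Pan-HOX consensus clustering.** Gene-body probes of HOXA/B/C/D-locus genes
are pooled across cohorts (probe intersection), batch effects are removed on
the logit(β) scale, and the samples are embedded 2-D with UMAP under many
random initializations, each embedding partitioned by 2-means. Per-sample
labels are aligned across runs; the *switch frequency* is the fraction of
runs disagreeing with the sample's majority label, and samples switching
more than 10% of the time are excluded before differential methylation
(Welch t on logit β, BH-FDR, effects averaged per gene and per HOX locus).

**Single-nucleus neoplastic calling and cell states.** Nuclei are clustered
(PCA + k-means); arm-level relative dosage is inferred from meta-cell
log-ratios against reference clusters (sliding window along the genome, arm
call at ±0.15 natural-log units); a cluster is *neoplastic* only when the
1p/19q-codeletion pattern (1p and 19q lost, 1q and 19p intact) is universal
(≥95% of meta-cells), *non-neoplastic* when universally absent, *excluded*
otherwise. Neoplastic nuclei are scored against cell-state programs
(OPC-like, Astro-like, Cycling, RE) with bin-matched control genes; each
nucleus gets a permutation p-value per state, p = (1 + #{null ≥ obs}) /
(1 + n_perm), BH-corrected over the nucleus × state grid, and is assigned
the argmin-FDR state when that FDR < 0.05/4 = 0.0125, else "gradient".

**Cohort statistics.** Log-rank, Cox PH with VIF > 10 collinearity
screening (Efron ties), Fisher exact, Mann-Whitney, Pearson, BH-FDR,
Shapiro-Wilk and a dip test of unimodality, and the rule-based calls:
15q loss (more than half of 15q genes lost), CDKN2A homozygous deletion
(GISTIC −2 in ≥2 of 3 call sets), adjuvant-therapy labelling (explicit
"ADJUVANT" label, or first treatment within 244 days of diagnosis).

A seeded synthetic-cohort generator (`oligohox.synthetic`) produces
bulk-cohort, multi-batch pan-HOX and single-nucleus datasets with known
planted truth, so every stage is testable without access to consortium data.

## Worked example

```python
from oligohox import synthetic as syn, signature as sig, stats as cstats

truth = syn.BulkCohortTruth(n=500, seed=11)        # planted HR 9.3, group means 0.3034/0.4121
clinical, meth, expr = syn.gen_bulk_cohort(truth)
calls = sig.signature_calls(meth, expr["HOXD12"])
print(calls[["signature", "threshold_reported", "hypermethylated"]].head())

res = cstats.logrank_test(clinical["os_years"], clinical["os_event"],
                          calls["hypermethylated"].astype(bool))
print(f"log-rank chi2 = {res.statistic:.1f}, p = {res.p:.2e}")
```

prints

```
           signature  threshold_reported  hypermethylated
sample_id
S0000       0.338496              0.3588            False
S0001       0.288666              0.3588            False
S0002       0.369832              0.3588             True
S0003       0.299443              0.3588            False
S0004       0.347903              0.3588            False
log-rank chi2 = 176.3, p = 3.11e-40
```

The derived threshold (0.3588 here) is the midpoint of this cohort's two
group means — at n=500 it scatters around the population value 0.3577 — and
hypermethylated samples have far worse survival, reflecting the planted
hazard ratio.

The same stages are available from a shell:

```bash
oligohox simulate bulk --seed 3 --out sim/
oligohox signature --beta sim/beta.tsv --manifest sim/manifest.tsv \
    --expr sim/expression.tsv --out calls/
oligohox panhox --beta a.tsv --manifest m.tsv --runs 1000 --seed 7 --out cons/
oligohox snstates --mtx matrix.mtx --features features.tsv \
    --barcodes barcodes.tsv --genesets sets.yaml --nperm 100000 --seed 11 --out ann/
```

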