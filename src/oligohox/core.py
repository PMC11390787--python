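"""Shared containers for methylation cohorts.

The central object is :class:`MethylationMatrix`, a samples x probes matrix of
Illumina-style beta values (fraction methylated, in [0, 1]) paired with a probe
manifest that records, for each probe, the annotated gene, the genomic region
class (TSS1500 / TSS200 / 5UTR / Body / 3UTR), the chromosome arm and the
position.  Downstream stages (gene-body signature, pan-HOX pooling) only ever
select probes through the manifest, never by probe-id string conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_CLASSES = ("TSS1500", "TSS200", "5UTR", "Body", "3UTR")

#: The four HOX clusters and the chromosomes that carry them.
HOX_LOCI = {"HOXA": "7p", "HOXB": "17q", "HOXC": "12q", "HOXD": "2q"}

MANIFEST_COLUMNS = ("gene", "region", "chrom_arm", "pos")


@dataclass
class MethylationMatrix:
    """Beta values (samples x probes) plus a per-probe manifest.

    Parameters
    ----------
    beta
        DataFrame indexed by sample id with one column per probe id.  Values
        must be finite and in [0, 1], or NaN for missing calls.
    manifest
        DataFrame indexed by probe id with columns ``gene``, ``region``,
        ``chrom_arm`` and ``pos``.  Every probe in ``beta`` must appear here.
    """

    beta: pd.DataFrame
    manifest: pd.DataFrame
    name: str = field(default="cohort")

    def __post_init__(self) -> None:
        if self.beta.columns.has_duplicates:
            raise ValueError("probe ids must be unique")
        missing = self.beta.columns.difference(self.manifest.index)
        if len(missing):
            raise ValueError(f"probes absent from manifest: {list(missing)[:5]}")
        for col in MANIFEST_COLUMNS:
            if col not in self.manifest.columns:
                raise ValueError(f"manifest lacks required column {col!r}")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.columns

    def subset_probes(self, probes) -> "MethylationMatrix":
        probes = pd.Index(probes)
        return MethylationMatrix(
            beta=self.beta.loc[:, probes],
            manifest=self.manifest.loc[probes],
            name=self.name,
        )

    def body_probes_for_loci(self, loci=tuple(HOX_LOCI)) -> pd.Index:
        """Gene-body probes whose annotated gene belongs to one of ``loci``."""
        genes = self.manifest["gene"].astype(str)
        in_locus = np.zeros(len(genes), dtype=bool)
        for locus in loci:
            in_locus |= genes.str.startswith(locus).to_numpy()
        is_body = (self.manifest["region"] == "Body").to_numpy()
        return self.manifest.index[in_locus & is_body]


def logit_beta(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Map beta values to M-like logit scale; clips to (eps, 1-eps) first."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return np.log(b / (1.0 - b))


def expit_beta(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`logit_beta` (without the clipping)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
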