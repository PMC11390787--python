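"""Plain-text readers/writers for the pipeline's interchange formats.

Beta matrices and manifests travel as TSV; single-nucleus counts as
MatrixMarket MTX with features.tsv / barcodes.tsv side files; gene sets as
YAML mapping set name -> list of genes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .core import MethylationMatrix


def read_methylation(beta_path, manifest_path, name: str = "cohort") -> MethylationMatrix:
    beta = pd.read_csv(beta_path, sep="\t", index_col=0)
    manifest = pd.read_csv(manifest_path, sep="\t", index_col=0)
    return MethylationMatrix(beta=beta, manifest=manifest, name=name)


def write_methylation(mm: MethylationMatrix, beta_path, manifest_path) -> None:
    mm.beta.to_csv(beta_path, sep="\t")
    mm.manifest.to_csv(manifest_path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_snseq(counts: sparse.spmatrix, features: pd.DataFrame, barcodes, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(counts))
    features.to_csv(outdir / "features.tsv", sep="\t")
    pd.Series(barcodes, name="barcode").to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False
    )


def read_snseq(mtx_path, features_path, barcodes_path):
    counts = sparse.csr_matrix(spio.mmread(mtx_path))
    features = pd.read_csv(features_path, sep="\t", index_col=0)
    barcodes = pd.Index(
        pd.read_csv(barcodes_path, sep="\t")["barcode"], name="barcode"
    )
    return counts, features, barcodes


def read_gene_sets(path) -> dict:
    with open(path) as fh:
        sets = yaml.safe_load(fh)
    if not isinstance(sets, dict):
        raise ValueError("gene-set YAML must map set name -> gene list")
    return {str(k): [str(g) for g in v] for k, v in sets.items()}
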