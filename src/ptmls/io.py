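"""Plain-text readers/writers for the pipeline's external formats.

Expression matrices and feature tables travel as TSV, single-cell counts as
MatrixMarket MTX plus feature/barcode TSVs, slides as PNG with a mask PNG
and nuclei CSV. Every generated artifact gets a sidecar JSON recording the
seed and parameters that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .scgrn import SCMatrix

__all__ = ["write_sidecar", "write_slide", "write_cohort", "write_sc",
           "read_sc", "read_expression", "read_survival", "read_gene_sets"]


def write_sidecar(path, params):
    path = Path(path)
    path.write_text(json.dumps(params, indent=2, default=str) + "\n")


def write_slide(slide, prefix, params=None):
    """PNG image + mask PNG + nuclei CSV (+ sidecar JSON)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(f"{prefix}.png", slide.image)
    iio.imwrite(f"{prefix}_mask.png",
                (slide.tissue_mask * 255).astype(np.uint8))
    pd.DataFrame(slide.nuclei, columns=["cx", "cy", "radius"]).to_csv(
        f"{prefix}_nuclei.csv", index=False)
    if params is not None:
        write_sidecar(f"{prefix}.json", params)


def write_cohort(cohort, outdir, params=None):
    """features.tsv (samples x expr_/path_ columns) + survival.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    feats = pd.DataFrame(
        np.hstack([cohort.expr, cohort.path]),
        index=cohort.sample_ids,
        columns=[f"expr_f{i}" for i in range(cohort.expr.shape[1])]
        + [f"path_f{i}" for i in range(cohort.path.shape[1])])
    feats.index.name = "sample"
    feats.to_csv(outdir / "features.tsv", sep="\t")
    surv = pd.DataFrame({"sample": cohort.sample_ids, "time": cohort.times,
                         "event": cohort.events})
    surv.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    if params is not None:
        write_sidecar(outdir / "cohort.json", params)


def write_sc(sc, outdir, params=None):
    """MatrixMarket counts + features.tsv + barcodes.tsv (+ sidecar)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(sc.counts))
    pd.Series(sc.gene_names).to_csv(outdir / "features.tsv", sep="\t",
                                    index=False, header=False)
    pd.Series(sc.cell_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                    index=False, header=False)
    if params is not None:
        write_sidecar(outdir / "sc.json", params)


def read_sc(outdir):
    outdir = Path(outdir)
    counts = np.asarray(spio.mmread(outdir / "matrix.mtx").todense())
    genes = pd.read_csv(outdir / "features.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    return SCMatrix(counts=counts.astype(np.int64), gene_names=genes,
                    cell_names=cells)


def read_expression(path):
    """Genes x samples TSV; genes with any NA are dropped."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.dropna(axis=0)


def read_survival(path):
    """TSV with sample, time, event columns, indexed by sample."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("sample")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be > 0")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df


def read_gene_sets(path):
    """GMT-style sets: name <tab> description <tab> gene1 <tab> gene2..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            sets[parts[0]] = parts[2:]
    return sets
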