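"""Readers and writers for the plain-text exchange formats.

Count matrices travel as a 10x-style triplet directory (``matrix.mtx`` +
``genes.tsv`` + ``barcodes.tsv``, gene-major Matrix Market); extra layers
(spliced/unspliced) as sibling ``<layer>.mtx`` files.  Gene signatures use
the GMT dialect (name, description, then genes, tab-separated) or a plain
two-column TSV.  Tables are TSV throughout.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData


def write_10x_mtx(adata: AnnData, outdir, layers: bool = True) -> None:
    """Write counts as a 10x triplet directory (genes x cells on disk)."""
    os.makedirs(outdir, exist_ok=True)
    mat = sp.csc_matrix(np.asarray(adata.X).T)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), mat, field="integer")
    genes = adata.var.reset_index()
    genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t",
                 header=True, index=False)
    adata.obs.reset_index().to_csv(os.path.join(outdir, "barcodes.tsv"),
                                   sep="\t", header=True, index=False)
    if layers:
        for name, layer in adata.layers.items():
            scipy.io.mmwrite(os.path.join(outdir, f"{name}.mtx"),
                             sp.csc_matrix(np.asarray(layer).T),
                             field="integer")


def read_10x_mtx(indir) -> AnnData:
    """Read a triplet directory written by :func:`write_10x_mtx`."""
    mat = scipy.io.mmread(os.path.join(indir, "matrix.mtx")).T.tocsr()
    var = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t")
    obs = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t")
    var = var.set_index(var.columns[0])
    obs = obs.set_index(obs.columns[0])
    adata = AnnData(X=np.asarray(mat.todense()).astype(np.int64),
                    obs=obs, var=var)
    for name in ("spliced", "unspliced"):
        path = os.path.join(indir, f"{name}.mtx")
        if os.path.exists(path):
            adata.layers[name] = np.asarray(
                scipy.io.mmread(path).T.todense()).astype(np.int64)
    return adata


def write_gmt(signatures: dict, path) -> None:
    """Write ``{name: [genes]}`` in GMT format (description column empty)."""
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


def read_signature_tsv(path) -> dict:
    """Two-column TSV: signature name, gene."""
    df = pd.read_csv(path, sep="\t", header=None, names=["signature", "gene"])
    return {name: grp["gene"].tolist()
            for name, grp in df.groupby("signature", sort=False)}
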