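"""Readers and writers for the on-disk exchange formats.

Bulk experiments travel as a counts TSV (first column ``gene_id``, one
column per sample) plus a samples TSV (``sample``, ``condition``, ``pair``,
``timepoint``).  Single-cell samples travel as 10x-style Matrix Market
triplets: ``matrix.mtx`` (coordinate integer, 1-based, genes × cells),
``features.tsv`` (gene_id, gene_name) and ``barcodes.tsv``, one directory
per sample.  Writing then reading round-trips losslessly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import BulkExperiment, SCExperiment


def write_bulk(experiment: BulkExperiment, outdir: str | os.PathLike) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_path = outdir / "counts.tsv"
    samples_path = outdir / "samples.tsv"
    try:
        experiment.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
        experiment.samples.rename_axis("sample").to_csv(samples_path, sep="\t")
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"failed writing bulk fixtures under {outdir}: {exc}") from exc
    return {"counts": counts_path, "samples": samples_path}


def read_bulk(counts_path: str | os.PathLike, samples_path: str | os.PathLike) -> BulkExperiment:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype={"pair": str})
    samples.index = samples.index.astype(str)
    return BulkExperiment(counts=counts, samples=samples)


def write_sc(experiment: SCExperiment, outdir: str | os.PathLike) -> dict[str, Path]:
    """Write one MTX triplet directory per sample; returns sample → path."""
    outdir = Path(outdir)
    written: dict[str, Path] = {}
    for label in experiment.samples:
        mask = experiment.sample_of == label
        sdir = outdir / label
        sdir.mkdir(parents=True, exist_ok=True)
        mat = sp.coo_matrix(experiment.counts[:, mask])
        try:
            scipy.io.mmwrite(sdir / "matrix.mtx", mat, field="integer")
            experiment.features[["gene_id", "gene_name"]].to_csv(
                sdir / "features.tsv", sep="\t", header=False, index=False
            )
            pd.Series(experiment.barcodes[mask]).to_csv(
                sdir / "barcodes.tsv", header=False, index=False
            )
        except OSError as exc:  # pragma: no cover
            raise OSError(f"failed writing sc fixtures under {sdir}: {exc}") from exc
        written[label] = sdir
    return written


def read_sc(sample_dirs: dict[str, str | os.PathLike], mito_genes=None) -> SCExperiment:
    """Assemble one SCExperiment from per-sample MTX triplet directories.

    Barcodes colliding across samples are disambiguated by suffixing the
    sample label.
    """
    mats, feats, bcs, labels = [], None, [], []
    for label, d in sample_dirs.items():
        d = Path(d)
        mat = sp.csr_matrix(scipy.io.mmread(d / "matrix.mtx"))
        try:
            features = pd.read_csv(
                d / "features.tsv", sep="\t", header=None, names=["gene_id", "gene_name"]
            )
        except pd.errors.EmptyDataError:
            features = pd.DataFrame({"gene_id": [], "gene_name": []})
        try:
            barcodes = pd.read_csv(d / "barcodes.tsv", header=None)[0].astype(str).to_numpy()
        except pd.errors.EmptyDataError:
            barcodes = np.array([], dtype=object)
        if feats is None:
            feats = features
        elif not feats["gene_id"].equals(features["gene_id"]):
            raise ValueError(f"feature table of sample {label!r} disagrees with the first sample")
        mats.append(mat)
        bcs.append(barcodes)
        labels.append(np.full(len(barcodes), label, dtype=object))
    if feats is None:
        raise ValueError("no sample directories given")
    all_bc = np.concatenate(bcs).astype(object)
    all_lab = np.concatenate(labels)
    if len(set(all_bc)) < len(all_bc):
        all_bc = np.array([f"{b}_{s}" for b, s in zip(all_bc, all_lab)], dtype=object)
    return SCExperiment(
        counts=sp.hstack(mats, format="csr"),
        features=feats,
        barcodes=all_bc,
        sample_of=all_lab,
        mito_genes=mito_genes,
    )
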