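"""Core data containers shared across the bulk and single-cell arms.

A :class:`BulkExperiment` holds a gene × sample integer count matrix with
the paired-design metadata (condition, donor pair, timepoint) needed for
paired differential expression.  A :class:`SCExperiment` holds a sparse
gene × cell count matrix with per-cell sample labels and per-gene
mitochondrial flags.  :class:`SignedGeneSet` is the common currency for
thresholded DE results on either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

CONDITIONS = ("Scr", "TKD")

MITO_PREFIX = "MT-"


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis configuration is invalid."""


@dataclass
class BulkExperiment:
    """Gene × sample counts plus paired-design sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, rows indexed by gene id, columns by
        sample name.
    samples
        One row per sample (index = sample name) with columns ``condition``
        (``Scr`` or ``TKD``), ``pair`` (donor/replicate pair id) and
        ``timepoint``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns must match samples index, in order")
        for col in ("condition", "pair", "timepoint"):
            if col not in self.samples.columns:
                raise ValueError(f"samples metadata missing column {col!r}")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        # one sample per (condition, pair, timepoint) cell of the design
        dup = self.samples.duplicated(subset=["condition", "pair", "timepoint"])
        if dup.any():
            raise ValueError(
                "each (condition, pair, timepoint) combination may appear once; "
                f"duplicated: {list(self.samples.index[dup])}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_timepoint(self, timepoint: str) -> "BulkExperiment":
        keep = self.samples["timepoint"] == timepoint
        if not keep.any():
            raise ValueError(f"no samples at timepoint {timepoint!r}")
        return BulkExperiment(
            counts=self.counts.loc[:, keep.to_numpy()],
            samples=self.samples.loc[keep],
        )


def _resolve_mito(features: pd.DataFrame, mito_genes) -> np.ndarray:
    if mito_genes is not None:
        mito_set = set(mito_genes)
        return features["gene_name"].isin(mito_set).to_numpy()
    return features["gene_name"].str.startswith(MITO_PREFIX).to_numpy()


@dataclass
class SCExperiment:
    """Sparse gene × cell counts with sample labels and mito flags.

    ``features`` carries ``gene_id`` and ``gene_name`` columns; the
    ``is_mito`` flag is derived from the ``MT-`` gene-name prefix unless an
    explicit ``mito_genes`` list is given.
    """

    counts: sp.csr_matrix
    features: pd.DataFrame
    barcodes: np.ndarray
    sample_of: np.ndarray
    mito_genes: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.sample_of = np.asarray(self.sample_of, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.features) != n_genes:
            raise ValueError("features rows must match count-matrix rows")
        if len(self.barcodes) != n_cells or len(self.sample_of) != n_cells:
            raise ValueError("barcodes/sample labels must match count-matrix columns")
        for col in ("gene_id", "gene_name"):
            if col not in self.features.columns:
                raise ValueError(f"features missing column {col!r}")
        if "is_mito" not in self.features.columns:
            self.features = self.features.copy()
            self.features["is_mito"] = _resolve_mito(self.features, self.mito_genes)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_of:
            seen.setdefault(s, None)
        return list(seen)

    def gene_index(self, gene_name: str) -> int:
        """Row index of a gene by name; KeyError naming the gene if absent."""
        hits = np.flatnonzero((self.features["gene_name"] == gene_name).to_numpy())
        if hits.size == 0:
            raise KeyError(f"gene {gene_name!r} not found in features")
        return int(hits[0])

    def subset_cells(self, mask: np.ndarray) -> "SCExperiment":
        mask = np.asarray(mask)
        return SCExperiment(
            counts=self.counts[:, mask].tocsr(),
            features=self.features,
            barcodes=self.barcodes[mask],
            sample_of=self.sample_of[mask],
        )


@dataclass
class SignedGeneSet:
    """A set of genes each tagged with a regulation direction.

    ``entries`` maps gene → ``"up"`` or ``"down"``; ``provenance`` records
    which analysis produced the set (e.g. ``bulk_6h``, ``sc``).
    """

    entries: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.entries.items() if d not in ("up", "down")}
        if bad:
            raise ValueError(f"directions must be 'up' or 'down': {bad}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def genes(self) -> set[str]:
        return set(self.entries)
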