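"""Single-cell arm: QC, log-normalization, knockdown classification, and
downsampling-balanced Wilcoxon differential expression.

Cells failing QC (mitochondrial fraction above 10% or fewer than 200
detected genes) are removed.  Expression is depth-normalized to 10⁴ counts
per cell and natural-log transformed.  A cell is called PIM⁻ when its raw
post-QC count is exactly zero for all three PIM genes.  DE between a small
case group (PIM⁻ cells) and a larger control group balances group sizes by
drawing 100 control subsets of the case size, testing each subset with a
two-sided Wilcoxon rank-sum test and Benjamini-Hochberg correction, and
aggregating per-gene stability as ``signif_prop`` — the proportion of
subsets in which the gene passes FDR < 0.05 and |log2FC| > 0.24.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .containers import SCExperiment, SignedGeneSet

DEFAULT_MARKERS = ("TBX21", "RORA")


@dataclass
class QCThresholds:
    """Cell-level QC cutoffs: >10% mitochondrial counts or <200 detected
    genes (strict inequalities) remove a cell."""

    max_mito_fraction: float = 0.10
    min_genes_detected: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.min_genes_detected < 0:
            raise ValueError("min_genes_detected must be ≥ 0")


@dataclass
class QCReport:
    n_input: int
    n_removed_mito: int
    n_removed_low_genes: int
    n_removed_zero_total: int
    n_kept: int

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class MarkerPanel:
    """The three knockdown targets plus co-assessed markers for joint states."""

    kd_targets: tuple[str, str, str] = ("PIM1", "PIM2", "PIM3")
    copositives: tuple[str, ...] = DEFAULT_MARKERS

    def __post_init__(self) -> None:
        if len(self.kd_targets) != 3:
            raise ValueError("kd_targets must have exactly 3 entries")


@dataclass
class DownsampleDEConfig:
    n_subsets: int = 100
    fdr_threshold: float = 0.05
    log2fc_threshold: float = 0.24
    min_detection_fraction: float = 0.10
    pseudocount: float = 1.0
    signed_log2fc: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be ≥ 1")
        if self.fdr_threshold <= 0 or self.log2fc_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class DownsampleDETable:
    """Aggregated table plus the per-subset p/FDR/log2FC matrices."""

    table: pd.DataFrame
    p_values: np.ndarray  # genes × subsets, NaN where untested
    fdr: np.ndarray
    log2fc: np.ndarray
    n_subsets: int


def qc_filter(
    experiment: SCExperiment, thresholds: QCThresholds | None = None
) -> tuple[SCExperiment, QCReport]:
    """Remove cells failing the mitochondrial-fraction or detected-gene QC.

    Zero-total cells (mitochondrial fraction undefined) are removed and
    counted separately.  The gene universe is unchanged.
    """
    thresholds = thresholds or QCThresholds()
    counts = experiment.counts.tocsc()
    totals = np.asarray(counts.sum(axis=0)).ravel()
    detected = counts.getnnz(axis=0)
    mito_mask = experiment.features["is_mito"].to_numpy()
    mito_counts = np.asarray(counts[mito_mask, :].sum(axis=0)).ravel()

    zero_total = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(zero_total, 0.0, mito_counts / np.maximum(totals, 1))
    fail_mito = ~zero_total & (mito_frac > thresholds.max_mito_fraction)
    fail_genes = ~zero_total & (detected < thresholds.min_genes_detected)
    keep = ~(zero_total | fail_mito | fail_genes)

    report = QCReport(
        n_input=experiment.n_cells,
        n_removed_mito=int(fail_mito.sum()),
        n_removed_low_genes=int(fail_genes.sum()),
        n_removed_zero_total=int(zero_total.sum()),
        n_kept=int(keep.sum()),
    )
    return experiment.subset_cells(keep), report


def log_normalize(experiment: SCExperiment, scale_factor: float = 1e4) -> sp.csr_matrix:
    """Depth-normalize each cell to ``scale_factor`` and apply ln(1 + x)."""
    counts = experiment.counts.tocsc().astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-total cells present; run qc_filter first")
    scaled = counts @ sp.diags(scale_factor / totals)
    scaled.data = np.log1p(scaled.data)
    return scaled.tocsr()


def classify_pim_negative(
    experiment: SCExperiment, panel: MarkerPanel | None = None
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-cell PIM⁻ call (zero raw count for all three targets) and the
    PIM⁻ fraction per sample."""
    panel = panel or MarkerPanel()
    idx = [experiment.gene_index(g) for g in panel.kd_targets]
    sub = experiment.counts[idx, :].toarray()
    is_neg = (sub == 0).all(axis=0)
    fractions = {
        s: float(is_neg[experiment.sample_of == s].mean())
        for s in experiment.samples
    }
    return is_neg, fractions


def joint_marker_state(
    experiment: SCExperiment, panel: MarkerPanel | None = None
) -> np.ndarray:
    """Per-cell joint detection state over the PIM group and each marker.

    The PIM group is positive when any of the three targets has a nonzero
    count; each marker is positive when its own count is nonzero.  States
    read e.g. ``"PIM-/TBX21-/RORA+"``.
    """
    panel = panel or MarkerPanel()
    kd_idx = [experiment.gene_index(g) for g in panel.kd_targets]
    pim_pos = (experiment.counts[kd_idx, :].toarray() > 0).any(axis=0)
    parts = [np.where(pim_pos, "PIM+", "PIM-")]
    for marker in panel.copositives:
        mi = experiment.gene_index(marker)
        pos = experiment.counts[mi, :].toarray().ravel() > 0
        parts.append(np.where(pos, f"{marker}+", f"{marker}-"))
    return np.array(["/".join(p) for p in zip(*parts)], dtype=object)


def rank_sum_pvalues(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 25
) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values, one per row.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` observations and a row has no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", axis=1).pvalue
    p = np.atleast_1d(np.asarray(p, dtype=float))
    p[~np.isfinite(p)] = 1.0  # fully tied rows carry no evidence
    if x.shape[1] <= exact_max_n and y.shape[1] <= exact_max_n:
        for g in range(x.shape[0]):
            row = np.concatenate([x[g], y[g]])
            if np.unique(row).size == row.size:  # tie-free
                p[g] = mannwhitneyu(
                    x[g], y[g], alternative="two-sided", method="exact"
                ).pvalue
    return p


def _subset_log2fc(xc: np.ndarray, xs: np.ndarray, pseudocount: float) -> np.ndarray:
    """log2 ratio of back-transformed group means with pseudocount."""
    mc = np.expm1(xc).mean(axis=1)
    ms = np.expm1(xs).mean(axis=1)
    return np.log2((mc + pseudocount) / (ms + pseudocount))


def downsample_balanced_de(
    case_cells: np.ndarray,
    ctrl_cells: np.ndarray,
    expr: sp.spmatrix,
    config: DownsampleDEConfig | None = None,
    genes: pd.Index | None = None,
) -> DownsampleDETable:
    """Balanced DE by repeated downsampling of the larger group.

    ``case_cells``/``ctrl_cells`` are column indices into ``expr`` (a
    log-normalized genes × cells matrix).  In each of ``n_subsets`` rounds
    the larger group is subsampled without replacement to the smaller
    group's size (independent RNG substream per round), genes detected in at
    least ``min_detection_fraction`` of either group's cells are tested with
    a two-sided Wilcoxon rank-sum test, p-values are BH-adjusted across the
    tested genes, and the round's log2FC is the ratio of back-transformed
    group means.  ``signif_prop`` counts the rounds in which a gene passes
    FDR < ``fdr_threshold`` and |log2FC| > ``log2fc_threshold``, divided by
    ``n_subsets``.
    """
    config = config or DownsampleDEConfig()
    case_cells = np.asarray(case_cells)
    ctrl_cells = np.asarray(ctrl_cells)
    if min(case_cells.size, ctrl_cells.size) < 2:
        raise ValueError("each group needs at least 2 cells")
    expr = sp.csc_matrix(expr)
    n_genes = expr.shape[0]
    if genes is None:
        genes = pd.RangeIndex(n_genes)

    # the smaller group is fixed; the larger one is downsampled each round
    if case_cells.size <= ctrl_cells.size:
        fixed_idx, pool_idx, case_is_fixed = case_cells, ctrl_cells, True
    else:
        fixed_idx, pool_idx, case_is_fixed = ctrl_cells, case_cells, False
    n_draw = fixed_idx.size
    X_fixed = expr[:, fixed_idx].toarray()

    substreams = np.random.SeedSequence(config.seed).spawn(config.n_subsets)
    S = config.n_subsets
    p_mat = np.full((n_genes, S), np.nan)
    q_mat = np.full((n_genes, S), np.nan)
    fc_mat = np.full((n_genes, S), np.nan)
    qualifies = np.zeros((n_genes, S), dtype=bool)

    for i, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        drawn = rng.choice(pool_idx, size=n_draw, replace=False)
        X_drawn = expr[:, np.sort(drawn)].toarray()
        X_case, X_ctrl = (X_fixed, X_drawn) if case_is_fixed else (X_drawn, X_fixed)

        det_case = (X_case > 0).mean(axis=1)
        det_ctrl = (X_ctrl > 0).mean(axis=1)
        tested = (det_case >= config.min_detection_fraction) | (
            det_ctrl >= config.min_detection_fraction
        )
        fc_mat[:, i] = _subset_log2fc(X_case, X_ctrl, config.pseudocount)
        if tested.any():
            p = rank_sum_pvalues(X_case[tested], X_ctrl[tested])
            q = multipletests(p, method="fdr_bh")[1]
            p_mat[tested, i] = p
            q_mat[tested, i] = q
            fc_pass = (
                fc_mat[:, i] > config.log2fc_threshold
                if config.signed_log2fc
                else np.abs(fc_mat[:, i]) > config.log2fc_threshold
            )
            qualifies[tested, i] = (q_mat[tested, i] < config.fdr_threshold) & fc_pass[tested]

    ever_tested = ~np.isnan(p_mat).all(axis=1)
    signif_prop = qualifies.sum(axis=1) / S
    median_fdr = np.full(n_genes, np.nan)
    if ever_tested.any():
        median_fdr[ever_tested] = np.nanmedian(q_mat[ever_tested], axis=1)
    table = pd.DataFrame(
        {
            "mean_log2fc": np.nanmean(fc_mat, axis=1),
            "signif_prop": signif_prop,
            "median_fdr": median_fdr,
            "n_subsets_qualifying": qualifies.sum(axis=1),
            "n_subsets_tested": (~np.isnan(p_mat)).sum(axis=1),
            "ever_tested": ever_tested,
        },
        index=genes,
    )
    return DownsampleDETable(
        table=table, p_values=p_mat, fdr=q_mat, log2fc=fc_mat, n_subsets=S
    )


def call_de_genes(
    result: DownsampleDETable, signif_prop_min: float, provenance: str = "sc"
) -> SignedGeneSet:
    """Genes with ``signif_prop`` at or above the cutoff, signed by the
    aggregated mean log2FC."""
    t = result.table
    keep = t["ever_tested"] & (t["signif_prop"] >= signif_prop_min)
    entries = {
        str(g): ("down" if t.loc[g, "mean_log2fc"] < 0 else "up")
        for g in t.index[keep]
    }
    return SignedGeneSet(entries=entries, provenance=provenance)
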