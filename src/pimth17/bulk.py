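"""Paired bulk differential expression.

Normalization uses trimmed mean of M-values (TMM): per-sample scaling
factors are precision-weighted means of log count ratios against a
reference sample, after trimming the extremes of the log-ratio (M) and
average-abundance (A) distributions, rescaled to geometric mean 1.

Testing uses a paired reproducibility-optimized statistic.  For each gene
the paired difference of log2 CPM between knockdown and control is reduced
to a mean m̄ and standard error s, and a statistic family

    d = |m̄| / (α₁ + α₂·s)

is tuned by bootstrap: the (α₁, α₂) member and top-list size k are chosen
to maximize the reproducibility of top-k lists between paired bootstrap
resamplings of the donor pairs, standardized against the same quantity on
sign-flip–randomized (null) data.  False-discovery rates for the selected
statistic come from sign-flip permutations of the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import BulkExperiment, SignedGeneSet


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors (geometric mean 1)."""

    lib_sizes: pd.Series
    tmm_factors: pd.Series
    trim_m: float
    trim_a: float
    reference_sample: str

    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.tmm_factors


def _tmm_pair_factor(y_j, y_r, N_j, N_r, trim_m, trim_a) -> float:
    """Trimmed, precision-weighted mean of M-values of sample j vs reference r."""
    both = (y_j > 0) & (y_r > 0)
    if not both.any():
        raise ValueError("no genes co-expressed with the reference sample")
    yj, yr = y_j[both].astype(float), y_r[both].astype(float)
    pj, pr = yj / N_j, yr / N_r
    M = np.log2(pj / pr)
    A = 0.5 * np.log2(pj * pr)
    w = 1.0 / ((N_j - yj) / (N_j * yj) + (N_r - yr) / (N_r * yr))

    n = M.size
    rM = rankdata(M)
    rA = rankdata(A)
    loM, hiM = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    loA, hiA = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep.any():
        return 1.0
    return float(2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep])))


def compute_tmm_factors(
    experiment: BulkExperiment,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> NormFactors:
    """TMM scaling factors for every sample of a bulk experiment.

    The reference defaults to the sample whose 75th-percentile depth-
    normalized count is closest to the mean of those percentiles across
    samples.  Factors are rescaled so their geometric mean is 1.
    """
    counts = experiment.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    N = counts.sum(axis=0).astype(float)
    if (N <= 0).any():
        bad = list(N.index[N <= 0])
        raise ValueError(f"samples with zero library size: {bad}")
    if reference is None:
        q75 = counts.div(N, axis=1).quantile(0.75, axis=0)
        reference = str((q75 - q75.mean()).abs().idxmin())
    elif reference not in counts.columns:
        raise ValueError(f"reference sample {reference!r} not in experiment")

    y_r = counts[reference].to_numpy()
    N_r = float(N[reference])
    factors = {}
    for s in counts.columns:
        if s == reference:
            factors[s] = 1.0
            continue
        try:
            factors[s] = _tmm_pair_factor(
                counts[s].to_numpy(), y_r, float(N[s]), N_r, trim_m, trim_a
            )
        except ValueError as exc:
            raise ValueError(f"sample {s!r}: {exc}") from exc
    f = pd.Series(factors).reindex(counts.columns)
    f = f / np.exp(np.log(f).mean())
    return NormFactors(
        lib_sizes=N.astype(int),
        tmm_factors=f,
        trim_m=trim_m,
        trim_a=trim_a,
        reference_sample=reference,
    )


def normalized_cpm(
    experiment: BulkExperiment, factors: NormFactors, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    if list(factors.tmm_factors.index) != list(experiment.counts.columns):
        raise ValueError("normalization factors do not match experiment samples")
    eff = factors.effective_lib_sizes().astype(float)
    return (experiment.counts + pseudocount).div(eff, axis=1) * 1e6


def drop_unexpressed(experiment: BulkExperiment) -> tuple[BulkExperiment, int]:
    """Remove genes with zero counts in every sample; returns (experiment, n_dropped)."""
    keep = (experiment.counts.sum(axis=1) > 0).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped == 0:
        return experiment, 0
    return BulkExperiment(experiment.counts.loc[keep], experiment.samples), n_dropped


# ---------------------------------------------------------------------------
# Paired reproducibility-optimized testing
# ---------------------------------------------------------------------------

def _default_k_grid(n_genes: int) -> tuple[int, ...]:
    ks = np.unique(np.geomspace(10, max(10, n_genes // 2), num=8).astype(int))
    return tuple(int(k) for k in ks if k >= 1)


@dataclass
class RotsConfig:
    """Settings of the paired reproducibility-optimized test.

    ``B`` bootstrap resamplings tune the statistic; ``n_perm`` sign-flip
    permutations calibrate the FDR.  ``alpha1_grid``/``alpha2_grid`` span the
    statistic family d = |m̄|/(α₁ + α₂·s); ``k_grid`` the candidate top-list
    sizes (defaults to a geometric ladder from 10 to half the gene count).
    """

    B: int = 500
    n_perm: int = 500
    alpha1_grid: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 0.5, 51), 4))
    alpha2_grid: tuple[float, ...] = (0.0, 1.0)
    k_grid: tuple[int, ...] | None = None
    pseudocount: float = 0.5
    seed: int = 0

    def validate(self, n_genes: int) -> None:
        if self.B < 2:
            raise ValueError("B must be at least 2")
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if not self.alpha1_grid or not self.alpha2_grid:
            raise ValueError("alpha grids must be non-empty")
        if self.k_grid is not None and any(k > n_genes for k in self.k_grid):
            raise ValueError("k_grid entries must not exceed the number of genes")


def _paired_differences(
    experiment: BulkExperiment, factors: NormFactors, timepoint: str, pseudocount: float
) -> tuple[pd.Index, np.ndarray, list[str]]:
    """Per-gene paired log2 CPM differences (TKD − Scr), one column per pair."""
    cpm = normalized_cpm(experiment, factors, pseudocount=pseudocount)
    meta = experiment.samples
    at_tp = meta[meta["timepoint"] == timepoint]
    pairs = sorted(at_tp["pair"].unique())
    cols = []
    for p in pairs:
        sub = at_tp[at_tp["pair"] == p]
        tkd = sub.index[sub["condition"] == "TKD"]
        scr = sub.index[sub["condition"] == "Scr"]
        if len(tkd) != 1 or len(scr) != 1:
            raise ValueError(
                f"pair {p!r} at timepoint {timepoint!r} must have exactly one TKD "
                "and one Scr sample"
            )
        cols.append(np.log2(cpm[tkd[0]].to_numpy()) - np.log2(cpm[scr[0]].to_numpy()))
    if len(cols) < 2:
        raise ValueError("paired testing requires at least 2 pairs")
    return cpm.index, np.column_stack(cols), pairs


def _mean_se(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = D.shape[1]
    m = D.mean(axis=1)
    s = D.std(axis=1, ddof=1) / np.sqrt(n)
    return m, s


def _stat_matrix(m: np.ndarray, s: np.ndarray, a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """d_gc = |m_g| / (α₁_c + α₂_c · s_g) for every candidate c; genes × candidates."""
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs(m)[:, None] / (a1[None, :] + a2[None, :] * s[:, None])
    return np.nan_to_num(d, nan=0.0, posinf=np.finfo(float).max)


def _top_ranks(d: np.ndarray) -> np.ndarray:
    """Rank (0 = best) of each gene per candidate; ties broken by stable gene order."""
    order = np.argsort(-d, axis=0, kind="stable")
    ranks = np.empty_like(order)
    cols = np.arange(d.shape[1])[None, :]
    ranks[order, cols] = np.arange(d.shape[0])[:, None]
    return ranks


def _candidates(config: RotsConfig) -> tuple[np.ndarray, np.ndarray]:
    """Expand the α grids; (0, 0) is excluded (undefined statistic).

    All α₂ = 0 members rank genes identically (pure fold change), so they are
    collapsed to a single representative.
    """
    a1, a2 = [], []
    fc_added = False
    for x2 in config.alpha2_grid:
        for x1 in config.alpha1_grid:
            if x1 == 0 and x2 == 0:
                continue
            if x2 == 0:
                if fc_added:
                    continue
                fc_added = True
            a1.append(float(x1))
            a2.append(float(x2))
    if not a1:
        raise ValueError("alpha grids contain no valid (α₁, α₂) candidate")
    return np.array(a1), np.array(a2)


def _informative_flip_patterns(n_pairs: int, n_perm: int, rng) -> np.ndarray:
    """Sign-flip patterns for the paired null, excluding the identity and the
    global negation (both reproduce the observed |m̄| and s exactly).

    Since the statistic is invariant under global negation, patterns are
    enumerated with the first sign fixed to +1; when ``2**(n_pairs-1) - 1``
    informative patterns exist and fit within ``n_perm`` they are used
    exhaustively, otherwise ``n_perm`` are sampled.
    """
    n_distinct = 2 ** (n_pairs - 1) - 1
    if n_distinct <= n_perm:
        codes = np.arange(1, n_distinct + 1)
    else:
        codes = rng.integers(1, n_distinct + 1, size=n_perm)
    bits = (codes[:, None] >> np.arange(n_pairs - 1)[None, :]) & 1
    flips = np.ones((codes.size, n_pairs))
    flips[:, 1:] = 1.0 - 2.0 * bits
    return flips


def _random_informative_flips(rng, n_pairs: int) -> np.ndarray:
    """One random sign pattern that is not the identity or global negation."""
    while True:
        f = rng.choice([-1.0, 1.0], size=n_pairs)
        if not (f == f[0]).all():
            return f


def paired_rots_test(
    experiment: BulkExperiment,
    factors: NormFactors,
    config: RotsConfig,
    timepoint: str,
) -> pd.DataFrame:
    """Reproducibility-optimized paired test of TKD vs Scr at one timepoint.

    Returns a gene-indexed table with columns ``mean_log2fc``, ``scale``
    (paired SE), ``statistic``, ``fdr``, ``fc`` (linear, ≥ 1) and
    ``direction``.  Deterministic given ``config.seed``.
    """
    genes, D, _ = _paired_differences(experiment, factors, timepoint, config.pseudocount)
    n_genes, n_pairs = D.shape
    config.validate(n_genes)
    k_grid = np.array(config.k_grid or _default_k_grid(n_genes))
    a1, a2 = _candidates(config)
    n_cand = a1.size

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    def overlap_props(data: np.ndarray) -> np.ndarray:
        """Top-k overlap proportions between two pair-bootstrap replicates."""
        out = np.empty((n_cand, k_grid.size))
        i1 = rng.integers(0, n_pairs, n_pairs)
        i2 = rng.integers(0, n_pairs, n_pairs)
        r_a = _top_ranks(_stat_matrix(*_mean_se(data[:, i1]), a1, a2))
        r_b = _top_ranks(_stat_matrix(*_mean_se(data[:, i2]), a1, a2))
        for ki, k in enumerate(k_grid):
            out[:, ki] = ((r_a < k) & (r_b < k)).sum(axis=0) / k
        return out

    R_obs = np.empty((config.B, n_cand, k_grid.size))
    R_null = np.empty_like(R_obs)
    for b in range(config.B):
        R_obs[b] = overlap_props(D)
        flips = _random_informative_flips(rng, n_pairs)
        R_null[b] = overlap_props(D * flips[None, :])

    R = R_obs.mean(axis=0)
    sdR = R_obs.std(axis=0, ddof=1)
    Z = np.where(sdR > 0, (R - R_null.mean(axis=0)) / np.where(sdR > 0, sdR, 1.0), -np.inf)
    best = np.unravel_index(np.argmax(Z), Z.shape)
    a1_star, a2_star = float(a1[best[0]]), float(a2[best[0]])
    k_star = int(k_grid[best[1]])

    m, s = _mean_se(D)
    d_obs = _stat_matrix(m, s, np.array([a1_star]), np.array([a2_star]))[:, 0]

    # permutation FDR by sign flips of the paired differences
    order = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[order]
    n_ge_obs = n_genes - np.searchsorted(d_sorted, d_obs, side="left")
    exceed = np.zeros(n_genes)
    perm_flips = _informative_flip_patterns(n_pairs, config.n_perm, rng)
    for flips in perm_flips:
        mp, sp_ = _mean_se(D * flips[None, :])
        d_p = np.sort(_stat_matrix(mp, sp_, np.array([a1_star]), np.array([a2_star]))[:, 0])
        exceed += n_genes - np.searchsorted(d_p, d_obs, side="left")
    q = exceed / len(perm_flips) / np.maximum(n_ge_obs, 1)

    # monotonize: q non-increasing in d, then clip to [0, 1]
    desc = np.argsort(-d_obs, kind="stable")
    q_desc = np.maximum.accumulate(q[desc])
    q_mon = np.empty_like(q)
    q_mon[desc] = np.clip(q_desc, 0.0, 1.0)

    direction = np.where(m < 0, "down", "up")
    table = pd.DataFrame(
        {
            "mean_log2fc": m,
            "scale": s,
            "statistic": d_obs,
            "fdr": q_mon,
            "fc": 2.0 ** np.abs(m),
            "direction": direction,
        },
        index=genes,
    )
    table.attrs["alpha1"] = a1_star
    table.attrs["alpha2"] = a2_star
    table.attrs["k"] = k_star
    table.attrs["timepoint"] = timepoint
    return table


def select_de(
    table: pd.DataFrame,
    fdr_max: float = 0.1,
    fc_min: float = 1.4,
    provenance: str = "",
) -> SignedGeneSet:
    """Genes with FDR strictly below ``fdr_max`` and linear FC strictly above
    ``fc_min``, tagged with direction."""
    keep = (table["fdr"] < fdr_max) & (table["fc"] > fc_min)
    entries = dict(zip(table.index[keep], table.loc[keep, "direction"]))
    return SignedGeneSet(entries=entries, provenance=provenance)


def zscore_matrix(expr: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Row-standardize an expression matrix (mean 0, sd 1 per gene; ddof=1)."""
    sub = expr.loc[list(genes)] if genes is not None else expr
    sd = sub.std(axis=1, ddof=1)
    zero_var = list(sub.index[sd == 0])
    if zero_var:
        raise ValueError(f"zero-variance genes cannot be standardized: {zero_var}")
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)


def common_direction_genes(set_a: SignedGeneSet, set_b: SignedGeneSet) -> SignedGeneSet:
    """Intersection of two signed gene sets restricted to matching direction."""
    entries = {
        g: d for g, d in set_a.entries.items() if set_b.entries.get(g) == d
    }
    return SignedGeneSet(
        entries=entries, provenance=f"{set_a.provenance}∩{set_b.provenance}"
    )
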