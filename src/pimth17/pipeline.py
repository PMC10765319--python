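"""End-to-end drivers tying the modules into the two analysis arms.

``bulk_de_analysis`` runs TMM normalization and the paired
reproducibility-optimized test at every timepoint, applies the FDR/FC
selection, and intersects timepoints by direction.  ``sc_analysis`` runs
QC, log-normalization, PIM⁻ classification, joint marker states, and the
downsampling-balanced Wilcoxon DE of PIM⁻ knockdown cells against the
control sample.  Both optionally write their tables under an output
directory; outputs are deterministic given the configs' seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bulk import (
    RotsConfig,
    common_direction_genes,
    compute_tmm_factors,
    drop_unexpressed,
    paired_rots_test,
    select_de,
)
from .containers import BulkExperiment, SCExperiment
from .sc import (
    DownsampleDEConfig,
    MarkerPanel,
    QCThresholds,
    classify_pim_negative,
    downsample_balanced_de,
    joint_marker_state,
    log_normalize,
    qc_filter,
)


def bulk_de_analysis(
    experiment: BulkExperiment,
    rots_config: RotsConfig | None = None,
    fdr_max: float = 0.1,
    fc_min: float = 1.4,
    outdir: str | Path | None = None,
) -> dict:
    """Paired DE at every timepoint plus the same-direction intersection."""
    rots_config = rots_config or RotsConfig()
    experiment, n_dropped = drop_unexpressed(experiment)
    factors = compute_tmm_factors(experiment)
    timepoints = list(dict.fromkeys(experiment.samples["timepoint"]))
    tables, selected = {}, {}
    for tp in timepoints:
        tables[tp] = paired_rots_test(experiment, factors, rots_config, tp)
        selected[tp] = select_de(tables[tp], fdr_max, fc_min, provenance=f"bulk_{tp}")
    common = None
    if len(timepoints) >= 2:
        common = common_direction_genes(selected[timepoints[0]], selected[timepoints[1]])
    summary = {
        "n_genes_tested": int(tables[timepoints[0]].shape[0]),
        "n_genes_dropped_unexpressed": n_dropped,
        **{f"n_de_{tp}": len(selected[tp]) for tp in timepoints},
        "n_common_same_direction": len(common) if common is not None else None,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tp, tab in tables.items():
            tab.rename_axis("gene").to_csv(outdir / f"de_table_{tp}.tsv", sep="\t")
            sel = pd.Series(selected[tp].entries, name="direction", dtype=object)
            sel.rename_axis("gene").to_csv(outdir / f"de_selected_{tp}.tsv", sep="\t")
        with open(outdir / "bulk_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return {
        "tables": tables,
        "selected": selected,
        "common": common,
        "factors": factors,
        "summary": summary,
    }


def sc_analysis(
    experiment: SCExperiment,
    thresholds: QCThresholds | None = None,
    panel: MarkerPanel | None = None,
    de_config: DownsampleDEConfig | None = None,
    case_sample: str = "TKD",
    ctrl_sample: str = "Scr",
    outdir: str | Path | None = None,
) -> dict:
    """QC → log-normalize → classify PIM⁻ → downsampling-balanced DE.

    The case group is the PIM⁻ cells of ``case_sample``; the control group
    is every QC-passing cell of ``ctrl_sample``, mirroring the knockdown
    vs scrambled-control comparison.
    """
    thresholds = thresholds or QCThresholds()
    panel = panel or MarkerPanel()
    de_config = de_config or DownsampleDEConfig()

    filtered, qc_report = qc_filter(experiment, thresholds)
    expr = log_normalize(filtered)
    pim_neg, fractions = classify_pim_negative(filtered, panel)
    states = joint_marker_state(filtered, panel)

    case_idx = np.flatnonzero(pim_neg & (filtered.sample_of == case_sample))
    ctrl_idx = np.flatnonzero(filtered.sample_of == ctrl_sample)
    de = downsample_balanced_de(
        case_idx, ctrl_idx, expr, de_config, genes=pd.Index(filtered.features["gene_name"])
    )

    cells = pd.DataFrame(
        {
            "barcode": filtered.barcodes,
            "sample": filtered.sample_of,
            "pim_negative": pim_neg,
            "joint_state": states,
        }
    )
    summary = {
        "qc": qc_report.to_dict(),
        "pim_negative_fraction": {k: float(v) for k, v in sorted(fractions.items())},
        "n_case_cells": int(case_idx.size),
        "n_ctrl_cells": int(ctrl_idx.size),
        "n_genes_ever_tested": int(de.table["ever_tested"].sum()),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cells.to_csv(outdir / "cell_classification.tsv", sep="\t", index=False)
        de.table.rename_axis("gene").to_csv(outdir / "sc_de_table.tsv", sep="\t")
        with open(outdir / "sc_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return {
        "filtered": filtered,
        "qc_report": qc_report,
        "pim_negative": pim_neg,
        "fractions": fractions,
        "states": states,
        "de": de,
        "cells": cells,
        "summary": summary,
    }
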