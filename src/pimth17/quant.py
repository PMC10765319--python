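"""Cross-modality DE concordance and small assay-quantification formulas.

Covers the overlap of signed bulk and single-cell DE gene sets, relative
qPCR quantification by the ddCt method (fold change 2^(−ΔΔCt) against an
endogenous control), and cytokine-readout normalization to live-cell count
and then to the scrambled control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SignedGeneSet


@dataclass
class CtRecord:
    """qPCR cycle thresholds for one condition: target gene and endogenous
    control (EF1α-style reference)."""

    ct_target: float
    ct_reference: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise ValueError("Ct values must be finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def average_ct(records: list[CtRecord]) -> CtRecord:
    """Arithmetic mean of technical replicates on the Ct scale."""
    if not records:
        raise ValueError("no Ct records to average")
    return CtRecord(
        ct_target=float(np.mean([r.ct_target for r in records])),
        ct_reference=float(np.mean([r.ct_reference for r in records])),
        condition=records[0].condition,
    )


def ddct_fold_change(case: CtRecord, control: CtRecord) -> float:
    """Relative expression of case vs control: FC = 2^(−ΔΔCt).

    ΔCt = Ct(target) − Ct(reference) per condition; ΔΔCt = ΔCt_case −
    ΔCt_control.  Assumes amplification efficiency 2.
    """
    ddct = case.delta_ct - control.delta_ct
    return float(2.0 ** (-ddct))


def overlap_de(
    set_a: SignedGeneSet, set_b: SignedGeneSet
) -> tuple[set[str], set[str], set[str]]:
    """(overlap, concordant, discordant) gene sets of two signed DE sets.

    Concordant genes share the regulation direction in both sets; the union
    of concordant and discordant is the overlap.
    """
    overlap = set_a.genes() & set_b.genes()
    concordant = {g for g in overlap if set_a.entries[g] == set_b.entries[g]}
    return overlap, concordant, overlap - concordant


def overlap_report(set_a: SignedGeneSet, set_b: SignedGeneSet) -> dict:
    overlap, concordant, discordant = overlap_de(set_a, set_b)
    return {
        "provenance_a": set_a.provenance,
        "provenance_b": set_b.provenance,
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_overlap": len(overlap),
        "n_concordant": len(concordant),
        "n_discordant": len(discordant),
        "overlap": sorted(overlap),
        "concordant": sorted(concordant),
        "discordant": sorted(discordant),
    }


def normalize_readout(
    values: pd.Series, live_counts: pd.Series, control_label: str
) -> pd.Series:
    """Normalize per-sample readouts by live-cell count, then to the control.

    v'_s = (values_s / live_counts_s) / (values_ctrl / live_counts_ctrl);
    the control itself maps to exactly 1.
    """
    values = pd.Series(values, dtype=float)
    live_counts = pd.Series(live_counts, dtype=float)
    if not values.index.equals(live_counts.index):
        live_counts = live_counts.reindex(values.index)
    if live_counts.isna().any():
        raise ValueError("live_counts missing for some samples")
    if (live_counts <= 0).any():
        bad = list(live_counts.index[live_counts <= 0])
        raise ValueError(f"live counts must be positive; offending samples: {bad}")
    if control_label not in values.index:
        raise ValueError(f"control sample {control_label!r} not found")
    per_cell = values / live_counts
    return per_cell / per_cell[control_label]
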