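"""Cross-modality concordance of the bulk and single-cell DE calls.

Loads a bulk selected-set TSV and the single-cell DE table, thresholds the
single-cell side by signif_prop, and reports the overlap with and without
direction concordance.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pimth17 import SignedGeneSet
from pimth17.quant import overlap_report
from pimth17.sc import call_de_genes


def load_signed_set(path: Path, provenance: str) -> SignedGeneSet:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignedGeneSet(dict(zip(df.index.astype(str), df["direction"])), provenance)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bulk-set", type=Path, default=Path("results/bulk_de/de_selected_6h.tsv"))
    ap.add_argument("--sc-table", type=Path, default=Path("results/sc_de/sc_de_table.tsv"))
    ap.add_argument("--signif-prop-min", type=float, default=0.9)
    ap.add_argument("--out", type=Path, default=Path("results/overlap_report.json"))
    args = ap.parse_args()

    bulk = load_signed_set(args.bulk_set, "bulk_6h")
    sc_table = pd.read_csv(args.sc_table, sep="\t", index_col=0)
    keep = sc_table["ever_tested"] & (sc_table["signif_prop"] >= args.signif_prop_min)
    sc = SignedGeneSet(
        {
            str(g): ("down" if sc_table.loc[g, "mean_log2fc"] < 0 else "up")
            for g in sc_table.index[keep]
        },
        "sc",
    )
    report = overlap_report(bulk, sc)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(report, fh, indent=2)
    print(f"bulk set: {report['n_a']} genes, sc set: {report['n_b']} genes")
    print(f"overlap {report['n_overlap']} (concordant {report['n_concordant']}, "
          f"discordant {report['n_discordant']})")
    print(f"report: {args.out}")


if __name__ == "__main__":
    main()
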