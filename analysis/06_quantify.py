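"""Assay quantification: ddCt fold changes and live-count-normalized readouts.

Accepts a Ct table CSV (condition, target_ct, reference_ct) and a readout
CSV (sample, value, live_count).  Without input files it runs on small
synthetic demonstration tables so the formulas can be inspected end to end.
"""

import argparse
from pathlib import Path

import pandas as pd

from pimth17.quant import CtRecord, average_ct, ddct_fold_change, normalize_readout

# synthetic demonstration inputs (not measured data)
DEMO_CT = pd.DataFrame(
    {
        "condition": ["Scr", "Scr", "TKD", "TKD"],
        "target_ct": [25.1, 24.9, 24.0, 24.2],
        "reference_ct": [20.0, 20.1, 20.0, 19.9],
    }
)
DEMO_READOUT = pd.DataFrame(
    {
        "sample": ["Scr", "TKD"],
        "value": [100.0, 150.0],
        "live_count": [1.0e5, 1.2e5],
    }
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--ct-table", type=Path, default=None)
    ap.add_argument("--readout", type=Path, default=None)
    ap.add_argument("--control", default="Scr")
    args = ap.parse_args()

    ct = pd.read_csv(args.ct_table) if args.ct_table else DEMO_CT
    readout = pd.read_csv(args.readout) if args.readout else DEMO_READOUT

    grouped = {
        cond: average_ct(
            [CtRecord(r.target_ct, r.reference_ct, cond) for r in sub.itertuples()]
        )
        for cond, sub in ct.groupby("condition")
    }
    control = grouped[args.control]
    print("ddCt fold changes vs", args.control)
    for cond, rec in grouped.items():
        print(f"  {cond}: FC = {ddct_fold_change(rec, control):.3f}")

    values = readout.set_index("sample")["value"]
    live = readout.set_index("sample")["live_count"]
    norm = normalize_readout(values, live, args.control)
    print(f"readout normalized to live count and {args.control}:")
    for s, v in norm.items():
        print(f"  {s}: {v:.3f}")


if __name__ == "__main__":
    main()
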