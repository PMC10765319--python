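"""Paired bulk differential expression.

Reads a counts/samples TSV pair, runs TMM normalization and the paired
reproducibility-optimized test at each timepoint, selects genes at
FDR < 0.1 and FC > 1.4, and reports how many calls the two timepoints
share with matching direction.  If a truth.json from the simulator sits
next to the counts, recovery (realized FDR, sensitivity) is printed too.
"""

import argparse
import json
from pathlib import Path

from pimth17 import RotsConfig, bulk_de_analysis
from pimth17.io import read_bulk


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--counts", type=Path, default=Path("results/bulk_sim/counts.tsv"))
    ap.add_argument("--samples", type=Path, default=Path("results/bulk_sim/samples.tsv"))
    ap.add_argument("--fdr", type=float, default=0.1)
    ap.add_argument("--fc", type=float, default=1.4)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/bulk_de"))
    args = ap.parse_args()

    experiment = read_bulk(args.counts, args.samples)
    result = bulk_de_analysis(
        experiment,
        RotsConfig(seed=args.seed),
        fdr_max=args.fdr,
        fc_min=args.fc,
        outdir=args.outdir,
    )
    for key, val in result["summary"].items():
        print(f"{key}: {val}")

    truth_path = args.counts.parent / "truth.json"
    if truth_path.exists():
        truth = set(json.load(open(truth_path))["de_genes"])
        for tp, sel in result["selected"].items():
            called = sel.genes()
            tp_hits = len(called & truth)
            fdr = (len(called) - tp_hits) / max(len(called), 1)
            sens = tp_hits / max(len(truth), 1)
            print(f"{tp}: realized FDR {fdr:.3f}, sensitivity {sens:.3f}")


if __name__ == "__main__":
    main()
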