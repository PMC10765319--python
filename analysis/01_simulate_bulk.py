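"""Simulate the paired bulk RNA-seq dataset.

Generates a gene × sample count matrix with the paired design of the
study system — four donor pairs, Scr and TKD conditions, 6h and 24h
timepoints — with 10% of genes carrying a planted |log2FC| = 1.5 condition
effect, and writes the counts TSV, samples TSV and the planted truth.
"""

import argparse
import json
from pathlib import Path

from pimth17 import BulkSimConfig, generate_bulk
from pimth17.io import write_bulk
from pimth17.simulate import STUDY_EFFECT_GENES


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-genes", type=int, default=1000)
    ap.add_argument("--de-fraction", type=float, default=0.1)
    ap.add_argument("--outdir", type=Path, default=Path("results/bulk_sim"))
    args = ap.parse_args()

    config = BulkSimConfig(
        n_genes=args.n_genes,
        de_fraction=args.de_fraction,
        effect_genes=dict(STUDY_EFFECT_GENES),
        seed=args.seed,
    )
    experiment, truth = generate_bulk(config)
    paths = write_bulk(experiment, args.outdir)
    with open(args.outdir / "truth.json", "w") as fh:
        json.dump({"de_genes": truth.de_genes}, fh, indent=2, sort_keys=True)

    print(f"wrote {experiment.n_genes} genes × {experiment.n_samples} samples")
    print(f"planted DE genes: {len(truth.de_genes)}")
    for k, p in paths.items():
        print(f"  {k}: {p}")


if __name__ == "__main__":
    main()
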