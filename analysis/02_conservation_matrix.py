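#!/usr/bin/env python
"""Build the region-by-region conservation matrix of a simulated family.

For each taxon and each annotated region, globally aligns the two region
subsequences and reports percent identity, its color band (green 85-100,
blue 70-84, yellow 55-69, red <55), and an indel note for gap runs of 3+
columns. Writes results/conservation/matrix.tsv and a plain-text banded
report, and prints the realized ordering of domain vs IDR conservation.
"""

import argparse
from pathlib import Path

from idrcons.conservation import region_identity_matrix
from idrcons.seq_regions import RegionClass
from idrcons.simulate import simulate_family


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path,
                    default=Path("results/conservation"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    truth = simulate_family(seed=args.seed)
    others = [(r, truth.region_sets[r.id]) for r in truth.taxa]
    matrix = region_identity_matrix(
        truth.reference, truth.region_sets["ref"], others)
    matrix.to_tsv(args.outdir / "matrix.tsv")
    report = matrix.to_text()
    (args.outdir / "matrix.txt").write_text(report + "\n")
    print(report)

    klass = {r.name: r.klass for r in truth.region_sets["ref"]}
    frame = matrix.to_frame()
    dom = frame[[n for n, k in klass.items()
                 if k is RegionClass.DOMAIN]].mean().mean()
    idr = frame[[n for n, k in klass.items()
                 if k is RegionClass.IDR]].mean().mean()
    print(f"\nmean domain identity {dom:.1f}% vs mean IDR identity {idr:.1f}%"
          f" — folded domains stay alignable while the IDR drifts toward the"
          f" 5% random floor")


if __name__ == "__main__":
    main()
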