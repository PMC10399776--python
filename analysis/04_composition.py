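#!/usr/bin/env python
"""Compare two IDRs by length, residue enrichment and charged fraction.

Contrasts the simulated reference IDR with a composition-biased counterpart
(glutamine/serine-rich, the signature of many insect IDRs) to show the
side-by-side property report. Writes results/composition/idr_comparison.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from idrcons.composition import aa_composition, idr_property_report
from idrcons.seq_regions import ProteinRecord, extract_region
from idrcons.simulate import simulate_family


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path,
                    default=Path("results/composition"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    truth = simulate_family(seed=args.seed)
    ref_idr = extract_region(truth.reference,
                             truth.region_sets["ref"].get("IDR"))

    # a Q/S/N-biased IDR of different length, as a composition contrast
    rng = np.random.default_rng(args.seed)
    residues = list("QSNAGPTEDKRLIVFMHWYC")
    probs = np.array([0.17, 0.11, 0.09] + [0.63 / 17] * 17)
    qs_idr = ProteinRecord("qs_rich|IDR", "".join(
        rng.choice(residues, size=360, p=probs / probs.sum())))

    rep_a = aa_composition(ref_idr, region="IDR")
    rep_b = aa_composition(qs_idr, region="IDR")
    cmp = idr_property_report(rep_a, rep_b)

    df = pd.DataFrame([
        {"metric": "length_aa", rep_a.protein_id: rep_a.length,
         rep_b.protein_id: rep_b.length},
        {"metric": "top3", rep_a.protein_id: ",".join(rep_a.top3),
         rep_b.protein_id: ",".join(rep_b.top3)},
        {"metric": "charged_pct",
         rep_a.protein_id: round(rep_a.charged_fraction, 1),
         rep_b.protein_id: round(rep_b.charged_fraction, 1)},
    ])
    df.to_csv(args.outdir / "idr_comparison.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\nlength difference {cmp.length_difference} aa, "
          f"charged-fraction difference {cmp.charged_difference:+.1f} points; "
          f"disjoint top-3 enrichment: "
          f"{not set(cmp.top3_a) & set(cmp.top3_b)}")


if __name__ == "__main__":
    main()
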