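#!/usr/bin/env python
"""Phenotype statistics on simulated cuticle and imaging data.

Scores simulated cuticle tables (0-5 ordinal categories), prints the
Mendelian lethality expectations for the two cross designs, and estimates
the mutant/control junctional-intensity ratio with its delta-method standard
deviation from a simulated two-group imaging experiment (true ratio 0.5).
Writes results/phenotypes/{cuticle_scores.tsv,intensity_ratio.tsv}.
"""

import argparse
from pathlib import Path

import pandas as pd

from idrcons.pheno import (CrossModel, CrossPreset, cuticle_score,
                           delta_ratio, expected_lethality,
                           relative_viability)
from idrcons.simulate import simulate_phenotypes


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/phenotypes"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    truth = simulate_phenotypes(seed=args.seed)

    rows = []
    for genotype, table in truth.cuticle_tables.items():
        out = cuticle_score(table)
        rows.append({"genotype": genotype, "n": out["n"],
                     "mean_score": round(out["mean_score"], 2),
                     "true_mean": round(truth.true_mean_scores[genotype], 2),
                     **{f"cat{k}": round(v, 3)
                        for k, v in out["distribution"].items()}})
    scores = pd.DataFrame(rows)
    scores.to_csv(args.outdir / "cuticle_scores.tsv", sep="\t", index=False)
    print(scores.to_string(index=False))

    het = CrossModel(CrossPreset.HET_X_HET_ZYGOTIC,
                     homozygote_viability=0.0, heterozygote_viability=1.0)
    glc = CrossModel(CrossPreset.GERMLINE_CLONE_X_HET,
                     homozygote_viability=0.0, zygotic_rescue=1.0)
    print(f"\nexpected lethality: het x het {expected_lethality(het):.0f}%, "
          f"germline clone x het {expected_lethality(glc):.0f}%")
    print(f"relative viability for counts (54, 46): "
          f"{relative_viability(54, 46):.0f}% of total progeny")

    est = delta_ratio(truth.x_values, truth.y_values)
    pd.DataFrame([{
        "ratio_pct": round(est.ratio_pct, 1),
        "sd_pct": round(100 * est.sd, 1),
        "true_ratio_pct": 100 * truth.true_ratio,
        "mu_x": round(est.mu_x, 1), "mu_y": round(est.mu_y, 1),
        "var_x": round(est.var_x, 1), "var_y": round(est.var_y, 1),
    }]).to_csv(args.outdir / "intensity_ratio.tsv", sep="\t", index=False)
    print(f"\njunctional intensity ratio {est.ratio_pct:.1f}% "
          f"+/- {100 * est.sd:.1f}% (delta method; truth "
          f"{100 * truth.true_ratio:.0f}%)")


if __name__ == "__main__":
    main()
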