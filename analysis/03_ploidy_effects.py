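#!/usr/bin/env python
"""Call ploidy-environment interactions and classify their conservation.

Per species and trait, the mean of the two haploid mating-type means is
compared to the diploid mean across strains (two-tailed homoscedastic
t-test, BH-FDR at alpha = 0.05 within species). A trait's effect is
conserved when significant with the same sign in both species. Reports
the fraction of environments affected and checks both against the
generator's planted truth.
"""

from pathlib import Path

import pandas as pd

from ploidypheno import io as pio
from ploidypheno.effects import (
    conserved_effects, fraction_significant_environments, ploidy_effect_table,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    matrix = pio.read_trait_matrix(OUT / "trait_matrix.tsv")
    meta = pio.read_meta(OUT / "meta.tsv")
    records = ploidy_effect_table(matrix, meta[~meta.is_standard], alpha=0.05)
    records.to_csv(OUT / "effects.tsv", sep="\t", index=False, float_format="%.8g")

    for sp, grp in records.groupby("species"):
        print(f"{sp}: {int(grp['significant'].sum())}/{len(grp)} trait records significant")

    envs = sorted(records["environment"].unique())
    frac_any = fraction_significant_environments(records, envs, mode="any")
    frac_all = fraction_significant_environments(records, envs, mode="all")
    print(f"environments with >=1 significant component: {frac_any:.1%}")
    print(f"environments significant for all components: {frac_all:.1%}")

    truth = pd.read_csv(OUT / "truth_traits.tsv", sep="\t")
    planted = truth.groupby("environment")["affected"].any().mean()
    print(f"planted fraction of affected environments:   {planted:.1%}")

    conservation = conserved_effects(records)
    conservation.to_csv(OUT / "conservation.tsv", sep="\t", index=False, float_format="%.8g")
    counts = conservation["classification"].value_counts()
    print("conservation classes:", dict(counts))


if __name__ == "__main__":
    main()
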