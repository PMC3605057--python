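#!/usr/bin/env python
"""Normalize raw components to the internal wild-type standard (LSC scale).

Each measurement is log2-transformed and referenced to the mean log2 of
the same-run haploid-reference wells; the efficiency axis is inverted so
that larger LSC = worse performance for every component. Writes the
strain x trait matrix (rows: strain x ploidy x mating type).
"""

from pathlib import Path

import pandas as pd

from ploidypheno import io as pio
from ploidypheno.normalize import build_trait_matrix

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    components = pd.read_csv(OUT / "components.tsv", sep="\t")
    matrix, counts = build_trait_matrix(components)
    pio.write_trait_matrix(matrix, OUT / "trait_matrix.tsv", counts=counts)
    n_cells = matrix.notna().sum().sum()
    print(f"trait matrix: {matrix.shape[0]} strain-variants x {matrix.shape[1]} traits, "
          f"{n_cells} filled cells ({n_cells / matrix.size:.1%})")
    print(f"missing cells come from censored lags / non-grown cultures")
    print(f"wrote {OUT / 'trait_matrix.tsv'} (+ .json sidecar with replicate counts)")


if __name__ == "__main__":
    main()
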