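#!/usr/bin/env python
"""Partition ploidy-effect similarity by species, population and source.

Per strain, the ploidy effect (haploid score minus diploid) per trait
forms a profile; pairwise Pearson correlations of these profiles measure
how similarly two strains respond to ploidy. One-way ANOVA on the
within/between labels of each factor quantifies the explained variance
(adjusted R^2). Population and source partitions use S. cerevisiae pairs
only. Also writes the UPGMA dendrogram (centered Pearson distance).
"""

from pathlib import Path

from ploidypheno import io as pio
from ploidypheno.effects import per_strain_effect_matrix
from ploidypheno.similarity import (
    label_pairs, pairwise_similarity, partition, scale_traits, to_newick, upgma_cluster,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    matrix = pio.read_trait_matrix(OUT / "trait_matrix.tsv")
    meta = pio.read_meta(OUT / "meta.tsv")
    strain_meta = meta[~meta.is_standard][
        ["strain_id", "species", "population", "source"]
    ].drop_duplicates().reset_index(drop=True)

    effect_matrix = per_strain_effect_matrix(matrix)
    scaled = scale_traits(effect_matrix)
    pairs = pairwise_similarity(scaled)
    pairs.to_csv(OUT / "pairs.tsv", sep="\t", index=False, float_format="%.8g")
    print(f"{len(pairs)} strain pairs over {scaled.shape[1]} traits "
          f"({int(pairs['valid'].sum())} valid)")

    cer = list(strain_meta.loc[strain_meta.species == "cerevisiae", "strain_id"])
    for factor, universe in (("species", None), ("population", cer), ("source", cer)):
        labelled = label_pairs(pairs, strain_meta, factor, universe=universe)
        res = partition(labelled, factor=factor)
        print(f"{factor:<11} F={res.F:8.2f}  p={res.p_value:9.3g}  "
              f"adjR2={res.adj_r2: .4f}  pairs={res.n_within} within / {res.n_between} between")

    tree = upgma_cluster(scaled)
    pio.write_newick(to_newick(tree), OUT / "ploidy_effects.nwk")
    print(f"wrote UPGMA tree over {len(tree.labels)} strains -> {OUT/'ploidy_effects.nwk'}")


if __name__ == "__main__":
    main()
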