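"""End-to-end orchestration: simulate -> extract -> normalize -> effects ->
similarity/partition -> cluster.

The pipeline is a pure function of (config, seed): re-running with the same
configuration reproduces every output table byte for byte. Each stage logs
its record count and the run writes a JSON manifest with the seed, stage
counts and output hashes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import effects as eff
from . import io as pio
from . import similarity as sim
from .growth import ExtractionParams, extract_table
from .normalize import build_trait_matrix
from .synthetic import (
    TruthConfig,
    make_design,
    make_panel,
    design_size,
    simulate_experiment,
    meta_to_frame,
)

log = logging.getLogger("ploidypheno")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Defaults reproduce the full study design; the ``demo`` preset in the
    CLI shrinks it to 6 strains x 4 environments.
    """

    seed: int = 0
    out_dir: str = "results"
    n_cerevisiae: int = 24
    n_paradoxus: int = 27
    n_environments: int = 33
    replicates_per_mating_type: int = 2
    replicates_diploid: int = 4
    standards_per_run: int = 8
    alpha: float = 0.05
    window: int = 5
    flip_sign: bool = False
    write_curves: bool = False  # the long curve table is large; opt in
    truth: TruthConfig = field(default_factory=TruthConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        truth = TruthConfig(**raw.pop("truth", {}))
        return cls(truth=truth, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns a result bundle of DataFrames/paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    log.info("stage simulate: building design")
    panel = make_panel(config.n_cerevisiae, config.n_paradoxus, seed=config.seed)
    from .synthetic import DEFAULT_ENVIRONMENTS

    envs = DEFAULT_ENVIRONMENTS[: config.n_environments]
    design = make_design(
        panel=panel,
        environments=envs,
        replicates_per_mating_type=config.replicates_per_mating_type,
        replicates_diploid=config.replicates_diploid,
        standards_per_run=config.standards_per_run,
    )
    counts["design_cultures"] = design_size(design)
    curves, truth_table = simulate_experiment(design, config.truth, seed=config.seed)
    counts["curves"] = len(curves)
    log.info("stage simulate: %d curves (%d non-standard)", len(curves), counts["design_cultures"])

    meta = meta_to_frame(curves, panel)
    pio.write_meta(meta, out / "meta.tsv")
    truth_table.cultures.to_csv(out / "truth_cultures.tsv", sep="\t", index=False, float_format="%.8g")
    truth_table.trait_effects.to_csv(out / "truth_traits.tsv", sep="\t", index=False, float_format="%.8g")
    if config.write_curves:
        pio.write_curves(curves, out / "curves.tsv")

    log.info("stage extract")
    params = ExtractionParams(window=config.window, blank=config.truth.blank_od)
    components = extract_table(curves, params)
    counts["components"] = len(components)
    components.to_csv(out / "components.tsv", sep="\t", index=False, float_format="%.8g")

    log.info("stage normalize")
    matrix, rep_counts = build_trait_matrix(components, flip_sign=config.flip_sign)
    counts["matrix_cells"] = int(matrix.notna().sum().sum())
    pio.write_trait_matrix(matrix, out / "trait_matrix.tsv", counts=rep_counts)

    log.info("stage effects")
    records = eff.ploidy_effect_table(matrix, meta[~meta.is_standard], alpha=config.alpha)
    counts["effect_records"] = len(records)
    records.to_csv(out / "effects.tsv", sep="\t", index=False, float_format="%.8g")
    conservation = eff.conserved_effects(records)
    conservation.to_csv(out / "conservation.tsv", sep="\t", index=False, float_format="%.8g")
    frac_any = eff.fraction_significant_environments(records, envs, mode="any")
    frac_all = eff.fraction_significant_environments(records, envs, mode="all")

    log.info("stage similarity/partition")
    effect_matrix = eff.per_strain_effect_matrix(matrix)
    scaled = sim.scale_traits(effect_matrix)
    pairs = sim.pairwise_similarity(scaled)
    counts["pairs"] = len(pairs)
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False, float_format="%.8g")

    strain_meta = (
        meta[~meta.is_standard][["strain_id", "species", "population", "source"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    cer = strain_meta.loc[strain_meta.species == "cerevisiae", "strain_id"]
    partitions = {}
    for factor, universe in (
        ("species", None),
        ("population", list(cer)),
        ("source", list(cer)),
    ):
        labelled = sim.label_pairs(pairs, strain_meta, factor, universe=universe)
        try:
            partitions[factor] = sim.partition(labelled, factor=factor)
        except ValueError as exc:  # degenerate small demo designs
            log.warning("partition %s skipped: %s", factor, exc)
    part_frame = pd.DataFrame(
        [
            dict(factor=k, F=v.F, p_value=v.p_value, adj_r2=v.adj_r2,
                 n_within=v.n_within, n_between=v.n_between,
                 mean_within=v.group_means["within"], mean_between=v.group_means["between"])
            for k, v in partitions.items()
        ]
    )
    part_frame.to_csv(out / "partition.tsv", sep="\t", index=False, float_format="%.8g")

    log.info("stage cluster")
    tree = sim.upgma_cluster(scaled)
    newick = sim.to_newick(tree)
    pio.write_newick(newick, out / "ploidy_effects.nwk")

    summary = dict(
        fraction_significant_environments_any=frac_any,
        fraction_significant_environments_all=frac_all,
        conserved_traits=int(conservation["conserved"].sum()),
        total_traits=len(conservation),
    )
    pio.write_manifest(
        out / "manifest.json",
        seed=config.seed,
        config=_config_dict(config),
        stage_counts=counts,
        summary=summary,
        outputs={
            p.name: pio.file_sha256(p)
            for p in sorted(out.glob("*.tsv"))
        },
    )
    return dict(
        design=design,
        truth=truth_table,
        meta=meta,
        components=components,
        matrix=matrix,
        effects=records,
        conservation=conservation,
        pairs=pairs,
        partitions=partitions,
        tree=tree,
        newick=newick,
        summary=summary,
        counts=counts,
        out_dir=out,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
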