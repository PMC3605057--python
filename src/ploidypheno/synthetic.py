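"""Synthetic growth-curve experiments with known ground truth.

This module emulates a high-throughput yeast phenomics screen: a panel of
natural isolates of two *Saccharomyces* species, each cultivated as two
haploid mating types and as an autodiploid across a battery of environments
in microcultivation runs, with replicate wells of a haploid reference
strain on every run serving as the internal normalization standard.

Population growth is modelled on the log2 (doublings) scale with the
Zwietering modified-Gompertz form

    l(t) = E * exp(-exp(e * s / E * (lag - t) + 1))

where ``s`` is the maximum specific growth rate in doublings per hour
(1/doubling time), ``lag`` the adaptation time in hours, and
``E = log2((baseline + amplitude) / baseline)`` the total number of
doublings. The observed optical density is
``OD(t) = blank + baseline * 2**l(t)`` plus additive Gaussian measurement
noise truncated at zero. The three parameters map one-to-one onto the
fitness components extracted downstream: the maximum slope of
``log2(OD - blank)`` equals ``s``, the tangent through the inflection
crosses the baseline level at ``t = lag``, and ``OD(inf) - OD(0)``
approaches ``amplitude``.

Trait architecture
------------------
Each culture's three latent parameters are composed additively on the log2
scale from a component baseline, strain effects (species + population +
strain deviations), an environment effect, a per-run offset (shared with
the standards, so it cancels under internal-standard normalization), a
ploidy term, and culture-level biological noise. The ploidy term for trait
*j* (environment x component) is ``+/- delta_ij / 2`` with the sign chosen
so that the haploid-minus-diploid difference on the *LSC* scale equals
``delta_ij`` for every component (the efficiency LSC is sign-inverted
downstream). Species-level effects ``delta_j`` are drawn per trait from a
bivariate normal across the two species with correlation ``rho``
(cross-species conservation), and are zero outside the planted fraction of
affected environments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    DesignSpec,
    GrowthCurve,
    StrainMeta,
    TruthTable,
    COMPONENTS,
    SOURCES,
)

__all__ = [
    "DEFAULT_ENVIRONMENTS",
    "TruthConfig",
    "make_panel",
    "make_design",
    "design_size",
    "gompertz_log2",
    "simulate_curve",
    "simulate_experiment",
    "simulate_trait_dataset",
    "curves_to_frame",
    "meta_to_frame",
]

#: Clean-lineage population labels per species (mosaic strains would carry
#: their majority-donor label).
POPULATIONS = {
    "cerevisiae": ["European", "WestAfrican", "NorthAmerican", "Malaysian", "Sake"],
    "paradoxus": ["European", "FarEastern", "American"],
}

#: A 33-environment battery patterned on a natural-isolate phenomics screen:
#: a permissive basal medium, temperature and pH variants, alternative carbon
#: and nitrogen sources, micronutrient depletions, salts, metals and drugs
#: (DNA-damaging agents, TOR inhibitors, oxidants).
DEFAULT_ENVIRONMENTS = [
    "SD_basal",
    "heat_37C",
    "cold_16C",
    "pH_3.5",
    "pH_8.0",
    "NaCl_0.85M",
    "LiCl_0.225M",
    "KCl_1M",
    "sorbitol_1.5M",
    "ethanol_6pct",
    "glycerol_carbon",
    "galactose_carbon",
    "maltose_carbon",
    "raffinose_carbon",
    "acetate_carbon",
    "N_proline",
    "N_tryptophan",
    "N_leucine",
    "N_phenylalanine",
    "N_urea",
    "N_isoleucine",
    "no_inositol",
    "no_zinc",
    "no_magnesium",
    "Cu_2mM",
    "paraquat_0.5mM",
    "H2O2_1mM",
    "phleomycin",
    "doxorubicin",
    "cisplatin",
    "hydroxyurea",
    "rapamycin",
    "caffeine_10mM",
]


@dataclass
class TruthConfig:
    """Latent-parameter architecture of a simulated experiment.

    All standard deviations are on the log2 scale of the underlying
    component (lag in h, doubling time in h, efficiency amplitude in OD
    units) unless noted otherwise.

    Parameters
    ----------
    lag_base_h, doubling_time_base_h, efficiency_base_od
        Baseline component values in a permissive environment.
    baseline_od
        Inoculation population density (above blank) in OD units.
    blank_od
        Instrument blank added to every reading.
    od_noise_sd
        Additive Gaussian measurement noise on OD readings, truncated at 0.
    sigma_species, sigma_population, sigma_strain
        Phenotype variance components across strains.
    sigma_env
        Spread of environment main effects.
    sigma_noise
        Culture-level (biological replicate) noise.
    run_offset_sd
        Per-run additive log2 offset shared by all wells of the run,
        standards included; exercised by the internal-standard
        normalization, which must cancel it exactly.
    prob_env_affected
        Fraction of environments planted with a true ploidy effect.
    ploidy_effect_sd
        Scale of planted species-level ploidy effects ``delta_j``.
    rho_conservation
        Correlation of ``delta_j`` between the two species (1 = fully
        conserved, 0 = independent).
    sigma_delta_population, sigma_delta_strain
        Population- and strain-level deviations of the ploidy effect around
        the species value; these create the strain-pair similarity
        structure partitioned downstream.
    multiplicative_noise_sd
        Optional multiplicative OD noise component; off (0) by default.
    """

    lag_base_h: float = 4.0
    doubling_time_base_h: float = 2.0
    efficiency_base_od: float = 1.2
    baseline_od: float = 0.1
    blank_od: float = 0.05
    od_noise_sd: float = 0.01
    sigma_species: float = 0.3
    sigma_population: float = 0.1
    sigma_strain: float = 0.2
    sigma_env: float = 0.3
    sigma_noise: float = 0.1
    run_offset_sd: float = 0.05
    prob_env_affected: float = 0.7
    ploidy_effect_sd: float = 0.5
    rho_conservation: float = 0.9
    sigma_delta_population: float = 0.1
    sigma_delta_strain: float = 0.1
    multiplicative_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_conservation <= 1.0:
            raise ValueError("rho_conservation must lie in [0, 1]")
        for name in (
            "sigma_species",
            "sigma_population",
            "sigma_strain",
            "sigma_env",
            "sigma_noise",
            "run_offset_sd",
            "ploidy_effect_sd",
            "sigma_delta_population",
            "sigma_delta_strain",
            "od_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.prob_env_affected <= 1.0:
            raise ValueError("prob_env_affected must lie in [0, 1]")
        if self.doubling_time_base_h <= 0 or self.efficiency_base_od <= 0:
            raise ValueError("baseline doubling time and efficiency must be > 0")


def make_panel(
    n_cerevisiae: int,
    n_paradoxus: int,
    populations_per_species: int = 4,
    seed: int = 0,
) -> list[StrainMeta]:
    """Generate a strain panel of two species with population structure.

    The first *S. cerevisiae* strain is the lab reference (the internal
    standard, an S288c-like strain assigned to the European population and
    the lab source). Population and source labels for the remaining strains
    are drawn reproducibly from ``seed``.

    Parameters
    ----------
    n_cerevisiae, n_paradoxus : int
        Panel size per species; must be >= 1.
    populations_per_species : int
        How many of each species' population labels to use.
    seed : int
        Master seed for label assignment.
    """
    if n_cerevisiae < 1 or n_paradoxus < 1:
        raise ValueError("panel counts must be >= 1")
    if populations_per_species < 1:
        raise ValueError("populations_per_species must be >= 1")
    rng = np.random.default_rng(seed)
    panel: list[StrainMeta] = []
    for species, n, prefix in (
        ("cerevisiae", n_cerevisiae, "SC"),
        ("paradoxus", n_paradoxus, "SP"),
    ):
        pops = POPULATIONS[species][: min(populations_per_species, len(POPULATIONS[species]))]
        for i in range(n):
            is_ref = species == "cerevisiae" and i == 0
            if is_ref:
                pop, source = "European", "lab"
            else:
                pop = pops[int(rng.integers(len(pops)))]
                source = SOURCES[int(rng.integers(len(SOURCES)))]
            panel.append(
                StrainMeta(
                    strain_id=f"{prefix}{i + 1:02d}",
                    species=species,
                    population=pop,
                    source=source,
                    is_reference=is_ref,
                )
            )
    return panel


def make_design(
    panel: Optional[Sequence[StrainMeta]] = None,
    environments: Optional[Sequence[str]] = None,
    **kwargs,
) -> DesignSpec:
    """Convenience constructor with study-scale defaults.

    With no arguments this reproduces the full design: 24 + 27 strains, 33
    environments, 2 replicates per haploid mating type, 4 diploid
    replicates, 8 standards per run, OD sampled every 20 min for 72 h.
    """
    if panel is None:
        panel = make_panel(24, 27, seed=kwargs.pop("panel_seed", 0))
    if environments is None:
        environments = list(DEFAULT_ENVIRONMENTS)
    return DesignSpec(panel=list(panel), environments=list(environments), **kwargs)


def design_size(design: DesignSpec) -> int:
    """Number of non-standard cultures in a design.

    ``|panel| * (2 * replicates_per_mating_type + replicates_diploid) * |environments|``.
    """
    return len(design.panel) * design.cultures_per_strain_env * len(design.environments)


def gompertz_log2(
    t: np.ndarray, lag: float, doubling_time: float, n_doublings: float
) -> np.ndarray:
    """Modified-Gompertz growth signal on the log2 (doublings) scale.

    Maximum slope is ``1/doubling_time`` doublings/h; the tangent through
    the inflection point crosses zero at ``t = lag``; the asymptote is
    ``n_doublings``.
    """
    s = 1.0 / doubling_time
    return n_doublings * np.exp(-np.exp(np.e * s / n_doublings * (lag - t) + 1.0))


def _curve_seed(master_seed: int, run_id: str, well_id: str) -> int:
    """Stable per-curve seed: master seed combined with a CRC of (run, well)."""
    tag = zlib.crc32(f"{run_id}|{well_id}".encode())
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_curve(
    lag: float,
    doubling_time: float,
    amplitude: float,
    baseline: float,
    noise_sd: float,
    times: np.ndarray,
    seed: int,
    blank: float = 0.0,
    well_id: str = "w0",
    strain_id: str = "S",
    ploidy: str = "haploid",
    mating_type: str = "alpha",
    environment: str = "SD_basal",
    run_id: str = "r0",
    is_standard: bool = False,
    multiplicative_noise_sd: float = 0.0,
) -> GrowthCurve:
    """Simulate one well's OD time series.

    Parameters
    ----------
    lag : float
        Adaptation time in hours.
    doubling_time : float
        Population doubling time in hours (> 0).
    amplitude : float
        Total change in population density, OD units (> 0).
    baseline : float
        Inoculation density above blank, OD units (> 0).
    noise_sd : float
        Additive Gaussian OD noise, truncated so OD >= 0.
    times : array
        Sampling grid in hours.
    seed : int
        Seed for the measurement-noise stream.
    """
    params = dict(lag=lag, doubling_time=doubling_time, amplitude=amplitude, baseline=baseline)
    for name, v in params.items():
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    if doubling_time <= 0:
        raise ValueError("doubling_time must be > 0")
    if amplitude <= 0 or baseline <= 0:
        raise ValueError("amplitude and baseline must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = np.asarray(times, dtype=float)
    n_doublings = np.log2((baseline + amplitude) / baseline)
    pop = baseline * 2.0 ** gompertz_log2(times, lag, doubling_time, n_doublings)
    od = blank + pop
    if noise_sd > 0 or multiplicative_noise_sd > 0:
        rng = np.random.default_rng(seed)
        if multiplicative_noise_sd > 0:
            od = od * (1.0 + multiplicative_noise_sd * rng.standard_normal(times.size))
        od = od + noise_sd * rng.standard_normal(times.size)
    od = np.maximum(od, 0.0)
    return GrowthCurve(
        well_id=well_id,
        strain_id=strain_id,
        ploidy=ploidy,
        mating_type=mating_type,
        environment=environment,
        run_id=run_id,
        times=times,
        od=od,
        is_standard=is_standard,
    )


def _draw_trait_truth(
    design: DesignSpec, truth: TruthConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw species-level deltas per trait and per-strain deviations."""
    envs = design.environments
    rho = truth.rho_conservation
    cov = truth.ploidy_effect_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    rows = []
    for env in envs:
        affected = rng.random() < truth.prob_env_affected
        for comp in COMPONENTS:
            if affected and truth.ploidy_effect_sd > 0:
                d_cer, d_par = rng.multivariate_normal([0.0, 0.0], cov)
            else:
                d_cer = d_par = 0.0
            rows.append((env, comp, affected, d_cer, d_par))
    trait_effects = pd.DataFrame(
        rows, columns=["environment", "component", "affected", "delta_cerevisiae", "delta_paradoxus"]
    )

    # Per-strain delta = species delta + population deviation + strain deviation.
    traits = pd.MultiIndex.from_frame(trait_effects[["environment", "component"]])
    strains = [s.strain_id for s in design.panel]
    delta_sp = np.where(
        np.array([s.species for s in design.panel])[:, None] == "cerevisiae",
        trait_effects["delta_cerevisiae"].to_numpy()[None, :],
        trait_effects["delta_paradoxus"].to_numpy()[None, :],
    )
    pops = sorted({(s.species, s.population) for s in design.panel})
    pop_dev = {
        p: rng.normal(0.0, truth.sigma_delta_population, size=len(traits)) for p in pops
    }
    dev = np.array([pop_dev[(s.species, s.population)] for s in design.panel])
    dev = dev + rng.normal(0.0, truth.sigma_delta_strain, size=(len(strains), len(traits)))
    strain_deltas = pd.DataFrame(delta_sp + dev, index=pd.Index(strains, name="strain_id"), columns=traits)
    return trait_effects, strain_deltas


def _assign_runs(design: DesignSpec) -> dict[str, list[str]]:
    """Chunk each environment's cultures into runs; returns env -> run ids."""
    n_cultures = len(design.panel) * design.cultures_per_strain_env
    capacity = design.wells_per_run - design.standards_per_run
    if capacity < 1:
        raise ValueError("wells_per_run must exceed standards_per_run")
    if design.runs_per_environment is not None:
        n_runs = design.runs_per_environment
    else:
        n_runs = max(1, -(-n_cultures // capacity))  # ceil division
    return {
        env: [f"{env}::run{k + 1}" for k in range(n_runs)] for env in design.environments
    }


def simulate_experiment(
    design: DesignSpec,
    truth: Optional[TruthConfig] = None,
    seed: int = 0,
) -> tuple[list[GrowthCurve], TruthTable]:
    """Simulate a full cultivation experiment.

    Every design cell (strain x environment x ploidy variant x replicate) is
    realized as a growth curve whose latent (lag, doubling time, amplitude)
    encode baseline + strain + environment + ploidy x environment effects
    per ``truth``; the internal-standard strain is simulated in every run.

    Returns the curves and a :class:`TruthTable` recording all latent
    values. Re-running with the same arguments is bit-identical.
    """
    if truth is None:
        truth = TruthConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 901]))
    trait_effects, strain_deltas = _draw_trait_truth(design, truth, rng)
    envs = design.environments
    strains = design.panel
    ref = design.reference()

    # Strain effects per component: species + population + strain deviations.
    comp_idx = {c: i for i, c in enumerate(COMPONENTS)}
    sp_eff = {
        (sp, c): rng.normal(0.0, truth.sigma_species) for sp in ("cerevisiae", "paradoxus") for c in COMPONENTS
    }
    pop_eff = {
        (s.species, s.population, c): 0.0 for s in strains for c in COMPONENTS
    }
    for key in sorted(pop_eff):
        pop_eff[key] = rng.normal(0.0, truth.sigma_population)
    g = {
        (s.strain_id, c): sp_eff[(s.species, c)]
        + pop_eff[(s.species, s.population, c)]
        + rng.normal(0.0, truth.sigma_strain)
        for s in strains
        for c in COMPONENTS
    }
    h = {(e, c): rng.normal(0.0, truth.sigma_env) for e in envs for c in COMPONENTS}

    runs_by_env = _assign_runs(design)
    run_offsets = {
        (r, c): rng.normal(0.0, truth.run_offset_sd)
        for env in envs
        for r in runs_by_env[env]
        for c in COMPONENTS
    }

    base = {
        "lag": np.log2(truth.lag_base_h),
        "rate": np.log2(truth.doubling_time_base_h),
        "efficiency": np.log2(truth.efficiency_base_od),
    }
    # Sign of the ploidy half-effect per component, chosen so that the
    # haploid-minus-diploid LSC difference equals delta for every component
    # (efficiency LSC is inverted downstream).
    ploidy_sign = {"lag": 1.0, "rate": 1.0, "efficiency": -1.0}

    times = design.times()
    curves: list[GrowthCurve] = []
    truth_rows: list[dict] = []
    # Flat dict lookup for the hot loop; .loc on a MultiIndex frame is slow.
    delta_of = {
        (sid, env, comp): strain_deltas.at[sid, (env, comp)]
        for sid in strain_deltas.index
        for (env, comp) in strain_deltas.columns
    }

    def emit(strain: StrainMeta, env: str, run_id: str, ploidy: str, mat: str, idx: int, is_std: bool):
        well_id = ("std::" if is_std else "") + f"{strain.strain_id}|{env}|{mat}|{idx}"
        vals = {}
        half = 0.5 if ploidy == "haploid" else -0.5
        for c in COMPONENTS:
            delta = delta_of[(strain.strain_id, env, c)]
            v = (
                base[c]
                + g[(strain.strain_id, c)]
                + h[(env, c)]
                + ploidy_sign[c] * half * delta
                + run_offsets[(run_id, c)]
                + rng.normal(0.0, truth.sigma_noise)
            )
            vals[c] = 2.0**v
        curve = simulate_curve(
            lag=vals["lag"],
            doubling_time=vals["rate"],
            amplitude=vals["efficiency"],
            baseline=truth.baseline_od,
            noise_sd=truth.od_noise_sd,
            times=times,
            seed=_curve_seed(seed, run_id, well_id),
            blank=truth.blank_od,
            well_id=well_id,
            strain_id=strain.strain_id,
            ploidy=ploidy,
            mating_type=mat,
            environment=env,
            run_id=run_id,
            is_standard=is_std,
            multiplicative_noise_sd=truth.multiplicative_noise_sd,
        )
        curves.append(curve)
        truth_rows.append(
            dict(
                well_id=well_id,
                strain_id=strain.strain_id,
                species=strain.species,
                environment=env,
                run_id=run_id,
                ploidy=ploidy,
                mating_type=mat,
                is_standard=is_std,
                lag_true_h=vals["lag"],
                doubling_time_true_h=vals["rate"],
                efficiency_true_od=vals["efficiency"],
            )
        )

    for env in envs:
        run_ids = runs_by_env[env]
        capacity = design.wells_per_run - design.standards_per_run
        slot = 0
        for strain in strains:
            variants = (
                [("haploid", "a")] * design.replicates_per_mating_type
                + [("haploid", "alpha")] * design.replicates_per_mating_type
                + [("diploid", "a_alpha")] * design.replicates_diploid
            )
            for idx, (ploidy, mat) in enumerate(variants):
                run_id = run_ids[min(slot // capacity, len(run_ids) - 1)]
                emit(strain, env, run_id, ploidy, mat, idx, is_std=False)
                slot += 1
        for run_id in run_ids:
            for k in range(design.standards_per_run):
                emit(ref, env, run_id, "haploid", "alpha", k, is_std=True)

    cultures = pd.DataFrame(truth_rows)
    config = asdict(truth)
    config["seed"] = int(seed)
    config["n_strains"] = len(strains)
    config["n_environments"] = len(envs)
    return curves, TruthTable(
        cultures=cultures,
        trait_effects=trait_effects,
        strain_deltas=strain_deltas,
        config=config,
    )


def simulate_trait_dataset(
    n_strains: int = 24,
    n_traits: int = 100,
    deltas: Optional[np.ndarray] = None,
    sigma_strain: float = 0.2,
    sigma_noise: float = 0.1,
    replicates_per_mating_type: int = 2,
    replicates_diploid: int = 4,
    seed: int = 0,
    species: str = "cerevisiae",
) -> pd.DataFrame:
    """Simulate a replicate-level LSC table directly, skipping the curve stage.

    Fast path for calibration studies of the effect-calling stage (null FDR
    control, power, planted-fraction recovery), where simulating and
    re-extracting hundreds of thousands of growth curves would add nothing:
    the curve -> component -> LSC stages are validated separately by the
    parameter-recovery and normalization-invariance studies.

    Produces the same schema as the trait matrix builder: rows indexed by
    (strain_id, ploidy, mating_type), one column per trait, cell = replicate
    mean LSC. ``deltas`` (length ``n_traits``) are true haploid-minus-diploid
    effects; strain x trait effects N(0, sigma_strain^2) are shared between a
    strain's ploidy variants; culture noise N(0, sigma_noise^2) averages over
    replicates.
    """
    rng = np.random.default_rng(seed)
    if deltas is None:
        deltas = np.zeros(n_traits)
    deltas = np.asarray(deltas, dtype=float)
    if deltas.shape != (n_traits,):
        raise ValueError("deltas must have length n_traits")
    strains = [f"{species[:2].upper()}{i + 1:02d}" for i in range(n_strains)]
    strain_eff = rng.normal(0.0, sigma_strain, size=(n_strains, n_traits))

    rows = []
    index = []
    for i, sid in enumerate(strains):
        for ploidy, mat, n_rep, half in (
            ("haploid", "a", replicates_per_mating_type, +0.5),
            ("haploid", "alpha", replicates_per_mating_type, +0.5),
            ("diploid", "a_alpha", replicates_diploid, -0.5),
        ):
            noise = rng.normal(0.0, sigma_noise, size=(n_rep, n_traits)).mean(axis=0)
            rows.append(strain_eff[i] + half * deltas + noise)
            index.append((sid, ploidy, mat))
    idx = pd.MultiIndex.from_tuples(index, names=["strain_id", "ploidy", "mating_type"])
    cols = pd.MultiIndex.from_tuples(
        [(f"env{j // 3 + 1:02d}", COMPONENTS[j % 3]) for j in range(n_traits)],
        names=["environment", "component"],
    )
    return pd.DataFrame(np.asarray(rows), index=idx, columns=cols)


def curves_to_frame(curves: Sequence[GrowthCurve]) -> pd.DataFrame:
    """Long-format curve table: well_id, time_h, od."""
    n = sum(c.times.size for c in curves)
    well = np.empty(n, dtype=object)
    t = np.empty(n)
    od = np.empty(n)
    pos = 0
    for c in curves:
        k = c.times.size
        well[pos : pos + k] = c.well_id
        t[pos : pos + k] = c.times
        od[pos : pos + k] = c.od
        pos += k
    return pd.DataFrame({"well_id": well, "time_h": t, "od": od})


def meta_to_frame(curves: Sequence[GrowthCurve], panel: Sequence[StrainMeta]) -> pd.DataFrame:
    """Per-well metadata table matching the long-format curve table."""
    by_id = {s.strain_id: s for s in panel}
    rows = []
    for c in curves:
        s = by_id[c.strain_id]
        rows.append(
            dict(
                well_id=c.well_id,
                strain_id=c.strain_id,
                species=s.species,
                population=s.population,
                source=s.source,
                ploidy=c.ploidy,
                mating_type=c.mating_type,
                environment=c.environment,
                run_id=c.run_id,
                is_standard=c.is_standard,
            )
        )
    return pd.DataFrame(rows)
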