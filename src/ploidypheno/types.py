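"""Core domain types for the ploidy-phenomics pipeline.

The pipeline moves through a small number of in-memory containers:

* :class:`StrainMeta` — one natural isolate and its annotations.
* :class:`DesignSpec` — the cultivation design (strains x ploidy variants x
  environments, replication, internal standards, sampling grid).
* :class:`GrowthCurve` — one well's optical-density time series.
* :class:`FitnessComponents` — lag, doubling time and efficiency extracted
  from one curve.
* Tabular results (trait matrices, effect tables, pair similarities) are
  plain :class:`pandas.DataFrame` objects with documented schemas; see the
  functions that produce them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SPECIES = ("cerevisiae", "paradoxus")
SOURCES = ("clinical", "fermentation", "lab", "wild")
PLOIDIES = ("haploid", "diploid")
#: Mating-type states. Haploids carry ``a`` or ``alpha``; diploids are
#: heterozygous ``a_alpha`` or, in the MAT-locus dissection experiment,
#: hemizygous ``a_hemi`` / ``alpha_hemi``.
MATING_TYPES = ("a", "alpha", "a_alpha", "a_hemi", "alpha_hemi")
HAPLOID_MATS = ("a", "alpha")
DIPLOID_MATS = ("a_alpha", "a_hemi", "alpha_hemi")
COMPONENTS = ("lag", "rate", "efficiency")


@dataclass(frozen=True)
class StrainMeta:
    """One strain of the panel.

    Attributes
    ----------
    strain_id : str
        Unique identifier within a panel.
    species : str
        ``"cerevisiae"`` or ``"paradoxus"``.
    population : str
        Clean-lineage population label (mosaic strains carry their
        majority-donor population).
    source : str
        Habitat the isolate was sampled from.
    is_reference : bool
        True for the single internal-standard strain (an S288c-like lab
        strain) used to normalize every run.
    """

    strain_id: str
    species: str
    population: str
    source: str
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class DesignSpec:
    """Cultivation design for one experiment.

    Every strain is grown as two haploid mating types (``replicates_per_mating_type``
    replicates each) and as an a/alpha diploid (``replicates_diploid`` replicates)
    in every environment. Each run additionally carries ``standards_per_run``
    wells of the haploid MATalpha reference strain.
    """

    panel: list[StrainMeta]
    environments: list[str]
    replicates_per_mating_type: int = 2
    replicates_diploid: int = 4
    standards_per_run: int = 8
    runs_per_environment: Optional[int] = None  # None -> derived from capacity
    wells_per_run: int = 200
    sampling_interval_h: float = 1.0 / 3.0
    duration_h: float = 72.0

    def __post_init__(self) -> None:
        if self.replicates_per_mating_type < 1:
            raise ValueError("replicates_per_mating_type must be >= 1")
        if self.replicates_diploid < 0:
            raise ValueError("replicates_diploid must be >= 0")
        if self.standards_per_run < 1:
            raise ValueError("standards_per_run must be >= 1")
        if self.duration_h <= 0 or self.sampling_interval_h <= 0:
            raise ValueError("duration and sampling interval must be positive")
        ids = [s.strain_id for s in self.panel]
        if len(set(ids)) != len(ids):
            raise ValueError("strain_id values must be unique within a panel")
        n_ref = sum(s.is_reference for s in self.panel)
        if self.panel and n_ref != 1:
            raise ValueError(f"exactly one reference strain required, got {n_ref}")

    @property
    def cultures_per_strain_env(self) -> int:
        return 2 * self.replicates_per_mating_type + self.replicates_diploid

    def times(self) -> np.ndarray:
        """Sampling grid in hours, 0 .. duration inclusive of the start."""
        n = int(np.floor(self.duration_h / self.sampling_interval_h)) + 1
        return np.arange(n) * self.sampling_interval_h

    def reference(self) -> StrainMeta:
        return next(s for s in self.panel if s.is_reference)


@dataclass
class GrowthCurve:
    """One well's OD time series plus design annotations."""

    well_id: str
    strain_id: str
    ploidy: str
    mating_type: str
    environment: str
    run_id: str
    times: np.ndarray
    od: np.ndarray
    plate_position: str = ""
    is_standard: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("od values must be >= 0")
        if self.ploidy == "diploid" and self.mating_type not in DIPLOID_MATS:
            raise ValueError(
                f"diploid mating_type must be one of {DIPLOID_MATS}, got {self.mating_type!r}"
            )


@dataclass
class FitnessComponents:
    """Lag, doubling time and efficiency extracted from one growth curve.

    ``lag_h`` is the population adaptation time (tangent construction in
    log2 space), ``doubling_time_h`` the inverse of the maximal log2 slope,
    ``efficiency_od`` the total change in population density. ``grew`` is
    False when the density change never exceeded the growth threshold; the
    lag is then censored at the assay duration and the doubling time is NaN.
    """

    lag_h: float
    doubling_time_h: float
    efficiency_od: float
    grew: bool
    flags: tuple[str, ...] = ()
    window: Optional[tuple[int, int]] = None  # [start, stop) of the rate window


@dataclass
class TruthTable:
    """Ground truth recorded by the synthetic-data generator.

    Attributes
    ----------
    cultures : pandas.DataFrame
        One row per simulated well: true lag (h), true doubling time (h),
        true efficiency amplitude (delta-OD), plus design annotations.
    trait_effects : pandas.DataFrame
        One row per species x environment x component with the true ploidy
        effect ``delta`` (log2 LSC units, haploid minus diploid) and whether
        the trait was planted as affected.
    strain_deltas : pandas.DataFrame
        Strains x traits matrix of per-strain true ploidy effects (species
        delta plus population- and strain-level deviations).
    config : dict
        Echo of the generator configuration, including variance components.
    """

    cultures: "pandas.DataFrame"  # noqa: F821 - forward ref for doc tools
    trait_effects: "pandas.DataFrame"  # noqa: F821
    strain_deltas: "pandas.DataFrame"  # noqa: F821
    config: dict = field(default_factory=dict)
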