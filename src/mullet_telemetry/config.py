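"""Simulation and pipeline configuration.

All tunable parameters of the synthetic detection generator and of the
analysis pipeline live here as plain dataclasses that round-trip through
YAML.  Defaults encode the study system the package emulates: a dense
receiver grid in a shallow coastal sea (90 stations over roughly
55 x 25 km), sparse offshore arrays a hundred-odd kilometres away, a single
freshwater receiver behind a sluice barrier, and two sympatric mullet
species that differ in arrival timing (day-of-year medians 158 vs 135),
mobility, and detectability during their summer residence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

REGIONS = ("wadden_sea", "north_sea", "fresh_water")
SPECIES = ("thicklip", "thinlip", "other")


@dataclass
class SpeciesParams:
    """Seasonal-residency and movement parameters for one species.

    Arrival/departure medians and spreads are day-of-year values (spread is
    the standard deviation of a truncated normal); mobility_step_m is the
    daily random-walk step scale in metres; station_fidelity is the per-day
    probability of remaining at the current anchor station (and hence within
    detection range); offshore_detection_prob is the per-day probability of
    passing an offshore (north_sea) station while outside the residence
    season; annual_return_prob is the probability that a fish present in one
    season returns the next; freshwater_day_prob is the per-residence-day
    probability of a foray to the freshwater receiver.
    """

    arrival_doy_median: float = 158.0
    arrival_doy_spread: float = 30.0
    departure_doy_median: float = 259.0
    departure_doy_spread: float = 31.0
    mobility_step_m: float = 1500.0
    station_fidelity: float = 0.30
    offshore_detection_prob: float = 0.01
    annual_return_prob: float = 0.16
    freshwater_day_prob: float = 0.0
    median_length_cm: float = 51.5

    def validate(self) -> None:
        for name in ("station_fidelity", "offshore_detection_prob",
                     "annual_return_prob", "freshwater_day_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.arrival_doy_spread < 0 or self.departure_doy_spread < 0:
            raise ValidationError("day-of-year spreads must be >= 0")
        if self.mobility_step_m < 0:
            raise ValidationError("mobility_step_m must be >= 0")


def _default_species_params() -> dict[str, SpeciesParams]:
    # Medians and spreads follow the printed day-of-year medians and IQRs
    # (spread = IQR / 1.349 under a normal residence-timing model).
    return {
        "thicklip": SpeciesParams(
            arrival_doy_median=158.0, arrival_doy_spread=30.0,
            departure_doy_median=259.0, departure_doy_spread=31.0,
            mobility_step_m=1500.0, station_fidelity=0.30,
            offshore_detection_prob=0.01, annual_return_prob=0.16,
            freshwater_day_prob=0.0, median_length_cm=51.5,
        ),
        "thinlip": SpeciesParams(
            arrival_doy_median=135.0, arrival_doy_spread=5.0,
            departure_doy_median=233.0, departure_doy_spread=30.0,
            mobility_step_m=3000.0, station_fidelity=0.50,
            offshore_detection_prob=0.01, annual_return_prob=0.50,
            freshwater_day_prob=0.02, median_length_cm=54.3,
        ),
    }


@dataclass
class SimulationConfig:
    """Full configuration of the synthetic telemetry generator.

    A fixed seed makes every downstream artefact (stations, trajectories,
    detections, noise) bit-reproducible.
    """

    seed: int = 0
    n_fish_per_species: dict[str, int] = field(
        default_factory=lambda: {"thicklip": 106, "thinlip": 16})
    species_params: dict[str, SpeciesParams] = field(
        default_factory=_default_species_params)

    # tag behaviour
    min_delay_s: int = 60
    max_delay_s: int = 120
    tag_lifespan_days: int = 800

    # detection-range model (metres / probability per transmission)
    d50_m: float = 149.0
    d_max_m: float = 610.0
    p_at_dmax: float = 0.05

    # receiver array layout
    n_wadden_stations: int = 90
    n_north_sea_stations: int = 21
    damaged_fraction: float = 0.05
    short_deployment_fraction: float = 0.05

    # study period
    n_years: int = 3
    start_year: int = 2021
    # fraction of fish tagged in the first study year (the rest in year 2)
    first_year_cohort_fraction: float = 0.6

    # fish behaviour shared across species
    mortality_fraction: float = 0.074
    anchor_radius_m: float = 140.0
    in_range_hours_per_day: float = 4.0
    post_death_emission_days: int = 60

    # injected noise (counts of labelled false records)
    n_false_positives: int = 50
    n_echo_duplicates: int = 50
    n_subdelay_ghosts: int = 50

    def validate(self) -> None:
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        if not self.n_fish_per_species:
            raise ValidationError("n_fish_per_species must be non-empty")
        for sp, n in self.n_fish_per_species.items():
            if sp not in self.species_params:
                raise ValidationError(f"no species_params for {sp!r}")
            if n < 0:
                raise ValidationError("fish counts must be >= 0")
        for sp in self.species_params.values():
            sp.validate()
        if not 0 < self.min_delay_s <= self.max_delay_s:
            raise ValidationError(
                "need 0 < min_delay_s <= max_delay_s, got "
                f"{self.min_delay_s}, {self.max_delay_s}")
        if not self.d50_m < self.d_max_m:
            raise ValidationError("d50_m must be < d_max_m")
        if not 0.0 < self.p_at_dmax < 0.5:
            raise ValidationError("p_at_dmax must be in (0, 0.5)")
        if self.n_wadden_stations <= 0:
            raise ValidationError("at least one wadden_sea station required")
        if self.n_north_sea_stations < 0:
            raise ValidationError("n_north_sea_stations must be >= 0")
        for name in ("damaged_fraction", "short_deployment_fraction",
                     "mortality_fraction", "first_year_cohort_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_years < 1:
            raise ValidationError("n_years must be >= 1")
        if not 0 < self.in_range_hours_per_day <= 24:
            raise ValidationError("in_range_hours_per_day must be in (0, 24]")
        for name in ("n_false_positives", "n_echo_duplicates",
                     "n_subdelay_ghosts"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "species_params" in d:
            d["species_params"] = {
                k: SpeciesParams(**v) if not isinstance(v, SpeciesParams) else v
                for k, v in d["species_params"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineConfig:
    """End-to-end run configuration: thresholds, exclusions, seeding."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    focal_region: str = "wadden_sea"
    min_residence_days: int = 5       # residence kept only if duration > this
    min_stations_mcp: int = 3
    station_min_deployment_days: int = 90
    significance: float = 0.05
    exclude_years_from_stats: list[int] = field(default_factory=list)
    output_dir: str = "results/pipeline"
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        if self.focal_region not in REGIONS:
            raise ValidationError(f"unknown focal region {self.focal_region!r}")
        if self.min_residence_days < 0 or self.min_stations_mcp < 1:
            raise ValidationError("thresholds must be positive")
        if self.station_min_deployment_days <= 0:
            raise ValidationError("station_min_deployment_days must be > 0")
        if not 0 < self.significance < 1:
            raise ValidationError("significance must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and not isinstance(d["simulation"], SimulationConfig):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
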