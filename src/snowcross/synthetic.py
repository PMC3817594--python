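"""Synthetic landscape, survey and count-data generation with known truth.

Every downstream stage (permeability estimation, count-model fitting, model
search, mapping) is exercised against data produced here, so the generators
carry their ground truth alongside the data.

The predictor generator mimics the structure of the field dataset: 12
hand-digitized habitat proportions recorded in a 200 m perceptual area around
each survey point, plus 11 remote-sensed variables each measured at three
buffer radii (200 m / 500 m / 1 km).  Scale variants of one variable are
correlated noisy views of a shared latent habitat axis, which reproduces the
cross-scale multicollinearity that makes scale selection a real problem.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from snowcross.survey import SurveyEffort, TrackRecord

#: Habitat-class proportions digitized inside the 200 m perceptual area.
DIGITIZED_VARIABLES: tuple[str, ...] = (
    "forest",
    "shrub",
    "herb",
    "riparian",
    "freshwater",
    "unvegetated",
    "highway",
    "road",
    "railroad",
    "residential",
    "disturbed",
    "wetland_pap",
)

#: Remote-sensed land-cover / infrastructure variables, one per scale radius.
REMOTE_VARIABLES: tuple[str, ...] = (
    "water",
    "exposed",
    "low_shrub",
    "wetland",
    "herbaceous",
    "dense_conifer",
    "open_conifer",
    "open_broadleaf",
    "gravel_road_length",
    "paved_road_length",
    "buildings",
)

DEFAULT_GROUPS: tuple[str, ...] = ("carnivores", "deer", "elk", "moose")

ZERO_INFLATED_FAMILIES = frozenset({"zip", "zinb"})
DISPERSED_FAMILIES = frozenset({"negbin", "zinb"})
FAMILIES = frozenset({"poisson", "negbin", "zip", "zinb"})


@dataclass(frozen=True)
class LandscapeConfig:
    """Geometry and predictor catalogue for one synthetic landscape."""

    n_highway_points: int = 463
    n_transect_points: int = 308
    highway_length_km: float = 95.0
    n_transects: int = 10
    transect_length_km: float = 1.0
    scale_set: tuple[int, ...] = (200, 500, 1000)
    digitized_variables: tuple[str, ...] = DIGITIZED_VARIABLES
    remote_variables: tuple[str, ...] = REMOTE_VARIABLES
    cross_scale_correlation: float = 0.6
    species: tuple[str, ...] = DEFAULT_GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_highway_points <= 0 or self.n_transect_points <= 0:
            raise ValueError("point counts must be positive")
        if self.highway_length_km <= 0:
            raise ValueError("highway_length_km must be positive")
        if self.n_transects <= 0 or self.transect_length_km <= 0:
            raise ValueError("transect geometry must be positive")
        radii = tuple(self.scale_set)
        if any(r <= 0 for r in radii):
            raise ValueError("scale radii must be strictly positive")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("scale radii must be strictly increasing")
        if not 0 <= self.cross_scale_correlation < 1:
            raise ValueError("cross_scale_correlation must lie in [0, 1)")
        names = self.predictor_names
        if len(set(names)) != len(names):
            raise ValueError("predictor catalogue contains duplicate names")

    @property
    def predictor_names(self) -> list[str]:
        """All candidate predictor column names (12 + 11 per scale = 45 at defaults)."""
        names = list(self.digitized_variables)
        for var in self.remote_variables:
            for radius in self.scale_set:
                names.append(f"{var}_{radius}m")
        return names

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_names)


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters for simulated counts and tracks.

    ``count_coefficients`` are on the log scale for the count mean,
    ``zero_coefficients`` on the logit scale for the structural-zero
    probability.  Both include an ``"intercept"`` entry.
    """

    family: str
    count_coefficients: Mapping[str, float]
    zero_coefficients: Mapping[str, float] = field(default_factory=dict)
    dispersion: float | None = None
    permeability_truth: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        zero_inflated = self.family in ZERO_INFLATED_FAMILIES
        if zero_inflated != bool(self.zero_coefficients):
            raise ValueError(
                "zero_coefficients must be non-empty exactly for zip/zinb families"
            )
        dispersed = self.family in DISPERSED_FAMILIES
        if dispersed != (self.dispersion is not None):
            raise ValueError("dispersion must be set exactly for negbin/zinb families")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.permeability_truth <= 1:
            raise ValueError("permeability_truth must lie in [0, 1]")

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["count_coefficients"] = dict(self.count_coefficients)
        payload["zero_coefficients"] = dict(self.zero_coefficients)
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        payload = json.loads(text)
        return cls(**payload)


@dataclass
class CountDataset:
    """Per-point species counts joined to their predictor matrix."""

    counts: np.ndarray
    predictors: pd.DataFrame
    truth: SimulationTruth | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.predictors):
            raise ValueError("counts and predictors disagree on row count")

    @property
    def n(self) -> int:
        return len(self.counts)

    def to_csv(self, path) -> None:
        out = self.predictors.copy()
        out.insert(0, "count", self.counts)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CountDataset":
        table = pd.read_csv(path)
        counts = table.pop("count").to_numpy()
        return cls(counts=counts, predictors=table)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_predictors(config: LandscapeConfig) -> pd.DataFrame:
    """Generate the per-point predictor table for one synthetic landscape.

    Returns one row per survey point (highway rows first, then transect rows)
    with metadata columns ``point_id``, ``route``, ``position_km``,
    ``offset_m`` followed by the 45 predictor columns.  Remote-sensed scale
    variants of one variable share a latent habitat axis so their pairwise
    correlation is close to ``config.cross_scale_correlation``; digitized
    proportions are logistic transforms of the same latent habitat plus noise
    and therefore lie in [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    n_h, n_t = config.n_highway_points, config.n_transect_points
    n = n_h + n_t
    rho = config.cross_scale_correlation

    meta = pd.DataFrame(
        {
            "point_id": np.arange(n),
            "route": ["highway"] * n_h
            + [
                f"T{1 + i % config.n_transects}"
                for i in range(n_t)
            ],
            "position_km": np.concatenate(
                [
                    rng.uniform(0.0, config.highway_length_km, n_h),
                    rng.uniform(0.0, config.transect_length_km, n_t),
                ]
            ),
            # transect offset from the highway; highway rows sit at 0
            "offset_m": np.concatenate(
                [np.zeros(n_h), rng.uniform(10.0, 900.0, n_t)]
            ),
        }
    )

    columns: dict[str, np.ndarray] = {}
    # Latent habitat axes: one per remote variable, shared by its scale
    # variants and re-used (cyclically) by the digitized proportions so the
    # two predictor families are correlated views of the same landscape.
    latents = {var: rng.standard_normal(n) for var in config.remote_variables}

    for var in config.remote_variables:
        shared = latents[var]
        for radius in config.scale_set:
            noise = rng.standard_normal(n)
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
            # exp(z/2): positive area/length-like values; the mild scale keeps
            # the transformed cross-scale correlation near rho
            columns[f"{var}_{radius}m"] = np.exp(0.5 * z) * radius
    remote_cycle = list(config.remote_variables)
    for i, var in enumerate(config.digitized_variables):
        anchor = latents[remote_cycle[i % len(remote_cycle)]]
        z = 0.6 * anchor + 0.8 * rng.standard_normal(n)
        columns[var] = _expit(z - 1.0)

    table = pd.concat([meta, pd.DataFrame(columns)], axis=1)
    return table[list(meta.columns) + config.predictor_names]


def _linear_predictor(
    predictors: pd.DataFrame, coefficients: Mapping[str, float]
) -> np.ndarray:
    eta = np.zeros(len(predictors))
    for name, value in coefficients.items():
        if name == "intercept":
            eta += value
        else:
            if name not in predictors.columns:
                raise KeyError(f"coefficient references unknown predictor {name!r}")
            eta += value * predictors[name].to_numpy(dtype=float)
    return eta


def simulate_counts(
    predictors: pd.DataFrame, truth: SimulationTruth, seed: int
) -> CountDataset:
    """Draw per-point counts from ``truth.family`` given the predictor table.

    Log link for the count mean, logit link for the structural-zero
    probability.  The negative binomial uses the (mu, theta) convention with
    variance mu + mu^2/theta.
    """
    rng = np.random.default_rng(seed)
    eta = np.clip(_linear_predictor(predictors, truth.count_coefficients), -30, 30)
    mu = np.exp(eta)
    n = len(mu)

    if truth.family == "poisson":
        counts = rng.poisson(mu)
    elif truth.family == "negbin":
        theta = float(truth.dispersion)  # type: ignore[arg-type]
        counts = rng.poisson(rng.gamma(theta, mu / theta))
    elif truth.family in ZERO_INFLATED_FAMILIES:
        pi = _expit(_linear_predictor(predictors, truth.zero_coefficients))
        if truth.family == "zip":
            base = rng.poisson(mu)
        else:
            theta = float(truth.dispersion)  # type: ignore[arg-type]
            base = rng.poisson(rng.gamma(theta, mu / theta))
        counts = np.where(rng.random(n) < pi, 0, base)
    else:  # pragma: no cover - guarded by SimulationTruth
        raise ValueError(f"unknown family {truth.family!r}")

    return CountDataset(
        counts=counts.astype(int), predictors=predictors, truth=truth, seed=seed
    )


def survey_efforts(
    config: LandscapeConfig, n_survey_days: int = 1
) -> list[SurveyEffort]:
    """Survey effort implied by the configured geometry (km per route/day)."""
    efforts = [
        SurveyEffort(route="highway", km_surveyed=config.highway_length_km * n_survey_days)
    ]
    for t in range(1, config.n_transects + 1):
        efforts.append(
            SurveyEffort(
                route=f"T{t}", km_surveyed=config.transect_length_km * n_survey_days
            )
        )
    return efforts


def simulate_tracks(
    config: LandscapeConfig,
    truth: SimulationTruth,
    seed: int,
    intensity_per_km: float | Mapping[str, float] = 2.0,
    intensity_profile: Callable[[np.ndarray], np.ndarray] | None = None,
    n_survey_days: int = 1,
    start_date: date = date(2010, 1, 15),
) -> list[TrackRecord]:
    """Simulate raw track records on the highway and the transects.

    Animals approach the highway and the transects at the same per-km Poisson
    intensity; a highway attempt succeeds (tracks continue on the far side)
    with probability ``truth.permeability_truth``, so the successful-crossing
    permeability estimator recovers that truth.  ``intensity_profile`` maps
    positions (km) to a relative intensity in [0, 1] for inhomogeneous
    scenarios (thinning); defaults to homogeneous.
    """
    if config.highway_length_km <= 0:
        raise ValueError("negative or zero highway length")
    rng = np.random.default_rng(seed)
    if isinstance(intensity_per_km, Mapping):
        intensities = {sp: float(intensity_per_km[sp]) for sp in config.species}
    else:
        intensities = {sp: float(intensity_per_km) for sp in config.species}

    records: list[TrackRecord] = []
    routes = [("highway", config.highway_length_km)] + [
        (f"T{t}", config.transect_length_km) for t in range(1, config.n_transects + 1)
    ]
    for day in range(n_survey_days):
        survey_date = start_date + timedelta(days=day)
        for route, length in routes:
            on_highway = route == "highway"
            for sp, mu in intensities.items():
                n_tracks = rng.poisson(mu * length)
                positions = np.sort(rng.uniform(0.0, length, n_tracks))
                if intensity_profile is not None:
                    keep = rng.random(n_tracks) < np.asarray(
                        intensity_profile(positions), dtype=float
                    )
                    positions = positions[keep]
                for pos in positions:
                    success = (
                        bool(rng.random() < truth.permeability_truth)
                        if on_highway
                        else None
                    )
                    records.append(
                        TrackRecord(
                            species=sp,
                            route=route,
                            position_km=float(pos),
                            count=1,
                            success=success,
                            hours_since_snowfall=float(rng.uniform(12.0, 36.0)),
                            survey_date=survey_date,
                        )
                    )
    return records


def write_predictor_table(table: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write the predictor table as UTF-8 delimited text with a header row."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        table.to_csv(fh, index=False)


def read_predictor_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
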