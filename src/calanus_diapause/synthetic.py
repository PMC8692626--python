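"""Synthetic field campaign: CTD profiles, individuals and net catches.

The generator emulates a late-summer ice-edge sampling campaign so that the
whole pipeline can be exercised, and its estimates checked against known
ground truth, without the (unpublished) field measurements:

* **CTD**: a two-water-mass profile — a warm surface mixed layer over a
  linear thermocline relaxing to cold deep water — constructed so the
  0–125 m mean matches a configured station archetype, plus small sensor
  noise.
* **Individuals**: stage drawn from a stage mix; prosome length L from a
  stage-specific normal (truncated at 0); lipid fullness from a Beta
  distribution; lipid carbon w = fullness · w_max(L); structural carbon
  m = a·L^b with lognormal noise; total carbon M = m + w (so no record can
  violate w < M); capture depth from a mixture of depth bands emulating the
  observed vertical distributions; lipid sac area back-computed from w so
  the pipeline's biometric chain inverts the generator exactly.
* **Catch table**: Poisson (optionally negative-binomial) counts per
  stratum with expectation = true concentration × volume filtered, volume =
  net mouth area × stratum thickness.

Ground truth for the capable fraction is obtained by dense Monte-Carlo
integration of the same generating distributions on a dedicated random
stream, at the generated station temperatures; because capability is
deterministic given the latent variables, a sample of n individuals then
yields an exactly Binomial(n, p) capable count.

One integer seed drives everything; each artifact (profile, population,
catch, ground truth) and each station gets its own child stream via
``default_rng([seed, stream, station_index])`` so artifacts can be
regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biometry import (
    MaxLipidAllometry,
    SYNTHETIC_ALLOMETRY,
    WE_AREA_COEF,
    WE_AREA_EXP,
    WE_CARBON_FRACTION,
    max_lipid_reserve,
)
from .hydrography import CTDProfile, temperature_at_depth
from .metabolism import ModelParams, diapause_duration, respiration_rate

__all__ = [
    "DepthBand",
    "StationArchetype",
    "GeneratorConfig",
    "GroundTruth",
    "default_config",
    "generate_ctd",
    "generate_population",
    "generate_catch_table",
    "generate_bundle",
]

# stream ids for child RNGs
_STREAM_CTD, _STREAM_POP, _STREAM_CATCH, _STREAM_TRUTH = 1, 2, 3, 4


@dataclass(frozen=True)
class DepthBand:
    """One band of a vertical-distribution mixture (uniform within band)."""

    upper_m: float
    lower_m: float
    weight: float

    def __post_init__(self) -> None:
        if not 0 <= self.upper_m < self.lower_m:
            raise ValueError("need 0 <= upper_m < lower_m")
        if self.weight < 0:
            raise ValueError("band weight must be >= 0")

    @property
    def thickness_m(self) -> float:
        return self.lower_m - self.upper_m


@dataclass(frozen=True)
class StationArchetype:
    """Station-level conditions: hydrography, stock size, vertical structure.

    ``surface_mean_C`` is the 0–125 m average the generated CTD profile
    reproduces; ``abundance_m2`` is the true depth-integrated abundance per
    stage (ind m⁻²) over the sampled column.
    """

    name: str
    surface_mean_C: float
    surface_sd_C: float
    deep_temp_C: float
    abundance_m2: Mapping[str, float]
    depth_bands: tuple[DepthBand, ...]

    def __post_init__(self) -> None:
        total_w = sum(b.weight for b in self.depth_bands)
        if not np.isclose(total_w, 1.0):
            raise ValueError(f"depth band weights must sum to 1, got {total_w}")
        if any(a <= 0 for a in self.abundance_m2.values()):
            raise ValueError("abundances must be > 0")


def _equal_strata(z_top: float, z_bottom: float, n: int) -> tuple[tuple[float, float], ...]:
    edges = np.linspace(z_top, z_bottom, n + 1)
    return tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))


def _default_stations() -> dict[str, StationArchetype]:
    # Archetypes shaped like a late-summer west→east transect across an
    # Arctic strait: warming surface layer and growing stock toward the
    # Atlantic-influenced side, with the easternmost station holding a
    # second deep abundance peak.
    return {
        "S1": StationArchetype(
            name="S1",
            surface_mean_C=2.362,
            surface_sd_C=1.589,
            deep_temp_C=-0.7,
            abundance_m2={"CIV": 3933.0, "CV": 2592.0, "CVI": 186.0},
            depth_bands=(
                DepthBand(5, 130, 0.55),
                DepthBand(130, 250, 0.26),
                DepthBand(250, 380, 0.12),
                DepthBand(380, 630, 0.05),
                DepthBand(630, 1000, 0.02),
            ),
        ),
        "S2": StationArchetype(
            name="S2",
            surface_mean_C=3.643,
            surface_sd_C=1.436,
            deep_temp_C=-0.5,
            abundance_m2={"CIV": 6023.0, "CV": 12098.0, "CVI": 1765.0},
            depth_bands=(
                DepthBand(5, 130, 0.50),
                DepthBand(130, 250, 0.244),
                DepthBand(250, 380, 0.15),
                DepthBand(380, 630, 0.08),
                DepthBand(630, 1000, 0.026),
            ),
        ),
        "S3": StationArchetype(
            name="S3",
            surface_mean_C=4.319,
            surface_sd_C=1.528,
            deep_temp_C=-0.3,
            abundance_m2={"CIV": 25061.0, "CV": 15710.0, "CVI": 3989.0},
            depth_bands=(
                DepthBand(5, 130, 0.12),
                DepthBand(130, 250, 0.10),
                DepthBand(250, 380, 0.13),
                DepthBand(380, 630, 0.55),
                DepthBand(630, 1000, 0.10),
            ),
        ),
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic campaign (defaults are the study conditions)."""

    seed: int = 0
    season: str = "late"
    taxon: str = "C. finmarchicus"
    stations: dict[str, StationArchetype] = field(default_factory=_default_stations)
    #: sampled-stage mix of the body-condition subsample
    stage_mix: dict[str, float] = field(
        default_factory=lambda: {"CIV": 0.2, "CV": 0.7, "CVI": 0.1}
    )
    length_mean_mm: dict[str, float] = field(
        default_factory=lambda: {"CIV": 1.55, "CV": 2.0, "CVI": 2.3}
    )
    length_sd_mm: dict[str, float] = field(
        default_factory=lambda: {"CIV": 0.12, "CV": 0.15, "CVI": 0.15}
    )
    #: lipid fullness ~ Beta(alpha, beta) on [0, 1]
    fullness_alpha: float = 2.7
    fullness_beta: float = 3.3
    #: structural carbon m = coef · L^exp · lognormal(0, sigma), μg C
    structural_coef: float = 12.0
    structural_exp: float = 2.9
    structural_sigma: float = 0.08
    allometry: MaxLipidAllometry = SYNTHETIC_ALLOMETRY
    params: ModelParams = field(default_factory=ModelParams)
    net_area_m2: float = 1.0
    #: multinet stratum plan: 8 equal intervals over 5–1000 m
    strata: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: _equal_strata(5.0, 1000.0, 8)
    )
    n_individuals_per_station: int = 80
    #: negative-binomial dispersion (None → Poisson counts)
    overdispersion: float | None = None
    # CTD construction
    mixed_layer_m: float = 30.0
    thermocline_bottom_m: float = 200.0
    ctd_max_depth_m: float = 1000.0
    ctd_step_m: float = 5.0
    ctd_noise_sd_C: float = 0.02
    #: Monte-Carlo sample size for the ground-truth capable fraction
    n_truth_mc: int = 200_000

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.stage_mix.values()), 1.0):
            raise ValueError("stage mix must sum to 1")
        for name, val in (
            ("fullness_alpha", self.fullness_alpha),
            ("fullness_beta", self.fullness_beta),
            ("structural_coef", self.structural_coef),
            ("structural_exp", self.structural_exp),
            ("net_area_m2", self.net_area_m2),
        ):
            if not val > 0:
                raise ValueError(f"{name} must be > 0")
        if self.structural_sigma < 0:
            raise ValueError("structural_sigma must be >= 0")

    def station_index(self, station: str) -> int:
        try:
            return sorted(self.stations).index(station)
        except ValueError:
            raise KeyError(f"unknown station {station!r}") from None


def default_config(seed: int = 0) -> GeneratorConfig:
    return GeneratorConfig(seed=seed)


def _child_rng(config: GeneratorConfig, stream: int, station: str, seed: int | None):
    base = config.seed if seed is None else seed
    return np.random.default_rng([int(base), stream, config.station_index(station)])


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

def generate_ctd(config: GeneratorConfig, station: str, seed: int | None = None) -> CTDProfile:
    """Two-water-mass temperature profile for one station.

    Mixed layer (0–``mixed_layer_m``) at a solved surface temperature, linear
    thermocline down to ``thermocline_bottom_m``, constant deep water below;
    the surface temperature is chosen so the exact 0–125 m mean of the
    noise-free profile equals the archetype's surface mean.
    """
    arch = config.stations[station]
    rng = _child_rng(config, _STREAM_CTD, station, seed)
    z_ml, z_t = config.mixed_layer_m, config.thermocline_bottom_m
    z_ref = 125.0  # layer over which the archetype mean is defined
    if not z_ml < z_ref < z_t:
        raise ValueError("need mixed_layer_m < 125 < thermocline_bottom_m")
    # mean over [0, z_ref] of the piecewise profile = alpha*T_top + beta*T_deep
    s_end = (z_ref - z_ml) / (z_t - z_ml)
    beta = (z_ref - z_ml) * (s_end / 2.0) / z_ref
    alpha = 1.0 - beta
    t_top = (arch.surface_mean_C - beta * arch.deep_temp_C) / alpha
    z = np.arange(0.0, config.ctd_max_depth_m + config.ctd_step_m / 2, config.ctd_step_m)
    s = np.clip((z - z_ml) / (z_t - z_ml), 0.0, 1.0)
    t = t_top + (arch.deep_temp_C - t_top) * s
    t = t + rng.normal(0.0, config.ctd_noise_sd_C, size=z.size)
    return CTDProfile(station=station, depth_m=z, temperature_C=t)


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------

def _stratum_for_depth(strata: Sequence[tuple[float, float]], z: np.ndarray):
    """Half-open [upper, lower) membership; deepest stratum closed below."""
    uppers = np.array([s[0] for s in strata])
    lowers = np.array([s[1] for s in strata])
    idx = np.searchsorted(uppers, z, side="right") - 1
    idx = np.clip(idx, 0, len(strata) - 1)
    if np.any(z < uppers[0]) or np.any(z > lowers[-1]):
        raise ValueError("sampled depth outside stratum plan")
    return uppers[idx], lowers[idx]


def _draw_latents(
    config: GeneratorConfig, arch: StationArchetype, profile: CTDProfile, n: int, rng
) -> pd.DataFrame:
    """Draw n individuals' latent state and evaluate capability exactly."""
    stages = list(config.stage_mix)
    probs = np.array([config.stage_mix[s] for s in stages])
    stage = rng.choice(stages, size=n, p=probs)

    mean = np.array([config.length_mean_mm[s] for s in stage])
    sd = np.array([config.length_sd_mm[s] for s in stage])
    L = rng.normal(mean, sd)
    bad = L <= 0
    while np.any(bad):  # truncate at 0 by redraw (practically never triggers)
        L[bad] = rng.normal(mean[bad], sd[bad])
        bad = L <= 0

    fullness = rng.beta(config.fullness_alpha, config.fullness_beta, size=n)
    w_max = max_lipid_reserve(L, config.allometry)
    w = fullness * w_max
    m = config.structural_coef * np.power(L, config.structural_exp)
    if config.structural_sigma > 0:
        m = m * np.exp(rng.normal(0.0, config.structural_sigma, size=n))

    weights = np.array([b.weight for b in arch.depth_bands])
    band_idx = rng.choice(len(arch.depth_bands), size=n, p=weights)
    band_up = np.array([b.upper_m for b in arch.depth_bands])[band_idx]
    band_lo = np.array([b.lower_m for b in arch.depth_bands])[band_idx]
    z = rng.uniform(band_up, band_lo)
    s_up, s_lo = _stratum_for_depth(config.strata, z)
    midpoint = (s_up + s_lo) / 2.0
    T = temperature_at_depth(profile, midpoint)

    r = respiration_rate(m, T, config.params)
    D = diapause_duration(w, r, config.params)
    return pd.DataFrame(
        {
            "stage": stage,
            "prosome_length_mm": L,
            "fullness": fullness,
            "max_lipid_carbon_ug": w_max,
            "lipid_carbon_ug": w,
            "structural_carbon_ug": m,
            "total_carbon_ug": m + w,
            "depth_m": z,
            "stratum_upper_m": s_up,
            "stratum_lower_m": s_lo,
            "assigned_temp_C": T,
            "respiration_ug_per_day": r,
            "diapause_days": D,
            "capable": D >= config.params.duration_threshold_days,
        }
    )


@dataclass
class GroundTruth:
    """Latent truth of a generated station population."""

    station: str
    true_capable_fraction: float  # all sampled depths
    true_deep_capable_fraction: float  # below the deep cutoff
    true_fullness_mean: float
    true_abundance_m2: dict[str, float]
    n_truth_mc: int
    latent: pd.DataFrame  # per generated individual

    def to_json_dict(self) -> dict:
        return {
            "station": self.station,
            "true_capable_fraction": self.true_capable_fraction,
            "true_deep_capable_fraction": self.true_deep_capable_fraction,
            "true_fullness_mean": self.true_fullness_mean,
            "true_abundance_m2": dict(self.true_abundance_m2),
            "n_truth_mc": self.n_truth_mc,
            "latent": self.latent.to_dict(orient="records"),
        }


def true_capable_fraction(
    config: GeneratorConfig,
    station: str,
    profile: CTDProfile,
    seed: int | None = None,
    deep_only: bool = False,
) -> float:
    """Capable fraction implied by the generating distributions.

    Dense Monte-Carlo integral (``n_truth_mc`` draws on a dedicated stream)
    of the deterministic capability indicator over the latent distributions,
    at the temperatures of the supplied profile.
    """
    arch = config.stations[station]
    rng = _child_rng(config, _STREAM_TRUTH, station, seed)
    lat = _draw_latents(config, arch, profile, config.n_truth_mc, rng)
    if deep_only:
        mid = (lat["stratum_upper_m"] + lat["stratum_lower_m"]) / 2.0
        lat = lat[mid > config.params.deep_cutoff_m]
    return float(lat["capable"].mean())


def generate_population(
    config: GeneratorConfig,
    station: str,
    profile: CTDProfile | None = None,
    n: int | None = None,
    seed: int | None = None,
    compute_truth: bool = True,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the body-condition subsample for one station.

    Returns ``(records, truth)``: ``records`` has exactly the individuals-CSV
    columns (lipid sac area back-computed from latent lipid carbon, so the
    biometric chain inverts the generator); ``truth`` carries the latent
    per-individual values and the Monte-Carlo capable fraction.
    """
    arch = config.stations[station]
    if profile is None:
        profile = generate_ctd(config, station, seed)
    n = config.n_individuals_per_station if n is None else int(n)
    if n < 1:
        raise ValueError("need n >= 1 individuals")
    rng = _child_rng(config, _STREAM_POP, station, seed)
    lat = _draw_latents(config, arch, profile, n, rng)

    we = lat["lipid_carbon_ug"].to_numpy() / WE_CARBON_FRACTION
    area = np.power(we / WE_AREA_COEF, 1.0 / WE_AREA_EXP)
    records = pd.DataFrame(
        {
            "individual_id": [f"{station}-{i:04d}" for i in range(n)],
            "station": station,
            "stage": lat["stage"],
            "stratum_upper_m": lat["stratum_upper_m"],
            "stratum_lower_m": lat["stratum_lower_m"],
            "prosome_length_mm": lat["prosome_length_mm"],
            "lipid_area_mm2": area,
            "total_carbon_ug": lat["total_carbon_ug"],
        }
    )
    lat = lat.copy()
    lat.insert(0, "individual_id", records["individual_id"].to_numpy())
    p_all = true_capable_fraction(config, station, profile, seed) if compute_truth else float("nan")
    p_deep = (
        true_capable_fraction(config, station, profile, seed, deep_only=True)
        if compute_truth
        else float("nan")
    )
    truth = GroundTruth(
        station=station,
        true_capable_fraction=p_all,
        true_deep_capable_fraction=p_deep,
        true_fullness_mean=config.fullness_alpha / (config.fullness_alpha + config.fullness_beta),
        true_abundance_m2=dict(arch.abundance_m2),
        n_truth_mc=config.n_truth_mc if compute_truth else 0,
        latent=lat,
    )
    return records, truth


# ---------------------------------------------------------------------------
# catch table
# ---------------------------------------------------------------------------

def _expected_count(
    arch: StationArchetype, total_m2: float, stratum: tuple[float, float], area_m2: float
) -> float:
    """Expected net count in a stratum: ∫ concentration dz × net area."""
    up, lo = stratum
    expect = 0.0
    for band in arch.depth_bands:
        overlap = max(0.0, min(lo, band.lower_m) - max(up, band.upper_m))
        conc = total_m2 * band.weight / band.thickness_m  # ind m^-3
        expect += conc * overlap
    return expect * area_m2


def generate_catch_table(
    config: GeneratorConfig, station: str, seed: int | None = None
) -> pd.DataFrame:
    """Multinet catch for one station: one row per stratum × stage.

    Counts are Poisson (negative-binomial when ``overdispersion`` is set)
    with expectation = true concentration × volume filtered; the volume is
    net mouth area × stratum thickness, so the recomputed depth-integrated
    abundance is unbiased for the configured total.
    """
    arch = config.stations[station]
    rng = _child_rng(config, _STREAM_CATCH, station, seed)
    rows = []
    for stage_name, total in arch.abundance_m2.items():
        for up, lo in config.strata:
            mu = _expected_count(arch, total, (up, lo), config.net_area_m2)
            if config.overdispersion is None:
                count = int(rng.poisson(mu)) if mu > 0 else 0
            else:
                k = config.overdispersion
                count = int(rng.negative_binomial(k, k / (k + mu))) if mu > 0 else 0
            rows.append(
                {
                    "station": station,
                    "season": config.season,
                    "stratum_upper_m": up,
                    "stratum_lower_m": lo,
                    "volume_filtered_m3": config.net_area_m2 * (lo - up),
                    "taxon": config.taxon,
                    "stage": stage_name,
                    "count": count,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def generate_bundle(
    config: GeneratorConfig,
    out_dir,
    stations: Sequence[str] | None = None,
) -> dict:
    """Write the full synthetic campaign to ``out_dir``.

    Produces ``individuals.csv``, ``catch.csv``, one ``ctd_<station>.csv``
    per station and ``ground_truth.json``; returns a dict of the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stations = sorted(config.stations) if stations is None else list(stations)
    individuals, catches, truths = [], [], {}
    ctd_paths = {}
    for st in stations:
        profile = generate_ctd(config, st)
        ctd_path = out / f"ctd_{st}.csv"
        pd.DataFrame(
            {"depth_m": profile.depth_m, "temperature_C": profile.temperature_C}
        ).to_csv(ctd_path, index=False)
        ctd_paths[st] = str(ctd_path)
        records, truth = generate_population(config, st, profile)
        individuals.append(records)
        catches.append(generate_catch_table(config, st))
        truths[st] = truth.to_json_dict()
    ind_path = out / "individuals.csv"
    catch_path = out / "catch.csv"
    pd.concat(individuals, ignore_index=True).to_csv(ind_path, index=False)
    pd.concat(catches, ignore_index=True).to_csv(catch_path, index=False)
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truths, indent=1))
    return {
        "individuals": str(ind_path),
        "catch": str(catch_path),
        "ctd": ctd_paths,
        "ground_truth": str(truth_path),
    }
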