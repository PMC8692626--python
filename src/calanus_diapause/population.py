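"""Depth-stratified abundance integration and population-level capability.

Net catches come from a multinet (MOCNESS-style) system: each net samples a
depth stratum with a known filtered volume, so ``count / volume`` is a
concentration (ind m⁻³) assumed uniform within the stratum.  Depth-integrated
abundance (ind m⁻²) is the sum over strata of concentration × overlapped
thickness; strata straddling an integration bound contribute pro rata.

The individual-level capability assessment (a subsample of ~10 animals per
stratum) is scaled to the population by multiplying the deep abundance
(below the 250 m cutoff by default) by the capable fraction of the assessed
deep individuals.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATCH_COLUMNS",
    "read_catch_table",
    "depth_integrated_abundance",
    "deep_abundance",
    "capable_fraction",
    "capable_abundance",
    "summarize_diapause",
    "classify_calanus_species",
    "station_summary",
]

#: Required columns of a catch CSV.
CATCH_COLUMNS = (
    "station",
    "season",
    "stratum_upper_m",
    "stratum_lower_m",
    "volume_filtered_m3",
    "taxon",
    "stage",
    "count",
)

SPECIES_LABELS = ("finmarchicus", "glacialis", "hyperboreus")


def read_catch_table(path) -> pd.DataFrame:
    """Read and validate a catch CSV (columns :data:`CATCH_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = [c for c in CATCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catch table missing columns: {missing}")
    for col in ("stratum_upper_m", "stratum_lower_m", "volume_filtered_m3", "count"):
        df[col] = pd.to_numeric(df[col])
    if (df["volume_filtered_m3"] <= 0).any():
        raise ValueError("volume filtered must be > 0 m^3")
    if (df["count"] < 0).any():
        raise ValueError("counts must be >= 0")
    if (df["stratum_upper_m"] >= df["stratum_lower_m"]).any():
        raise ValueError("stratum bounds must satisfy upper < lower")
    return df


def depth_integrated_abundance(
    catch: pd.DataFrame,
    taxon: str,
    stage: str,
    z_from: float,
    z_to: float,
) -> float:
    """Depth-integrated abundance (ind m⁻²) of one taxon/stage over [z_from, z_to].

    Σ over strata of (count / volume) × overlapped thickness, concentration
    uniform within each stratum.  Returns 0 with a warning when no stratum
    overlaps the range.
    """
    if not z_from < z_to:
        raise ValueError("need z_from < z_to")
    rows = catch[(catch["taxon"] == taxon) & (catch["stage"] == stage)]
    if (rows["volume_filtered_m3"] <= 0).any():
        raise ValueError("volume filtered must be > 0 m^3")
    upper = rows["stratum_upper_m"].to_numpy(float)
    lower = rows["stratum_lower_m"].to_numpy(float)
    overlap = np.maximum(
        0.0, np.minimum(lower, z_to) - np.maximum(upper, z_from)
    )
    if len(rows) == 0 or not np.any(overlap > 0):
        warnings.warn(
            f"no strata overlap [{z_from}, {z_to}] m for {taxon} {stage}",
            stacklevel=2,
        )
        return 0.0
    conc = rows["count"].to_numpy(float) / rows["volume_filtered_m3"].to_numpy(float)
    return float(np.sum(conc * overlap))


def deep_abundance(
    catch: pd.DataFrame,
    taxon: str,
    stage: str,
    deep_cutoff_m: float = 250.0,
) -> float:
    """Abundance (ind m⁻²) below the deep cutoff (pro-rata across the cutoff)."""
    z_max = float(catch["stratum_lower_m"].max())
    if z_max <= deep_cutoff_m:
        return 0.0
    return depth_integrated_abundance(catch, taxon, stage, deep_cutoff_m, z_max)


def capable_fraction(capable: Iterable) -> tuple[float, int, int]:
    """Fraction of assessed individuals classified overwinter-capable.

    ``capable`` is a boolean sequence (or a profiles DataFrame with a
    ``capable`` column).  Returns ``(fraction, n_capable, n_assessed)``;
    an empty input is an error because it cannot scale a population.
    """
    if isinstance(capable, pd.DataFrame):
        capable = capable["capable"]
    flags = np.asarray(list(capable), dtype=bool)
    n = flags.size
    if n == 0:
        raise ValueError("no assessed individuals: cannot compute capable fraction")
    n_capable = int(flags.sum())
    return n_capable / n, n_capable, n


def capable_abundance(deep_abundance_m2: float, fraction: float) -> int:
    """Capable deep abundance (ind m⁻²), rounded half-up to an integer."""
    if deep_abundance_m2 < 0:
        raise ValueError("deep abundance must be >= 0")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    return int(math.floor(deep_abundance_m2 * fraction + 0.5))


def summarize_diapause(diapause_days: Iterable) -> tuple[float, float, float]:
    """(max, min, mean) of diapause durations in days."""
    if isinstance(diapause_days, pd.DataFrame):
        diapause_days = diapause_days["diapause_days"]
    d = np.asarray(list(diapause_days), dtype=float)
    if d.size == 0:
        raise ValueError("no diapause durations to summarise")
    return float(d.max()), float(d.min()), float(d.mean())


def classify_calanus_species(
    stage: str,
    prosome_length_mm: float,
    thresholds: Mapping[str, Mapping[str, Sequence[float]]],
) -> str:
    """Assign a Calanus species from stage-specific prosome-length classes.

    ``thresholds`` maps stage → {species: (lower_mm, upper_mm)}; intervals
    are closed on the lower bound and open on the upper, so adjoining
    intervals give a unique assignment at the shared boundary.  A length
    matching no interval (or more than one, for overlapping configuration)
    is labelled ``"ambiguous"``.
    """
    if stage not in thresholds:
        raise ValueError(f"no species length thresholds configured for stage {stage!r}")
    if not prosome_length_mm > 0:
        raise ValueError("prosome length must be > 0 mm")
    matches = [
        species
        for species, (lo, hi) in thresholds[stage].items()
        if lo <= prosome_length_mm < hi
    ]
    if len(matches) == 1:
        return matches[0]
    return "ambiguous"


def station_summary(
    catch: pd.DataFrame,
    deep_profiles: pd.DataFrame,
    taxon: str = "C. finmarchicus",
    stage: str = "CV",
    deep_cutoff_m: float = 250.0,
) -> dict:
    """Population summary for one station (shape of a deep-population table).

    ``deep_profiles`` are the assessed individuals captured below the
    cutoff.  Abundances are reported to integer ind m⁻² and durations to
    integer days, as is conventional for such tables; the returned dict also
    keeps the unrounded values (``*_raw``).
    """
    z_min = float(catch["stratum_upper_m"].min())
    z_max = float(catch["stratum_lower_m"].max())
    total = depth_integrated_abundance(catch, taxon, stage, z_min, z_max)
    deep = deep_abundance(catch, taxon, stage, deep_cutoff_m)
    frac, n_capable, n_assessed = capable_fraction(deep_profiles)
    d_max, d_min, d_mean = summarize_diapause(deep_profiles)
    return {
        "taxon": taxon,
        "stage": stage,
        "total_abundance_m2": int(math.floor(total + 0.5)),
        "deep_abundance_m2": int(math.floor(deep + 0.5)),
        "capable_fraction": frac,
        "n_capable": n_capable,
        "n_assessed": n_assessed,
        "capable_abundance_m2": capable_abundance(deep, frac),
        "diapause_max_days": int(math.floor(d_max + 0.5)),
        "diapause_min_days": int(math.floor(d_min + 0.5)),
        "diapause_mean_days": int(math.floor(d_mean + 0.5)),
        "total_abundance_m2_raw": total,
        "deep_abundance_m2_raw": deep,
        "diapause_mean_days_raw": d_mean,
    }
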