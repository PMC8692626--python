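"""Diapause respiration, duration and overwinter-capability classification.

The model is carbon based.  Only the structural mass ``m`` (total body
carbon minus lipid-reserve carbon) drives metabolism; respiration of a
diapausing individual follows a 3/4-power allometry with Boltzmann–Arrhenius
temperature scaling,

    r = b · m^(3/4) · exp[ E · (T − T0) / (k · T · T0) ]        (μg C s⁻¹)

converted to μg C day⁻¹ by multiplying by 86 400.  Diapause ends when the
lipid reserve ``w`` has been respired down to a retained fraction (default
20%) kept for the spring moult and reproduction, so the duration is

    D = (w − retained_fraction · w) / r                          (days)

and an individual is classified overwinter-capable when D ≥ 150 days
(closed boundary).

Two constants deserve a note.  The base temperature ``T0`` is taken as
273.15 K (0 °C): with this choice the Arrhenius factor is exactly 1 at
0 °C, the usual deviation-from-reference form.  (Interpreting T0 as
absolute zero would make the exponent singular.)  The activation energy
defaults to E = 0.65 eV, the canonical metabolic-theory value; both are
configurable because field studies differ in the exact choice.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .biometry import (
    MaxLipidAllometry,
    lipid_area_to_wax_ester,
    lipid_fullness,
    max_lipid_reserve,
    partition_carbon,
    wax_ester_to_carbon,
)

__all__ = [
    "BOLTZMANN_EV_PER_K",
    "ModelParams",
    "EnergeticsProfile",
    "respiration_rate",
    "diapause_duration",
    "is_overwinter_capable",
    "required_reserve",
    "max_diapause_duration",
    "assess_individual",
    "assess_table",
]

#: Boltzmann constant in eV K⁻¹ (CODATA).
BOLTZMANN_EV_PER_K = 8.617333e-5

#: Sanity window for assigned temperatures, °C (warn outside, do not fail).
_TEMP_SANITY_C = (-3.0, 30.0)

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class ModelParams:
    """All constants of the respiration/duration model.

    Parameters
    ----------
    b : universal metabolic scaling constant, μg C^(1/4) s⁻¹.
    activation_energy_eV : Arrhenius activation energy E, eV.
    boltzmann_eV_per_K : Boltzmann constant k, eV K⁻¹.
    base_temperature_K : reference temperature T0, K (Arrhenius factor = 1
        at this temperature).
    retained_fraction : fraction of the pre-diapause lipid reserve kept at
        emergence (not respired during diapause).
    duration_threshold_days : minimum diapause duration classified as a
        successful overwinter.
    deep_cutoff_m : depth separating the surface population from the deep
        (candidate overwintering) population.
    """

    b: float = 2.5e-7
    activation_energy_eV: float = 0.65
    boltzmann_eV_per_K: float = BOLTZMANN_EV_PER_K
    base_temperature_K: float = 273.15
    seconds_per_day: float = SECONDS_PER_DAY
    retained_fraction: float = 0.2
    duration_threshold_days: float = 150.0
    deep_cutoff_m: float = 250.0

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("b must be > 0")
        if self.activation_energy_eV < 0:
            raise ValueError("activation energy must be >= 0")
        if not self.boltzmann_eV_per_K > 0:
            raise ValueError("Boltzmann constant must be > 0")
        if not self.base_temperature_K > 0:
            raise ValueError("base temperature must be > 0 K")
        if not 0 <= self.retained_fraction < 1:
            raise ValueError("retained fraction must lie in [0, 1)")
        if not self.duration_threshold_days > 0:
            raise ValueError("duration threshold must be > 0 days")

    # keys used in parameter files, mapped to field names
    _FILE_KEYS = {
        "b": "b",
        "E_eV": "activation_energy_eV",
        "k_eV_per_K": "boltzmann_eV_per_K",
        "T0_K": "base_temperature_K",
        "retained_fraction": "retained_fraction",
        "D_threshold_days": "duration_threshold_days",
        "deep_cutoff_m": "deep_cutoff_m",
    }

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ModelParams":
        """Build params from a key-value mapping (unrecognised keys ignored)."""
        kwargs = {
            field_name: float(mapping[key])
            for key, field_name in cls._FILE_KEYS.items()
            if key in mapping
        }
        return cls(**kwargs)

    def to_mapping(self) -> dict:
        """Inverse of :meth:`from_mapping` (file-key → value)."""
        d = asdict(self)
        return {key: d[field_name] for key, field_name in self._FILE_KEYS.items()}

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class EnergeticsProfile:
    """Derived per-individual energetic state."""

    individual_id: str
    we_ug: float
    lipid_carbon_ug: float
    structural_carbon_ug: float
    max_lipid_carbon_ug: float
    fullness: float
    over_ceiling: bool
    assigned_temp_C: float
    respiration_ug_per_day: float
    diapause_days: float
    capable: bool


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def respiration_rate(structural_carbon_ug, temperature_C, params: ModelParams = ModelParams()):
    """Diapause respiration rate r (μg C day⁻¹) of structural mass at T (°C).

    ``r = b · m^(3/4) · exp[E (T − T0)/(k T T0)] · 86 400`` with T in Kelvin.
    Strictly increasing in m, and in T when E > 0.  Warns if T is outside a
    [−3, 30] °C sanity window.
    """
    m = _as_array(structural_carbon_ug)
    t_c = _as_array(temperature_C)
    if np.any(m <= 0):
        raise ValueError("structural carbon must be > 0 ug for respiration")
    T = t_c + 273.15
    if np.any(T <= 0):
        raise ValueError("temperature below absolute zero")
    if np.any((t_c < _TEMP_SANITY_C[0]) | (t_c > _TEMP_SANITY_C[1])):
        warnings.warn(
            f"temperature outside sanity window {_TEMP_SANITY_C} degC",
            stacklevel=2,
        )
    T0 = params.base_temperature_K
    arrhenius = np.exp(
        params.activation_energy_eV * (T - T0) / (params.boltzmann_eV_per_K * T * T0)
    )
    r = params.b * np.power(m, 0.75) * arrhenius * params.seconds_per_day
    return float(r) if np.isscalar(structural_carbon_ug) and np.isscalar(temperature_C) else r


def diapause_duration(lipid_carbon_ug, respiration_ug_per_day, params: ModelParams = ModelParams()):
    """Days to respire the lipid reserve down to the retained fraction.

    ``D = (w − retained_fraction · w) / r``; linear in w.
    """
    w = _as_array(lipid_carbon_ug)
    r = _as_array(respiration_ug_per_day)
    if np.any(w < 0):
        raise ValueError("lipid carbon must be >= 0 ug")
    if np.any(r <= 0):
        raise ValueError("respiration rate must be > 0")
    d = (w - params.retained_fraction * w) / r
    return float(d) if np.isscalar(lipid_carbon_ug) and np.isscalar(respiration_ug_per_day) else d


def is_overwinter_capable(diapause_days, params: ModelParams = ModelParams()):
    """True when D ≥ the duration threshold (closed boundary, default 150 d)."""
    d = _as_array(diapause_days)
    if np.any(d < 0):
        raise ValueError("diapause duration must be >= 0 days")
    capable = d >= params.duration_threshold_days
    return bool(capable) if np.isscalar(diapause_days) else capable


def required_reserve(respiration_ug_per_day, params: ModelParams = ModelParams()):
    """Lipid carbon (μg C) needed to sustain exactly the threshold duration.

    Closed-form inversion of the duration equation:
    ``w_req = D_threshold · r / (1 − retained_fraction)``, so
    ``diapause_duration(w_req, r) == D_threshold``.
    """
    r = _as_array(respiration_ug_per_day)
    if np.any(r <= 0):
        raise ValueError("respiration rate must be > 0")
    w_req = params.duration_threshold_days * r / (1.0 - params.retained_fraction)
    return float(w_req) if np.isscalar(respiration_ug_per_day) else w_req


def max_diapause_duration(
    prosome_length_mm,
    structural_carbon_ug,
    temperature_C,
    allometry: MaxLipidAllometry,
    params: ModelParams = ModelParams(),
):
    """Theoretical maximum diapause duration at the allometric lipid ceiling.

    Evaluates the duration with w replaced by w_max(L); an upper bound on D
    for any individual with the same L, m and T and w ≤ w_max.
    """
    w_max = max_lipid_reserve(prosome_length_mm, allometry)
    r = respiration_rate(structural_carbon_ug, temperature_C, params)
    return diapause_duration(w_max, r, params)


def assess_individual(
    record,
    temperature_C: float,
    allometry: MaxLipidAllometry,
    params: ModelParams = ModelParams(),
) -> EnergeticsProfile:
    """Run the full biometry→metabolism chain for one individual record.

    ``record`` is any mapping with the individuals-table fields.  Raises
    ``ValueError`` (with the individual id attached) if any stage of the
    chain rejects the record, including a lipid-carbon estimate that meets
    or exceeds the measured total carbon.
    """
    rid = str(record["individual_id"])
    try:
        we = lipid_area_to_wax_ester(float(record["lipid_area_mm2"]))
        w = wax_ester_to_carbon(we)
        m = partition_carbon(float(record["total_carbon_ug"]), w)
        w_max = max_lipid_reserve(float(record["prosome_length_mm"]), allometry)
        fullness = lipid_fullness(w, w_max) if w > 0 else 0.0
        r = respiration_rate(m, temperature_C, params)
        d = diapause_duration(w, r, params)
        capable = is_overwinter_capable(d, params)
    except ValueError as exc:
        raise ValueError(f"individual {rid}: {exc}") from exc
    return EnergeticsProfile(
        individual_id=rid,
        we_ug=we,
        lipid_carbon_ug=w,
        structural_carbon_ug=m,
        max_lipid_carbon_ug=w_max,
        fullness=fullness,
        over_ceiling=fullness > 1.0,
        assigned_temp_C=float(temperature_C),
        respiration_ug_per_day=r,
        diapause_days=d,
        capable=capable,
    )


def assess_table(
    records: pd.DataFrame,
    temperatures_C,
    allometry: MaxLipidAllometry,
    params: ModelParams = ModelParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised assessment of a validated individuals table.

    Parameters
    ----------
    records : accepted individuals (see :func:`~.biometry.read_individuals`).
    temperatures_C : per-record assigned temperature, aligned with records.

    Returns
    -------
    (profiles, exclusions) : profiles carries the record identity columns
        plus every energetic quantity; exclusions lists records whose lipid
        carbon met or exceeded their measured total carbon (these cannot be
        partitioned into a positive structural mass and are excluded rather
        than clamped).
    """
    t = np.broadcast_to(_as_array(temperatures_C), (len(records),)).astype(float)
    we = lipid_area_to_wax_ester(records["lipid_area_mm2"].to_numpy(float))
    w = wax_ester_to_carbon(we)
    M = records["total_carbon_ug"].to_numpy(float)
    infeasible = w >= M
    exclusions = pd.DataFrame(
        {
            "individual_id": records.loc[infeasible, "individual_id"].to_numpy(),
            "reason": "lipid carbon >= total carbon",
        },
        columns=["individual_id", "reason"],
    )
    keep = ~infeasible
    rec = records.loc[keep].reset_index(drop=True)
    we, w, M, t = we[keep], w[keep], M[keep], t[keep]

    m = M - w
    L = rec["prosome_length_mm"].to_numpy(float)
    w_max = max_lipid_reserve(L, allometry)
    fullness = w / w_max
    r = respiration_rate(m, t, params) if len(rec) else np.array([])
    d = diapause_duration(w, r, params) if len(rec) else np.array([])

    profiles = rec.copy()
    profiles["we_ug"] = we
    profiles["lipid_carbon_ug"] = w
    profiles["structural_carbon_ug"] = m
    profiles["max_lipid_carbon_ug"] = w_max
    profiles["fullness"] = fullness
    profiles["over_ceiling"] = fullness > 1.0
    profiles["assigned_temp_C"] = t
    profiles["respiration_ug_per_day"] = r
    profiles["diapause_days"] = d
    profiles["capable"] = d >= params.duration_threshold_days
    return profiles, exclusions
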