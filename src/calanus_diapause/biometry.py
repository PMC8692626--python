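"""Carbon-based body-condition quantities from individual copepod biometrics.

Raw measurements per individual are prosome length ``L`` (mm), lipid sac
area ``A`` (mm²; planar area from a lateral image) and total body carbon
``M`` (μg C, from elemental analysis).  These are turned into the energetic
state used by the diapause model:

* wax-ester mass   ``WE = 0.167 · A^1.42`` (μg)
* lipid carbon     ``w  = 0.79 · WE``      (μg C)
* structural carbon ``m = M − w``          (μg C)
* allometric ceiling ``w_max = c · L^e``   (μg C)
* fullness          ``w / w_max``          (dimensionless)

All units are fixed at this boundary (mm, mm², μg C); no unit inference is
performed anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "WE_AREA_COEF",
    "WE_AREA_EXP",
    "WE_CARBON_FRACTION",
    "MaxLipidAllometry",
    "SYNTHETIC_ALLOMETRY",
    "lipid_area_to_wax_ester",
    "wax_ester_to_carbon",
    "partition_carbon",
    "max_lipid_reserve",
    "lipid_fullness",
    "read_individuals",
    "INDIVIDUAL_COLUMNS",
]

#: Copepodite developmental stages (CVI = adult).
STAGES = ("CI", "CII", "CIII", "CIV", "CV", "CVI")

#: Coefficient of the lipid-sac-area → wax-ester-mass conversion (μg mm⁻²ᵉ).
WE_AREA_COEF = 0.167
#: Exponent of the lipid-sac-area → wax-ester-mass conversion.
WE_AREA_EXP = 1.42
#: Carbon fraction of wax esters (μg C per μg WE).
WE_CARBON_FRACTION = 0.79

#: Required columns of an individuals CSV.
INDIVIDUAL_COLUMNS = (
    "individual_id",
    "station",
    "stage",
    "stratum_upper_m",
    "stratum_lower_m",
    "prosome_length_mm",
    "lipid_area_mm2",
    "total_carbon_ug",
)


@dataclass(frozen=True)
class MaxLipidAllometry:
    """Power-law ceiling on the lipid reserve as a function of prosome length.

    ``w_max = coefficient · L^exponent`` with ``L`` in mm and ``w_max`` in
    μg C.  The coefficients are configuration: no literature default is
    baked in, because published values vary by population and the pipeline
    must never silently assume one.
    """

    coefficient: float  # μg C per mm^exponent
    exponent: float  # dimensionless

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise ValueError(f"allometry coefficient must be > 0, got {self.coefficient}")
        if not self.exponent > 0:
            raise ValueError(f"allometry exponent must be > 0, got {self.exponent}")


#: Synthetic allometry used by the data generator and the examples.  These
#: are round plausibility-tuned numbers (w_max = 160 μg C at L = 2 mm), not
#: values from any field study.
SYNTHETIC_ALLOMETRY = MaxLipidAllometry(coefficient=20.0, exponent=3.0)


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def lipid_area_to_wax_ester(area_mm2):
    """Wax-ester mass (μg) from lipid sac area (mm²): ``WE = 0.167 · A^1.42``.

    Accepts scalars or arrays.  Raises ``ValueError`` on negative areas.
    """
    a = _as_array(area_mm2)
    if np.any(a < 0):
        raise ValueError("lipid sac area must be >= 0 mm^2")
    we = WE_AREA_COEF * np.power(a, WE_AREA_EXP)
    return float(we) if np.isscalar(area_mm2) else we


def wax_ester_to_carbon(we_ug):
    """Lipid carbon w (μg C) from wax-ester mass (μg): ``w = 0.79 · WE``."""
    we = _as_array(we_ug)
    if np.any(we < 0):
        raise ValueError("wax-ester mass must be >= 0 ug")
    w = WE_CARBON_FRACTION * we
    return float(w) if np.isscalar(we_ug) else w


def partition_carbon(total_carbon_ug, lipid_carbon_ug):
    """Structural carbon ``m = M − w`` (μg C).

    An individual whose estimated lipid carbon meets or exceeds its measured
    total carbon has no positive structural mass and cannot be run through
    the respiration model; such inputs raise ``ValueError`` (callers that
    process tables catch this per record and report it, rather than clamping
    m to ~0, which would explode respiration-based durations).
    """
    M = _as_array(total_carbon_ug)
    w = _as_array(lipid_carbon_ug)
    if np.any(M <= 0):
        raise ValueError("total carbon must be > 0 ug")
    if np.any(w < 0):
        raise ValueError("lipid carbon must be >= 0 ug")
    if np.any(w >= M):
        raise ValueError("lipid carbon >= total carbon: no positive structural mass")
    m = M - w
    return float(m) if np.isscalar(total_carbon_ug) else m


def max_lipid_reserve(prosome_length_mm, allometry: MaxLipidAllometry):
    """Maximum possible lipid reserve w_max (μg C) for a given prosome length."""
    L = _as_array(prosome_length_mm)
    if np.any(L <= 0):
        raise ValueError("prosome length must be > 0 mm")
    w_max = allometry.coefficient * np.power(L, allometry.exponent)
    return float(w_max) if np.isscalar(prosome_length_mm) else w_max


def lipid_fullness(lipid_carbon_ug, max_lipid_carbon_ug):
    """Fullness ``w / w_max`` of the lipid reserve.

    Values above 1 are returned untruncated (a measured reserve can exceed
    the allometric ceiling); callers flag them via ``fullness > 1``.
    """
    w = _as_array(lipid_carbon_ug)
    w_max = _as_array(max_lipid_carbon_ug)
    if np.any(w < 0):
        raise ValueError("lipid carbon must be >= 0 ug")
    if np.any(w_max <= 0):
        raise ValueError("max lipid reserve must be > 0 ug")
    f = w / w_max
    return float(f) if np.isscalar(lipid_carbon_ug) else f


def _reject(rejections: list, individual_id, reason: str) -> None:
    rejections.append({"individual_id": individual_id, "reason": reason})


def validate_individuals(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an individuals table into accepted records and rejections.

    Checks the per-record preconditions: stage in the copepodite enumeration,
    0 ≤ stratum_upper < stratum_lower, L > 0, A ≥ 0, M > 0.  Returns
    ``(accepted, rejections)`` where rejections has columns
    ``individual_id, reason``.
    """
    missing = [c for c in INDIVIDUAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"individuals table missing columns: {missing}")
    rejections: list[dict] = []
    ok = pd.Series(True, index=df.index)

    def fail(mask: pd.Series, reason: str) -> None:
        nonlocal ok
        for rid in df.loc[mask & ok, "individual_id"]:
            _reject(rejections, rid, reason)
        ok &= ~mask

    numeric = {}
    for col in ("stratum_upper_m", "stratum_lower_m", "prosome_length_mm",
                "lipid_area_mm2", "total_carbon_ug"):
        numeric[col] = pd.to_numeric(df[col], errors="coerce")
        fail(numeric[col].isna(), f"non-numeric {col}")

    fail(~df["stage"].isin(STAGES), "unknown stage")
    fail(numeric["stratum_upper_m"] < 0, "negative stratum_upper_m")
    fail(~(numeric["stratum_upper_m"] < numeric["stratum_lower_m"]),
         "stratum bounds not increasing")
    fail(~(numeric["prosome_length_mm"] > 0), "non-positive prosome length")
    fail(numeric["lipid_area_mm2"] < 0, "negative lipid sac area")
    fail(~(numeric["total_carbon_ug"] > 0), "non-positive total carbon")

    accepted = df.loc[ok].copy()
    for col, series in numeric.items():
        accepted[col] = series.loc[ok]
    rej = pd.DataFrame(rejections, columns=["individual_id", "reason"])
    return accepted.reset_index(drop=True), rej


def read_individuals(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an individuals CSV and validate it.

    The CSV must have a header with the columns in :data:`INDIVIDUAL_COLUMNS`
    (UTF-8, '.' decimal separator).  Returns ``(accepted, rejections)``.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "station": str, "stage": str})
    return validate_individuals(df)


def write_rejections(rejections: pd.DataFrame, path) -> None:
    """Write the per-record rejection report (individual_id, reason) as CSV."""
    rejections.to_csv(path, index=False)
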