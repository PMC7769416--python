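"""Organ equivalent dose and excess absolute risk.

Second-cancer risk for organ T is estimated as

    EAR_T = EAR_T0 * OED_T

where EAR_T0 is the epidemiological excess-absolute-risk coefficient (per
10^4 person-years per Gy, atomic-bomb-survivor incidence data, attained
age 70, exposure ages 30 or 50) and OED_T is the organ equivalent dose
summarizing the organ's DVH under an assumed dose-response shape:

    linear:              OED = (1/V_T) * sum_i V_i * D_i      (= mean dose)
    linear-exponential:  OED = (1/V_T) * sum_i V_i * D_i * exp(-alpha D_i)

with alpha = 0.044 / Gy from combined survivor/Hodgkin cohort fits.  The
linear model is used below a mean organ dose of 2 Gy, where it is a good
approximation; above 2 Gy cell kill bends the response and the
linear-exponential model is selected instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dosimetry import DVH, OrganStats

__all__ = [
    "RiskModelConfig",
    "RiskCoefficient",
    "OEDResult",
    "EARResult",
    "oed_linear",
    "oed_linexp",
    "select_model",
    "ear",
    "ear_ci",
    "risk_table",
    "load_risk_coefficients",
    "default_risk_coefficients",
]


@dataclass
class RiskModelConfig:
    """Dose-response model settings."""

    alpha_per_gy: float = 0.044
    selection_threshold_gy: float = 2.0  # mean-dose threshold for model switch

    def __post_init__(self) -> None:
        if self.alpha_per_gy < 0:
            raise ValueError("alpha must be >= 0")
        if self.selection_threshold_gy <= 0:
            raise ValueError("selection threshold must be > 0")


@dataclass(frozen=True)
class RiskCoefficient:
    """Per-organ epidemiological EAR coefficient with 90% CI.

    Units: excess cases per 10^4 person-years per Gy at the reference
    attained age, for one exposure age.
    """

    organ: str
    exposure_age: int
    ear0: float
    ci90: tuple[float, float] | None = None
    attained_age: int = 70
    source: str = ""

    def __post_init__(self) -> None:
        if self.ear0 < 0:
            raise ValueError("EAR0 must be >= 0")
        if self.ci90 is not None:
            lo, hi = self.ci90
            if not (lo <= self.ear0 <= hi) or lo < 0:
                raise ValueError(f"invalid CI {self.ci90} for EAR0={self.ear0}")


@dataclass
class OEDResult:
    organ: str
    model: str  # "linear" | "linear-exponential"
    oed_gy: float

    def __post_init__(self) -> None:
        if self.oed_gy < 0:
            raise ValueError("OED must be >= 0")


@dataclass
class EARResult:
    organ: str
    exposure_age: int
    ear: float  # per 10^4 person-years
    ci90: tuple[float, float] | None = None
    model: str = "linear"


def oed_linear(dvh: DVH) -> OEDResult:
    """Linear-response OED: the DVH-weighted mean dose."""
    vt = dvh.total_volume
    if vt <= 0:
        raise ValueError("DVH has zero total volume")
    oed = float(np.dot(dvh.volumes, dvh.bin_doses) / vt)
    return OEDResult(organ=dvh.organ, model="linear", oed_gy=oed)


def oed_linexp(dvh: DVH, config: RiskModelConfig | None = None) -> OEDResult:
    """Linear-exponential OED; reduces exactly to the linear OED at alpha=0."""
    config = config or RiskModelConfig()
    vt = dvh.total_volume
    if vt <= 0:
        raise ValueError("DVH has zero total volume")
    d = dvh.bin_doses
    oed = float(np.dot(dvh.volumes, d * np.exp(-config.alpha_per_gy * d)) / vt)
    return OEDResult(organ=dvh.organ, model="linear-exponential", oed_gy=oed)


def select_model(stats: OrganStats, config: RiskModelConfig | None = None) -> str:
    """Pick the dose-response model from the organ's mean dose.

    Strictly above the threshold (default 2 Gy) -> linear-exponential;
    at or below -> linear.
    """
    config = config or RiskModelConfig()
    return (
        "linear-exponential"
        if stats.mean_gy > config.selection_threshold_gy
        else "linear"
    )


def ear(oed: OEDResult, coeff: RiskCoefficient) -> EARResult:
    """EAR = EAR0 x OED (per 10^4 person-years)."""
    result = coeff.ear0 * oed.oed_gy
    return EARResult(
        organ=oed.organ,
        exposure_age=coeff.exposure_age,
        ear=result,
        ci90=ear_ci(oed, coeff),
        model=oed.model,
    )


def ear_ci(oed: OEDResult, coeff: RiskCoefficient) -> tuple[float, float] | None:
    """90% CI scaled from the coefficient CI; lower bound clamped at 0.

    Dose statistical uncertainty is reported separately in the organ-dose
    table and is not folded into this interval.
    """
    if coeff.ci90 is None:
        return None
    lo, hi = coeff.ci90
    return (max(0.0, lo * oed.oed_gy), hi * oed.oed_gy)


def risk_table(
    organ_data: list[tuple[OrganStats, DVH]],
    coefficients: list[RiskCoefficient],
    config: RiskModelConfig | None = None,
    site_map: dict[str, str] | None = None,
    plan: str = "",
) -> pd.DataFrame:
    """Per-organ x exposure-age EAR table.

    ``site_map`` maps phantom organ names to coefficient-table site names
    (identity by default).  Organs without a matching coefficient appear
    with blank EAR, matching the reporting convention for sites with no
    survivor-data coefficient.
    """
    config = config or RiskModelConfig()
    site_map = site_map or {}
    by_site: dict[tuple[str, int], RiskCoefficient] = {
        (c.organ, c.exposure_age): c for c in coefficients
    }
    ages = sorted({c.exposure_age for c in coefficients}) or [30, 50]

    rows = []
    for stats, dvh in organ_data:
        model = select_model(stats, config)
        oed = oed_linexp(dvh, config) if model == "linear-exponential" else oed_linear(dvh)
        site = site_map.get(stats.organ, stats.organ)
        for age in ages:
            coeff = by_site.get((site, age))
            row = {
                "organ": stats.organ,
                "site": site,
                "plan": plan,
                "exposure_age": age,
                "model": model,
                "oed_gy": oed.oed_gy,
                "mean_dose_gy": stats.mean_gy,
                "ear_per_10k_py": np.nan,
                "ci90_lo": np.nan,
                "ci90_hi": np.nan,
            }
            if coeff is not None:
                res = ear(oed, coeff)
                row["ear_per_10k_py"] = res.ear
                if res.ci90 is not None:
                    row["ci90_lo"], row["ci90_hi"] = res.ci90
            rows.append(row)
    return pd.DataFrame(rows)


# -- coefficient table IO -------------------------------------------------

def load_risk_coefficients(path: str | Path) -> list[RiskCoefficient]:
    """Load a YAML coefficient table.

    Schema: ``coefficients`` is a list of mappings with keys ``organ``,
    ``exposure_age``, ``ear0_per_10k_py_gy``, optional ``ci90`` (two
    floats), ``attained_age`` and ``source``.
    """
    doc = yaml.safe_load(Path(path).read_text())
    out = []
    for c in doc["coefficients"]:
        ci = c.get("ci90")
        out.append(
            RiskCoefficient(
                organ=c["organ"],
                exposure_age=int(c["exposure_age"]),
                ear0=float(c["ear0_per_10k_py_gy"]),
                ci90=tuple(ci) if ci else None,
                attained_age=int(c.get("attained_age", 70)),
                source=c.get("source", ""),
            )
        )
    return out


def default_risk_coefficients() -> list[RiskCoefficient]:
    """Coefficient table shipped with the package (editable YAML)."""
    ref = resources.files("scatterrisk.data") / "risk_coefficients.yaml"
    with resources.as_file(ref) as path:
        return load_risk_coefficients(path)
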