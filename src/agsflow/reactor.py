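"""Sequencing-batch-reactor bookkeeping.

Solids retention time, cycle arithmetic, removal efficiencies, sieve size
fractions, SVI ratios, influent composition ratios, and the start-up success
classifier (settling + granulation + stable removal).

Start-up boundary handling follows the criterion wording exactly: strict for
``SVI30 < 90`` and ``SVI30/SVI10 > 0.8``, inclusive for the granule fraction
(``>= 50%`` of TSS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .containers import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SrtInputs",
    "ReactorConfig",
    "srt",
    "cycles_per_day",
    "removal_efficiency",
    "size_fractions",
    "cnp_ratio",
    "vfa_cod_ratio",
    "startup_classifier",
    "removal_stability",
    "first_startup_day",
]

STARTUP_SVI30_MAX = 90.0       # mL/g, strict
STARTUP_RATIO_MIN = 0.8        # SVI30/SVI10, strict
STARTUP_GRANULE_MIN = 0.5      # fraction of TSS, inclusive


@dataclass(frozen=True)
class SrtInputs:
    """Inputs to the solids-retention-time balance.

    Volumes in L, solids in g TSS/L, flows in L/d.
    """

    v_r: float          # reactor volume
    tss_r: float        # reactor solids
    q_ex: float = 0.0   # excess-sludge flow
    tss_ex: float = 0.0
    q_eff: float = 0.0  # effluent flow
    tss_eff: float = 0.0

    def __post_init__(self) -> None:
        if self.v_r <= 0:
            raise ValidationError("reactor volume must be positive")
        for name in ("tss_r", "q_ex", "tss_ex", "q_eff", "tss_eff"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ReactorConfig:
    """Operational set-points of one sequencing batch reactor."""

    v_crit: float = 1.7        # critical settling velocity, m/h
    v_ww: float = 0.25         # upflow velocity during plug-flow feeding, m/h
    ver: float = 0.3           # volume exchange ratio
    cycle_length_h: float = 5.6
    do_setpoint: float = 2.0   # mg O2/L

    def __post_init__(self) -> None:
        if not 0 < self.ver <= 1:
            raise ValidationError("VER must lie in (0, 1]")
        if self.v_crit <= 0 or self.v_ww <= 0:
            raise ValidationError("settling/upflow velocities must be positive")


def srt(inputs: SrtInputs) -> float:
    """Solids retention time in days.

    ``SRT = V_r * TSS_r / (Q_ex * TSS_ex + Q_eff * TSS_eff)``.  A zero solids
    wastage denominator returns ``inf`` (no solids leave the reactor), which
    is distinct from numeric overflow.
    """
    denom = inputs.q_ex * inputs.tss_ex + inputs.q_eff * inputs.tss_eff
    numer = inputs.v_r * inputs.tss_r
    if denom == 0:
        return float("inf") if numer > 0 else 0.0
    return numer / denom


def cycles_per_day(cycle_length_h: float) -> float:
    """Cycles per day, rounded half-up to one decimal (5.6 h -> 4.3)."""
    if cycle_length_h <= 0:
        raise ValidationError("cycle length must be positive")
    raw = Decimal(24) / Decimal(str(cycle_length_h))
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def removal_efficiency(influent: float, effluent: float) -> float:
    """Percent removal ``100 * (in - out) / in``.

    Negative efficiencies (effluent above influent) are reported, not
    clamped, and logged as anomalies.
    """
    if influent <= 0:
        raise ValidationError("influent concentration must be positive")
    if effluent < 0:
        raise ValidationError("effluent concentration must be non-negative")
    eff = 100.0 * (influent - effluent) / influent
    if eff < 0:
        logger.warning("negative removal efficiency %.1f%% (in=%s, out=%s)",
                       eff, influent, effluent)
    return eff


def size_fractions(mass_large: float, mass_medium: float, mass_small: float,
                   mass_floc: float) -> dict:
    """Normalise sieve-fraction masses (>1.0, 0.63-1.0, 0.25-0.63, <0.25 mm).

    Returns the four fractions plus the total granule fraction
    (d > 0.25 mm = 1 - floc fraction).
    """
    masses = np.array([mass_large, mass_medium, mass_small, mass_floc],
                      dtype=float)
    if (masses < 0).any():
        raise ValidationError("sieve masses must be non-negative")
    total = masses.sum()
    if total == 0:
        raise ValidationError("total sieve mass is zero")
    frac = masses / total
    return {
        "frac_large": frac[0],
        "frac_medium": frac[1],
        "frac_small": frac[2],
        "frac_floc": frac[3],
        "frac_granule": 1.0 - frac[3],
    }


def cnp_ratio(cod: float, tn: float, tp: float) -> tuple[float, float, float]:
    """Influent C:N:P ratio normalised to carbon = 100 (COD basis)."""
    if cod <= 0:
        raise ValidationError("COD must be positive")
    return 100.0, 100.0 * tn / cod, 100.0 * tp / cod


def vfa_cod_ratio(ac_pr_cod: float, total_cod: float) -> float:
    """Acetate+propionate share of total influent COD."""
    if total_cod <= 0:
        raise ValidationError("total COD must be positive")
    if ac_pr_cod < 0:
        raise ValidationError("VFA COD must be non-negative")
    return ac_pr_cod / total_cod


def startup_classifier(svi30: float, svi_30_10: float, granule_fraction: float,
                       removal_stable: bool) -> tuple[bool, list]:
    """Start-up success test on one measurement.

    Success iff ``SVI30 < 90`` mL/g, ``SVI30/SVI10 > 0.8``, granule fraction
    (d > 0.25 mm) at least 50% of TSS, and stable substrate/nutrient removal.
    Returns ``(success, failed_criteria)``.
    """
    for name, value in (("svi30", svi30), ("svi_30_10", svi_30_10),
                        ("granule_fraction", granule_fraction),
                        ("removal_stable", removal_stable)):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValidationError(f"missing start-up field: {name}")
    failed = []
    if not svi30 < STARTUP_SVI30_MAX:
        failed.append("svi30")
    if not svi_30_10 > STARTUP_RATIO_MIN:
        failed.append("svi_30_10")
    if not granule_fraction >= STARTUP_GRANULE_MIN:
        failed.append("granule_fraction")
    if not removal_stable:
        failed.append("removal_stable")
    return (not failed), failed


def removal_stability(efficiencies, window: int = 5,
                      cv_threshold: float = 0.10) -> pd.Series:
    """Boolean series: rolling coefficient of variation below threshold.

    Operationalises "stable substrate and nutrient removal" as the rolling
    CV (sd/mean over ``window`` measurements) of a removal-efficiency series
    staying below ``cv_threshold``.  The first ``window - 1`` points inherit
    the first complete window's verdict.
    """
    s = pd.Series(efficiencies, dtype=float)
    mean = s.rolling(window).mean()
    sd = s.rolling(window).std(ddof=1)
    cv = sd / mean.abs()
    flag = pd.Series(np.where(cv.isna(), np.nan, (cv < cv_threshold)),
                     index=s.index)
    flag = flag.bfill().fillna(0.0).astype(bool)
    return flag


def first_startup_day(series: pd.DataFrame, persistence: int = 2):
    """First day from which the start-up classifier passes and keeps passing
    for ``persistence`` consecutive measurements.

    ``series`` needs columns ``day``, ``svi30``, ``svi_30_10``, a granule
    fraction (``frac_granule`` or ``1 - frac_floc``) and a boolean
    ``removal_stable``.  Returns the day, or ``None`` if never satisfied.
    """
    if "day" not in series.columns:
        raise ValidationError("series lacks a 'day' column")
    days = series["day"].to_numpy(dtype=float)
    if len(days) > 1 and not (np.diff(days) > 0).all():
        raise ValidationError("series must be time-ordered")
    if "frac_granule" in series.columns:
        gran = series["frac_granule"].to_numpy(dtype=float)
    elif "frac_floc" in series.columns:
        gran = 1.0 - series["frac_floc"].to_numpy(dtype=float)
    else:
        raise ValidationError("series lacks a granule fraction column")
    ok = np.array([
        startup_classifier(sv, ratio, g, bool(rs))[0]
        for sv, ratio, g, rs in zip(
            series["svi30"].to_numpy(dtype=float),
            series["svi_30_10"].to_numpy(dtype=float),
            gran,
            series["removal_stable"].to_numpy(),
        )
    ])
    n = len(ok)
    persistence = max(int(persistence), 1)
    for i in range(n):
        upto = min(i + persistence, n)
        if upto - i < persistence:
            break
        if ok[i:upto].all():
            return float(days[i])
    logger.info("start-up criteria never satisfied for %d consecutive points",
                persistence)
    return None
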