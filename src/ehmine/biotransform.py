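"""Chromatogram data reduction: conversion, e.e. and stereochemical calls.

Peak integrals from chiral HPLC/GC traces are converted to product
concentrations through a 5-point external-standard calibration line,
background-corrected against a no-enzyme control, and expressed as a
percent conversion of the initial epoxide load (default 10 mM).
Enantiomer pairs additionally yield the enantiomeric excess
``100 * |a - b| / (a + b)`` and the major configuration, and, for
mono-stereocentre benzylic epoxides, the regiochemical reading: a product
whose configuration is inverted relative to the substrate implies attack
of water at the benzylic (stereocentre) carbon, retention implies attack
at the terminal carbon.

Replicate conversions are summarised as mean and sample (n-1) standard
deviation, flagged when the SD exceeds 7 percentage points (the
reporting convention for assays run in duplicate or triplicate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SD_FLAG_THRESHOLD = 7.0   # percentage points
DEFAULT_S0 = 10.0         # mM initial epoxide


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line ``integral = slope * conc + intercept`` from standards."""

    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class EnantiomerPair:
    """Concentrations of the two enantiomers of one diol product."""

    conc_a: float
    conc_b: float
    config_a: str
    config_b: str

    def __post_init__(self) -> None:
        if self.conc_a < 0 or self.conc_b < 0:
            raise ValueError("enantiomer concentrations must be >= 0")


@dataclass
class BiotransformResult:
    enzyme: str
    substrate: str
    s0: float
    replicate_conversions: list[float]
    conversion: float
    sd: float
    sd_flag: bool
    ee: float | None = None
    major_config: str | None = None
    outcome: str = "n/a"
    field_notes: dict = field(default_factory=dict)


def fit_calibration(points: list[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary-least-squares calibration line from (conc, integral) pairs.

    Needs at least two distinct concentrations (a 5-point series in
    routine use).
    """
    if len(points) < 2:
        raise ValueError("calibration needs at least 2 points")
    conc = np.array([p[0] for p in points], dtype=float)
    integral = np.array([p[1] for p in points], dtype=float)
    if np.all(conc == conc[0]):
        raise ValueError("calibration concentrations are all identical")
    fit = stats.linregress(conc, integral)
    return CalibrationCurve(points=tuple((float(c), float(v)) for c, v in points),
                            slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2))


def quantify(curve: CalibrationCurve, integral: float) -> float:
    """Integral -> concentration; negative values clamp to 0 with a warning."""
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    conc = (integral - curve.intercept) / curve.slope
    if conc < 0:
        logger.warning("integral %.3g below calibration intercept; clamping "
                       "concentration %.3g to 0", integral, conc)
        return 0.0
    return conc


def percent_conversion(product_conc: float, background_conc: float,
                       s0: float = DEFAULT_S0) -> float:
    """Background-corrected conversion, capped to [0, 100]."""
    if s0 <= 0:
        raise ValueError("initial substrate concentration must be positive")
    if product_conc < 0 or background_conc < 0:
        raise ValueError("concentrations must be >= 0")
    conv = 100.0 * max(product_conc - background_conc, 0.0) / s0
    if conv > 100.0:
        logger.warning("conversion %.1f%% exceeds 100%%; capping", conv)
        return 100.0
    return conv


def enantiomeric_excess(pair: EnantiomerPair) -> tuple[float, str]:
    """e.e. percent and major configuration ("racemic" on an exact tie)."""
    total = pair.conc_a + pair.conc_b
    if total <= 0:
        raise ValueError("cannot compute e.e. of an empty enantiomer pair")
    ee = 100.0 * abs(pair.conc_a - pair.conc_b) / total
    if pair.conc_a == pair.conc_b:
        return 0.0, "racemic"
    major = pair.config_a if pair.conc_a > pair.conc_b else pair.config_b
    return ee, major


def stereo_outcome(substrate_config: str, major_product_config: str) -> str:
    """Regiochemical reading for a mono-stereocentre benzylic epoxide.

    Configurations that differ mean the stereocentre was inverted, i.e.
    water attacked the benzylic carbon; identical configurations mean
    retention, i.e. attack at the terminal carbon.  Meso or unresolved
    inputs return "n/a".
    """
    sub, prod = substrate_config.strip(), major_product_config.strip()
    if sub.lower() in {"meso", "rac", "racemic", "n/a", ""} or \
            prod.lower() in {"racemic", "n/a", ""}:
        return "n/a"
    if sub not in {"R", "S"} or prod not in {"R", "S"}:
        raise ValueError(f"unknown configuration labels {sub!r}/{prod!r}")
    return "inversion->benzylic" if sub != prod else "retention->terminal"


def summarize_replicates(conversions: list[float]) -> tuple[float, float, bool]:
    """Mean, sample SD and the >7-percentage-point variability flag."""
    if len(conversions) < 2:
        raise ValueError("need at least 2 replicates")
    arr = np.asarray(conversions, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return mean, sd, sd > SD_FLAG_THRESHOLD


# ---------------------------------------------------------------------------
# table-level reduction


def _calibration_from_table(df: pd.DataFrame) -> CalibrationCurve:
    std = df[df["role"].str.startswith("standard:")]
    if std.empty:
        raise ValueError("table contains no calibration standards")
    points = [(float(role.split(":", 1)[1]), float(integral))
              for role, integral in zip(std["role"], std["integral"])]
    return fit_calibration(points)


def reduce_table(df: pd.DataFrame, s0: float = DEFAULT_S0,
                 substrate_configs: dict[str, str] | None = None
                 ) -> list[BiotransformResult]:
    """Reduce an integral table to per enzyme x substrate results.

    Expects columns ``enzyme, substrate, replicate, peak, integral, role``
    with ``role`` one of ``standard:<conc>``, ``sample`` or ``control``
    (the layout `ehmine.synthetic_data.make_chromatogram_table` emits).
    ``substrate_configs`` maps substrate ids to their configuration
    (``R``/``S``/``meso``) to enable the stereochemical-outcome call.
    """
    required = {"enzyme", "substrate", "replicate", "peak", "integral", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    curve = _calibration_from_table(df)
    results = []
    samples = df[df["role"] == "sample"]
    for (enzyme, substrate), part in samples.groupby(["enzyme", "substrate"], sort=True):
        controls = df[(df["role"] == "control") & (df["enzyme"] == enzyme)
                      & (df["substrate"] == substrate)]
        background = float(np.mean([quantify(curve, v) for v in controls["integral"]])) \
            if len(controls) else 0.0
        conversions = []
        for _, rep in part.groupby("replicate"):
            total = sum(quantify(curve, v) for v in rep["integral"])
            conversions.append(percent_conversion(total, background, s0))
        mean, sd, flag = summarize_replicates(conversions) if len(conversions) > 1 \
            else (conversions[0], 0.0, False)
        peak_means = part.groupby("peak")["integral"].mean()
        ee = major = None
        if len(peak_means) == 2:
            (ca, cb) = (quantify(curve, v) for v in peak_means)
            pair = EnantiomerPair(ca, cb, *peak_means.index)
            if ca + cb > 0:
                ee, major = enantiomeric_excess(pair)
        outcome = "n/a"
        if substrate_configs and major is not None:
            sub_config = substrate_configs.get(str(substrate))
            if sub_config is not None:
                outcome = stereo_outcome(sub_config, major)
        results.append(BiotransformResult(
            enzyme=str(enzyme), substrate=str(substrate), s0=s0,
            replicate_conversions=conversions, conversion=mean, sd=sd,
            sd_flag=flag, ee=ee, major_config=major, outcome=outcome))
    return results


def results_tsv(results: list[BiotransformResult], path) -> None:
    """Write a result table mirroring the usual screening-table columns."""
    with open(path, "w") as fh:
        fh.write("enzyme\tsubstrate\tyield_pct\tsd\tsd_flag\tee_pct\t"
                 "abs_config\toutcome\n")
        for r in results:
            ee = "-" if r.ee is None else f"{r.ee:.1f}"
            major = r.major_config or "-"
            fh.write(f"{r.enzyme}\t{r.substrate}\t{r.conversion:.1f}\t"
                     f"{r.sd:.2f}\t{int(r.sd_flag)}\t{ee}\t{major}\t{r.outcome}\n")
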