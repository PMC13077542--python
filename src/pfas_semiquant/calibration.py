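"""Calibration curves and anchor-relative ionization efficiencies.

Electrospray response is proportional to analyte amount over the working
range, so the slope of a peak-area vs. concentration calibration line
operationalizes a compound's ionization efficiency (IE).  Absolute IE is
instrument- and condition-dependent; what transfers between compounds is
the *relative* IE against a designated anchor compound (by default FHUEA,
2H-perfluoro-2-octenoic acid), expressed on a log10 scale:

    exp_logIE = log10( (S_c / S_anchor) * (MW_anchor / MW_c) )

where ``S`` are calibration slopes fitted against *mass* concentration
(ng/mL) and the molecular-weight ratio converts the comparison to a molar
basis.  Given a predicted relative logIE for a compound without a
standard, its concentration follows from the anchor's calibration alone:

    C_pred = A * MW_anchor / (10**logIE * S_anchor * MW_c)

The inversion deliberately uses only the slope; intercepts are estimated
and reported but never enter the back-calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationError",
    "Compound",
    "CalibrationSeries",
    "CalibrationFit",
    "RelativeIE",
    "fit_calibration",
    "relative_log_ie",
    "predict_concentration",
    "read_registry",
    "read_calibration_table",
    "write_ie_table",
]

DEFAULT_ANCHOR_ID = "FHUEA"


class CalibrationError(ValueError):
    """Invalid calibration input (degenerate series, bad slope, bad units)."""


@dataclass(frozen=True)
class Compound:
    """A registered analyte: identifier, display name, molecular weight (g/mol)."""

    id: str
    name: str
    mw: float

    def __post_init__(self) -> None:
        if not self.id:
            raise CalibrationError("compound id must be a non-empty string")
        if not (math.isfinite(self.mw) and self.mw > 0):
            raise CalibrationError(
                f"compound {self.id!r}: molecular weight must be positive, got {self.mw}"
            )


@dataclass(frozen=True)
class CalibrationSeries:
    """Concentration levels (ng/mL, strictly positive) and matching peak areas."""

    compound_id: str
    levels: tuple
    areas: tuple

    def __init__(self, compound_id: str, levels: Sequence[float], areas: Sequence[float]):
        lv = tuple(float(x) for x in levels)
        ar = tuple(float(x) for x in areas)
        if len(lv) != len(ar):
            raise CalibrationError(
                f"{compound_id}: levels ({len(lv)}) and areas ({len(ar)}) differ in length"
            )
        if any(not math.isfinite(x) or x <= 0 for x in lv):
            raise CalibrationError(f"{compound_id}: levels must be finite and > 0")
        if any(not math.isfinite(a) for a in ar):
            raise CalibrationError(f"{compound_id}: non-finite peak area")
        object.__setattr__(self, "compound_id", compound_id)
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "areas", ar)

    @property
    def n_distinct_levels(self) -> int:
        return len(set(self.levels))


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line through a calibration series: area = slope*level + intercept."""

    compound_id: str
    slope: float
    intercept: float
    r2: float


@dataclass(frozen=True)
class RelativeIE:
    """log10 ionization efficiency relative to the anchor compound.

    ``source`` is ``"experimental"`` (from calibration slopes) or
    ``"predicted"`` (from a QSAR model).
    """

    compound_id: str
    log_ie: float
    source: str = "experimental"

    def __post_init__(self) -> None:
        if self.source not in ("experimental", "predicted"):
            raise ValueError(f"unknown RelativeIE source {self.source!r}")


def fit_calibration(series: CalibrationSeries) -> CalibrationFit:
    """Fit an unweighted OLS calibration line, area against mass concentration.

    ``r2`` is the squared Pearson correlation between fitted and observed
    areas, which for simple OLS equals the squared correlation of areas
    with levels.

    Raises
    ------
    CalibrationError
        If the series has fewer than two distinct concentration levels.
    """
    if series.n_distinct_levels < 2:
        raise CalibrationError(
            f"{series.compound_id}: need >=2 distinct levels to fit, "
            f"got {series.n_distinct_levels}"
        )
    x = np.asarray(series.levels, dtype=float)
    y = np.asarray(series.areas, dtype=float)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue) ** 2 if math.isfinite(res.rvalue) else 0.0
    return CalibrationFit(
        compound_id=series.compound_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
    )


def relative_log_ie(
    fit: CalibrationFit,
    compound: Compound,
    anchor_fit: CalibrationFit,
    anchor: Compound,
) -> RelativeIE:
    """Experimental relative logIE of ``compound`` against ``anchor``.

    Both slopes must be strictly positive; mass-based slopes are put on a
    molar footing via the molecular-weight ratio.
    """
    for f, c in ((fit, compound), (anchor_fit, anchor)):
        if not (math.isfinite(f.slope) and f.slope > 0):
            raise CalibrationError(
                f"{c.id}: calibration slope must be positive to form logIE, got {f.slope}"
            )
    value = math.log10((fit.slope / anchor_fit.slope) * (anchor.mw / compound.mw))
    return RelativeIE(compound_id=compound.id, log_ie=value, source="experimental")


def predict_concentration(
    area: float,
    pred: Union[RelativeIE, float],
    compound: Compound,
    anchor_fit: CalibrationFit,
    anchor: Compound,
) -> float:
    """Invert a (predicted) relative logIE into a mass concentration, ng/mL.

    Slope-only inversion through the anchor's calibration; the anchor's
    intercept is intentionally ignored, which biases the lowest levels when
    real intercepts are large.
    """
    log_ie = pred.log_ie if isinstance(pred, RelativeIE) else float(pred)
    if not (math.isfinite(anchor_fit.slope) and anchor_fit.slope > 0):
        raise CalibrationError(
            f"anchor {anchor.id}: slope must be positive, got {anchor_fit.slope}"
        )
    if not math.isfinite(area) or area < 0:
        raise CalibrationError(f"{compound.id}: peak area must be finite and >= 0")
    return area * anchor.mw / (10.0**log_ie * anchor_fit.slope * compound.mw)


# ---------------------------------------------------------------------------
# Delimited-text interfaces


def read_registry(path: Union[str, Path]) -> dict:
    """Read a compound registry CSV with columns compound_id, name, mw."""
    df = pd.read_csv(path)
    required = {"compound_id", "mw"}
    if not required.issubset(df.columns):
        raise CalibrationError(
            f"registry {path}: missing columns {sorted(required - set(df.columns))}"
        )
    if df["compound_id"].duplicated().any():
        dups = df.loc[df["compound_id"].duplicated(), "compound_id"].tolist()
        raise CalibrationError(f"registry {path}: duplicate compound ids {dups}")
    names = df["name"] if "name" in df.columns else df["compound_id"]
    return {
        str(row.compound_id): Compound(str(row.compound_id), str(name), float(row.mw))
        for row, name in zip(df.itertuples(index=False), names)
    }


def read_calibration_table(path: Union[str, Path]) -> list:
    """Read long-format calibration points: compound_id, level_ng_per_mL, area."""
    df = pd.read_csv(path)
    required = {"compound_id", "level_ng_per_mL", "area"}
    if not required.issubset(df.columns):
        raise CalibrationError(
            f"calibration table {path}: missing columns {sorted(required - set(df.columns))}"
        )
    series = []
    for cid, grp in df.groupby("compound_id", sort=True):
        series.append(
            CalibrationSeries(
                str(cid),
                grp["level_ng_per_mL"].to_numpy(dtype=float),
                grp["area"].to_numpy(dtype=float),
            )
        )
    return series


def write_ie_table(
    fits: Mapping[str, CalibrationFit],
    ies: Mapping[str, RelativeIE],
    path: Union[str, Path],
) -> pd.DataFrame:
    """Write per-compound slope/intercept/r2/exp_log_ie as delimited text."""
    rows = []
    for cid in sorted(fits):
        fit = fits[cid]
        ie = ies.get(cid)
        rows.append(
            {
                "compound_id": cid,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "exp_log_ie": ie.log_ie if ie is not None else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(path, index=False)
    return out
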