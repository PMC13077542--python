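"""Fold-error metrics for semi-quantitative predictions.

Two error conventions are used side by side:

- the symmetric IE fold error ``max(pred/actual, actual/pred)`` (always
  >= 1), suited to ionization efficiencies where only the magnitude of
  disagreement matters;
- the directional concentration error ``pred/actual`` (> 0, may be < 1),
  which preserves the sign of the bias.

Summaries report the median and arithmetic mean of the raw ratios plus a
geometric root-mean-square fold error, ``10**rms(log10(error))``, which
treats x-fold over- and under-prediction symmetrically and is >= 1 by
construction.  (The plain RMS of the raw ratios is also kept, but for
ratio data the geometric form is the headline number: a list of fold
errors all >= 1 with mean 1.10 can still have geometric RMS 1.06, which a
plain RMS never could.)

A worked example ships with the package: nine PFASs quantified in a fish
powder certified reference material by isotope-dilution MS (the reference
method) and by QSAR-predicted ionization efficiencies; see
:func:`load_fish_powder_example`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationError",
    "ErrorRecord",
    "ErrorSummary",
    "ie_fold_error",
    "concentration_error",
    "summarize_errors",
    "group_errors",
    "level_dispersion",
    "table2_report",
    "load_fish_powder_example",
    "round_half_up",
]


class EvaluationError(ValueError):
    """Invalid error-metric input."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used for display tables (1.005 -> 1.01)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ErrorRecord:
    """One prediction/reference pair with its error ratio."""

    compound_id: str
    level: Optional[float]
    predicted: float
    actual: float
    error: float


@dataclass(frozen=True)
class ErrorSummary:
    """Aggregate of error ratios: median, mean, geometric RMS fold, plain RMS."""

    median: float
    mean: float
    rms_fold: float
    rms_plain: float
    n: int


def ie_fold_error(pred: float, actual: float) -> float:
    """Symmetric fold error: max(pred/actual, actual/pred), always >= 1."""
    if not (pred > 0 and actual > 0) or not (math.isfinite(pred) and math.isfinite(actual)):
        raise EvaluationError(
            f"ie_fold_error needs strictly positive finite inputs, got ({pred}, {actual})"
        )
    return max(pred / actual, actual / pred)


def concentration_error(pred: float, actual: float) -> float:
    """Directional error ratio pred/actual; > 1 over-predicts, < 1 under-predicts."""
    if not (actual > 0 and math.isfinite(actual)):
        raise EvaluationError(f"concentration_error needs actual > 0, got {actual}")
    if not math.isfinite(pred):
        raise EvaluationError(f"concentration_error: non-finite prediction {pred}")
    return pred / actual


def _errors_array(records: Iterable) -> np.ndarray:
    vals = np.asarray(
        [r.error if isinstance(r, ErrorRecord) else float(r) for r in records],
        dtype=float,
    )
    if vals.size == 0:
        raise EvaluationError("summarize_errors: empty record list")
    if not (np.isfinite(vals).all() and (vals > 0).all()):
        raise EvaluationError("summarize_errors: error ratios must be finite and > 0")
    return vals


def summarize_errors(records: Iterable) -> ErrorSummary:
    """Median/mean of the ratios plus geometric and plain RMS fold errors."""
    vals = _errors_array(records)
    logs = np.log10(vals)
    return ErrorSummary(
        median=float(np.median(vals)),
        mean=float(np.mean(vals)),
        rms_fold=float(10.0 ** np.sqrt(np.mean(logs**2))),
        rms_plain=float(np.sqrt(np.mean(vals**2))),
        n=int(vals.size),
    )


def group_errors(records: Sequence[ErrorRecord], by: str = "compound") -> dict:
    """Per-group summaries keyed by compound id or concentration level.

    Groups are returned ordered by key.  Records lacking the grouping key
    (e.g. ``level is None`` when grouping by level) are a validation error.
    """
    if by not in ("compound", "level"):
        raise EvaluationError(f"group_errors: unknown grouping {by!r}")
    keyed: dict = {}
    for r in records:
        key = r.compound_id if by == "compound" else r.level
        if key is None:
            raise EvaluationError(f"group_errors: record for {r.compound_id} has no level")
        keyed.setdefault(key, []).append(r)
    return {k: summarize_errors(keyed[k]) for k in sorted(keyed)}


def level_dispersion(records: Sequence[ErrorRecord]) -> dict:
    """Interquartile range of error ratios per concentration level.

    The low end of a calibration ladder is where intercepts and additive
    noise bite hardest, so dispersion shrinking with level is the
    signature of a well-behaved inversion.
    """
    keyed: dict = {}
    for r in records:
        if r.level is None:
            raise EvaluationError(f"level_dispersion: record for {r.compound_id} has no level")
        keyed.setdefault(float(r.level), []).append(r.error)
    return {
        lvl: float(np.subtract(*np.percentile(keyed[lvl], [75, 25])))
        for lvl in sorted(keyed)
    }


def table2_report(
    certified: Mapping[str, float],
    idms: Mapping[str, float],
    qsar_pred: Mapping[str, float],
) -> tuple[list, ErrorSummary]:
    """Directional errors of QSAR predictions against the IDMS reference.

    The three maps must share exactly the same compound keys.  Records hold
    the unrounded ratio; display tables round half-up to 2 decimals.
    """
    keys = set(certified)
    if set(idms) != keys or set(qsar_pred) != keys:
        raise EvaluationError(
            "table2_report: certified/idms/qsar maps must share compound keys"
        )
    records = [
        ErrorRecord(
            compound_id=cid,
            level=None,
            predicted=float(qsar_pred[cid]),
            actual=float(idms[cid]),
            error=concentration_error(float(qsar_pred[cid]), float(idms[cid])),
        )
        for cid in certified  # preserve the caller's ordering
    ]
    return records, summarize_errors(records)


def load_fish_powder_example() -> pd.DataFrame:
    """Nine PFASs in a fish-powder certified reference material.

    Columns: certified value and its uncertainty, the isotope-dilution MS
    result, and the concentration predicted from QSAR ionization
    efficiencies (all ng/g).  Index: compound acronym.
    """
    with resources.files("pfas_semiquant.data").joinpath(
        "fish_powder_reference.csv"
    ).open() as fh:
        df = pd.read_csv(fh, index_col="compound")
    return df


def render_error_table(records: Sequence[ErrorRecord], summary: ErrorSummary) -> str:
    """Plain-text report: per-record errors (2 decimals) plus a summary block."""
    lines = ["compound\tlevel\tpredicted\tactual\terror"]
    for r in records:
        lvl = "" if r.level is None else f"{r.level:g}"
        lines.append(
            f"{r.compound_id}\t{lvl}\t{r.predicted:g}\t{r.actual:g}\t"
            f"{round_half_up(r.error, 2):.2f}"
        )
    lines += [
        "",
        f"n\t{summary.n}",
        f"median\t{summary.median:.4f}",
        f"mean\t{summary.mean:.4f}",
        f"rms_fold(geometric)\t{summary.rms_fold:.4f}",
        f"rms(plain)\t{summary.rms_plain:.4f}",
    ]
    return "\n".join(lines)
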