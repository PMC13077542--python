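"""End-to-end semi-quantification workflow on a synthetic study.

calibrate -> anchor-relative logIE -> clean descriptors -> RFE -> train ->
predict logIE for held-out compounds -> invert to concentrations ->
fold-error evaluation.  Feature cleaning and RFE see only the training
compounds, so the held-out compounds play the role of standards-free
analytes end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationFit,
    CalibrationSeries,
    Compound,
    RelativeIE,
    fit_calibration,
    predict_concentration,
    relative_log_ie,
)
from .descriptors import SelectionReport, clean_cascade, rfe_select
from .evaluation import (
    ErrorRecord,
    ErrorSummary,
    concentration_error,
    group_errors,
    ie_fold_error,
    summarize_errors,
)
from .model import FitMetrics, IEModel, SplitPlan, evaluate, make_split, train
from .synthetic import GeneratorConfig, SyntheticDataset, generate_dataset

__all__ = ["StudyResult", "calibrate_dataset", "run_semiquant_study", "derive_seed"]


def derive_seed(seed: int, stream: int) -> int:
    """A reproducible 31-bit child seed for a named pipeline stage."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(100 + stream,))
    return int(ss.generate_state(1)[0] % (2**31))


def calibrate_dataset(
    series: Sequence[CalibrationSeries],
    registry: Mapping[str, Compound],
    anchor_id: str,
) -> tuple[dict, dict]:
    """Fit every calibration series and anchor the logIE scale.

    Returns ``(fits, exp_ie)`` keyed by compound id.
    """
    fits = {s.compound_id: fit_calibration(s) for s in series}
    if anchor_id not in fits:
        raise KeyError(f"anchor compound {anchor_id!r} has no calibration series")
    if anchor_id not in registry:
        raise KeyError(f"anchor compound {anchor_id!r} is not in the registry")
    anchor_fit, anchor = fits[anchor_id], registry[anchor_id]
    exp_ie = {
        cid: relative_log_ie(fit, registry[cid], anchor_fit, anchor)
        for cid, fit in fits.items()
    }
    return fits, exp_ie


@dataclass
class StudyResult:
    """Everything a full synthetic study run produces."""

    dataset: SyntheticDataset
    fits: dict
    exp_ie: dict
    selection: SelectionReport
    split: SplitPlan
    models: dict = field(default_factory=dict)  # algorithm -> IEModel
    train_metrics: dict = field(default_factory=dict)  # algorithm -> FitMetrics
    test_metrics: dict = field(default_factory=dict)
    ie_records: dict = field(default_factory=dict)  # algorithm -> [ErrorRecord]
    ie_summary: dict = field(default_factory=dict)  # algorithm -> ErrorSummary
    conc_records: dict = field(default_factory=dict)
    level_summaries: dict = field(default_factory=dict)  # algorithm -> {level: ErrorSummary}


def run_semiquant_study(
    cfg: GeneratorConfig,
    algorithms: Sequence[str] = ("gbt",),
    train_n: int = 42,
    subset_sizes: Sequence[int] = (5, 10, 18, 30, 60),
    rfe_folds: int = 5,
    rfe_repeats: int = 5,
    rfe_trees: int = 300,
    dataset: Optional[SyntheticDataset] = None,
) -> StudyResult:
    """Run the full pipeline on one synthetic study.

    ``train_n`` defaults to the study's 42/8 partition of 50 compounds.
    All stage seeds derive from ``cfg.seed``.
    """
    ds = dataset if dataset is not None else generate_dataset(cfg)
    fits, exp_ie = calibrate_dataset(ds.calibration, ds.registry, cfg.anchor_id)
    y = pd.Series({cid: ie.log_ie for cid, ie in exp_ie.items()}, name="exp_log_ie")
    y = y.loc[ds.descriptors.index]  # align with descriptor rows

    split = make_split(list(ds.descriptors.index), train_n, derive_seed(cfg.seed, 1))
    train_ids, test_ids = list(split.train_ids), list(split.test_ids)

    # Unsupervised cleaning and supervised RFE on training compounds only.
    cleaned, dropped = clean_cascade(ds.descriptors.loc[train_ids])
    selection = rfe_select(
        cleaned,
        y.loc[train_ids],
        subset_sizes=[s for s in subset_sizes if s <= cleaned.shape[1]],
        folds=rfe_folds,
        repeats=rfe_repeats,
        seed=derive_seed(cfg.seed, 2),
        n_estimators=rfe_trees,
    )
    selection.dropped_missing = dropped["dropped_missing"]
    selection.dropped_nzv = dropped["dropped_nzv"]
    selection.dropped_correlated = dropped["dropped_correlated"]

    X = ds.descriptors[selection.selected]
    result = StudyResult(
        dataset=ds, fits=fits, exp_ie=exp_ie, selection=selection, split=split
    )
    anchor_fit, anchor = fits[cfg.anchor_id], ds.registry[cfg.anchor_id]
    series_by_id = {s.compound_id: s for s in ds.calibration}

    for alg in algorithms:
        model = train(
            X.loc[train_ids],
            y.loc[train_ids],
            algorithm=alg,
            seed=derive_seed(cfg.seed, 3),
        )
        result.models[alg] = model
        result.train_metrics[alg] = evaluate(model, X.loc[train_ids], y.loc[train_ids])
        result.test_metrics[alg] = evaluate(model, X.loc[test_ids], y.loc[test_ids])

        pred_log = pd.Series(model.predict(X.loc[test_ids]), index=test_ids)
        ie_records = [
            ErrorRecord(
                compound_id=cid,
                level=None,
                predicted=10.0 ** float(pred_log.loc[cid]),
                actual=10.0 ** float(y.loc[cid]),
                error=ie_fold_error(
                    10.0 ** float(pred_log.loc[cid]), 10.0 ** float(y.loc[cid])
                ),
            )
            for cid in test_ids
        ]
        result.ie_records[alg] = ie_records
        result.ie_summary[alg] = summarize_errors(ie_records)

        conc_records = []
        for cid in test_ids:
            pred_ie = RelativeIE(cid, float(pred_log.loc[cid]), source="predicted")
            s = series_by_id[cid]
            for level, area in zip(s.levels, s.areas):
                c_pred = predict_concentration(
                    area, pred_ie, ds.registry[cid], anchor_fit, anchor
                )
                conc_records.append(
                    ErrorRecord(
                        compound_id=cid,
                        level=float(level),
                        predicted=c_pred,
                        actual=float(level),
                        error=concentration_error(c_pred, float(level)),
                    )
                )
        result.conc_records[alg] = conc_records
        result.level_summaries[alg] = group_errors(conc_records, by="level")

    return result
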