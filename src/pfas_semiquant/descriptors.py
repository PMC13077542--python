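"""Descriptor-table ingestion, feature cleaning, and recursive feature elimination.

With ~50 compounds and >1000 two-dimensional molecular descriptors the
feature space is far wider than the sample, so a cleaning cascade runs
before any model sees the data:

1. ``drop_missing``            — remove columns with any missing/non-finite cell;
2. ``drop_near_zero_variance`` — remove (near-)constant columns, using the
   frequency-ratio + percent-unique rule familiar from R's caret
   ``nearZeroVar`` (defaults 95/5 => ratio 19, unique < 10 %);
3. ``drop_correlated``         — greedily break up pairs with |Pearson r|
   above a threshold (default 0.8), caret ``findCorrelation`` style;
4. ``rfe_select``              — backward elimination ranked by
   random-forest importance, choosing the subset size by repeated
   cross-validated RMSE.

A descriptor matrix is a plain :class:`pandas.DataFrame` whose index holds
compound identifiers and whose columns are numeric descriptors, matching
the PaDEL export layout (first column ``Name``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold

__all__ = [
    "DescriptorError",
    "SelectionReport",
    "read_descriptor_table",
    "drop_missing",
    "drop_near_zero_variance",
    "drop_correlated",
    "clean_cascade",
    "rfe_select",
]


class DescriptorError(ValueError):
    """Invalid descriptor matrix or selection configuration."""


def read_descriptor_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a PaDEL-style descriptor table (first column = compound name).

    Empty cells and non-numeric markers are preserved as NaN, never as
    zero.  Duplicate compound names or a table without descriptor columns
    raise :class:`DescriptorError`.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DescriptorError(f"{path}: no descriptor columns beyond the name column")
    name_col = df.columns[0]
    names = df[name_col].astype(str)
    if names.duplicated().any():
        dups = sorted(names[names.duplicated()].unique())
        raise DescriptorError(f"{path}: duplicate compound names {dups}")
    values = df.drop(columns=[name_col]).apply(pd.to_numeric, errors="coerce")
    if values.columns.duplicated().any():
        raise DescriptorError(f"{path}: duplicate descriptor column names")
    values.index = pd.Index(names, name="compound_id")
    return values


def _check_no_missing(m: pd.DataFrame, op: str) -> np.ndarray:
    x = m.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise DescriptorError(f"{op}: matrix still contains missing/non-finite values")
    return x


def drop_missing(m: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Remove every column containing a missing or non-finite value."""
    x = m.to_numpy(dtype=float)
    bad = ~np.isfinite(x).all(axis=0)
    dropped = [c for c, b in zip(m.columns, bad) if b]
    kept = m.loc[:, ~bad]
    if kept.shape[1] == 0:
        raise DescriptorError("drop_missing removed every column")
    return kept, dropped


def drop_near_zero_variance(
    m: pd.DataFrame, freq_ratio: float = 19.0, unique_pct: float = 10.0
) -> tuple[pd.DataFrame, list]:
    """Remove near-constant columns.

    A column goes iff (count of most frequent value / count of second most
    frequent) exceeds ``freq_ratio`` AND the percentage of distinct values
    is below ``unique_pct``.  Constant columns always go (the frequency
    ratio is taken as infinite).
    """
    _check_no_missing(m, "drop_near_zero_variance")
    n = m.shape[0]
    dropped = []
    for c in m.columns:
        counts = m[c].value_counts().to_numpy()
        if len(counts) == 1:
            dropped.append(c)
            continue
        ratio = counts[0] / counts[1]
        pct_unique = 100.0 * len(counts) / n
        if ratio > freq_ratio and pct_unique < unique_pct:
            dropped.append(c)
    kept = m.drop(columns=dropped)
    return kept, dropped


def drop_correlated(m: pd.DataFrame, threshold: float = 0.8) -> tuple[pd.DataFrame, list]:
    """Greedily remove columns until no pair has |Pearson r| > ``threshold``.

    At each step the most correlated remaining pair is found and the
    member with the larger mean absolute correlation to all remaining
    columns is dropped (ties: the earlier column in the original order).
    Deterministic; the survivors provably contain no offending pair.
    """
    _check_no_missing(m, "drop_correlated")
    if m.shape[0] < 2:
        raise DescriptorError("drop_correlated: need at least two rows")
    cols = list(m.columns)
    corr = np.abs(np.corrcoef(m.to_numpy(dtype=float), rowvar=False))
    # constant columns yield NaN correlations; treat as uncorrelated
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(len(cols), dtype=bool)
    dropped = []
    while True:
        sub = np.where(alive)[0]
        block = corr[np.ix_(sub, sub)]
        if block.size == 0 or block.max() <= threshold:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(block), block.shape)
        i, j = sub[i_loc], sub[j_loc]
        mean_i = corr[i, sub].mean()
        mean_j = corr[j, sub].mean()
        if mean_i > mean_j:
            victim = i
        elif mean_j > mean_i:
            victim = j
        else:
            victim = min(i, j)
        alive[victim] = False
        dropped.append(cols[victim])
    kept = m.loc[:, [c for c, a in zip(cols, alive) if a]]
    return kept, dropped


def clean_cascade(
    m: pd.DataFrame,
    freq_ratio: float = 19.0,
    unique_pct: float = 10.0,
    corr_threshold: float = 0.8,
) -> tuple[pd.DataFrame, dict]:
    """Run missing -> near-zero-variance -> correlation filters in order."""
    m1, miss = drop_missing(m)
    m2, nzv = drop_near_zero_variance(m1, freq_ratio=freq_ratio, unique_pct=unique_pct)
    m3, corr = drop_correlated(m2, threshold=corr_threshold)
    return m3, {
        "dropped_missing": miss,
        "dropped_nzv": nzv,
        "dropped_correlated": corr,
    }


@dataclass
class SelectionReport:
    """Record of the full feature-selection cascade.

    ``cv_profile`` maps candidate subset size -> (mean CV RMSE, standard
    error over resamples).
    """

    dropped_missing: list = field(default_factory=list)
    dropped_nzv: list = field(default_factory=list)
    dropped_correlated: list = field(default_factory=list)
    rfe_candidates: list = field(default_factory=list)
    selected: list = field(default_factory=list)
    cv_profile: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"size": s, "cv_rmse": m, "cv_rmse_se": se}
            for s, (m, se) in sorted(self.cv_profile.items())
        ]
        return pd.DataFrame(rows)


def _rf(seed: int, n_estimators: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )


def rfe_select(
    m: pd.DataFrame,
    y: Sequence[float],
    subset_sizes: Sequence[int],
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    n_estimators: int = 300,
    pick: str = "best",
) -> SelectionReport:
    """Recursive feature elimination with external cross-validation.

    For each of ``folds``x``repeats`` resamples a random forest ranks all
    candidate descriptors on the analysis fold; for every candidate size
    ``s`` a fresh forest fit on the top-``s`` descriptors is scored (RMSE)
    on the held-out fold.  The selected size minimizes mean CV RMSE
    (``pick="best"``, ties to the smaller size) or is the smallest size
    within one standard error of the optimum (``pick="1se"``).  The final
    descriptor set is the top-``s`` ranking of a forest fit on all rows.

    Fully deterministic given ``seed``.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != m.shape[0]:
        raise DescriptorError(
            f"rfe_select: y has {len(y)} entries for {m.shape[0]} rows"
        )
    if folds > m.shape[0]:
        raise DescriptorError("rfe_select: more CV folds than rows")
    if pick not in ("best", "1se"):
        raise DescriptorError(f"rfe_select: unknown pick rule {pick!r}")
    p = m.shape[1]
    sizes = sorted({int(s) for s in subset_sizes})
    if not sizes:
        raise DescriptorError("rfe_select: empty subset_sizes")
    if sizes[-1] > p:
        raise DescriptorError(
            f"rfe_select: subset size {sizes[-1]} exceeds {p} candidate columns"
        )
    if sizes[-1] < p:
        sizes.append(p)  # always profile the full model, caret-style

    X = _check_no_missing(m, "rfe_select")
    cols = np.asarray(m.columns)
    rkf = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    scores = {s: [] for s in sizes}
    for split_i, (tr, te) in enumerate(rkf.split(X)):
        ranker = _rf(seed + 1000 + split_i, n_estimators).fit(X[tr], y[tr])
        order = np.argsort(-ranker.feature_importances_, kind="stable")
        for s in sizes:
            top = order[:s]
            est = _rf(seed + 2000 + split_i, n_estimators).fit(X[tr][:, top], y[tr])
            resid = est.predict(X[te][:, top]) - y[te]
            scores[s].append(float(np.sqrt(np.mean(resid**2))))

    profile = {}
    for s in sizes:
        arr = np.asarray(scores[s])
        profile[s] = (float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr))))

    best_size = min(sizes, key=lambda s: (profile[s][0], s))
    if pick == "1se":
        cutoff = profile[best_size][0] + profile[best_size][1]
        best_size = min(s for s in sizes if profile[s][0] <= cutoff)

    final = _rf(seed + 3000, n_estimators).fit(X, y)
    order = np.argsort(-final.feature_importances_, kind="stable")
    selected = [str(c) for c in cols[order[:best_size]]]
    return SelectionReport(
        rfe_candidates=[str(c) for c in cols],
        selected=selected,
        cv_profile=profile,
    )
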