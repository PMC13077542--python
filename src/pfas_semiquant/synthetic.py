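"""Synthetic study generator: descriptors, latent logIE, calibration series.

Emulates the statistical structure the semi-quantification pipeline
assumes, so every stage is testable without a descriptor calculator or
instrument data:

- a compounds x descriptors matrix in which the informative descriptors
  form one equicorrelated family (molecular-size/fluorination proxies are
  strongly collinear in real descriptor panels, and that redundancy is
  what makes QSAR on ~50 compounds workable), part of the nuisance
  columns sit in correlated blocks, and planted near-constant columns and
  missing cells exercise the cleaning cascade;
- a latent relative logIE that is a smooth nonlinear function (linear +
  saturating + pairwise-interaction terms) of an informative-descriptor
  composite, scaled to roughly [-1.5, 1.5] and anchored so the anchor
  compound sits at exactly 0;
- per-compound calibration series over the study's concentration ladder
  (0.2, 0.5, 1, 2, 5, 10 ng/mL) with multiplicative area noise and
  optional positive intercepts, the mechanism behind poor low-level
  back-calculation.

Composite weights decay geometrically so a handful of descriptors lead
the importance ranking, mirroring the top-heavy importance profiles QSAR
models of ionization efficiency typically show.  All randomness flows
from a single seed through numbered `numpy` SeedSequence spawn keys (one
stream per stage), so stages are independently reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .calibration import CalibrationSeries, Compound

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_descriptors",
    "generate_log_ie",
    "generate_calibration",
    "generate_dataset",
    "write_dataset",
]

# stream ids for SeedSequence spawn keys
_STREAM_DESCRIPTORS = 0
_STREAM_IE = 1
_STREAM_MW = 2
_STREAM_CALIBRATION = 3


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic pipeline.

    Defaults mirror the study scale: 50 compounds, a wide 2D-descriptor
    panel (200 columns, trimmed from the thousands a descriptor
    calculator emits, for speed; roughly 120 survive the cleaning
    cascade), 18 informative descriptors, and the six-level calibration
    ladder in ng/mL.
    """

    n_compounds: int = 50
    n_descriptors: int = 200
    n_informative: int = 18
    informative_correlation: float = 0.65
    block_correlation: float = 0.85
    block_size: int = 5
    correlated_fraction: float = 0.45  # share of nuisance columns in blocks
    nzv_fraction: float = 0.05
    missing_fraction: float = 0.05
    ie_noise_sd: float = 0.02  # log10 units
    weight_decay: float = 0.9  # geometric decay of composite weights
    composite_coef: float = 0.25  # linear share riding on the composite
    sat_coef: float = 1.0  # saturating term on the leading descriptor
    sat_steepness: float = 1.6
    interaction_coef: float = 0.15
    linear_ie: bool = False
    calib_levels: tuple = (0.2, 0.5, 1.0, 2.0, 5.0, 10.0)
    area_noise_cv: float = 0.03
    intercept_scale: float = 0.05
    anchor_slope: float = 5.0e4  # area counts per ng/mL
    anchor_id: str = "FHUEA"
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.n_informative <= self.n_descriptors:
            raise ValueError("n_informative must be in (0, n_descriptors]")
        for name in ("informative_correlation", "block_correlation"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("nzv_fraction", "missing_fraction", "correlated_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        n_special = (
            self.n_informative
            + round(self.nzv_fraction * self.n_descriptors)
            + round(self.missing_fraction * self.n_descriptors)
        )
        if n_special > self.n_descriptors:
            raise ValueError(
                "informative + near-zero-variance + missing columns exceed n_descriptors"
            )
        if min(self.ie_noise_sd, self.area_noise_cv, self.intercept_scale) < 0:
            raise ValueError("noise scales must be >= 0")
        if any(l <= 0 for l in self.calib_levels):
            raise ValueError("calibration levels must be > 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Stage-local generator: one numbered child stream per pipeline stage."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


@dataclass
class SyntheticTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    compound_ids: list
    anchor_id: str
    informative_features: list  # ordered by decreasing composite weight
    weights: dict  # feature -> effective linear loading on the scaled logIE
    nonlinear_spec: dict  # term coefficients of the latent function
    nzv_features: list
    missing_features: list
    block_members: list  # lists of correlated nuisance columns
    informative_values: pd.DataFrame
    latent_factor: Optional[pd.Series] = None
    scale: float = 1.0
    center: float = 0.0
    anchor_offset: float = 0.0
    true_log_ie: Optional[pd.Series] = None
    true_mws: Optional[pd.Series] = None
    true_slopes: Optional[pd.Series] = None


def generate_descriptors(cfg: GeneratorConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw the descriptor matrix and record the planted structure."""
    rng = cfg.rng(_STREAM_DESCRIPTORS)
    n, p = cfg.n_compounds, cfg.n_descriptors
    ids = [cfg.anchor_id] + [f"SC{i:03d}" for i in range(2, n + 1)]

    n_nzv = round(cfg.nzv_fraction * p)
    n_missing = round(cfg.missing_fraction * p)
    n_nuisance = p - cfg.n_informative - n_nzv - n_missing
    n_block = round(cfg.correlated_fraction * n_nuisance)

    columns: dict = {}
    names = [f"D{j:04d}" for j in range(1, p + 1)]
    order = rng.permutation(p)  # scatter roles across column positions
    slots = iter(order)

    # Informative family: common latent factor, equal loadings.
    informative = [names[next(slots)] for _ in range(cfg.n_informative)]
    g = rng.standard_normal(n)
    r = cfg.informative_correlation
    for name in informative:
        columns[name] = math.sqrt(r) * g + math.sqrt(1 - r) * rng.standard_normal(n)

    nzv_features = []
    for _ in range(n_nzv):
        name = names[next(slots)]
        base = float(rng.normal())
        col = np.full(n, base)
        k_spike = max(1, int(round(0.04 * n)))
        spots = rng.choice(n, size=k_spike, replace=False)
        col[spots] = base + float(rng.normal(loc=3.0))
        columns[name] = col
        nzv_features.append(name)

    missing_features = []
    for _ in range(n_missing):
        name = names[next(slots)]
        col = rng.standard_normal(n)
        holes = rng.choice(n, size=int(rng.integers(1, 4)), replace=False)
        col[holes] = np.nan
        columns[name] = col
        missing_features.append(name)

    rho = cfg.block_correlation
    block_members: list = []
    remaining = n_block
    while remaining > 1:
        size = min(cfg.block_size, remaining)
        members = [names[next(slots)] for _ in range(size)]
        shared = rng.standard_normal(n)
        for name in members:
            columns[name] = math.sqrt(rho) * shared + math.sqrt(1 - rho) * rng.standard_normal(n)
        block_members.append(members)
        remaining -= size
    for _ in range(n_nuisance - n_block + (remaining if remaining > 0 else 0)):
        name = names[next(slots)]
        columns[name] = rng.standard_normal(n)

    df = pd.DataFrame(
        {name: columns[name] for name in names},
        index=pd.Index(ids, name="compound_id"),
    )
    truth = SyntheticTruth(
        compound_ids=ids,
        anchor_id=cfg.anchor_id,
        informative_features=informative,
        weights={},
        nonlinear_spec={},
        nzv_features=nzv_features,
        missing_features=missing_features,
        block_members=block_members,
        informative_values=df[informative].copy(),
        latent_factor=pd.Series(g, index=ids, name="latent_factor"),
    )
    return df, truth


def generate_log_ie(
    truth: SyntheticTruth,
    cfg: GeneratorConfig,
    descriptors: Optional[pd.DataFrame] = None,
) -> pd.Series:
    """Latent relative logIE from the informative descriptors.

    The latent function has three parts: a small linear share riding on a
    geometrically weighted composite ``u`` of all informative columns
    (``composite_coef``), a saturating response of the leading descriptor
    (``sat_coef * tanh(sat_steepness * z1)``) capturing the signal-plateau
    behaviour electrospray response shows against the dominant molecular
    property, and a pairwise interaction of the next two descriptors
    (``interaction_coef * z2*z3``).  The sum is centred, scaled so the
    extremes sit at +-1.5, noised (``ie_noise_sd``, log10 units) and
    shifted so the anchor compound is exactly 0.  Only informative
    columns are read, so permuting every other column leaves the result
    unchanged; with ``ie_noise_sd == 0`` the output is an exact
    deterministic function of the truth spec.  ``linear_ie`` keeps the
    composite only (a sanity mode for linear-model tests).
    """
    Z = (descriptors if descriptors is not None else truth.informative_values)[
        truth.informative_features
    ].to_numpy(dtype=float)
    k = len(truth.informative_features)
    rng = cfg.rng(_STREAM_IE)
    w = cfg.weight_decay ** np.arange(k)

    u_raw = Z @ w
    u = (u_raw - u_raw.mean()) / u_raw.std()
    spec: dict = {
        "composite_weights": w.tolist(),
        "u_mean": float(u_raw.mean()),
        "u_sd": float(u_raw.std()),
        "composite_coef": cfg.composite_coef,
    }
    if cfg.linear_ie or k < 3:
        f = u.copy()
    else:
        f = cfg.composite_coef * u
        f = f + cfg.sat_coef * np.tanh(cfg.sat_steepness * Z[:, 0])
        f = f + cfg.interaction_coef * Z[:, 1] * Z[:, 2]
        spec.update(
            sat_coef=cfg.sat_coef,
            sat_steepness=cfg.sat_steepness,
            saturating=truth.informative_features[0],
            interaction=(truth.informative_features[1], truth.informative_features[2]),
            interaction_coef=cfg.interaction_coef,
        )

    center = float(f.mean())
    span = float(np.max(np.abs(f - center)))
    scale = 1.5 / span if span > 0 else 1.0
    values = scale * (f - center)
    if cfg.ie_noise_sd > 0:
        values = values + rng.normal(scale=cfg.ie_noise_sd, size=len(values))

    ids = truth.informative_values.index if descriptors is None else descriptors.index
    series = pd.Series(values, index=ids, name="log_ie")
    anchor_offset = float(series.loc[truth.anchor_id]) if truth.anchor_id in series.index else 0.0
    series = series - anchor_offset

    truth.weights = {
        name: float(scale * wj / spec["u_sd"])
        for name, wj in zip(truth.informative_features, w)
    }
    truth.nonlinear_spec = spec
    truth.scale = scale
    truth.center = center
    truth.anchor_offset = anchor_offset
    truth.true_log_ie = series
    return series


def generate_calibration(truth: SyntheticTruth, cfg: GeneratorConfig) -> list:
    """Noisy calibration series consistent with the latent relative logIE.

    Molecular weights are drawn uniformly over the PFAS range (200-750
    g/mol); slopes follow from the anchored logIE by inverting the
    anchor-relative definition, so a noiseless run of the calibration +
    anchoring stages reproduces ``true_log_ie`` to machine precision.
    Areas are ``intercept + slope*level*(1 + eps)`` with
    ``eps ~ N(0, area_noise_cv)`` and ``intercept ~ |N(0, intercept_scale*slope)|``.
    """
    if truth.true_log_ie is None:
        raise ValueError("generate_calibration: call generate_log_ie first")
    mw_rng = cfg.rng(_STREAM_MW)
    rng = cfg.rng(_STREAM_CALIBRATION)
    ids = truth.compound_ids
    mws = pd.Series(mw_rng.uniform(200.0, 750.0, size=len(ids)), index=ids, name="mw")
    anchor_mw = float(mws.loc[truth.anchor_id])
    slopes = pd.Series(
        {
            cid: cfg.anchor_slope
            * 10.0 ** float(truth.true_log_ie.loc[cid])
            * float(mws.loc[cid])
            / anchor_mw
            for cid in ids
        },
        name="slope",
    )
    levels = np.asarray(cfg.calib_levels, dtype=float)
    series = []
    for cid in ids:
        s = float(slopes.loc[cid])
        intercept = (
            abs(rng.normal(scale=cfg.intercept_scale * s)) if cfg.intercept_scale > 0 else 0.0
        )
        eps = (
            rng.normal(scale=cfg.area_noise_cv, size=len(levels))
            if cfg.area_noise_cv > 0
            else np.zeros(len(levels))
        )
        areas = intercept + s * levels * (1.0 + eps)
        series.append(CalibrationSeries(cid, levels, areas))
    truth.true_mws = mws
    truth.true_slopes = slopes
    return series


@dataclass
class SyntheticDataset:
    """A complete drop-in study: descriptor table, registry, calibration, truth."""

    config: GeneratorConfig
    descriptors: pd.DataFrame
    calibration: list
    registry: dict
    truth: SyntheticTruth


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Run all three generator stages under one seed."""
    descriptors, truth = generate_descriptors(cfg)
    generate_log_ie(truth, cfg)
    calibration = generate_calibration(truth, cfg)
    registry = {
        cid: Compound(cid, cid, float(truth.true_mws.loc[cid]))
        for cid in truth.compound_ids
    }
    return SyntheticDataset(
        config=cfg,
        descriptors=descriptors,
        calibration=calibration,
        registry=registry,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: Union[str, Path]) -> dict:
    """Write the delimited files the pipeline readers consume.

    descriptors.csv uses the PaDEL export dialect (first column ``Name``);
    calibration.csv is long format; registry.csv holds id/name/mw; a JSON
    truth sidecar records the planted structure for audits.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / f"{k}.csv" for k in ("descriptors", "calibration", "registry")}

    desc = ds.descriptors.copy()
    desc.insert(0, "Name", desc.index)
    desc.to_csv(paths["descriptors"], index=False)

    rows = [
        {"compound_id": s.compound_id, "level_ng_per_mL": lv, "area": ar}
        for s in ds.calibration
        for lv, ar in zip(s.levels, s.areas)
    ]
    pd.DataFrame(rows).to_csv(paths["calibration"], index=False)

    pd.DataFrame(
        [{"compound_id": c.id, "name": c.name, "mw": c.mw} for c in ds.registry.values()]
    ).to_csv(paths["registry"], index=False)

    truth_path = out / "truth.json"
    sidecar = {
        "seed": ds.config.seed,
        "anchor_id": ds.truth.anchor_id,
        "informative_features": ds.truth.informative_features,
        "weights": ds.truth.weights,
        "nzv_features": ds.truth.nzv_features,
        "missing_features": ds.truth.missing_features,
        "true_log_ie": {k: float(v) for k, v in ds.truth.true_log_ie.items()},
        "true_slopes": {k: float(v) for k, v in ds.truth.true_slopes.items()},
        "true_mws": {k: float(v) for k, v in ds.truth.true_mws.items()},
    }
    truth_path.write_text(json.dumps(sidecar, indent=2))
    paths["truth"] = truth_path
    return {k: str(v) for k, v in paths.items()}
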