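"""Synthetic breath-record generator and preprocessing.

Real per-recording ventilator tables of the kind this emulates hold
roughly 6000-8000 rows, each describing one breath with 28 recorded
aspects: ventilator settings and measurements (tidal volume, I:E ratio,
pressures, PEEP, flows) alongside demographic and laboratory values (age,
gender, urine output, blood-gas and chemistry panels).  Each row carries
a binary ventilation-mode label: volume-controlled operation is class 0,
pressure-controlled (CPAP/PAV-style) operation is class 1.

No feature distributions are published for such data, so the generator
documents its own: every numeric feature is Gaussian with a
physiologically plausible mean and spread, and the mode-linked features
(the pressure and flow channels) receive a mode-conditional mean shift
scaled by one ``effect_size`` knob.  The label rule is therefore the
generative map itself — a row's class is the mode whose conditional
distributions produced it — which makes the classes learnable but
overlapping at the default effect size.

Preprocessing mirrors standard practice: z-score standardization
(sample standard deviation, divisor n-1) with fitted parameters reusable
on held-out data, one-hot encoding with a fitted category registry, and
a stratified 70/30 train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ventilab.errors import (
    DegenerateColumnError,
    EncodingError,
    ParameterError,
    SchemaError,
    StratificationError,
)

LABEL_COLUMN = "mode_class"
#: Binary label semantics: volume-controlled = 0, pressure-controlled = 1.
VOLUME_CLASS = 0
PRESSURE_CLASS = 1


@dataclass(frozen=True)
class NumericFeature:
    """Gaussian feature: mean, sd, and the pressure-mode mean shift."""

    mean: float
    sd: float
    shift: float = 0.0
    minimum: Optional[float] = None


@dataclass(frozen=True)
class CategoricalFeature:
    """Categorical feature with fixed levels and sampling probabilities."""

    levels: Tuple[str, ...]
    probs: Tuple[float, ...]


def default_feature_spec() -> Dict[str, object]:
    """The 28-feature default specification.

    Mode-linked shifts are expressed in the feature's own units and are
    multiplied by the config's ``effect_size``; at effect_size 1 each
    shifted feature moves by roughly half to three-quarters of a standard
    deviation, giving overlapping but clearly learnable classes.
    """
    return {
        # ventilator settings / measurements (mode-linked channels shifted)
        "tidal_volume": NumericFeature(480.0, 60.0, shift=-30.0, minimum=100.0),
        "ie_ratio": NumericFeature(0.50, 0.08, shift=0.05, minimum=0.1),
        "peak_pressure": NumericFeature(22.0, 4.0, shift=3.0, minimum=5.0),
        "reduced_pressure": NumericFeature(8.0, 2.0, shift=1.5, minimum=0.0),
        "peep": NumericFeature(7.0, 1.5, shift=0.8, minimum=0.0),
        "mean_airway_pressure": NumericFeature(12.0, 2.5, shift=2.0, minimum=0.0),
        "plateau_pressure": NumericFeature(18.0, 3.0, shift=2.0, minimum=0.0),
        "inspiratory_flow": NumericFeature(500.0, 100.0, shift=-50.0, minimum=50.0),
        "respiratory_rate": NumericFeature(16.0, 3.0, minimum=4.0),
        "minute_volume": NumericFeature(7.5, 1.5, minimum=1.0),
        "fio2": NumericFeature(0.45, 0.10, minimum=0.21),
        "spo2": NumericFeature(95.0, 2.5, minimum=60.0),
        "etco2": NumericFeature(38.0, 5.0, minimum=10.0),
        "dynamic_compliance": NumericFeature(45.0, 10.0, minimum=5.0),
        "airway_resistance": NumericFeature(10.0, 3.0, minimum=1.0),
        # demographics
        "age": NumericFeature(58.0, 16.0, minimum=18.0),
        "gender": CategoricalFeature(("F", "M"), (0.45, 0.55)),
        "weight": NumericFeature(70.0, 14.0, minimum=30.0),
        "height": NumericFeature(167.0, 10.0, minimum=120.0),
        "urine_output": NumericFeature(1400.0, 450.0, minimum=0.0),
        # laboratory values
        "ph": NumericFeature(7.38, 0.06),
        "pao2": NumericFeature(85.0, 15.0, minimum=30.0),
        "paco2": NumericFeature(42.0, 7.0, minimum=15.0),
        "hco3": NumericFeature(24.0, 3.5, minimum=5.0),
        "lactate": NumericFeature(1.8, 0.9, minimum=0.1),
        "creatinine": NumericFeature(1.1, 0.5, minimum=0.2),
        "hemoglobin": NumericFeature(11.5, 1.8, minimum=4.0),
        "wbc": NumericFeature(9.5, 3.5, minimum=1.0),
    }


N_FEATURES = 28


@dataclass
class DatasetConfig:
    """Configuration of one synthetic breath-record table.

    ``n_rows`` defaults into the realistic 6000-8000 band; ``effect_size``
    scales every mode-conditional shift in the feature spec.
    """

    n_rows: int = 7000
    class_balance: float = 0.5
    seed: int = 0
    effect_size: float = 1.0
    feature_spec: Dict[str, object] = field(default_factory=default_feature_spec)

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ParameterError(f"n_rows must be >= 1, got {self.n_rows!r}")
        if not (0.0 < self.class_balance < 1.0):
            raise ParameterError(
                f"class_balance must lie in (0, 1), got {self.class_balance!r}"
            )
        missing = set(default_feature_spec()) - set(self.feature_spec)
        if missing:
            raise SchemaError(
                "feature_spec is missing declared features: "
                + ", ".join(sorted(missing))
            )


@dataclass
class BreathTable:
    """A breath-record feature table plus its binary mode label."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if LABEL_COLUMN not in self.frame.columns:
            raise SchemaError(f"table lacks the {LABEL_COLUMN!r} label column")
        labels = set(self.frame[LABEL_COLUMN].unique())
        if not labels <= {VOLUME_CLASS, PRESSURE_CLASS}:
            raise SchemaError(f"labels must be 0/1, found {sorted(labels)}")
        if self.frame.isna().any().any():
            raise SchemaError("table contains missing values")

    @property
    def features(self) -> pd.DataFrame:
        return self.frame.drop(columns=[LABEL_COLUMN])

    @property
    def labels(self) -> pd.Series:
        return self.frame[LABEL_COLUMN]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def numeric_columns(self) -> list:
        return [
            c
            for c in self.features.columns
            if pd.api.types.is_numeric_dtype(self.frame[c])
        ]

    def categorical_columns(self) -> list:
        return [c for c in self.features.columns if c not in self.numeric_columns()]


def generate(cfg: DatasetConfig) -> BreathTable:
    """Draw a synthetic breath table; deterministic given ``cfg.seed``.

    The class column is stratified to hit ``class_balance`` exactly
    (rounded): round(n_rows * class_balance) rows are pressure-mode
    (class 1), the rest volume-mode (class 0).  Pressure-mode rows draw
    each mode-linked feature from its shifted conditional distribution.
    """
    rng = np.random.default_rng(cfg.seed)
    n1 = int(round(cfg.n_rows * cfg.class_balance))
    n1 = min(max(n1, 0), cfg.n_rows)
    labels = np.zeros(cfg.n_rows, dtype=int)
    labels[:n1] = PRESSURE_CLASS
    rng.shuffle(labels)

    columns = {}
    for name, spec in cfg.feature_spec.items():
        if isinstance(spec, CategoricalFeature):
            columns[name] = rng.choice(spec.levels, size=cfg.n_rows, p=spec.probs)
        elif isinstance(spec, NumericFeature):
            shift = cfg.effect_size * spec.shift * (labels == PRESSURE_CLASS)
            values = rng.normal(spec.mean + shift, spec.sd)
            if spec.minimum is not None:
                values = np.maximum(values, spec.minimum)
            columns[name] = values
        else:
            raise SchemaError(f"unsupported feature spec for {name!r}: {spec!r}")
    frame = pd.DataFrame(columns)
    frame[LABEL_COLUMN] = labels
    return BreathTable(frame)


@dataclass(frozen=True)
class ZScoreParams:
    """Fitted per-column means and sample standard deviations."""

    means: Dict[str, float]
    sds: Dict[str, float]

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for col, mu in self.means.items():
            out[col] = (out[col] - mu) / self.sds[col]
        return out

    def inverse(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for col, mu in self.means.items():
            out[col] = out[col] * self.sds[col] + mu
        return out


def zscore(
    table: BreathTable, columns: Optional[Sequence[str]] = None
) -> Tuple[BreathTable, ZScoreParams]:
    """Standardize numeric columns to mean 0, unit sample sd (divisor n-1).

    Returns the transformed table and the fitted parameters, which can be
    re-applied to held-out data via :meth:`ZScoreParams.transform` so test
    statistics are never peeked at.
    """
    if columns is None:
        columns = table.numeric_columns()
    means, sds = {}, {}
    for col in columns:
        if not pd.api.types.is_numeric_dtype(table.frame[col]):
            raise DegenerateColumnError(f"column {col!r} is not numeric")
        sd = float(table.frame[col].std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise DegenerateColumnError(
                f"column {col!r} has no spread (sd={sd!r}) and cannot be z-scored"
            )
        means[col] = float(table.frame[col].mean())
        sds[col] = sd
    params = ZScoreParams(means=means, sds=sds)
    return BreathTable(params.transform(table.frame)), params


@dataclass(frozen=True)
class CategoryRegistry:
    """Fitted category levels per encoded column."""

    levels: Dict[str, Tuple[str, ...]]

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for col, levels in self.levels.items():
            seen = set(map(str, out[col].unique()))
            unseen = seen - set(levels)
            if unseen:
                raise EncodingError(
                    f"column {col!r} holds categories {sorted(unseen)} not in "
                    f"the fitted registry {list(levels)}"
                )
            for level in levels:
                out[f"{col}={level}"] = (out[col].astype(str) == level).astype(int)
            out = out.drop(columns=[col])
        return out


def one_hot(
    table: BreathTable, column: str
) -> Tuple[BreathTable, CategoryRegistry]:
    """One-hot encode a categorical column: one binary column per level.

    Each encoded row has exactly one 1 across the new columns.  The
    returned registry re-applies the same levels to held-out data and
    raises on unseen categories.
    """
    if column not in table.frame.columns:
        raise SchemaError(f"no column named {column!r}")
    levels = tuple(sorted(map(str, table.frame[column].unique())))
    if len(levels) < 1:
        raise SchemaError(f"column {column!r} has no levels")
    registry = CategoryRegistry(levels={column: levels})
    return BreathTable(registry.transform(table.frame)), registry


def split(
    table: BreathTable, train_fraction: float = 0.7, seed: int = 0
) -> Tuple[BreathTable, BreathTable]:
    """Stratified train/test split; train size = round(n * fraction).

    Per-class train counts are allocated by largest remainder so the
    overall train size is exact and each class is represented in both
    halves wherever its size allows.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ParameterError(
            f"train_fraction must lie in (0, 1), got {train_fraction!r}"
        )
    labels = table.labels.to_numpy()
    n = len(labels)
    n_train = int(round(n * train_fraction))
    rng = np.random.default_rng(seed)
    class_indices = {}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise StratificationError(
                f"class {cls} has {len(idx)} row(s); need >= 2 to stratify"
            )
        rng.shuffle(idx)
        class_indices[cls] = idx
    # largest-remainder allocation of the train quota across classes
    quotas = {c: len(ix) * train_fraction for c, ix in class_indices.items()}
    base = {c: int(np.floor(q)) for c, q in quotas.items()}
    shortfall = n_train - sum(base.values())
    order = sorted(quotas, key=lambda c: quotas[c] - base[c], reverse=True)
    for c in order[:shortfall]:
        base[c] += 1
    train_idx, test_idx = [], []
    for c, ix in class_indices.items():
        k = min(max(base[c], 1), len(ix) - 1)
        train_idx.extend(ix[:k])
        test_idx.extend(ix[k:])
    train = table.frame.iloc[sorted(train_idx)].reset_index(drop=True)
    test = table.frame.iloc[sorted(test_idx)].reset_index(drop=True)
    return BreathTable(train), BreathTable(test)
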