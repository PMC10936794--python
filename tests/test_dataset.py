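"""Synthetic breath-table generation and preprocessing contracts."""

import numpy as np
import pandas as pd
import pytest

from ventilab.dataset import (
    LABEL_COLUMN,
    BreathTable,
    DatasetConfig,
    default_feature_spec,
    generate,
    one_hot,
    split,
    zscore,
)
from ventilab.errors import (
    DegenerateColumnError,
    EncodingError,
    ParameterError,
    SchemaError,
    StratificationError,
)


def small_table(values, labels):
    frame = pd.DataFrame({"x": values, LABEL_COLUMN: labels})
    return BreathTable(frame)


class TestGenerate:
    def test_seeded_determinism(self):
        cfg = DatasetConfig(n_rows=100, seed=7)
        assert generate(cfg).frame.equals(generate(cfg).frame)

    def test_exact_stratification(self):
        table = generate(DatasetConfig(n_rows=1000, class_balance=0.5, seed=1))
        assert (table.labels == 1).sum() == 500
        assert (table.labels == 0).sum() == 500

    def test_default_schema_is_28_features_plus_label(self):
        table = generate(DatasetConfig(n_rows=50, seed=0))
        assert table.features.shape[1] == 28
        assert LABEL_COLUMN in table.frame.columns
        assert not table.frame.isna().any().any()

    def test_missing_declared_feature_rejected(self):
        spec = default_feature_spec()
        spec.pop("tidal_volume")
        with pytest.raises(SchemaError, match="tidal_volume"):
            DatasetConfig(n_rows=10, feature_spec=spec)

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            DatasetConfig(n_rows=0)
        with pytest.raises(ParameterError):
            DatasetConfig(class_balance=1.0)

    def test_classes_are_learnable_by_nearest_centroid(self):
        """The default mode shifts carry real signal: > 70% test accuracy."""
        table = generate(DatasetConfig(seed=11))
        train, test = split(table, seed=3)
        train_z, params = zscore(train)
        test_frame = params.transform(test.frame)
        num = train.numeric_columns()
        c0 = train_z.frame.loc[train_z.labels == 0, num].mean()
        c1 = train_z.frame.loc[train_z.labels == 1, num].mean()
        d0 = ((test_frame[num] - c0) ** 2).sum(axis=1)
        d1 = ((test_frame[num] - c1) ** 2).sum(axis=1)
        accuracy = ((d1 < d0).astype(int) == test.labels.to_numpy()).mean()
        assert accuracy > 0.70


class TestZScore:
    def test_three_point_column(self):
        table = small_table([1.0, 2.0, 3.0], [0, 1, 0])
        out, params = zscore(table, ["x"])
        assert np.allclose(out.frame["x"], [-1.0, 0.0, 1.0])
        assert params.means["x"] == 2.0 and params.sds["x"] == 1.0

    def test_transformed_moments(self):
        rng = np.random.default_rng(0)
        table = small_table(rng.normal(50, 7, 500), rng.integers(0, 2, 500))
        out, _ = zscore(table, ["x"])
        assert abs(out.frame["x"].mean()) < 1e-12
        assert abs(out.frame["x"].std(ddof=1) - 1.0) < 1e-12

    def test_inverse_recovers_original(self):
        rng = np.random.default_rng(1)
        table = small_table(rng.normal(480, 60, 200), rng.integers(0, 2, 200))
        out, params = zscore(table, ["x"])
        back = params.inverse(out.frame)
        assert np.max(np.abs(back["x"] - table.frame["x"])) < 1e-10

    def test_constant_column_names_offender(self):
        table = small_table([5.0] * 10, [0, 1] * 5)
        with pytest.raises(DegenerateColumnError, match="'x'"):
            zscore(table, ["x"])

    def test_fitted_params_reused_on_heldout_without_peeking(self):
        rng = np.random.default_rng(2)
        train = small_table(rng.normal(0, 1, 300), rng.integers(0, 2, 300))
        held = small_table(rng.normal(5, 1, 300), rng.integers(0, 2, 300))
        _, params = zscore(train, ["x"])
        transformed = params.transform(held.frame)
        # held-out mean maps through the *train* statistics, not its own
        assert transformed["x"].mean() == pytest.approx(
            (held.frame["x"].mean() - params.means["x"]) / params.sds["x"]
        )
        assert abs(transformed["x"].mean()) > 1.0


class TestOneHot:
    def test_two_levels_rows_sum_to_one(self):
        frame = pd.DataFrame(
            {"mode": ["CPAP", "PAV", "CPAP"], LABEL_COLUMN: [0, 1, 0]}
        )
        out, _ = one_hot(BreathTable(frame), "mode")
        cols = ["mode=CPAP", "mode=PAV"]
        assert all(c in out.frame.columns for c in cols)
        assert (out.frame[cols].sum(axis=1) == 1).all()

    def test_single_level_gives_all_ones(self):
        frame = pd.DataFrame({"mode": ["CPAP"] * 4, LABEL_COLUMN: [0, 1, 0, 1]})
        out, _ = one_hot(BreathTable(frame), "mode")
        assert (out.frame["mode=CPAP"] == 1).all()

    def test_unseen_category_rejected(self):
        fit = pd.DataFrame({"mode": ["A", "B"], LABEL_COLUMN: [0, 1]})
        _, registry = one_hot(BreathTable(fit), "mode")
        apply = pd.DataFrame({"mode": ["C"], LABEL_COLUMN: [0]})
        with pytest.raises(EncodingError, match="C"):
            registry.transform(apply)


class TestSplit:
    def test_seventy_thirty_counts(self):
        table = generate(DatasetConfig(n_rows=1000, seed=4))
        train, test = split(table, train_fraction=0.7, seed=0)
        assert (train.n_rows, test.n_rows) == (700, 300)

    def test_partition_is_exact_and_stratified(self):
        table = generate(DatasetConfig(n_rows=501, class_balance=0.4, seed=5))
        train, test = split(table, seed=9)
        assert train.n_rows + test.n_rows == 501
        combined = pd.concat([train.frame, test.frame])
        assert (
            combined.sort_values(list(combined.columns))
            .reset_index(drop=True)
            .equals(
                table.frame.sort_values(list(combined.columns)).reset_index(drop=True)
            )
        )
        # class proportions preserved within one row
        frac = train.labels.mean()
        assert abs(frac - table.labels.mean()) < 1.0 / train.n_rows + 1e-9

    def test_same_seed_same_split(self):
        table = generate(DatasetConfig(n_rows=200, seed=6))
        a_train, _ = split(table, seed=42)
        b_train, _ = split(table, seed=42)
        assert a_train.frame.equals(b_train.frame)

    def test_tiny_class_rejected(self):
        table = small_table([1.0, 2.0, 3.0], [0, 0, 1])
        with pytest.raises(StratificationError):
            split(table)

    def test_invalid_fraction_rejected(self):
        table = generate(DatasetConfig(n_rows=20, seed=0))
        with pytest.raises(ParameterError):
            split(table, train_fraction=1.0)
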