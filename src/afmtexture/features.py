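"""Feature tables over cells×channels and Gini-importance feature ranking.

A feature is a (channel_kind, parameter_name) pair, so combining channels
simply widens the table.  Ranking uses mean decrease in Gini impurity from a
bagged decision-tree ensemble (random-forest), the standard estimator for
this importance measure; ties are broken by table column order, which follows
registry order, for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import CellRecord
from .params import DEFAULT_REGISTRY, ParameterRegistry, compute_all

FeatureKey = Tuple[str, str]  # (channel_kind, parameter_name)


class FeatureTableError(ValueError):
    pass


@dataclass
class FeatureTable:
    """Cells × features matrix with labels.

    ``frame`` is indexed by cell_id with a 2-level column MultiIndex
    (channel_kind, parameter_name); ``labels`` aligns with the index and may
    contain None for unlabelled cells.
    """

    frame: pd.DataFrame
    labels: pd.Series

    def __post_init__(self):
        if not self.frame.index.equals(self.labels.index):
            raise FeatureTableError("labels index must match feature frame index")
        if self.frame.isna().any().any():
            raise FeatureTableError("feature table contains missing entries")
        if self.frame.columns.duplicated().any():
            raise FeatureTableError("duplicate feature columns")

    @property
    def feature_keys(self) -> List[FeatureKey]:
        return list(self.frame.columns)

    @property
    def cell_ids(self) -> List[str]:
        return list(self.frame.index)

    @property
    def is_labeled(self) -> bool:
        return self.labels.notna().all() and len(self.labels) > 0

    def y(self) -> np.ndarray:
        """Binary target: 1 = high aggressiveness."""
        if not self.is_labeled:
            raise FeatureTableError("table has unlabelled rows")
        return (self.labels == "high").to_numpy().astype(int)

    def x(self, keys: Optional[Sequence[FeatureKey]] = None) -> np.ndarray:
        if keys is None:
            return self.frame.to_numpy(dtype=float)
        return self.frame.loc[:, list(keys)].to_numpy(dtype=float)

    def subset_rows(self, cell_ids: Sequence[str]) -> "FeatureTable":
        ids = list(cell_ids)
        return FeatureTable(self.frame.loc[ids], self.labels.loc[ids])

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts()

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.columns = [f"{ch}:{par}" for ch, par in out.columns]
        out.insert(0, "label", self.labels)
        out.to_csv(path, index_label="cell_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        raw = pd.read_csv(path, index_col="cell_id")
        labels = raw.pop("label").astype(object).where(lambda s: s.notna(), None)
        cols = pd.MultiIndex.from_tuples([tuple(c.split(":", 1)) for c in raw.columns])
        frame = raw.copy()
        frame.columns = cols
        return cls(frame, labels)


def build_feature_table(
    cells: Sequence[CellRecord],
    channel_kinds: Sequence[str],
    registry: ParameterRegistry = DEFAULT_REGISTRY,
) -> FeatureTable:
    """One row per cell, columns = channel_kinds × registry parameters.

    Every requested channel must be present on every cell and large enough
    for the full registry.
    """
    rows = {}
    labels = {}
    columns = None
    for cell in cells:
        vec = {}
        for kind in channel_kinds:
            if kind not in cell.channels:
                raise FeatureTableError(f"cell {cell.cell_id!r} is missing channel {kind!r}")
            spv = compute_all(cell.channels[kind], registry)
            missing = [n for n in registry.names if n not in spv.values]
            if missing:
                raise FeatureTableError(
                    f"cell {cell.cell_id!r} channel {kind!r} too small for {missing}"
                )
            for name in registry.names:
                vec[(kind, name)] = spv.values[name]
        if columns is None:
            columns = list(vec)
        rows[cell.cell_id] = vec
        labels[cell.cell_id] = cell.label
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame = frame.loc[:, columns]
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return FeatureTable(frame, pd.Series(labels, dtype=object))


@dataclass
class ImportanceRanking:
    """Features sorted by decreasing Gini importance (sums to 1)."""

    entries: List[Tuple[FeatureKey, float]]

    def __post_init__(self):
        imps = np.array([v for _, v in self.entries])
        if imps.size and not np.isclose(imps.sum(), 1.0, atol=1e-9):
            raise ValueError("importances must sum to 1")
        if np.any(np.diff(imps) > 1e-12):
            raise ValueError("importances must be sorted non-increasing")

    @property
    def keys(self) -> List[FeatureKey]:
        return [k for k, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": [k[0] for k, _ in self.entries],
                "parameter": [k[1] for k, _ in self.entries],
                "importance": [v for _, v in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rank_gini_importance(
    table: FeatureTable,
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceRanking:
    """Rank features by mean decrease in Gini impurity.

    Ensemble: ``n_trees`` bootstrap-grown trees with sqrt(n_features) random
    feature subsets per split, Gini split criterion.  Ties are broken by
    column (registry) order.
    """
    if not table.is_labeled:
        raise FeatureTableError("Gini ranking needs a fully labelled table")
    counts = table.class_counts()
    if len(counts) < 2:
        raise FeatureTableError("Gini ranking needs both classes present")
    if counts.min() < 2:
        raise FeatureTableError("Gini ranking needs at least 2 cells per class")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(table.x(), table.y())
    imps = rf.feature_importances_
    keys = table.feature_keys
    # stable sort on descending importance keeps column order for exact ties
    order = np.argsort(-imps, kind="stable")
    entries = [(keys[i], float(imps[i])) for i in order]
    return ImportanceRanking(entries)


def select_top_k(ranking: ImportanceRanking, k: int) -> List[FeatureKey]:
    """The k highest-importance feature keys (all keys if k exceeds the list).

    Defaults used by the pipeline: k=10 for single-channel runs, k=20 when
    channels are combined.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return ranking.keys[:k]


def default_top_k(n_channels: int) -> int:
    """10 features for a single channel, 20 for any channel combination."""
    return 10 if n_channels <= 1 else 20
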