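"""Gaussian-process aggressiveness classifier (Model / Results objects).

:class:`AggressivenessGP` is the model: a binary Gaussian-process classifier
with an isotropic RBF kernel over z-scored surface-texture features, the
positive class being "high" aggressiveness.  ``fit()`` returns an
:class:`AggressivenessGPResults` carrying the selected features, the training
standardisation statistics, the fitted GP state, per-cell fitted
probabilities and a ``summary()`` table.  The latent posterior uses the
Laplace approximation with kernel hyperparameters optimised by marginal
likelihood; the Newton iteration cap defaults to 1000.

Features are standardised with training mean/sd because they mix physical
units (nm, nN, %, dimensionless); an RBF kernel on raw values would let one
unit dominate the length scale.  The same statistics are applied verbatim at
heatmap time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.model_selection import train_test_split

from .features import FeatureKey, FeatureTable, FeatureTableError


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split specification."""

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


class SplitError(ValueError):
    pass


def split_train_test(table: FeatureTable, spec: SplitSpec) -> Tuple[FeatureTable, FeatureTable]:
    """Disjoint stratified train/test split of the table's rows."""
    if not table.is_labeled:
        raise SplitError("cannot split an unlabelled table")
    counts = table.class_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise SplitError(f"need at least 2 cells per class to split, got {counts.to_dict()}")
    ids = table.cell_ids
    strat = table.labels.to_numpy() if spec.stratified else None
    train_ids, test_ids = train_test_split(
        ids, train_size=spec.train_fraction, stratify=strat, random_state=spec.seed
    )
    return table.subset_rows(train_ids), table.subset_rows(test_ids)


class AggressivenessGP:
    """Binary GP classifier over selected surface-texture features.

    Parameters
    ----------
    table : FeatureTable
        Labelled training table.
    features : sequence of (channel, parameter) keys, optional
        Feature subset; defaults to every column.
    max_iter : int
        Newton iteration cap for the Laplace approximation (default 1000).
    ard : bool
        Use one RBF length scale per feature instead of a shared one.
    seed : int
        Random state for the GP optimiser.
    """

    def __init__(
        self,
        table: FeatureTable,
        features: Optional[Sequence[FeatureKey]] = None,
        max_iter: int = 1000,
        ard: bool = False,
        seed: int = 0,
    ):
        if not table.is_labeled:
            raise FeatureTableError("training table must be fully labelled")
        counts = table.class_counts()
        if len(counts) < 2:
            raise FeatureTableError("training table has a single class")
        self.table = table
        self.features: List[FeatureKey] = (
            list(features) if features is not None else table.feature_keys
        )
        missing = [f for f in self.features if f not in table.feature_keys]
        if missing:
            raise FeatureTableError(f"features not in table: {missing}")
        self.max_iter = int(max_iter)
        self.ard = bool(ard)
        self.seed = int(seed)

    def fit(self) -> "AggressivenessGPResults":
        x = self.table.x(self.features)
        if not np.all(np.isfinite(x)):
            raise FeatureTableError("non-finite feature values in training table")
        y = self.table.y()
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        if np.any(sd <= 0):
            bad = [self.features[i] for i in np.flatnonzero(sd <= 0)]
            raise FeatureTableError(f"constant features cannot be standardised: {bad}")
        xs = (x - mean) / sd
        length = np.ones(len(self.features)) if self.ard else 1.0
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(length, (1e-2, 1e3))
        gpc = GaussianProcessClassifier(
            kernel=kernel,
            max_iter_predict=self.max_iter,
            random_state=self.seed,
            n_restarts_optimizer=0,
        )
        gpc.fit(xs, y)
        return AggressivenessGPResults(self, mean, sd, gpc, xs, y)


class AggressivenessGPResults:
    """Fitted GP classifier: estimates, diagnostics and prediction."""

    positive_class = "high"

    def __init__(self, model, mean, sd, gpc, x_train_std, y_train):
        self.model = model
        self.features: List[FeatureKey] = list(model.features)
        self.standardization_mean = np.asarray(mean, dtype=float)
        self.standardization_sd = np.asarray(sd, dtype=float)
        self.gpc = gpc
        self._x_train_std = np.asarray(x_train_std, dtype=float)
        self._y_train = np.asarray(y_train, dtype=int)
        #: fitted P(high) on the training rows
        self.fittedvalues = pd.Series(
            self.gpc.predict_proba(self._x_train_std)[:, 1], index=model.table.cell_ids
        )

    # -- prediction ----------------------------------------------------------

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.standardization_mean) / self.standardization_sd

    def predict_proba_matrix(self, x: np.ndarray) -> np.ndarray:
        """P(high) for raw (unstandardised) feature rows ordered like ``features``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(self.features):
            raise ValueError(f"expected {len(self.features)} features, got {x.shape[1]}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite feature values")
        return self.gpc.predict_proba(self._standardize(x))[:, 1]

    def predict_proba(self, table: FeatureTable) -> pd.Series:
        """Per-cell P(high aggressiveness) for the rows of a feature table."""
        return pd.Series(
            self.predict_proba_matrix(table.x(self.features)), index=table.cell_ids
        )

    def predict_probability(self, vector: Mapping[FeatureKey, float]) -> float:
        """P(high) for one feature mapping keyed like ``features``."""
        try:
            row = [vector[k] for k in self.features]
        except KeyError as exc:
            raise KeyError(f"missing feature {exc.args[0]!r}") from None
        return float(self.predict_proba_matrix(np.array([row]))[0])

    def classify(self, table: FeatureTable, threshold: float = 0.5) -> "ClassificationReport":
        """Per-cell probabilities and predicted labels (high iff P >= threshold)."""
        probs = self.predict_proba(table)
        predicted = np.where(probs.to_numpy() >= threshold, "high", "low")
        frame = pd.DataFrame(
            {
                "label": table.labels,
                "probability_high": probs,
                "predicted": predicted,
            },
            index=probs.index,
        )
        accuracy = None
        if table.labels.notna().all() and len(frame):
            accuracy = float((frame["label"] == frame["predicted"]).mean())
        return ClassificationReport(frame, threshold, accuracy)

    # -- diagnostics ---------------------------------------------------------

    @property
    def kernel_(self):
        return self.gpc.kernel_

    @property
    def log_marginal_likelihood(self) -> float:
        return float(self.gpc.log_marginal_likelihood_value_)

    @property
    def train_accuracy(self) -> float:
        pred = (self.fittedvalues.to_numpy() >= 0.5).astype(int)
        return float((pred == self._y_train).mean())

    def summary(self) -> str:
        counts = self.model.table.class_counts()
        lines = [
            "Gaussian-process aggressiveness classifier",
            "=" * 58,
            f"Training cells:        {len(self._y_train)} "
            f"(high={counts.get('high', 0)}, low={counts.get('low', 0)})",
            f"Selected features:     {len(self.features)}",
            f"Kernel:                {self.kernel_}",
            f"Log marginal lik.:     {self.log_marginal_likelihood:.4f}",
            f"Training accuracy:     {self.train_accuracy:.3f}",
            f"Newton iteration cap:  {self.model.max_iter}",
            "-" * 58,
            "feature (channel : parameter)      mean          sd",
        ]
        for (ch, par), mu, sd in zip(
            self.features, self.standardization_mean, self.standardization_sd
        ):
            lines.append(f"  {ch:>24s} : {par:<6s} {mu:>12.5g} {sd:>11.5g}")
        return "\n".join(lines)

    # -- serialisation -------------------------------------------------------

    def save(self, path) -> None:
        """Serialise to a JSON bundle (features, standardisation, kernel
        hyperparameters and standardised training data; the Laplace latent
        state is reconstructed deterministically on load)."""
        payload = {
            "features": [list(k) for k in self.features],
            "mean": self.standardization_mean.tolist(),
            "sd": self.standardization_sd.tolist(),
            "kernel_theta": self.gpc.kernel_.theta.tolist(),
            "max_iter": self.model.max_iter,
            "ard": self.model.ard,
            "seed": self.model.seed,
            "x_train_std": self._x_train_std.tolist(),
            "y_train": self._y_train.tolist(),
            "cell_ids": list(self.model.table.cell_ids),
            "labels": list(self.model.table.labels),
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def load(path) -> "AggressivenessGPResults":
        payload = json.loads(Path(path).read_text())
        features = [tuple(k) for k in payload["features"]]
        xs = np.asarray(payload["x_train_std"], dtype=float)
        y = np.asarray(payload["y_train"], dtype=int)
        length = np.ones(len(features)) if payload["ard"] else 1.0
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(length, (1e-2, 1e3))
        kernel.theta = np.asarray(payload["kernel_theta"], dtype=float)
        gpc = GaussianProcessClassifier(
            kernel=kernel,
            optimizer=None,  # hyperparameters already optimised; refit latent only
            max_iter_predict=payload["max_iter"],
            random_state=payload["seed"],
        )
        gpc.fit(xs, y)
        mean = np.asarray(payload["mean"], dtype=float)
        sd = np.asarray(payload["sd"], dtype=float)
        # rebuild a minimal model/table so the results object is self-consistent
        frame = pd.DataFrame(
            xs * sd + mean,
            index=payload["cell_ids"],
            columns=pd.MultiIndex.from_tuples(features),
        )
        table = FeatureTable(frame, pd.Series(payload["labels"], index=payload["cell_ids"]))
        model = AggressivenessGP(
            table, features, max_iter=payload["max_iter"], ard=payload["ard"], seed=payload["seed"]
        )
        return AggressivenessGPResults(model, mean, sd, gpc, xs, y)


@dataclass
class ClassificationReport:
    """Per-cell classification outcome (Fig-2-style table)."""

    frame: pd.DataFrame  # index cell_id; columns label, probability_high, predicted
    threshold: float
    accuracy: Optional[float]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="cell_id")


def classify_cells(
    results: AggressivenessGPResults, table: FeatureTable, threshold: float = 0.5
) -> ClassificationReport:
    """Functional wrapper around :meth:`AggressivenessGPResults.classify`."""
    return results.classify(table, threshold)
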