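"""Model pool handling, consensus scoring and the stacked QA regressor.

The ranking machinery mirrors how a structure-prediction pipeline selects
models for a target:

1. near-duplicate models from the same group are filtered out (pairwise
   GDT-TS > 0.95);
2. each model gets a *consensus* score — its mean structural similarity to
   every other model in the pool (the clustering/multi-model QA family);
3. per-model feature vectors (map matching, contact matching, consensus,
   auxiliary single-model scores) feed a two-level stacked regressor that
   predicts GDT-TS: ten level-1 networks trained by tenfold cross-validation
   whose out-of-fold outputs join the input features for a level-2 network;
4. independent rankings can also be fused by mean rank position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from . import metrics
from .structio import Structure

__all__ = [
    "ModelPool",
    "Ranking",
    "StackedQA",
    "filter_redundant",
    "consensus_scores",
    "rank_average",
    "select_top",
]

log = logging.getLogger(__name__)

REDUNDANCY_CUTOFF = 0.95


@dataclass
class ModelPool:
    """Candidate models for one target with group labels and optional truth."""

    target_id: str
    model_ids: list[str]
    models: list[Structure]
    groups: list[str] | None = None
    server_rank: list[int] | None = None
    true_scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        k = len(self.models)
        if len(self.model_ids) != k:
            raise ValueError("model_ids and models length mismatch")
        if len(set(self.model_ids)) != k:
            raise ValueError("model identifiers must be unique")
        if self.groups is None:
            self.groups = ["g0"] * k
        if self.server_rank is None:
            self.server_rank = list(range(1, k + 1))
        if self.true_scores is not None:
            for v in self.true_scores.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("true scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, model_id: str) -> Structure:
        return self.models[self.model_ids.index(model_id)]

    def subset(self, keep_ids: list[str]) -> "ModelPool":
        pos = [self.model_ids.index(m) for m in keep_ids]
        return ModelPool(
            target_id=self.target_id,
            model_ids=[self.model_ids[p] for p in pos],
            models=[self.models[p] for p in pos],
            groups=[self.groups[p] for p in pos],
            server_rank=[self.server_rank[p] for p in pos],
            true_scores=None if self.true_scores is None else {
                m: self.true_scores[m] for m in keep_ids if m in self.true_scores},
        )


@dataclass
class Ranking:
    """Models ordered by descending predicted score, ties broken by id."""

    entries: list[tuple[str, float]] = field(default_factory=list)

    @classmethod
    def from_scores(cls, scores: dict[str, float]) -> "Ranking":
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(entries=ordered)

    @property
    def model_ids(self) -> list[str]:
        return [m for m, _ in self.entries]

    @property
    def scores(self) -> dict[str, float]:
        return dict(self.entries)

    def rank_of(self, model_id: str) -> int:
        """1-based rank position of *model_id*."""
        return self.model_ids.index(model_id) + 1

    def __len__(self) -> int:
        return len(self.entries)


def filter_redundant(
    pool: ModelPool,
    cutoff: float = REDUNDANCY_CUTOFF,
    pairwise: np.ndarray | None = None,
) -> ModelPool:
    """Drop near-duplicate models within each group (GDT-TS > *cutoff*).

    Models are processed greedily in server-rank order; of any same-group
    pair above the cutoff the better-ranked model is kept.  Cross-group
    pairs are never filtered.  *pairwise* may carry a precomputed GDT-TS
    matrix aligned with ``pool.model_ids``.
    """
    k = len(pool)
    order = np.argsort(pool.server_rank, kind="stable")
    if pairwise is None and k > 1:
        pairwise = metrics.pairwise_matrix(pool.models, "gdt_ts")
    kept: list[int] = []
    for p in order:
        dup = any(
            pool.groups[q] == pool.groups[p] and pairwise[p, q] > cutoff
            for q in kept)
        if dup:
            log.info("filter_redundant: dropping %s (GDT-TS > %.2f to a "
                     "better-ranked same-group model)", pool.model_ids[p], cutoff)
        else:
            kept.append(p)
    kept.sort()
    return pool.subset([pool.model_ids[p] for p in kept])


def consensus_scores(
    pool: ModelPool,
    metric: str = "gdt_ts",
    pairwise: np.ndarray | None = None,
) -> dict[str, float]:
    """Mean similarity of each model to all other models in the pool."""
    if len(pool) < 2:
        raise ValueError("consensus scoring needs at least 2 models")
    if pairwise is None:
        pairwise = metrics.pairwise_matrix(pool.models, metric)
    k = len(pool)
    out = {}
    for p in range(k):
        others = np.delete(pairwise[p], p)
        out[pool.model_ids[p]] = float(np.mean(others))
    return out


def rank_average(rankings: list[Ranking]) -> Ranking:
    """Fuse rankings by mean rank position (lower mean rank is better)."""
    if len(rankings) < 2:
        raise ValueError("need at least 2 rankings to average")
    ids = set(rankings[0].model_ids)
    for r in rankings[1:]:
        if set(r.model_ids) != ids:
            raise ValueError("rankings cover different model sets")
    mean_rank = {
        m: float(np.mean([r.rank_of(m) for r in rankings])) for m in ids}
    # re-express as a descending score so Ranking's ordering applies
    ordered = sorted(mean_rank.items(), key=lambda kv: (kv[1], kv[0]))
    return Ranking(entries=[(m, -mr) for m, mr in ordered])


def select_top(ranking: Ranking, n: int = 5) -> list[str]:
    """The first min(n, size) model ids of the ranking."""
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    return ranking.model_ids[: max(n, 0)]


class StackedQA:
    """Two-level stacked regressor predicting GDT-TS from model features.

    The first level holds ``n_folds`` small feed-forward networks trained by
    cross-validation; each training row receives an out-of-fold level-1
    prediction, which joins the original features as input to the level-2
    network.  At prediction time the level-1 output is the mean over the
    fold networks.  Predictions are clipped to [0, 1].  Fully deterministic
    for a fixed ``seed``.

    Parameters
    ----------
    hidden : tuple of int
        Hidden-layer sizes of every network.
    n_folds : int
        Number of level-1 cross-validation folds (and networks).
    seed : int
        Seed controlling fold assignment and weight initialisation.
    """

    def __init__(self, hidden: tuple[int, ...] = (64, 32), n_folds: int = 10,
                 seed: int = 0):
        self.hidden = tuple(hidden)
        self.n_folds = n_folds
        self.seed = seed
        self.feature_schema: list[str] | None = None
        self.level1: list[MLPRegressor] = []
        self.level2: MLPRegressor | None = None
        self._scaler: StandardScaler | None = None
        self._medians: pd.Series | None = None

    def _make_net(self, seed: int) -> MLPRegressor:
        return MLPRegressor(
            hidden_layer_sizes=self.hidden, solver="lbfgs", max_iter=400,
            random_state=seed, alpha=1e-3)

    def _prepare(self, features: pd.DataFrame) -> np.ndarray:
        if self.feature_schema is None:
            raise RuntimeError("model is not fitted")
        missing = [c for c in self.feature_schema if c not in features.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        x = features[self.feature_schema].copy()
        na = x.isna().any()
        if na.any():
            log.info("imputing missing values in columns %s with training "
                     "medians", list(x.columns[na]))
        x = x.fillna(self._medians)
        return self._scaler.transform(x.to_numpy(dtype=float))

    def fit(self, features: pd.DataFrame, labels: pd.Series | np.ndarray) -> "StackedQA":
        """Train both levels on per-model features and true GDT-TS labels."""
        y = np.asarray(labels, dtype=float)
        if len(features) < 50:
            raise ValueError("need at least 50 training rows")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("labels must lie in [0, 1]")
        if np.std(y) == 0:
            warnings.warn("zero-variance labels; the fitted model is degenerate")
        if features.columns.duplicated().any():
            raise ValueError("feature columns must be uniquely named")
        self.feature_schema = list(features.columns)
        self._medians = features.median(numeric_only=True)
        xdf = features.fillna(self._medians)
        self._scaler = StandardScaler().fit(xdf.to_numpy(dtype=float))
        x = self._scaler.transform(xdf.to_numpy(dtype=float))

        kf = KFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        oof = np.zeros(len(y))
        self.level1 = []
        for f, (tr, te) in enumerate(kf.split(x)):
            net = self._make_net(self.seed + 1 + f)
            net.fit(x[tr], y[tr])
            oof[te] = net.predict(x[te])
            self.level1.append(net)
        x2 = np.column_stack([np.clip(oof, 0, 1), x])
        self.level2 = self._make_net(self.seed + 101)
        self.level2.fit(x2, y)
        return self

    def predict(self, features: pd.DataFrame) -> pd.Series:
        """Per-model predicted GDT-TS, clipped to [0, 1]."""
        x = self._prepare(features)
        l1 = np.mean([net.predict(x) for net in self.level1], axis=0)
        x2 = np.column_stack([np.clip(l1, 0, 1), x])
        pred = np.clip(self.level2.predict(x2), 0.0, 1.0)
        return pd.Series(pred, index=features.index, name="predicted_gdt_ts")

    def rank(self, features: pd.DataFrame) -> Ranking:
        """Predict and order the rows into a Ranking."""
        pred = self.predict(features)
        return Ranking.from_scores({str(m): float(v) for m, v in pred.items()})

    def save(self, path) -> None:
        """Serialise the fitted model (schema and seed included) to one file."""
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "StackedQA":
        import joblib

        model = joblib.load(path)
        if not isinstance(model, StackedQA):
            raise ValueError(f"{path} does not contain a StackedQA model")
        return model
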