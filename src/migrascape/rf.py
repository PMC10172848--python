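"""Random-forest regression of deme-level migration on landscape predictors.

The model object / results object split follows the convention of the
statistical-modelling packages this module sits alongside:

* :class:`MigrationForest` is built from a predictor table (one row per
  habitable deme) and a log-migration response, aligned on deme id.
* ``fit()`` returns a :class:`MigrationForestResults` carrying the
  out-of-bag percent variance explained (RSQ), permutation importances
  (mean decrease in accuracy), OOB predictions and a ``summary()`` table.
* ``cross_validate()`` returns a :class:`CVResult` with per-fold RSQ,
  r_train and r_test (Pearson correlations of observed vs predicted
  migration on the training and held-out demes).

RSQ is the ensemble's out-of-bag estimate, 100 * (1 - OOB MSE / var(y)) —
the "percent variance explained" convention of the classical random-forest
packages.  Importance is OOB permutation importance: for each tree, the
increase in MSE on that tree's out-of-bag demes when one predictor's values
are shuffled, averaged over trees.

Hyperparameters follow the field's names: ``mtry`` (features tried per
split) and ``nodesize`` (minimum terminal-node size); ``tune`` grid-searches
both by OOB error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .migration import ResponseVector
from .predictors import KERNEL_COLUMN

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "MigrationForest",
    "MigrationForestResults",
    "CVResult",
    "tune",
    "fit",
    "cross_validate",
    "compare_with_without_kernel",
]

_PERM_SEED_OFFSET = 7_654_321  # decouples the importance-permutation stream


@dataclass(frozen=True)
class ModelConfig:
    """Forest hyperparameters. ``mtry=None`` means ceil(P/3) at fit time."""

    n_trees: int = 1000
    mtry: int | None = None
    nodesize: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be at least 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be at least 1")


class MigrationForest:
    """Random-forest regression model of migration response on predictors.

    Parameters
    ----------
    table : DataFrame indexed by deme_id, one numeric column per predictor.
    response : ResponseVector or Series indexed by deme_id.

    Rows are intersected on deme id (order: table order); demes present in
    only one input raise.
    """

    def __init__(self, table: pd.DataFrame, response):
        if isinstance(response, ResponseVector):
            y = pd.Series(response.y, index=pd.Index(response.deme_ids, name="deme_id"))
        else:
            y = pd.Series(response)
        missing = set(table.index).symmetric_difference(y.index)
        if missing:
            raise ValueError(
                f"predictor table and response disagree on demes: {sorted(missing)[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        self.table = table
        self.y = y.loc[table.index]
        self.exog_names = list(table.columns)
        if table.isna().any().any():
            raise ValueError("predictor table contains missing values")
        self.X = table.to_numpy(dtype=float)
        self.yv = self.y.to_numpy(dtype=float)

    # ------------------------------------------------------------------ fit
    def fit(self, config: ModelConfig | None = None) -> "MigrationForestResults":
        config = config or ModelConfig()
        if np.var(self.yv) == 0:
            raise ValueError("response has zero variance; nothing to explain")
        forest = self._grow(self.X, self.yv, config)
        oob_pred = forest.oob_prediction_
        rsq = _rsq_pct(self.yv, oob_pred)
        importances = self._permutation_importance(forest, config)
        return MigrationForestResults(
            model=self,
            forest=forest,
            config=config,
            rsq_pct=rsq,
            importances=importances,
            oob_predictions=pd.Series(oob_pred, index=self.table.index, name="oob_pred"),
        )

    def _grow(self, X, y, config: ModelConfig, seed=None) -> RandomForestRegressor:
        mtry = config.mtry or math.ceil(X.shape[1] / 3)
        mtry = min(mtry, X.shape[1])
        forest = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_features=mtry,
            min_samples_leaf=config.nodesize,
            bootstrap=True,
            oob_score=True,
            random_state=config.seed if seed is None else seed,
            n_jobs=1,
        )
        import warnings

        with warnings.catch_warnings():
            # tiny forests can leave rows never OOB; handled downstream
            warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
            forest.fit(X, y)
        return forest

    def _permutation_importance(self, forest, config: ModelConfig) -> pd.DataFrame:
        """OOB permutation importance (mean decrease in accuracy), per tree."""
        X, y = self.X, self.yv
        n, p = X.shape
        rng = np.random.default_rng(config.seed + _PERM_SEED_OFFSET)
        increase = np.zeros(p)
        n_used = 0
        for tree, sample_idx in zip(forest.estimators_, forest.estimators_samples_):
            oob = np.ones(n, dtype=bool)
            oob[sample_idx] = False
            if oob.sum() < 2:
                continue
            n_used += 1
            Xo, yo = X[oob], y[oob]
            base = np.mean((tree.predict(Xo) - yo) ** 2)
            perm = rng.permutation(len(yo))
            Xp = Xo.copy()
            for j in range(p):
                saved = Xp[:, j].copy()
                Xp[:, j] = saved[perm]
                increase[j] += np.mean((tree.predict(Xp) - yo) ** 2) - base
                Xp[:, j] = saved
        if n_used:
            increase /= n_used
        order = np.argsort(-increase, kind="stable")
        ranks = np.empty(p, dtype=int)
        ranks[order] = np.arange(1, p + 1)
        return pd.DataFrame(
            {"importance": increase, "rank": ranks}, index=pd.Index(self.exog_names, name="variable")
        ).sort_values("rank")

    # ----------------------------------------------------------------- tune
    def tune(self, seed: int = 0, n_trees: int = 1000) -> tuple[int, int]:
        """Grid-search (mtry, nodesize) minimizing OOB mean squared error.

        Grid: mtry in ceil(P/3) * {0.5, 1, 2} (rounded, clipped to [1, P],
        deduplicated) x nodesize in {1, 5, 10, 20}.  Ties break to smaller
        mtry, then smaller nodesize.
        """
        n, p = self.X.shape
        if n < 20:
            raise ValueError(f"tune requires at least 20 rows, got {n}")
        base = math.ceil(p / 3)
        mtries = sorted({min(max(1, round(base * f)), p) for f in (0.5, 1.0, 2.0)})
        nodesizes = [1, 5, 10, 20]
        best = None
        for mtry in mtries:
            for nodesize in nodesizes:
                cfg = ModelConfig(n_trees=n_trees, mtry=mtry, nodesize=nodesize, seed=seed)
                forest = self._grow(self.X, self.yv, cfg)
                mse = _oob_mse(self.yv, forest.oob_prediction_)
                key = (mse, mtry, nodesize)
                if best is None or key < best:
                    best = key
        logger.info("tune: selected mtry=%d nodesize=%d (OOB MSE %.4g)", best[1], best[2], best[0])
        return best[1], best[2]

    # ------------------------------------------------------- cross-validate
    def cross_validate(
        self,
        k: int = 10,
        config: ModelConfig | None = None,
        fold_seed: int | None = None,
    ) -> "CVResult":
        """Seeded k-fold cross-validation over demes.

        Per fold: a forest is grown on the k-1 training folds; r_train and
        r_test are Pearson correlations of observed vs predicted migration
        on the training and held-out demes, and RSQ is the training model's
        out-of-bag percent variance explained.
        """
        config = config or ModelConfig()
        n = len(self.yv)
        if k < 2:
            raise ValueError("k must be at least 2")
        if k > n:
            raise ValueError(f"k={k} exceeds the number of demes ({n})")
        if k > n // 2:
            logger.warning("cross_validate: k=%d is large for n=%d rows", k, n)
        seed = config.seed if fold_seed is None else fold_seed
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        records = []
        test_demes = []
        for fold, (tr, te) in enumerate(kf.split(self.X)):
            forest = self._grow(self.X[tr], self.yv[tr], config, seed=config.seed + fold)
            rsq = _rsq_pct(self.yv[tr], forest.oob_prediction_)
            r_train = _pearson(self.yv[tr], forest.predict(self.X[tr]))
            r_test = _pearson(self.yv[te], forest.predict(self.X[te]))
            records.append(
                {"fold": fold, "n_test": len(te), "rsq_pct": rsq,
                 "r_train": r_train, "r_test": r_test}
            )
            test_demes.append(np.asarray(self.table.index[te]))
        return CVResult(pd.DataFrame(records).set_index("fold"), test_demes, config, seed)

    def compare_with_without_kernel(
        self,
        k: int = 10,
        config: ModelConfig | None = None,
        kernel_column: str = KERNEL_COLUMN,
        fold_seed: int | None = None,
    ) -> tuple["CVResult", "CVResult"]:
        """Paired CV with identical folds, with and without the kernel column."""
        if kernel_column not in self.table.columns:
            raise ValueError(f"kernel column {kernel_column!r} absent from table")
        config = config or ModelConfig()
        if config.mtry is None:
            # pin a common mtry so the paired comparison is not confounded by
            # the default ceil(P/3) differing between the two column sets
            config = replace(config, mtry=math.ceil((self.table.shape[1] - 1) / 3))
        seed = config.seed if fold_seed is None else fold_seed
        with_k = self.cross_validate(k, config, fold_seed=seed)
        reduced = MigrationForest(self.table.drop(columns=[kernel_column]), self.y)
        without_k = reduced.cross_validate(k, config, fold_seed=seed)
        return with_k, without_k


@dataclass
class MigrationForestResults:
    """Fitted-forest results: OOB RSQ, permutation importances, predictions."""

    model: MigrationForest
    forest: RandomForestRegressor
    config: ModelConfig
    rsq_pct: float
    importances: pd.DataFrame
    oob_predictions: pd.Series

    @property
    def r_full(self) -> float:
        """Pearson correlation of observed vs in-sample predicted response."""
        return _pearson(self.model.yv, self.forest.predict(self.model.X))

    def top_variables(self, n: int = 4) -> list[str]:
        return list(self.importances.index[:n])

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(table[self.model.exog_names].to_numpy(dtype=float))

    def summary(self) -> str:
        lines = [
            "Migration random-forest regression",
            "=" * 50,
            f"demes: {len(self.model.yv)}   predictors: {len(self.model.exog_names)}",
            f"trees: {self.config.n_trees}   mtry: "
            f"{self.config.mtry or math.ceil(len(self.model.exog_names) / 3)}   "
            f"nodesize: {self.config.nodesize}   seed: {self.config.seed}",
            f"OOB percent variance explained (RSQ): {self.rsq_pct:.1f}",
            f"r_full (observed vs predicted): {self.r_full:.3f}",
            "",
            "Permutation importance (mean decrease in accuracy)",
            "-" * 50,
        ]
        for var, row in self.importances.iterrows():
            lines.append(f"{int(row['rank']):>4}  {var:<28} {row['importance']:.5f}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "rsq_pct": self.rsq_pct,
            "r_full": self.r_full,
            "config": {
                "n_trees": self.config.n_trees,
                "mtry": self.config.mtry,
                "nodesize": self.config.nodesize,
                "seed": self.config.seed,
            },
            "importances": [
                {"variable": v, "importance": float(r["importance"]), "rank": int(r["rank"])}
                for v, r in self.importances.iterrows()
            ],
        }


@dataclass
class CVResult:
    """Per-fold cross-validation metrics and fold membership."""

    folds: pd.DataFrame  # columns: n_test, rsq_pct, r_train, r_test
    test_demes: list[np.ndarray]
    config: ModelConfig
    fold_seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def mean(self, metric: str) -> float:
        return float(self.folds[metric].mean())

    def sd(self, metric: str) -> float:
        return float(self.folds[metric].std(ddof=1))

    def summary(self) -> str:
        lines = [
            f"{self.k}-fold cross-validation (fold seed {self.fold_seed})",
            "-" * 50,
        ]
        for m, label in (
            ("rsq_pct", "RSQ (%)"),
            ("r_train", "r_train"),
            ("r_test", "r_test"),
        ):
            lines.append(f"{label:<10} {self.mean(m):8.3f} +/- {self.sd(m):.3f}")
        return "\n".join(lines)


# ------------------------------------------------------------- module-level API

def tune(table: pd.DataFrame, response, seed: int = 0, n_trees: int = 1000) -> tuple[int, int]:
    return MigrationForest(table, response).tune(seed=seed, n_trees=n_trees)


def fit(table: pd.DataFrame, response, config: ModelConfig | None = None) -> MigrationForestResults:
    return MigrationForest(table, response).fit(config)


def cross_validate(table, response, k: int = 10, config: ModelConfig | None = None,
                   fold_seed: int | None = None) -> CVResult:
    return MigrationForest(table, response).cross_validate(k, config, fold_seed)


def compare_with_without_kernel(table, response, k: int = 10,
                                config: ModelConfig | None = None,
                                kernel_column: str = KERNEL_COLUMN,
                                fold_seed: int | None = None):
    return MigrationForest(table, response).compare_with_without_kernel(
        k, config, kernel_column, fold_seed
    )


# ----------------------------------------------------------------- helpers

def _oob_mse(y, oob_pred) -> float:
    ok = np.isfinite(oob_pred)
    return float(np.mean((y[ok] - oob_pred[ok]) ** 2))


def _rsq_pct(y, oob_pred) -> float:
    return 100.0 * (1.0 - _oob_mse(y, oob_pred) / np.var(y))


def _pearson(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
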