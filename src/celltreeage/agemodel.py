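"""Cell tree age: penalized regression of chronological age on tree shape.

The model regresses chronological age on the 31 tree-shape metrics plus sex
and sex x metric interactions (63 predictors), one row per pseudo-replicate
tree, with all of a sample's pseudo-replicates sharing its age. The fit
minimizes the elastic-net objective

    (1 / 2 N_tot) sum_ij (y_ij - mu - x_ij' beta)^2
        + lambda [ (1 - alpha) ||beta||_2^2 / 2 + alpha ||beta||_1 ]

with regularization constant lambda and lasso fraction alpha chosen by
exhaustive grid search. Prediction accuracy is estimated with nested
leave-one-*sample*-out cross-validation: the outer loop holds out one
sample's replicates, the inner loop (leave-one-out over the remaining
samples) picks the (lambda, alpha) pair with the lowest held-out mean
absolute error. This yields exactly one age prediction per pseudo-replicate
and one coefficient vector per outer fold.

Organisation follows the statsmodels convention: :class:`CellTreeAge` is the
model (built from a feature table + metadata via :meth:`from_features`);
its ``fit*`` methods return results objects carrying predictions,
hyperparameters, coefficients, performance and a ``summary()``.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

#: default hyperparameter grids
GRID_LAMBDA = (0.1, 0.3, 1.0, 3.0, 10.0)
GRID_ALPHA = (0.6, 0.7, 0.8, 0.9, 1.0)

_SEX_CODE = {"F": 0.0, "f": 0.0, "0": 0.0, 0: 0.0, "M": 1.0, "m": 1.0, "1": 1.0, 1: 1.0}


# ---------------------------------------------------------------------------
# elastic net (Eq. objective above)


@dataclass
class ElasticNetFit:
    """A single elastic-net solution, with its standardization transform."""

    mu: float
    beta: np.ndarray
    lam: float
    alpha: float
    feature_names: list | None = None
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.center is not None:
            X = (X - self.center) / self.scale
        return self.mu + X @ self.beta


def _standardize_columns(X: np.ndarray):
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    zero = scale == 0
    if zero.any():
        logger.debug("standardization: %d zero-variance columns kept at scale 1", int(zero.sum()))
        scale = np.where(zero, 1.0, scale)
    return center, scale


def elastic_net(X, y, lam: float, alpha: float, standardize: bool = True,
                feature_names=None) -> ElasticNetFit:
    """Solve the elastic-net objective for fixed (lambda, alpha).

    ``lambda`` is the regularization constant, ``alpha`` in [0, 1] the lasso
    fraction (alpha = 1 is the lasso, alpha = 0 the ridge limit). With
    ``standardize`` the columns of X are z-scored on the given data and the
    coefficients are reported on the standardized scale (transform stored on
    the fit). ``lambda = 0`` falls back to ordinary least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in X or y")
    if lam < 0 or not (0.0 <= alpha <= 1.0):
        raise ValueError("need lambda >= 0 and alpha in [0, 1]")
    center = scale = None
    if standardize:
        center, scale = _standardize_columns(X)
        X = (X - center) / scale
    if lam == 0:
        Xc = np.column_stack([np.ones(len(y)), X])
        coef, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        mu, beta = float(coef[0]), coef[1:]
    else:
        from sklearn.linear_model import ElasticNet

        # sklearn's objective is exactly the one above with alpha=lambda,
        # l1_ratio=alpha; l1_ratio=0 is refused by sklearn's coordinate
        # descent only in CV classes, plain ElasticNet accepts it.
        model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True,
                           max_iter=50000, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        mu, beta = float(model.intercept_), model.coef_.astype(float)
    return ElasticNetFit(mu=mu, beta=beta, lam=float(lam), alpha=float(alpha),
                         feature_names=list(feature_names) if feature_names is not None else None,
                         center=center, scale=scale)


def enet_objective(X, y, mu, beta, lam, alpha) -> float:
    """Value of the elastic-net objective (for oracle checks)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.asarray(beta, float)
    resid = y - mu - X @ beta
    n = len(y)
    return float((resid @ resid) / (2 * n)
                 + lam * ((1 - alpha) * (beta @ beta) / 2 + alpha * np.abs(beta).sum()))


# ---------------------------------------------------------------------------
# cohort design


@dataclass
class CohortDesign:
    """Samples x pseudo-replicate feature rows ready for regression.

    ``stats`` holds the raw 31 tree metrics per replicate row; ``sex`` the
    0/1-coded sex (F=0, M=1) and ``y`` the chronological age, constant
    across a sample's replicates. The full 63-column predictor vector
    [31 stats, sex, sex x stat_1..31] is assembled at fit time because the
    interactions are formed from (fold-)standardized statistics.
    """

    sample_ids: list
    replicate_ids: list
    stats: np.ndarray
    sex: np.ndarray
    y: np.ndarray
    feature_names: list = field(default_factory=lambda: list(FEATURE_NAMES))
    samples: pd.DataFrame | None = None

    def __post_init__(self):
        self.stats = np.asarray(self.stats, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.sample_ids)
        if not (self.stats.shape[0] == n == len(self.replicate_ids) == len(self.sex) == len(self.y)):
            raise ValueError("inconsistent design dimensions")
        if self.stats.shape[1] != len(self.feature_names):
            raise ValueError("stats width does not match feature names")
        ages = {}
        for sid, age in zip(self.sample_ids, self.y):
            if sid in ages and ages[sid] != age:
                raise ValueError(f"sample {sid} has inconsistent ages across replicates")
            ages[sid] = age

    @property
    def n_tot(self) -> int:
        return self.stats.shape[0]

    @property
    def unique_samples(self) -> list:
        seen = []
        for sid in self.sample_ids:
            if sid not in seen:
                seen.append(sid)
        return seen

    @property
    def n_samples(self) -> int:
        return len(self.unique_samples)

    @property
    def predictor_names(self) -> list:
        return (list(self.feature_names) + ["sex"]
                + [f"sex:{f}" for f in self.feature_names])

    def rows_of(self, sample_set) -> np.ndarray:
        sset = set(sample_set)
        return np.array([i for i, sid in enumerate(self.sample_ids) if sid in sset], dtype=int)


def build_design(features_table: pd.DataFrame, metadata: pd.DataFrame) -> CohortDesign:
    """Join a per-replicate feature table with sample metadata.

    ``features_table`` needs columns ``sample_id, replicate_id`` plus the 31
    metrics; ``metadata`` needs ``sample_id, age, sex``. Sexes are coded
    F=0, M=1. Rows with missing metadata or non-finite features raise.
    """
    meta = metadata.set_index("sample_id")
    sample_ids, replicate_ids, sexes, ys = [], [], [], []
    for feat in FEATURE_NAMES:
        if feat not in features_table.columns:
            raise ValueError(f"feature table lacks metric column {feat!r}")
    stats_mat = features_table[FEATURE_NAMES].to_numpy(dtype=float)
    for i, row in features_table.reset_index(drop=True).iterrows():
        sid = row["sample_id"]
        if sid not in meta.index:
            raise ValueError(f"feature row {i} (sample {sid}): no metadata entry")
        if not np.isfinite(stats_mat[i]).all():
            bad = [f for f, v in zip(FEATURE_NAMES, stats_mat[i]) if not np.isfinite(v)]
            raise ValueError(f"feature row {i} (sample {sid}): non-finite metrics {bad}")
        sex_raw = meta.loc[sid, "sex"]
        if sex_raw not in _SEX_CODE:
            raise ValueError(f"sample {sid}: sex {sex_raw!r} not interpretable as F/M")
        sample_ids.append(sid)
        replicate_ids.append(row["replicate_id"])
        sexes.append(_SEX_CODE[sex_raw])
        ys.append(float(meta.loc[sid, "age"]))
    samples = meta.reset_index()[["sample_id", "age", "sex"]]
    return CohortDesign(sample_ids=sample_ids, replicate_ids=replicate_ids,
                        stats=stats_mat, sex=np.array(sexes), y=np.array(ys),
                        samples=samples)


# ---------------------------------------------------------------------------
# performance


@dataclass
class PerformanceReport:
    """Prediction accuracy over all (predicted, chronological) age pairs."""

    mae: float
    mdae: float
    rmse: float
    r: float
    r2: float
    n: int
    r_defined: bool = True

    def as_dict(self) -> dict:
        return {"mae": self.mae, "mdae": self.mdae, "rmse": self.rmse,
                "r": self.r, "r2": self.r2, "n": self.n}

    def __str__(self) -> str:
        tag = "" if self.r_defined else " (r undefined: zero-variance predictions)"
        return (f"MAE={self.mae:.3f}  MdAE={self.mdae:.3f}  RMSE={self.rmse:.3f}  "
                f"r={self.r:.3f}  R2={self.r2:.3f}  n={self.n}{tag}")


def performance_metrics(y, y_hat) -> PerformanceReport:
    """MAE, MdAE, RMSE, Pearson r (and r^2) of predictions vs ages."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("predictions and ages must be equal-length, non-empty")
    err = y_hat - y
    mae = float(np.abs(err).mean())
    mdae = float(np.median(np.abs(err)))
    rmse = float(np.sqrt((err ** 2).mean()))
    r_defined = y_hat.std() > 0 and y.std() > 0
    if r_defined:
        r = float(np.corrcoef(y_hat, y)[0, 1])
    else:
        logger.warning("performance: zero-variance predictions or ages; r reported as 0")
        r = 0.0
    return PerformanceReport(mae=mae, mdae=mdae, rmse=rmse, r=r, r2=r * r,
                             n=y.size, r_defined=r_defined)


def age_acceleration(y, y_hat):
    """Age difference and age acceleration per replicate.

    The age difference is ``y_hat - y``; the age acceleration is the
    residual of ``y_hat`` from the OLS line of predicted on chronological
    age (so accelerations average to zero by construction).
    """
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if np.unique(y).size < 2:
        raise ValueError("age acceleration needs at least 2 distinct ages")
    b, a = np.polyfit(y, y_hat, 1)
    return y_hat - y, y_hat - (a + b * y)


# ---------------------------------------------------------------------------
# the model


class CellTreeAge:
    """Cell tree age model over a cohort of pseudo-replicate tree features.

    Parameters
    ----------
    design : CohortDesign
        Per-replicate metrics, sex and age (see :func:`build_design`).
    standardize : bool
        z-score the 31 metric columns on each training partition (the
        default; penalized regression is scale-sensitive). Interactions are
        formed as sex x standardized metric.
    """

    def __init__(self, design: CohortDesign, standardize: bool = True):
        self.design = design
        self.standardize = standardize

    @classmethod
    def from_features(cls, features_table: pd.DataFrame, metadata: pd.DataFrame,
                      standardize: bool = True) -> "CellTreeAge":
        return cls(build_design(features_table, metadata), standardize=standardize)

    # -- internal: fold-wise design assembly ----------------------------

    def _make_transform(self, rows: np.ndarray):
        S = self.design.stats[rows]
        if self.standardize:
            center, scale = _standardize_columns(S)
        else:
            center = np.zeros(S.shape[1])
            scale = np.ones(S.shape[1])
        return center, scale

    def _design_matrix(self, rows: np.ndarray, center, scale,
                       columns: np.ndarray | None = None) -> np.ndarray:
        Z = (self.design.stats[rows] - center) / scale
        sex = self.design.sex[rows][:, None]
        X = np.hstack([Z, sex, sex * Z])
        if columns is not None:
            X = X[:, columns]
        return X

    def _fit_fold(self, train_rows, lam, alpha, columns=None):
        center, scale = self._make_transform(train_rows)
        X = self._design_matrix(train_rows, center, scale, columns)
        fit = elastic_net(X, self.design.y[train_rows], lam, alpha, standardize=False)
        return fit, center, scale

    def _predict_rows(self, fit, center, scale, rows, columns=None):
        X = self._design_matrix(rows, center, scale, columns)
        return fit.predict(X)

    def _inner_select(self, train_samples, pairs, columns=None):
        """Leave-one-sample-out over ``train_samples``; MAE per (lam, alpha)."""
        d = self.design
        abs_err = {pair: [] for pair in pairs}
        for held in train_samples:
            inner_train = [s for s in train_samples if s != held]
            tr = d.rows_of(inner_train)
            te = d.rows_of([held])
            center, scale = self._make_transform(tr)
            Xtr = self._design_matrix(tr, center, scale, columns)
            Xte = self._design_matrix(te, center, scale, columns)
            ytr = d.y[tr]
            for pair in pairs:
                fit = elastic_net(Xtr, ytr, pair[0], pair[1], standardize=False)
                abs_err[pair].extend(np.abs(fit.predict(Xte) - d.y[te]))
        maes = {pair: float(np.mean(abs_err[pair])) for pair in pairs}
        best = min(pairs, key=lambda p: maes[p])  # ties: first in grid order
        return best, maes

    # -- public fitting API ---------------------------------------------

    def fit(self, lambda_grid=GRID_LAMBDA, alpha_grid=GRID_ALPHA,
            columns: np.ndarray | None = None) -> "CellTreeAgeResults":
        """Nested leave-one-sample-out cross-validation.

        Returns a results object with one prediction per pseudo-replicate,
        the (lambda, alpha) chosen per outer fold, and the coefficient
        vector estimated in each outer fold.
        """
        d = self.design
        if d.n_samples < 3:
            raise ValueError("nested CV needs at least 3 samples")
        pairs = list(itertools.product(lambda_grid, alpha_grid))
        if not pairs:
            raise ValueError("empty hyperparameter grid")
        names = d.predictor_names
        col_names = [names[c] for c in columns] if columns is not None else names
        preds = np.full(d.n_tot, np.nan)
        fold_rows = []
        coef_rows = []
        folds = {}
        for held in d.unique_samples:
            train_samples = [s for s in d.unique_samples if s != held]
            best, _ = self._inner_select(train_samples, pairs, columns)
            tr = d.rows_of(train_samples)
            te = d.rows_of([held])
            fit, center, scale = self._fit_fold(tr, best[0], best[1], columns)
            preds[te] = self._predict_rows(fit, center, scale, te, columns)
            folds[held] = sorted(train_samples)
            fold_rows.append({"held_out": held, "lambda": best[0], "alpha": best[1]})
            coef_rows.append({"held_out": held, "mu": fit.mu,
                              **dict(zip(col_names, fit.beta))})
        return CellTreeAgeResults(
            model=self,
            predictions=self._prediction_frame(preds),
            fold_hyperparams=pd.DataFrame(fold_rows),
            coefficients=pd.DataFrame(coef_rows),
            folds=folds,
            columns=columns,
            kind="nested-cv",
        )

    def fit_dummy(self) -> "CellTreeAgeResults":
        """Leave-one-sample-out baseline predicting the training mean age."""
        d = self.design
        if d.n_samples < 2:
            raise ValueError("dummy baseline needs at least 2 samples")
        preds = np.full(d.n_tot, np.nan)
        folds = {}
        for held in d.unique_samples:
            train_samples = [s for s in d.unique_samples if s != held]
            tr = d.rows_of(train_samples)
            te = d.rows_of([held])
            preds[te] = d.y[tr].mean()
            folds[held] = sorted(train_samples)
        return CellTreeAgeResults(model=self, predictions=self._prediction_frame(preds),
                                  fold_hyperparams=pd.DataFrame(), coefficients=pd.DataFrame(),
                                  folds=folds, kind="dummy")

    def fit_external(self, test: "CellTreeAge", lambda_grid=GRID_LAMBDA,
                     alpha_grid=GRID_ALPHA) -> "CellTreeAgeResults":
        """Train on this whole cohort, predict an external cohort.

        One step of the outer loop: the inner leave-one-sample-out CV on the
        training cohort picks (lambda, alpha), the model is refit on all
        training rows and applied to every test replicate.
        """
        d = self.design
        td = test.design if isinstance(test, CellTreeAge) else test
        if td.n_tot == 0:
            raise ValueError("external test cohort is empty")
        if list(td.feature_names) != list(d.feature_names):
            diff = set(td.feature_names) ^ set(d.feature_names)
            raise ValueError(f"feature mismatch between cohorts: {sorted(diff)}")
        pairs = list(itertools.product(lambda_grid, alpha_grid))
        best, _ = self._inner_select(d.unique_samples, pairs)
        tr = d.rows_of(d.unique_samples)
        fit, center, scale = self._fit_fold(tr, best[0], best[1])
        Zt = (td.stats - center) / scale
        sext = td.sex[:, None]
        Xt = np.hstack([Zt, sext, sext * Zt])
        preds = fit.predict(Xt)
        res = CellTreeAgeResults(
            model=CellTreeAge(td, standardize=self.standardize),
            predictions=pd.DataFrame({
                "sample_id": td.sample_ids,
                "replicate_id": td.replicate_ids,
                "age": td.y,
                "predicted_age": preds,
            }),
            fold_hyperparams=pd.DataFrame([{"held_out": "<external>",
                                            "lambda": best[0], "alpha": best[1]}]),
            coefficients=pd.DataFrame([{"held_out": "<external>", "mu": fit.mu,
                                        **dict(zip(d.predictor_names, fit.beta))}]),
            folds={"<external>": sorted(d.unique_samples)},
            kind="external",
        )
        return res

    def fit_preselected(self, k_values, lambda_grid=GRID_LAMBDA,
                        alpha_grid=GRID_ALPHA) -> "PreselectionResults":
        """Two-step regression: rank features, refit on the top k.

        The selection step is the plain nested CV on all 63 predictors;
        features are ranked by the mean |coefficient| across the outer-fold
        estimates (ties broken by fixed column order). The estimation step
        reruns the nested CV restricted to the top-k columns for each k;
        the best k is the one with the lowest MAE.
        """
        d = self.design
        base = self.fit(lambda_grid, alpha_grid)
        names = d.predictor_names
        coef = base.coefficients[names].to_numpy(dtype=float)
        magnitude = np.abs(coef).mean(axis=0)
        order = np.argsort(-magnitude, kind="stable")  # ties: fixed column order
        ranking = [names[i] for i in order]
        results = {}
        for k in k_values:
            if not 1 <= k <= len(names):
                raise ValueError(f"k={k} outside [1, {len(names)}]")
            # k covering every predictor is exactly the unrestricted model
            cols = None if k == len(names) else np.sort(order[:k])
            results[k] = self.fit(lambda_grid, alpha_grid, columns=cols)
        best_k = min(results, key=lambda k: results[k].performance.mae)
        return PreselectionResults(base=base, per_k=results, ranking=ranking,
                                   magnitudes=dict(zip(names, magnitude)), best_k=best_k)

    def fit_final(self, lambda_grid=GRID_LAMBDA, alpha_grid=GRID_ALPHA) -> "FittedModel":
        """Fit a single deployable model on the whole cohort.

        (lambda, alpha) come from the inner leave-one-sample-out CV; the fit
        uses every replicate row.
        """
        d = self.design
        pairs = list(itertools.product(lambda_grid, alpha_grid))
        best, _ = self._inner_select(d.unique_samples, pairs)
        tr = d.rows_of(d.unique_samples)
        fit, center, scale = self._fit_fold(tr, best[0], best[1])
        return FittedModel(mu=fit.mu, beta=fit.beta, lam=best[0], alpha=best[1],
                           center=center, scale=scale,
                           feature_names=list(d.feature_names),
                           standardize=self.standardize)

    def _prediction_frame(self, preds) -> pd.DataFrame:
        d = self.design
        return pd.DataFrame({
            "sample_id": d.sample_ids,
            "replicate_id": d.replicate_ids,
            "age": d.y,
            "predicted_age": preds,
        })


# ---------------------------------------------------------------------------
# results


class CellTreeAgeResults:
    """Predictions + per-fold estimates of a :class:`CellTreeAge` fit."""

    def __init__(self, model, predictions, fold_hyperparams, coefficients,
                 folds, columns=None, kind="nested-cv"):
        self.model = model
        self.predictions = predictions
        self.fold_hyperparams = fold_hyperparams
        self.coefficients = coefficients
        self.folds = folds
        self.columns = columns
        self.kind = kind
        self.performance = performance_metrics(predictions["age"].to_numpy(),
                                               predictions["predicted_age"].to_numpy())
        try:
            diff, acc = age_acceleration(predictions["age"].to_numpy(),
                                         predictions["predicted_age"].to_numpy())
            self.predictions = self.predictions.assign(age_difference=diff,
                                                       age_acceleration=acc)
        except ValueError:
            self.predictions = self.predictions.assign(age_difference=np.nan,
                                                       age_acceleration=np.nan)

    @property
    def sample_predictions(self) -> pd.DataFrame:
        """Per-sample mean predicted age (the sample's cell tree age)."""
        return (self.predictions.groupby("sample_id", sort=False)
                .agg(age=("age", "first"), cell_tree_age=("predicted_age", "mean"))
                .reset_index())

    def summary(self) -> str:
        lines = [
            "Cell tree age model" + (f" [{self.kind}]" if self.kind else ""),
            "=" * 60,
            f"samples: {self.model.design.n_samples}   "
            f"pseudo-replicates: {self.model.design.n_tot}   "
            f"predictors: {len(self.model.design.predictor_names) if self.columns is None else len(self.columns)}",
            str(self.performance),
        ]
        if len(self.fold_hyperparams):
            counts = (self.fold_hyperparams.groupby(["lambda", "alpha"]).size()
                      .sort_values(ascending=False))
            lines.append("chosen (lambda, alpha) across folds: "
                         + ", ".join(f"({l:g},{a:g})x{c}" for (l, a), c in counts.items()))
        if len(self.coefficients):
            names = [c for c in self.coefficients.columns if c not in ("held_out", "mu")]
            mags = self.coefficients[names].abs().mean(axis=0).sort_values(ascending=False)
            top = mags.head(6)
            lines.append("largest mean |coefficient|: "
                         + ", ".join(f"{n}={v:.3f}" for n, v in top.items()))
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Scatter predicted vs chronological age (dots: replicates; crosses: sample means)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        p = self.predictions
        ax.scatter(p["age"], p["predicted_age"], s=12, alpha=0.5, label="pseudo-replicates")
        m = self.sample_predictions
        ax.scatter(m["age"], m["cell_tree_age"], marker="x", s=60, color="k",
                   label="sample means")
        lo = min(p["age"].min(), p["predicted_age"].min())
        hi = max(p["age"].max(), p["predicted_age"].max())
        ax.plot([lo, hi], [lo, hi], "r:", label="y = x")
        ax.set_xlabel("chronological age (years)")
        ax.set_ylabel("predicted cell tree age (years)")
        ax.legend(frameon=False)
        return ax


@dataclass
class PreselectionResults:
    """Feature ranking + nested-CV results per number of retained features."""

    base: CellTreeAgeResults
    per_k: dict
    ranking: list
    magnitudes: dict
    best_k: int

    def summary(self) -> str:
        lines = ["Feature pre-selection", "=" * 60,
                 "ranking (top 10): " + ", ".join(self.ranking[:10])]
        for k in sorted(self.per_k):
            lines.append(f"k={k:3d}: {self.per_k[k].performance}")
        lines.append(f"best k by MAE: {self.best_k}")
        return "\n".join(lines)


@dataclass
class FittedModel:
    """A deployable single fit (for external prediction / CLI `ctr predict`)."""

    mu: float
    beta: np.ndarray
    lam: float
    alpha: float
    center: np.ndarray
    scale: np.ndarray
    feature_names: list
    standardize: bool = True

    def predict_design(self, design: CohortDesign) -> pd.DataFrame:
        if list(design.feature_names) != list(self.feature_names):
            raise ValueError("feature names differ from the fitted model")
        Z = (design.stats - self.center) / self.scale
        sex = design.sex[:, None]
        X = np.hstack([Z, sex, sex * Z])
        preds = self.mu + X @ np.asarray(self.beta)
        return pd.DataFrame({"sample_id": design.sample_ids,
                             "replicate_id": design.replicate_ids,
                             "age": design.y, "predicted_age": preds})

    def to_json(self, path) -> None:
        obj = {"mu": self.mu, "beta": list(map(float, self.beta)),
               "lambda": self.lam, "alpha": self.alpha,
               "center": list(map(float, self.center)),
               "scale": list(map(float, self.scale)),
               "feature_names": self.feature_names,
               "standardize": self.standardize}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(mu=obj["mu"], beta=np.array(obj["beta"]), lam=obj["lambda"],
                   alpha=obj["alpha"], center=np.array(obj["center"]),
                   scale=np.array(obj["scale"]), feature_names=obj["feature_names"],
                   standardize=obj["standardize"])


# ---------------------------------------------------------------------------
# clinical marker associations


def marker_associations(sample_table: pd.DataFrame, markers: pd.DataFrame,
                        strata=("All", "Male", "Female")) -> pd.DataFrame:
    """Correlate blood markers with cell tree age and chronological age.

    ``sample_table`` needs columns ``sample_id, age, cell_tree_age, sex``;
    ``markers`` needs ``sample_id`` plus numeric marker columns. For each
    stratum (All / Male / Female) and marker, the Pearson r against the
    per-sample cell tree age and against chronological age is reported with
    two-sided p-values from the t-distribution and a significance flag at
    p < 0.05. Strata with fewer than 3 pairs, or constant vectors, are
    skipped with a note.
    """
    df = sample_table.merge(markers, on="sample_id", how="inner")
    sex_col = df["sex"].map(lambda s: _SEX_CODE.get(s, np.nan))
    marker_cols = [c for c in markers.columns if c != "sample_id"]
    rows = []
    for stratum in strata:
        if stratum == "All":
            sub = df
        elif stratum == "Male":
            sub = df[sex_col == 1.0]
        elif stratum == "Female":
            sub = df[sex_col == 0.0]
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
        for marker in marker_cols:
            vals = pd.to_numeric(sub[marker], errors="coerce")
            ok = vals.notna()
            row = {"stratum": stratum, "marker": marker, "n": int(ok.sum())}
            if ok.sum() < 3:
                row["note"] = "skipped: fewer than 3 pairs"
                rows.append(row)
                continue
            v = vals[ok].to_numpy(float)
            if v.max() == v.min():
                row["note"] = "skipped: constant marker"
                rows.append(row)
                continue
            for target, label in (("cell_tree_age", "cell_tree_age"), ("age", "chron_age")):
                tv = sub.loc[ok, target].to_numpy(float)
                if tv.max() == tv.min():
                    row[f"r_{label}"] = np.nan
                    row[f"p_{label}"] = np.nan
                    row[f"sig_{label}"] = False
                    continue
                r, p = sps.pearsonr(v, tv)
                row[f"r_{label}"] = float(r)
                row[f"p_{label}"] = float(p)
                row[f"sig_{label}"] = bool(p < 0.05)
            row["note"] = ""
            rows.append(row)
    return pd.DataFrame(rows)
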