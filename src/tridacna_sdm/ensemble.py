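"""Candidate suitability learners, TSS/AUC evaluation, repeated
cross-validation, gating, weighted ensembling, permutation importance and
response curves.

Ten candidate algorithms are fitted on the balanced presence /
pseudo-absence table: GLM, GAM, MARS, CTA, RF, GBM, ANN, FDA, MAXENT and
SRE.  Each exposes a suitability in [0, 1].  Performance is scored by
5-fold cross-validation repeated 10 times with the true skill statistic
(TSS = sensitivity + specificity - 1, maximized over thresholds) and the
rank-based AUC.  Learners pass the gates mean TSS > 0.7 and mean
AUC > 0.8; survivors are refitted on the full table and combined with
equal weights (optionally TSS-proportional).

Algorithm realizations (hyperparameters fixed, logged in the run
manifest):

- GLM: logistic regression on linear + squared terms
- GAM: logistic regression on per-variable cubic spline bases
- MARS: logistic regression on hinge features at quantile knots
- CTA: decision tree classifier
- RF / GBM: random forest / gradient boosting classifiers
- ANN: single-hidden-layer perceptron on standardized inputs
- FDA: linear discriminant analysis on linear + squared terms
- MAXENT: L2-regularized logistic regression on a full quadratic
  feature expansion of standardized inputs
- SRE: bespoke surface range envelope — suitability 1 iff every variable
  lies within the presences' [q, 1-q] percentile envelope (q = 0.025)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

log = logging.getLogger(__name__)

ALGORITHMS = ["GLM", "GAM", "MARS", "CTA", "RF", "GBM", "ANN", "FDA", "MAXENT", "SRE"]

DEFAULT_TSS_MIN = 0.7
DEFAULT_AUC_MIN = 0.8


class ModellingError(ValueError):
    pass


@dataclass(frozen=True)
class LearnerSpec:
    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ALGORITHMS:
            raise ModellingError(f"unknown algorithm '{self.name}'")


def default_specs(names: list[str] | None = None) -> list[LearnerSpec]:
    return [LearnerSpec(n) for n in (names or ALGORITHMS)]


# ---------------------------------------------------------------------------
# learners

class SRELearner:
    """Surface range envelope: binary suitability from per-variable
    percentile envelopes of the presence records."""

    def __init__(self, q: float = 0.025):
        if not 0 <= q < 0.5:
            raise ModellingError("q must lie in [0, 0.5)")
        self.q = q

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SRELearner":
        pres = X[y == 1]
        self.lo_ = np.quantile(pres, self.q, axis=0)
        self.hi_ = np.quantile(pres, 1.0 - self.q, axis=0)
        return self

    def predict_suitability(self, X: np.ndarray) -> np.ndarray:
        ok = (X >= self.lo_) & (X <= self.hi_)
        return ok.all(axis=1).astype(float)


def _quadratic(seed: int | None = None) -> PolynomialFeatures:
    return PolynomialFeatures(degree=2, include_bias=False)


def _make_estimator(spec: LearnerSpec, seed: int):
    """sklearn estimator (or SRELearner) realizing one algorithm."""
    name, p = spec.name, spec.params
    if name == "GLM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("sq", _quadratic()),
                ("lr", LogisticRegression(max_iter=2000, C=p.get("C", 1.0))),
            ]
        )
    if name == "GAM":
        return Pipeline(
            [
                ("spline", SplineTransformer(degree=3, n_knots=p.get("n_knots", 5))),
                ("lr", LogisticRegression(max_iter=2000, C=p.get("C", 1.0))),
            ]
        )
    if name == "MARS":
        return Pipeline(
            [
                ("hinge", HingeFeatures(n_knots=p.get("n_knots", 3))),
                ("lr", LogisticRegression(max_iter=2000, C=p.get("C", 1.0))),
            ]
        )
    if name == "CTA":
        return DecisionTreeClassifier(
            max_depth=p.get("max_depth", 6),
            min_samples_leaf=p.get("min_samples_leaf", 5),
            random_state=seed,
        )
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 200),
            min_samples_leaf=p.get("min_samples_leaf", 2),
            random_state=seed,
            n_jobs=1,
        )
    if name == "GBM":
        return GradientBoostingClassifier(
            n_estimators=p.get("n_estimators", 100),
            max_depth=p.get("max_depth", 3),
            random_state=seed,
        )
    if name == "ANN":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=p.get("hidden", (8,)),
                        max_iter=p.get("max_iter", 400),
                        random_state=seed,
                    ),
                ),
            ]
        )
    if name == "FDA":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("sq", _quadratic()),
                ("lda", LinearDiscriminantAnalysis()),
            ]
        )
    if name == "MAXENT":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("quad", PolynomialFeatures(degree=2, include_bias=False)),
                ("lr", LogisticRegression(max_iter=2000, C=p.get("C", 0.1))),
            ]
        )
    if name == "SRE":
        return SRELearner(q=p.get("q", 0.025))
    raise ModellingError(f"unknown algorithm '{name}'")


class HingeFeatures:
    """Piecewise-linear hinge basis max(0, x-k), max(0, k-x) at quantile
    knots per variable (the additive part of a MARS expansion)."""

    def __init__(self, n_knots: int = 3):
        self.n_knots = n_knots

    def fit(self, X: np.ndarray, y=None) -> "HingeFeatures":
        qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
        self.knots_ = np.quantile(X, qs, axis=0)  # n_knots x p
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        feats = [X]
        for k in self.knots_:
            feats.append(np.maximum(0.0, X - k))
            feats.append(np.maximum(0.0, k - X))
        return np.column_stack(feats)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {"n_knots": self.n_knots}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


@dataclass
class FittedLearner:
    """A fitted algorithm exposing suitability in [0, 1] on a named-column
    environment frame."""

    spec: LearnerSpec
    columns: list[str]
    model: object

    def predict(self, env: pd.DataFrame) -> np.ndarray:
        X = env[self.columns].to_numpy(dtype=float)
        if isinstance(self.model, SRELearner):
            return self.model.predict_suitability(X)
        proba = self.model.predict_proba(X)
        cls = list(self.model.classes_)
        return np.clip(proba[:, cls.index(1)], 0.0, 1.0)


def fit_learner(
    spec: LearnerSpec, env: pd.DataFrame, response: np.ndarray, seed: int = 0
) -> FittedLearner:
    """Fit one algorithm on the balanced 0/1 table."""
    y = np.asarray(response, dtype=int)
    if len(np.unique(y)) < 2:
        raise ModellingError("response contains a single class")
    if len(y) < 20:
        raise ModellingError(f"need >= 20 rows to fit, got {len(y)}")
    X = env.to_numpy(dtype=float)
    model = _make_estimator(spec, seed)
    model.fit(X, y)
    return FittedLearner(spec=spec, columns=list(env.columns), model=model)


# ---------------------------------------------------------------------------
# evaluation

def auc_score(pred: np.ndarray, obs: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction: the probability
    that a random presence outscores a random absence."""
    obs = np.asarray(obs, dtype=int)
    pred = np.asarray(pred, dtype=float)
    n1 = int(obs.sum())
    n0 = len(obs) - n1
    if n1 == 0 or n0 == 0:
        raise ModellingError("observations contain a single class")
    ranks = rankdata(pred)
    return float((ranks[obs == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def tss_at_threshold(pred: np.ndarray, obs: np.ndarray, tau: float) -> float:
    """sensitivity + specificity - 1 with 'pred >= tau' counting as presence."""
    obs = np.asarray(obs, dtype=int)
    hit = np.asarray(pred) >= tau
    pos = obs == 1
    sens = hit[pos].mean() if pos.any() else np.nan
    spec = (~hit[~pos]).mean() if (~pos).any() else np.nan
    return float(sens + spec - 1.0)


def evaluate(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float, float]:
    """(max TSS, AUC, argmax threshold) over candidate thresholds.

    Candidates are the sorted unique predictions and their midpoints; this
    covers every distinct confusion table, so the maximum matches a dense
    threshold scan.
    """
    obs = np.asarray(obs, dtype=int)
    pred = np.asarray(pred, dtype=float)
    if len(np.unique(obs)) < 2:
        raise ModellingError("observations contain a single class")
    uniq = np.unique(pred)
    cand = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2.0]) if len(uniq) > 1 else uniq
    # vectorized confusion tables over all candidates
    hit = pred[None, :] >= cand[:, None]
    pos = obs == 1
    sens = hit[:, pos].mean(axis=1)
    spec = 1.0 - hit[:, ~pos].mean(axis=1)
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))
    return float(tss[best]), auc_score(pred, obs), float(cand[best])


@dataclass
class CvScores:
    """Per-learner mean ± SE of TSS and AUC over replicate × fold runs."""

    table: pd.DataFrame  # index learner; columns tss_mean/tss_se/auc_mean/auc_se/n_runs
    folds: int
    replicates: int


def cross_validate(
    specs: list[LearnerSpec],
    env: pd.DataFrame,
    response: np.ndarray,
    folds: int = 5,
    replicates: int = 10,
    seed: int = 0,
) -> CvScores:
    """Stratified k-fold cross-validation repeated with fresh partitions.

    Each replicate draws a new stratified partition; each fold trains on
    the remaining (k-1)/k of the data and scores the held-out fold.  A
    learner failing on a fold has that run logged and excluded from its
    mean.  Deterministic given ``seed``.
    """
    y = np.asarray(response, dtype=int)
    rows: dict[str, dict[str, list[float]]] = {
        s.name: {"tss": [], "auc": []} for s in specs
    }
    for r in range(replicates):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for f, (tr, te) in enumerate(skf.split(env, y)):
            for spec in specs:
                try:
                    fitted = fit_learner(
                        spec, env.iloc[tr], y[tr], seed=seed + 1000 * r + f
                    )
                    tss, auc, _ = evaluate(fitted.predict(env.iloc[te]), y[te])
                except Exception as exc:  # noqa: BLE001 - per-run isolation
                    log.warning(
                        "%s failed on replicate %d fold %d: %s", spec.name, r, f, exc
                    )
                    continue
                rows[spec.name]["tss"].append(tss)
                rows[spec.name]["auc"].append(auc)
    records = []
    for spec in specs:
        tss = np.array(rows[spec.name]["tss"])
        auc = np.array(rows[spec.name]["auc"])
        n = len(tss)
        records.append(
            {
                "learner": spec.name,
                "tss_mean": tss.mean() if n else np.nan,
                "tss_se": tss.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "auc_mean": auc.mean() if n else np.nan,
                "auc_se": auc.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n_runs": n,
            }
        )
    table = pd.DataFrame(records).set_index("learner")
    return CvScores(table=table, folds=folds, replicates=replicates)


def select_members(
    scores: CvScores,
    tss_min: float = DEFAULT_TSS_MIN,
    auc_min: float = DEFAULT_AUC_MIN,
) -> tuple[list[str], pd.DataFrame]:
    """Gate learners on mean TSS > tss_min and mean AUC > auc_min (strict).

    Returns the included names and an exclusion report naming each failing
    statistic.  An empty inclusion set raises.
    """
    included, excluded = [], []
    for name, row in scores.table.iterrows():
        fails = []
        if not row["tss_mean"] > tss_min:
            fails.append(f"TSS {row['tss_mean']:.3f} <= {tss_min}")
        if not row["auc_mean"] > auc_min:
            fails.append(f"AUC {row['auc_mean']:.3f} <= {auc_min}")
        if fails:
            excluded.append({"learner": name, "reason": "; ".join(fails)})
            log.info("excluded %s: %s", name, "; ".join(fails))
        else:
            included.append(name)
    if not included:
        raise ModellingError(
            "no learner passed the gates; review tss_min/auc_min or the data"
        )
    return included, pd.DataFrame(excluded, columns=["learner", "reason"])


@dataclass
class EnsembleModel:
    """Gated, weighted set of learners fitted on the full table."""

    members: list[FittedLearner]
    weights: np.ndarray
    tss_min: float
    auc_min: float
    weighting: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.members):
            raise ModellingError("one weight per member required")
        if (self.weights < 0).any():
            raise ModellingError("weights must be non-negative")
        self.weights = self.weights / self.weights.sum()

    @property
    def member_names(self) -> list[str]:
        return [m.spec.name for m in self.members]

    def predict(self, env: pd.DataFrame) -> np.ndarray:
        preds = np.column_stack([m.predict(env) for m in self.members])
        return preds @ self.weights


def build_ensemble(
    included: list[str],
    scores: CvScores,
    env: pd.DataFrame,
    response: np.ndarray,
    weighting: str = "equal",
    seed: int = 0,
    specs: list[LearnerSpec] | None = None,
    tss_min: float = DEFAULT_TSS_MIN,
    auc_min: float = DEFAULT_AUC_MIN,
) -> EnsembleModel:
    """Refit the gated members on the full table and combine them.

    ``weighting`` is "equal" (default) or "tss_proportional" (weights
    proportional to mean cross-validated TSS).
    """
    if weighting not in ("equal", "tss_proportional"):
        raise ModellingError(f"unknown weighting '{weighting}'")
    by_name = {s.name: s for s in (specs or default_specs())}
    members = [fit_learner(by_name[n], env, response, seed=seed) for n in included]
    if weighting == "equal":
        w = np.ones(len(members))
    else:
        w = scores.table.loc[included, "tss_mean"].to_numpy(dtype=float)
    return EnsembleModel(
        members=members, weights=w, tss_min=tss_min, auc_min=auc_min,
        weighting=weighting,
    )


# ---------------------------------------------------------------------------
# interpretation

def _permutation_importance_once(
    ensemble: EnsembleModel,
    env: pd.DataFrame,
    variable: str,
    perm: np.ndarray,
    base_pred: np.ndarray,
) -> float:
    """1 - Pearson r between original and variable-permuted predictions."""
    shuffled = env.copy()
    shuffled[variable] = env[variable].to_numpy()[perm]
    pred = ensemble.predict(shuffled)
    if np.std(base_pred) == 0 or np.std(pred) == 0:
        return 0.0
    r = np.corrcoef(base_pred, pred)[0, 1]
    return float(np.clip(1.0 - r, 0.0, 1.0))


def variable_importance(
    ensemble: EnsembleModel,
    env: pd.DataFrame,
    n_perm: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance per variable: mean ± SE over shuffles of
    1 - cor(prediction, prediction with that variable permuted), in [0, 1]."""
    rng = np.random.default_rng(seed)
    base = ensemble.predict(env)
    if np.std(base) == 0:
        log.warning("constant ensemble predictions; importances set to 0")
        return pd.DataFrame(
            {"importance": 0.0, "se": 0.0}, index=list(env.columns)
        )
    records = {}
    for var in env.columns:
        vals = [
            _permutation_importance_once(
                ensemble, env, var, rng.permutation(len(env)), base
            )
            for _ in range(n_perm)
        ]
        vals = np.array(vals)
        records[var] = {
            "importance": vals.mean(),
            "se": vals.std(ddof=1) / np.sqrt(n_perm) if n_perm > 1 else np.nan,
        }
    return pd.DataFrame(records).T[["importance", "se"]]


def response_curve(
    ensemble: EnsembleModel, env: pd.DataFrame, variable: str, n_grid: int = 100
) -> pd.DataFrame:
    """Evaluation-strip response curve: sweep one variable over its observed
    range with every other variable held at its median."""
    if variable not in env.columns:
        raise ModellingError(f"unknown variable '{variable}'")
    grid = np.linspace(env[variable].min(), env[variable].max(), n_grid)
    strip = pd.DataFrame(
        {c: np.full(n_grid, env[c].median()) for c in env.columns}
    )
    strip[variable] = grid
    return pd.DataFrame({"value": grid, "suitability": ensemble.predict(strip)})
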