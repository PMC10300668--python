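"""Four-learner habitat-suitability ensemble.

Feature assembly from point records and raster stacks, normalization,
collinearity screening (single-linkage on |Pearson r|), random-forest
backward variable selection with a 1-SE parsimony rule, four tuned member
models (GLM, GAM, RF, BRT) under repeated stratified 10-fold
cross-validation maximizing out-of-sample AUC, an unweighted ensemble
(arithmetic mean of member probabilities), rank-based AUC / TSS evaluation,
correlation-metric permutation variable importance, and response curves.

Member families:

* GLM — logistic regression, linear terms, one-hot categoricals with a
  reference level.
* GAM — logistic model with penalized smooth terms: a cubic B-spline basis
  (~9 functions) on each continuous feature with an L2 penalty on the basis
  coefficients; the ridge strength is the tuned smoothing parameter.
* RF — random forest (500 trees by default), tuned over ``mtry`` (the
  number of candidate features per split).
* BRT — gradient-boosted trees, tuned over learning rate / depth / trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer

from .rasters import EnvStack, GridSpec, OccurrenceSet, SuitabilityMap

MEMBER_KINDS = ("GLM", "GAM", "RF", "BRT")


@dataclass
class FeatureTable:
    """Point-level modelling table: binary label + named features.

    Continuous features are floats (standardized before fitting);
    categorical features hold integer level codes indexing
    ``categorical[name]``.
    """

    df: pd.DataFrame
    continuous: list[str]
    categorical: dict[str, list[str]]

    def __post_init__(self) -> None:
        if "label" not in self.df.columns:
            raise ValueError("feature table needs a 'label' column")
        labels = set(self.df["label"].unique().tolist())
        if not labels <= {0, 1}:
            raise ValueError("labels must be 0/1")
        for name in self.feature_names:
            if self.df[name].isna().any():
                raise ValueError(f"missing values in feature {name!r}")

    @property
    def feature_names(self) -> list[str]:
        return self.continuous + list(self.categorical)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        names = list(names)
        cont = [n for n in self.continuous if n in names]
        cat = {n: lv for n, lv in self.categorical.items() if n in names}
        cols = ["label"] + cont + list(cat)
        return FeatureTable(self.df[cols].copy(), cont, cat)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CVSpec:
    k: int = 10
    repeats: int = 25

    def __post_init__(self) -> None:
        if self.k < 2 or self.repeats < 1:
            raise ValueError("need k >= 2 folds and repeats >= 1")


@dataclass
class Preprocessor:
    """Center/scale parameters for continuous features; fixed level rosters."""

    centers: dict[str, float]
    scales: dict[str, float]
    categorical_levels: dict[str, list[str]]


@dataclass
class MemberModel:
    kind: str
    tuned_params: dict
    model: object
    cv_auc: float
    cv_tss: float
    features: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.model.predict_proba(X)[:, 1]
        return np.clip(p, 0.0, 1.0)


@dataclass
class FittedEnsemble:
    members: dict[str, MemberModel]
    preprocessor: Preprocessor
    selected_features: list[str]
    continuous: list[str]
    categorical: dict[str, list[str]]
    cv_spec: CVSpec

    def __post_init__(self) -> None:
        missing = [k for k in MEMBER_KINDS if k not in self.members]
        if missing:
            raise ValueError(f"ensemble missing members: {missing}")


@dataclass
class EvalReport:
    auc: float
    tss: float
    sensitivity: float
    specificity: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "tss": self.tss,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
        }


@dataclass
class ImportanceReport:
    """Relative variable importance (normalized to sum 1)."""

    rvi: dict[str, float]

    def top_feature(self) -> str:
        return max(self.rvi, key=lambda k: self.rvi[k])


# ---------------------------------------------------------------------------
# Feature assembly and preprocessing


def extract_features(
    points: OccurrenceSet, labels: Sequence[int], stack: EnvStack
) -> FeatureTable:
    """Read per-point features from the cell containing each point."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(points):
        raise ValueError("labels length must match points")
    row, col = stack.grid.cell_of(points.x, points.y)
    if (row < 0).any():
        raise ValueError("point outside grid extent")
    if not stack.grid.mask[row, col].all():
        raise ValueError("point on masked cell")
    data: dict[str, np.ndarray] = {"label": labels}
    cont: list[str] = []
    cat: dict[str, list[str]] = {}
    for name, layer in stack.layers.items():
        vals = np.asarray(layer.values)[row, col]
        if layer.kind == "continuous":
            cont.append(name)
            data[name] = vals.astype(float)
        else:
            cat[name] = list(layer.levels or [])
            data[name] = vals.astype(int)
    return FeatureTable(pd.DataFrame(data), cont, cat)


def fit_preprocessor(table: FeatureTable) -> Preprocessor:
    centers: dict[str, float] = {}
    scales: dict[str, float] = {}
    for name in table.continuous:
        v = table.df[name].to_numpy(dtype=float)
        sd = float(v.std(ddof=0))
        if sd < 1e-12:
            raise ValueError(f"zero-variance continuous feature {name!r}")
        centers[name] = float(v.mean())
        scales[name] = sd
    return Preprocessor(centers, scales, dict(table.categorical))


def apply_preprocessor(p: Preprocessor, x: FeatureTable | EnvStack):
    """Standardize continuous features/layers with the training parameters."""
    if isinstance(x, FeatureTable):
        df = x.df.copy()
        for name in x.continuous:
            if name in p.centers:
                df[name] = (df[name] - p.centers[name]) / p.scales[name]
        return FeatureTable(df, x.continuous, x.categorical)
    if isinstance(x, EnvStack):
        out = x.copy()
        for name, layer in out.layers.items():
            if layer.kind == "continuous" and name in p.centers:
                layer.values = (layer.values - p.centers[name]) / p.scales[name]
        return out
    raise TypeError(f"cannot apply preprocessor to {type(x)!r}")


def drop_zero_variance(table: FeatureTable) -> FeatureTable:
    """Remove zero-variance continuous features (with a warning)."""
    keep = []
    for name in table.continuous:
        if table.df[name].to_numpy(dtype=float).std(ddof=0) < 1e-12:
            warnings.warn(f"dropping zero-variance feature {name!r}")
        else:
            keep.append(name)
    return table.subset_features(keep + list(table.categorical))


# ---------------------------------------------------------------------------
# Collinearity screening


def collinearity_filter(table: FeatureTable, cutoff: float = 0.7) -> list[str]:
    """Single-linkage grouping of continuous features at |r| >= cutoff.

    One representative per group is kept: the member with the largest
    absolute point-biserial correlation with the label (ties broken
    alphabetically). Categorical features are exempt. Returns retained
    feature names in table order.
    """
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must be in (0, 1)")
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    cont = table.continuous
    if not cont:
        return table.feature_names
    X = table.df[cont].to_numpy(dtype=float)
    y = table.labels.astype(float)
    r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    parent = list(range(len(cont)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(cont)):
        for j in range(i + 1, len(cont)):
            if abs(r[i, j]) >= cutoff:
                parent[find(i)] = find(j)
    label_r = np.array(
        [abs(np.corrcoef(X[:, i], y)[0, 1]) if X[:, i].std() > 0 else 0.0
         for i in range(len(cont))]
    )
    groups: dict[int, list[int]] = {}
    for i in range(len(cont)):
        groups.setdefault(find(i), []).append(i)
    keep: set[str] = set()
    for members in groups.values():
        best = sorted(members, key=lambda i: (-label_r[i], cont[i]))[0]
        keep.add(cont[best])
    return [n for n in table.feature_names if n in keep or n in table.categorical]


# ---------------------------------------------------------------------------
# Design matrices


def _design(table: FeatureTable, features: Sequence[str] | None = None):
    """Numeric design matrix: continuous as-is, categoricals one-hot
    (reference level dropped). Returns (X, continuous column indices)."""
    features = list(features) if features is not None else table.feature_names
    cols: list[np.ndarray] = []
    cont_idx: list[int] = []
    j = 0
    for name in features:
        if name in table.continuous:
            cols.append(table.df[name].to_numpy(dtype=float))
            cont_idx.append(j)
            j += 1
        elif name in table.categorical:
            codes = table.df[name].to_numpy(dtype=int)
            for lv in range(1, len(table.categorical[name])):
                cols.append((codes == lv).astype(float))
                j += 1
        else:
            raise KeyError(f"unknown feature {name!r}")
    X = np.column_stack(cols) if cols else np.empty((len(table), 0))
    return X, cont_idx


# ---------------------------------------------------------------------------
# Evaluation metrics


def auc_score(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Rank-based AUC: P(random presence outranks random absence), ties ½."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(predictions)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(
    predictions: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """AUC, sensitivity/specificity at ``prediction > threshold``, TSS."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=float)
    auc = auc_score(labels, predictions)
    pos = predictions > threshold
    sens = float(pos[labels == 1].mean())
    spec = float((~pos)[labels == 0].mean())
    return EvalReport(auc, sens + spec - 1.0, sens, spec, threshold)


# ---------------------------------------------------------------------------
# Member models


def _build_estimator(kind: str, params: Mapping, cont_idx: list[int], seed: int):
    params = dict(params)
    if kind == "GLM":
        return LogisticRegression(penalty=None, max_iter=2000)
    if kind == "GAM":
        spline = SplineTransformer(
            n_knots=int(params.get("n_knots", 7)), degree=3, include_bias=False
        )
        ct = ColumnTransformer(
            [("smooth", spline, cont_idx)], remainder="passthrough"
        )
        lr = LogisticRegression(C=float(params.get("C", 1.0)), max_iter=2000)
        return Pipeline([("basis", ct), ("logit", lr)])
    if kind == "RF":
        mtry = params.get("mtry", "sqrt")
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 500)),
            max_features=mtry,
            random_state=seed % (2**31),
            n_jobs=1,
        )
    if kind == "BRT":
        return GradientBoostingClassifier(
            learning_rate=float(params.get("learning_rate", 0.1)),
            max_depth=int(params.get("max_depth", 3)),
            n_estimators=int(params.get("n_estimators", 100)),
            random_state=seed % (2**31),
        )
    raise ValueError(f"unknown member kind {kind!r}")


def default_tuning_grids(fast: bool = False) -> dict[str, list[dict]]:
    """Per-member hyperparameter grids (``fast`` shrinks forests for tests)."""
    trees = 100 if fast else 500
    return {
        "GLM": [{}],
        "GAM": [{"C": 0.1}, {"C": 1.0}, {"C": 10.0}],
        "RF": [{"mtry": m, "n_estimators": trees} for m in (1, 2, "sqrt")],
        "BRT": [
            {"learning_rate": lr, "max_depth": d, "n_estimators": 100 if fast else 500}
            for lr in (0.01, 0.1)
            for d in (2, 3)
        ],
    }


def _cv_splits(labels: np.ndarray, cv: CVSpec, seed: int):
    splitter = RepeatedStratifiedKFold(
        n_splits=cv.k, n_repeats=cv.repeats, random_state=seed % (2**31)
    )
    return list(splitter.split(np.zeros(len(labels)), labels))


def fit_member(
    kind: str,
    table: FeatureTable,
    cv_spec: CVSpec,
    tuning_grid: Sequence[Mapping],
    seed: int,
    features: Sequence[str] | None = None,
) -> MemberModel:
    """Tune one member by repeated stratified k-fold CV, maximizing AUC.

    All grid points share one fold assignment (derived from ``seed``). Grid
    points whose fit fails are skipped with a warning; ties go to the first
    grid point in declared order. The winner is refit on all rows.
    """
    if not tuning_grid:
        raise ValueError("tuning grid must be non-empty")
    features = list(features) if features is not None else table.feature_names
    X, cont_idx = _design(table, features)
    y = table.labels
    splits = _cv_splits(y, cv_spec, seed)
    best_params: dict | None = None
    best_auc = -np.inf
    best_tss = np.nan
    for params in tuning_grid:
        fold_aucs: list[float] = []
        fold_tsss: list[float] = []
        try:
            for tr, te in splits:
                est = _build_estimator(kind, params, cont_idx, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr], y[tr])
                p = est.predict_proba(X[te])[:, 1]
                rep = evaluate(p, y[te])
                fold_aucs.append(rep.auc)
                fold_tsss.append(rep.tss)
        except Exception as exc:  # non-convergence etc.: skip this grid point
            warnings.warn(f"{kind} grid point {dict(params)} skipped: {exc}")
            continue
        mean_auc = float(np.mean(fold_aucs))
        if mean_auc > best_auc:
            best_auc = mean_auc
            best_tss = float(np.mean(fold_tsss))
            best_params = dict(params)
    if best_params is None:
        raise RuntimeError(f"no {kind} grid point fit successfully")
    final = _build_estimator(kind, best_params, cont_idx, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return MemberModel(kind, best_params, final, best_auc, best_tss, features)


# ---------------------------------------------------------------------------
# Variable selection


def rf_variable_selection(
    table: FeatureTable,
    cv_spec: CVSpec,
    seed: int,
    n_trees: int = 200,
    n_perm: int = 5,
) -> list[str]:
    """Backward elimination by RF permutation importance with a 1-SE rule.

    At each step the current feature set's CV AUC is recorded, an RF is fit
    on all rows, grouped permutation importance (AUC drop when one raw
    feature column is shuffled) is computed, and the least important feature
    is dropped. The selected set is the smallest whose CV AUC is within one
    standard error of the best. Deterministic per seed.
    """
    if len(table.feature_names) < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(seed)
    y = table.labels
    splits = _cv_splits(y, cv_spec, seed)
    current = list(table.feature_names)
    path: list[tuple[list[str], float, float]] = []
    while current:
        sub = table.subset_features(current)
        X, _ = _design(sub)
        fold_aucs = []
        for tr, te in splits:
            rf = RandomForestClassifier(
                n_estimators=n_trees, random_state=seed % (2**31), n_jobs=1
            )
            rf.fit(X[tr], y[tr])
            fold_aucs.append(auc_score(y[te], rf.predict_proba(X[te])[:, 1]))
        mean_auc = float(np.mean(fold_aucs))
        se = float(np.std(fold_aucs, ddof=1) / np.sqrt(len(fold_aucs)))
        path.append((list(current), mean_auc, se))
        if len(current) == 1:
            break
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed % (2**31), n_jobs=1
        )
        rf.fit(X, y)
        base = auc_score(y, rf.predict_proba(X)[:, 1])
        importances = {}
        for name in current:
            drops = []
            for _ in range(n_perm):
                shuffled = sub.df.copy()
                shuffled[name] = rng.permutation(shuffled[name].to_numpy())
                Xp, _ = _design(
                    FeatureTable(shuffled, sub.continuous, sub.categorical)
                )
                drops.append(base - auc_score(y, rf.predict_proba(Xp)[:, 1]))
            importances[name] = float(np.mean(drops))
        worst = min(current, key=lambda n: (importances[n], n))
        current = [n for n in current if n != worst]
    best_set, best_auc, best_se = max(path, key=lambda t: t[1])
    eligible = [(f, a) for f, a, _ in path if a >= best_auc - best_se]
    selected = min(eligible, key=lambda t: (len(t[0]), -t[1]))[0]
    return [n for n in table.feature_names if n in selected]


# ---------------------------------------------------------------------------
# Ensemble


def fit_ensemble(
    table: FeatureTable,
    cv_spec: CVSpec,
    grids: Mapping[str, Sequence[Mapping]] | None,
    seed: int,
    preprocessor: Preprocessor | None = None,
    selected_features: Sequence[str] | None = None,
) -> FittedEnsemble:
    """Fit all four members on identical rows/features.

    ``table`` must already be standardized; pass the fitted ``preprocessor``
    so projection rasters get the same transform.
    """
    grids = dict(grids) if grids else default_tuning_grids()
    features = (
        list(selected_features) if selected_features else table.feature_names
    )
    sub = table.subset_features(features)
    if preprocessor is None:
        preprocessor = Preprocessor({}, {}, dict(sub.categorical))
    members = {
        kind: fit_member(kind, sub, cv_spec, grids[kind], seed + i, features)
        for i, kind in enumerate(MEMBER_KINDS)
    }
    return FittedEnsemble(
        members, preprocessor, features, sub.continuous, sub.categorical, cv_spec
    )


def _ensemble_table(ens: FittedEnsemble, table: FeatureTable) -> FeatureTable:
    return table.subset_features(ens.selected_features)


def predict_members(ens: FittedEnsemble, table: FeatureTable) -> dict[str, np.ndarray]:
    sub = _ensemble_table(ens, table)
    X, _ = _design(sub)
    return {kind: m.predict(X) for kind, m in ens.members.items()}


def predict_ensemble(ens: FittedEnsemble, table: FeatureTable) -> np.ndarray:
    """Unweighted ensemble: arithmetic mean of the four member probabilities."""
    preds = predict_members(ens, table)
    return np.mean(np.column_stack([preds[k] for k in MEMBER_KINDS]), axis=1)


def model_averaged_metrics(ens: FittedEnsemble) -> tuple[float, float]:
    """(mean member CV AUC, mean member CV TSS) — the headline skill summary."""
    aucs = [m.cv_auc for m in ens.members.values()]
    tsss = [m.cv_tss for m in ens.members.values()]
    return float(np.mean(aucs)), float(np.mean(tsss))


# ---------------------------------------------------------------------------
# Importance and response curves


def variable_importance(
    ens: FittedEnsemble, table: FeatureTable, n_perm: int = 10, seed: int = 0
) -> ImportanceReport:
    """Correlation-metric permutation importance, normalized to sum 1.

    For each feature and member: permute the raw feature column ``n_perm``
    times and take the mean of (1 − Pearson r) between the member's
    predictions before and after permutation. Member scores are averaged,
    then normalized across features.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    sub = _ensemble_table(ens, table)
    X, _ = _design(sub)
    orig = {k: m.predict(X) for k, m in ens.members.items()}
    raw: dict[str, float] = {}
    for name in ens.selected_features:
        member_scores = []
        for kind, member in ens.members.items():
            p0 = orig[kind]
            vals = []
            for _ in range(n_perm):
                shuffled = sub.df.copy()
                shuffled[name] = rng.permutation(shuffled[name].to_numpy())
                Xp, _ = _design(
                    FeatureTable(shuffled, sub.continuous, sub.categorical)
                )
                pp = member.predict(Xp)
                if p0.std() < 1e-12 or pp.std() < 1e-12:
                    vals.append(0.0)
                else:
                    vals.append(1.0 - float(np.corrcoef(p0, pp)[0, 1]))
            member_scores.append(float(np.mean(vals)))
        raw[name] = float(np.mean(member_scores))
    total = sum(raw.values())
    if total <= 0:
        rvi = {n: 1.0 / len(raw) for n in raw}
    else:
        rvi = {n: v / total for n, v in raw.items()}
    return ImportanceReport(rvi)


def response_curves(
    ens: FittedEnsemble, table: FeatureTable, feature: str, n_steps: int = 25
):
    """Ensemble prediction as one feature varies, others held at centre.

    Continuous features sweep their observed range over ``n_steps`` points;
    categorical features take each level. Other continuous features are
    fixed at their training mean, other categoricals at their modal level.
    Returns (grid values, mean predictions).
    """
    if feature not in ens.selected_features:
        raise KeyError(f"feature {feature!r} not in selected set")
    sub = _ensemble_table(ens, table)
    base: dict[str, float] = {}
    for name in sub.continuous:
        base[name] = float(sub.df[name].mean())
    for name in sub.categorical:
        base[name] = int(sub.df[name].mode().iloc[0])
    if feature in sub.continuous:
        lo = float(sub.df[feature].min())
        hi = float(sub.df[feature].max())
        grid_vals = np.linspace(lo, hi, n_steps)
    else:
        grid_vals = np.arange(len(sub.categorical[feature]))
    rows = pd.DataFrame([dict(base, label=0) for _ in grid_vals])
    rows[feature] = grid_vals
    probe = FeatureTable(rows, sub.continuous, sub.categorical)
    preds = predict_ensemble(ens, probe)
    return grid_vals, preds
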