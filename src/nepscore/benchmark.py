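"""Cohort-distinction benchmark.

Per-image NEP scores are vectorized into feature vectors (one feature
per ordered cell-type pair, index-type-major order; non-directional
scores are copied to both directions), a random forest is trained on
repeated stratified 80/20 splits with 5-fold cross-validated tuning, and
the held-out F1 plus feature importances are reported.  Feature
importances are compared against the ground-truth adjacency difference
H_a - H_b via scaled cosine similarity, (cos theta + 1) / 2.

Baselines: the same protocol on cell-type abundance features, and on
randomly shuffled cohort labels (F1 ~ 0.5 = no signal in a balanced
binary problem).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score as _sk_f1
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .errors import ParameterError, ValidationError
from .simulate import AdjacencySpec


def f1(tp: int, fp: int, fn: int) -> float:
    """F1 = 2 TP / (2 TP + FP + FN); NaN when all counts are zero."""
    if min(tp, fp, fn) < 0:
        raise ParameterError("counts must be nonnegative")
    denom = 2 * tp + fp + fn
    if denom == 0:
        return float("nan")
    return 2.0 * tp / denom


def scaled_cosine(a, b) -> float:
    """(cos theta + 1) / 2 in [0, 1]; NaN (with no exception) for a zero
    vector."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        import warnings

        warnings.warn("zero vector in cosine similarity; returning NaN")
        return float("nan")
    return (float(a @ b) / (na * nb) + 1.0) / 2.0


def pair_columns(type_names) -> list[str]:
    """Feature-column names, index-type-major: t0->t0, t0->t1, ..."""
    return [f"{a}->{b}" for a in type_names for b in type_names]


def ground_truth_vector(spec_a: AdjacencySpec, spec_b: AdjacencySpec) -> np.ndarray:
    """Vectorized H_a - H_b in feature-column (index-major) order."""
    if spec_a.k_types != spec_b.k_types:
        raise ValidationError("adjacency specs have different K")
    return (spec_a.H - spec_b.H).ravel()


def scores_to_features(
    scores: pd.DataFrame, score_name: str, type_names, fill_missing: float = 0.0
) -> pd.DataFrame:
    """Wide per-image feature matrix from a long score table.

    Non-directional scores (stored once per unordered pair) are copied to
    both directions.  Missing scores (absent pairs, degenerate nulls) are
    imputed with ``fill_missing`` (default 0 = no evidence of preference).
    """
    sub = scores[scores["score_name"] == score_name]
    if len(sub) == 0:
        raise ValidationError(f"no rows with score_name={score_name!r}")
    wide = sub.pivot_table(
        index="image_id", columns=["index_type", "neighbor_type"],
        values="score_value", aggfunc="first", dropna=False,
    )
    nondirectional = score_name == "cpscore"

    def _column(key):
        if key in wide.columns and wide[key].notna().any():
            return wide[key]
        return None

    cols = {}
    for a in type_names:
        for b in type_names:
            col = _column((a, b))
            if col is None and nondirectional:  # copy A-B to represent B-A
                col = _column((b, a))
            if col is None:
                col = pd.Series(np.nan, index=wide.index)
            cols[f"{a}->{b}"] = col
    X = pd.DataFrame(cols, index=wide.index)
    return X.fillna(fill_missing)


def abundance_features(cells_df: pd.DataFrame, type_names) -> pd.DataFrame:
    """Per-image cell-type proportions (the abundance-only baseline)."""
    counts = (
        cells_df.groupby(["image_id", "cell_type"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(type_names), fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


@dataclass
class BenchmarkReport:
    """Results of one cohort comparison."""

    comparison: tuple[str, str]
    f1_scores: list[float]
    importances: np.ndarray  # mean over repeats, per feature
    feature_names: list[str]
    cosine_raw: float | None = None
    cosine_scaled: float | None = None
    abundance_f1: list[float] = field(default_factory=list)
    shuffled_f1: list[float] = field(default_factory=list)

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1_scores))

    def to_dict(self) -> dict:
        return {
            "comparison": list(self.comparison),
            "mean_f1": self.mean_f1,
            "f1_scores": [float(v) for v in self.f1_scores],
            "importances": {
                n: float(v) for n, v in zip(self.feature_names, self.importances)
            },
            "cosine_raw": self.cosine_raw,
            "cosine_scaled": self.cosine_scaled,
            "abundance_mean_f1": float(np.mean(self.abundance_f1))
            if self.abundance_f1 else None,
            "shuffled_mean_f1": float(np.mean(self.shuffled_f1))
            if self.shuffled_f1 else None,
        }


def _fit_and_score(X, y, seed, cv_folds=5, n_estimators=100):
    """One stratified 80/20 split; forest tuned by CV on the training
    split; returns (held-out F1, importances of the refit best model)."""
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=seed
    )
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    grid = GridSearchCV(
        rf,
        {"max_features": ["sqrt", 1.0]},
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        scoring="f1",
        n_jobs=1,
    )
    grid.fit(X_tr, y_tr)
    pred = grid.best_estimator_.predict(X_te)
    return _sk_f1(y_te, pred), grid.best_estimator_.feature_importances_


def classify_cohorts(
    X: pd.DataFrame,
    cohorts: pd.Series,
    n_repeats: int = 20,
    seed: int = 0,
    abundance: pd.DataFrame | None = None,
    with_baselines: bool = True,
    n_estimators: int = 100,
) -> BenchmarkReport:
    """Repeated split/train/evaluate on a two-cohort feature matrix.

    ``cohorts`` maps each row of ``X`` to its cohort label; exactly two
    cohorts are required, each with at least 10 images.  The
    lexicographically larger cohort is the positive class for F1.
    """
    cohorts = pd.Series(cohorts, index=X.index).astype(str)
    names = sorted(cohorts.unique())
    if len(names) != 2:
        raise ParameterError(f"need exactly 2 cohorts, got {names}")
    if (cohorts.value_counts() < 10).any():
        raise ParameterError("each cohort needs >= 10 images")
    y = (cohorts == names[1]).to_numpy().astype(int)
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    f1s, imps, ab_f1s, sh_f1s = [], [], [], []
    for rep in range(n_repeats):
        rs = int(rng.integers(2**31))
        s, imp = _fit_and_score(Xv, y, rs, n_estimators=n_estimators)
        f1s.append(float(s))
        imps.append(imp)
        if with_baselines:
            if abundance is not None:
                ab = abundance.reindex(X.index).to_numpy(dtype=float)
                ab_f1s.append(float(_fit_and_score(ab, y, rs,
                                                   n_estimators=n_estimators)[0]))
            y_sh = rng.permutation(y)
            sh_f1s.append(float(_fit_and_score(Xv, y_sh, rs,
                                               n_estimators=n_estimators)[0]))
    return BenchmarkReport(
        comparison=(names[0], names[1]),
        f1_scores=f1s,
        importances=np.mean(imps, axis=0),
        feature_names=list(X.columns),
        abundance_f1=ab_f1s,
        shuffled_f1=sh_f1s,
    )


def run_benchmark(
    scores: pd.DataFrame,
    cohort_of_image: dict[str, str],
    comparisons: list[tuple[str, str]],
    score_name: str,
    type_names,
    truth: dict[str, AdjacencySpec] | None = None,
    n_repeats: int = 20,
    seed: int = 0,
    cells_df: pd.DataFrame | None = None,
    with_baselines: bool = False,
    n_estimators: int = 100,
) -> dict[tuple[str, str], BenchmarkReport]:
    """End-to-end benchmark over a scored multi-cohort dataset.

    For each requested (cohort_a, cohort_b) comparison: assemble the
    feature matrix, classify, and — when ground-truth adjacency specs are
    supplied — attach the cosine similarity between the mean feature
    importances and vec(H_a - H_b).  Forest importances are nonnegative
    while the truth difference is signed; the scaled cosine therefore
    rewards importance mass on pairs whose adjacency probability
    increased from b to a and penalizes mass on pairs where it decreased.
    """
    X_all = scores_to_features(scores, score_name, type_names)
    cohort_series = pd.Series(
        {img: cohort_of_image.get(img) for img in X_all.index}, name="cohort"
    )
    missing = cohort_series.isna()
    if missing.any():
        raise ParameterError(
            f"images without cohort assignment: {list(X_all.index[missing][:5])}"
        )
    abundance = (
        abundance_features(cells_df, type_names) if cells_df is not None else None
    )
    available = set(cohort_series.unique())
    reports = {}
    for a, b in comparisons:
        if a not in available or b not in available:
            raise ParameterError(
                f"cohort(s) {a!r}/{b!r} not found; available: {sorted(available)}"
            )
        mask = cohort_series.isin([a, b])
        rep = classify_cohorts(
            X_all[mask], cohort_series[mask], n_repeats=n_repeats,
            seed=seed, abundance=abundance, with_baselines=with_baselines,
            n_estimators=n_estimators,
        )
        if truth and a in truth and b in truth:
            gt = ground_truth_vector(truth[a], truth[b])
            rep.cosine_scaled = scaled_cosine(rep.importances, gt)
            rep.cosine_raw = 2 * rep.cosine_scaled - 1
        reports[(a, b)] = rep
    return reports


def write_report(reports: dict, json_path, csv_path=None) -> None:
    """JSON (machine) + optional CSV (per-repeat F1) report files."""
    payload = {f"{a}_vs_{b}": r.to_dict() for (a, b), r in reports.items()}
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    if csv_path is not None:
        rows = []
        for (a, b), r in reports.items():
            for i, v in enumerate(r.f1_scores):
                rows.append({"comparison": f"{a}_vs_{b}", "repeat": i, "f1": v})
        pd.DataFrame(rows).to_csv(csv_path, index=False)
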