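"""Objective validation of the morphological classes.

Feature tables (cells x named morphometric features) are z-normalized,
screened for outlier cells, and summarized by feature power; unsupervised
structure is probed with PCA and the hypothesized class labels are tested
with LDA under ten rounds of ten-fold cross-validation, compared against
the same procedure run with randomized class assignments (Welch's t-test
on the fold scores).  A high-coefficient-of-variation drop list (by default
the two tortuosity features) is applied before normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureTable",
    "ValidationReport",
    "DEFAULT_DROP_FEATURES",
    "znormalize",
    "flag_outliers",
    "feature_power",
    "run_pca",
    "run_lda",
    "crossvalidate_randomized",
    "lda_group_study",
]

#: Features dropped before normalization for their high coefficient of
#: variation across reconstructions (the two tortuosity features).
DEFAULT_DROP_FEATURES = ("axon_tortuosity", "dend_tortuosity")


@dataclass
class FeatureTable:
    """Cells x features real matrix with optional class labels."""

    values: pd.DataFrame                 # index = cell ids, columns = features
    labels: pd.Series | None = None      # categorical, aligned with index

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.labels is not None:
            self.labels = pd.Series(self.labels, index=self.values.index)

    @property
    def cell_ids(self):
        return self.values.index

    @property
    def feature_names(self):
        return list(self.values.columns)


@dataclass
class ValidationReport:
    """Cross-validation scores against the label-randomized null."""

    actual_scores: np.ndarray       # rounds x folds accuracies, flattened
    randomized_scores: np.ndarray   # pooled over randomized replicates
    t_statistic: float
    p_value: float
    mean_actual: float = field(init=False)
    mean_randomized: float = field(init=False)

    def __post_init__(self) -> None:
        self.actual_scores = np.asarray(self.actual_scores, float)
        self.randomized_scores = np.asarray(self.randomized_scores, float)
        self.mean_actual = float(self.actual_scores.mean())
        self.mean_randomized = float(self.randomized_scores.mean())


def znormalize(table: FeatureTable, drop_features=None) -> FeatureTable:
    """Z-score every feature column (sample SD); drop constant columns.

    ``drop_features`` names are removed before normalization (pass () to
    keep everything; default drops :data:`DEFAULT_DROP_FEATURES` when
    present).  Constant columns are dropped with a warning.
    """
    if len(table.values) < 2:
        raise ValueError("need >= 2 cells to normalize")
    df = table.values.copy()
    if drop_features is None:
        drop_features = [c for c in DEFAULT_DROP_FEATURES if c in df.columns]
    df = df.drop(columns=list(drop_features), errors="raise")
    sd = df.std(ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(
            f"dropping constant features: {list(constant)}", stacklevel=2
        )
        df = df.drop(columns=constant)
        sd = sd.drop(constant)
    normalized = (df - df.mean()) / sd
    return FeatureTable(normalized, table.labels)


def flag_outliers(table: FeatureTable, sd_limit: float = 2.0) -> pd.DataFrame:
    """Cells whose normalized values exceed ``sd_limit`` SDs on any feature.

    Expects a z-normalized table; returns one row per flagged cell with the
    offending feature of largest magnitude and its z value.
    """
    z = table.values
    rows = []
    for cell in z.index:
        absz = z.loc[cell].abs()
        if (absz > sd_limit).any():
            worst = absz.idxmax()
            rows.append({
                "cell_id": cell,
                "max_abs_z": float(absz.max()),
                "worst_feature": worst,
                "n_offending": int((absz > sd_limit).sum()),
            })
    return pd.DataFrame(rows, columns=["cell_id", "max_abs_z",
                                       "worst_feature", "n_offending"])


def feature_power(table: FeatureTable, labels=None) -> pd.DataFrame:
    """Per-feature discriminative power against the class labels.

    ``variance`` is the pooled within-class variance of the z-scored
    feature (low = tight classes); ``var_ratio`` is between-class variance
    over total variance (high = discriminative).  Classes with one member
    are excluded from the pooling.  Features are ranked by ``var_ratio``
    descending.
    """
    labels = table.labels if labels is None else pd.Series(labels, index=table.values.index)
    if labels is None:
        raise ValueError("labels required for feature power")
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    usable = [c for c in classes if (labels == c).sum() >= 2]
    out = []
    grand = table.values.mean()
    total_var = table.values.var(ddof=1)
    for feat in table.values.columns:
        x = table.values[feat]
        within = []
        between = []
        for c in usable:
            xs = x[labels == c]
            within.append((len(xs) - 1) * xs.var(ddof=1))
            between.append(len(xs) * (xs.mean() - grand[feat]) ** 2)
        n_used = int(sum((labels == c).sum() for c in usable))
        pooled_var = float(sum(within) / max(n_used - len(usable), 1))
        tv = float(total_var[feat])
        vr = float(sum(between) / ((len(x) - 1) * tv)) if tv > 0 else 0.0
        out.append({"feature": feat, "variance": pooled_var, "var_ratio": vr})
    return (
        pd.DataFrame(out)
        .sort_values("var_ratio", ascending=False)
        .reset_index(drop=True)
    )


def run_pca(table: FeatureTable) -> dict:
    """Principal components of the normalized table.

    Returns orthonormal ``components`` (rows), ``explained_variance_fractions``
    summing to 1, and per-cell ``projections``.
    """
    if len(table.values) < 2:
        raise ValueError("need > 1 cell")
    x = table.values.to_numpy()
    pca = PCA()
    proj = pca.fit_transform(x)
    return {
        "components": pca.components_,
        "explained_variance_fractions": pca.explained_variance_ratio_,
        "projections": proj,
    }


def run_lda(table: FeatureTable, labels=None, n_components: int | None = None) -> dict:
    """Fisher discriminant projection of the labelled table.

    When the feature count exceeds cells - classes the within-class scatter
    is singular and Ledoit-Wolf shrinkage is applied (noted in the result).
    Projections are deterministic up to sign.
    """
    labels = table.labels if labels is None else pd.Series(labels, index=table.values.index)
    if labels is None:
        raise ValueError("labels required for LDA")
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 members")
    x = table.values.to_numpy()
    y = labels.to_numpy()
    n, p = x.shape
    shrunk = p > n - len(classes)
    if shrunk:
        lda = LinearDiscriminantAnalysis(
            solver="eigen", shrinkage="auto", n_components=n_components
        )
    else:
        lda = LinearDiscriminantAnalysis(solver="svd", n_components=n_components)
    proj = lda.fit_transform(x, y)
    return {
        "projections": proj,
        "class_means": {c: x[y == c].mean(axis=0) for c in classes},
        "weight_vectors": lda.scalings_.T if hasattr(lda, "scalings_") else None,
        "training_accuracy": float(lda.score(x, y)),
        "shrinkage_applied": shrunk,
        "estimator": lda,
    }


def _cv_scores(x: np.ndarray, y: np.ndarray, rounds: int, folds: int,
               rng: np.random.Generator, shrink: bool) -> np.ndarray:
    """Fold accuracies over ``rounds`` re-partitions of stratified k-fold CV."""
    scores = []
    _, counts = np.unique(y, return_counts=True)
    eff_folds = int(min(folds, counts.min()))
    if eff_folds < 2:
        raise ValueError("smallest class has < 2 members; cannot cross-validate")
    for _ in range(rounds):
        skf = StratifiedKFold(
            n_splits=eff_folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        for train, test in skf.split(x, y):
            if shrink:
                lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
            else:
                lda = LinearDiscriminantAnalysis(solver="svd")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lda.fit(x[train], y[train])
                scores.append(lda.score(x[test], y[test]))
    return np.array(scores)


def crossvalidate_randomized(
    table: FeatureTable,
    labels=None,
    rounds: int = 10,
    folds: int = 10,
    n_randomizations: int = 10,
    seed: int = 0,
) -> ValidationReport:
    """Label-preserving CV scores against a label-randomized null.

    Runs ``rounds`` repetitions of stratified ``folds``-fold LDA
    cross-validation with the true labels, then the same procedure
    ``n_randomizations`` times with shuffled labels.  The t-test compares
    the actual mean score against the distribution of randomized replicate
    mean scores (one observation per shuffle, Student reference with
    K - 1 degrees of freedom and a 1 + 1/K variance correction): fold
    scores within one label assignment are correlated through the shared
    data, so pooling them as independent observations would overstate the
    evidence; one mean per label assignment keeps the test level-correct
    on unstructured data.  Folds shrink to the smallest class when needed.
    Fully determined by ``seed``.
    """
    labels = table.labels if labels is None else pd.Series(labels, index=table.values.index)
    if labels is None or labels.nunique() < 2:
        raise ValueError("need >= 2 classes for a validation run")
    x = table.values.to_numpy()
    y = labels.to_numpy()
    rng = np.random.default_rng(seed)
    shrink = x.shape[1] > x.shape[0] - labels.nunique()
    actual = _cv_scores(x, y, rounds, folds, rng, shrink)
    randomized = []
    rep_means = []
    for _ in range(n_randomizations):
        y_shuf = rng.permutation(y)
        scores = _cv_scores(x, y_shuf, rounds, folds, rng, shrink)
        randomized.append(scores)
        rep_means.append(scores.mean())
    randomized_arr = np.concatenate(randomized)
    rep_means_arr = np.array(rep_means)
    k = len(rep_means_arr)
    null_sd = rep_means_arr.std(ddof=1)
    diff = actual.mean() - rep_means_arr.mean()
    if null_sd == 0:
        t = np.inf if diff != 0 else 0.0
        p = 0.0 if diff != 0 else 1.0
    else:
        t = diff / (null_sd * np.sqrt(1.0 + 1.0 / k))
        p = float(2.0 * stats.t.sf(abs(t), df=k - 1))
    return ValidationReport(actual, randomized_arr, float(t), float(p))


def lda_group_study(
    table: FeatureTable,
    labels=None,
    drop_groups=("DAC",),
    merge_groups=(("NGC-DA", "NGC-SA"), ),
    merged_name: str = "NGC",
    **cv_kwargs,
) -> dict[str, ValidationReport]:
    """The three-scenario LDA study: all classes, minus a group, groups merged.

    Returns a ValidationReport per scenario (``full``, ``drop:<name>``,
    ``merge:<name>``).  Unknown group names raise.
    """
    labels = table.labels if labels is None else pd.Series(labels, index=table.values.index)
    if labels is None:
        raise ValueError("labels required")
    present = set(labels.unique())
    reports: dict[str, ValidationReport] = {}
    reports["full"] = crossvalidate_randomized(table, labels, **cv_kwargs)
    for g in drop_groups:
        if g not in present:
            raise ValueError(f"unknown group {g!r}")
        keep = labels != g
        sub = FeatureTable(table.values.loc[keep], labels[keep])
        reports[f"drop:{g}"] = crossvalidate_randomized(sub, **cv_kwargs)
    for group_set in merge_groups:
        missing = [g for g in group_set if g not in present]
        if missing:
            raise ValueError(f"unknown groups {missing}")
        merged = labels.replace({g: merged_name for g in group_set})
        reports[f"merge:{merged_name}"] = crossvalidate_randomized(
            table, merged, **cv_kwargs
        )
    return reports
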