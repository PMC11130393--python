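"""Cross-omics subtype label transfer via quartile tiers and probabilistic SVC.

Proteomic subtype labels are transferred to other layers (transcriptomes, cell
lines, IHC panels) by (1) gating features on tabulated protein-mRNA Spearman
correlation, (2) discretizing each layer by its own per-feature quartiles with
the 2nd and 3rd quartile pooled (low / medium / high), (3) a support-vector
classifier with calibrated class probabilities, assigning a label only when
the maximum class probability clears a confidence floor, and (4) resampled
recursive feature elimination for compact marker panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import RFE
from sklearn.model_selection import cross_val_score, train_test_split
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_gate",
    "quartile_tier_transform",
    "TierMatrix",
    "deduplicate_features",
    "train_transfer_classifier",
    "predict_with_floor",
    "resampled_rfe",
    "SubtypeTransferModel",
    "SubtypeTransferResults",
]

TIER_CODES = {"low": 0, "medium": 1, "high": 2}


@dataclass
class TierMatrix:
    """Features x samples ordinal matrix in {0: low, 1: medium, 2: high}."""

    tiers: pd.DataFrame
    #: per-feature (Q1, Q3) thresholds retained for audit
    thresholds: pd.DataFrame = field(default_factory=pd.DataFrame)


def correlation_gate(
    features: list[str], corr_table: pd.DataFrame, rho_min: float = 0.75
) -> list[str]:
    """Retain features whose tabulated correlation is >= rho_min (inclusive).

    Features missing from the table are dropped with a warning; an empty
    result is an error (the threshold is too strict for the data at hand).
    """
    rho = corr_table.set_index("feature").rho
    missing = [f for f in features if f not in rho.index]
    if missing:
        logger.warning("%d feature(s) missing from the correlation table; dropped",
                       len(missing))
    kept = [f for f in features if f in rho.index and rho[f] >= rho_min]
    if not kept:
        raise ValueError(
            f"no feature passes the correlation gate at rho >= {rho_min}; "
            "consider a lower threshold"
        )
    return kept


def quartile_tier_transform(values: pd.DataFrame) -> TierMatrix:
    """Per-feature quartile discretization with the middle quartiles pooled.

    For each feature (row): x < Q1 -> low, Q1 <= x <= Q3 -> medium,
    x > Q3 -> high; quartiles are linearly interpolated order statistics of
    the feature's own finite values.  Boundary values fall in the medium tier.
    A constant feature becomes all-medium with a warning.  Because quartiles
    are rank statistics the transform is invariant under strictly monotone
    increasing transformations of a feature.
    """
    tiers = pd.DataFrame(1, index=values.index, columns=values.columns, dtype=int)
    thresholds = pd.DataFrame(index=values.index, columns=["q1", "q3"], dtype=float)
    for feat, row in values.iterrows():
        finite = row[np.isfinite(row.astype(float))]
        if len(finite) < 4:
            raise ValueError(f"feature {feat} has fewer than 4 finite values")
        q1, q3 = np.quantile(finite.astype(float), [0.25, 0.75])
        thresholds.loc[feat] = (q1, q3)
        if q1 == q3:
            logger.warning("feature %s is (near-)constant; all samples tiered medium", feat)
            continue
        tiers.loc[feat] = np.where(row < q1, 0, np.where(row > q3, 2, 1))
    return TierMatrix(tiers=tiers, thresholds=thresholds)


def deduplicate_features(
    values: pd.DataFrame, rho_max: float = 0.7, seed: int = 0
) -> list[str]:
    """Keep one representative of each correlated feature group.

    Features are visited in a seeded shuffled order; a feature is kept only if
    its absolute Spearman correlation with every already-kept feature is below
    ``rho_max`` (a single randomly retained feature per correlated group).
    """
    rng = np.random.default_rng(seed)
    order = list(values.index)
    rng.shuffle(order)
    corr = values.T.corr(method="spearman").abs()
    kept: list[str] = []
    for feat in order:
        if all(corr.loc[feat, k] < rho_max for k in kept):
            kept.append(feat)
    return sorted(kept, key=list(values.index).index)


def train_transfer_classifier(
    tiers: pd.DataFrame,
    labels: pd.Series,
    kernel: str = "rbf",
    min_class_size: int = 5,
    seed: int = 0,
) -> SVC:
    """Fit a probabilistic SVC on a tiered training matrix (features x samples).

    Radial-basis kernel by default (a linear kernel suits very small marker
    panels); class-membership probabilities come from the standard
    pairwise-coupling calibration.  Any classifier exposing predict_proba
    could substitute; this is the reference configuration.
    """
    y = labels.reindex(tiers.columns)
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("training needs >= 2 classes")
    small = counts[counts < min_class_size]
    if len(small):
        raise ValueError(f"class(es) with < {min_class_size} training samples: "
                         f"{small.to_dict()}")
    clf = SVC(kernel=kernel, probability=True, random_state=seed)
    clf.fit(tiers.T.to_numpy(float), y.to_numpy())
    return clf


def predict_with_floor(
    classifier: SVC,
    tiers: pd.DataFrame,
    floor: float = 0.5,
    train_features: list[str] | None = None,
) -> pd.DataFrame:
    """Class probabilities with a confidence floor; below it -> 'unclassified'.

    ``tiers`` must be tiered with the target layer's own quartiles (thresholds
    are layer-specific so the relative tier distributions match across
    layers).  Returns a frame with one probability column per class, the
    assigned label and the confidence (max probability).
    """
    if train_features is not None:
        missing = [f for f in train_features if f not in tiers.index]
        if missing:
            raise ValueError(f"target layer lacks training feature(s): {missing}")
        tiers = tiers.loc[train_features]
    probs = classifier.predict_proba(tiers.T.to_numpy(float))
    classes = classifier.classes_
    out = pd.DataFrame(probs, index=tiers.columns,
                       columns=[f"p_{c}" for c in classes])
    conf = probs.max(axis=1)
    label = np.asarray(classes, dtype=object)[probs.argmax(axis=1)]
    out["label"] = np.where(conf >= floor, label, "unclassified")
    out["confidence"] = conf
    return out


def _rfe_nested_path(X, y, kernel, cv_folds, random_state):
    """Elimination order + CV score per nested feature-set size.

    Recursive elimination with a linear-weight estimator defines a nested
    family of feature sets (drop the lowest-|weight| feature one at a time);
    each set size is scored by stratified cross-validated accuracy.
    """
    n_feat = X.shape[1]
    ranking = RFE(SVC(kernel=kernel, random_state=random_state),
                  n_features_to_select=1, step=1).fit(X, y).ranking_
    means = np.empty(n_feat)
    sems = np.empty(n_feat)
    for size in range(1, n_feat + 1):
        idx = ranking <= size
        scores = cross_val_score(SVC(kernel=kernel, random_state=random_state),
                                 X[:, idx], y, cv=cv_folds)
        means[size - 1] = scores.mean()
        sems[size - 1] = scores.std(ddof=1) / np.sqrt(len(scores))
    return ranking, means, sems


def resampled_rfe(
    values: pd.DataFrame,
    labels: pd.Series,
    n_runs: int = 50,
    holdout: float = 0.2,
    cv_folds: int = 5,
    seed: int = 0,
    kernel: str = "linear",
    parsimony: bool = True,
) -> pd.DataFrame:
    """Feature selection frequencies over resampled recursive elimination.

    Per run: hold out ``holdout`` of the samples (stratified), rank features
    by recursive elimination of the lowest linear-SVC weight, score every
    nested feature-set size by ``cv_folds``-fold cross-validated accuracy,
    and keep the chosen set.  With ``parsimony`` (default) the smallest size
    whose mean CV score is within one standard error of the best is chosen -
    without it, uninformative features are retained freely whenever the CV
    curve is flat; ``parsimony=False`` keeps the raw best-scoring size.
    Features are ranked by selection frequency across runs, ties broken by
    the mean CV accuracy of the runs where the feature was selected, then
    lexicographic.

    Returns a frame indexed by feature with columns (frequency, mean_cv_score,
    rank), sorted by rank.
    """
    if n_runs < 2:
        raise ValueError("resampling needs n_runs >= 2")
    y = labels.reindex(values.columns)
    if y.nunique() < 2:
        raise ValueError("labels are degenerate (single class)")
    X = values.T.to_numpy(float)
    feats = list(values.index)
    counts = pd.Series(0.0, index=feats)
    score_sum = pd.Series(0.0, index=feats)
    rng = np.random.default_rng(seed)
    for _ in range(n_runs):
        rs = int(rng.integers(0, 2**31 - 1))
        X_tr, _, y_tr, _ = train_test_split(
            X, y.to_numpy(), test_size=holdout, random_state=rs, stratify=y.to_numpy()
        )
        ranking, means, sems = _rfe_nested_path(X_tr, y_tr, kernel, cv_folds, rs)
        best = int(np.argmax(means))
        if parsimony:
            size = int(np.argmax(means >= means[best] - sems[best])) + 1
        else:
            size = best + 1
        cv_score = float(means[size - 1])
        for f, r in zip(feats, ranking):
            if r <= size:
                counts[f] += 1
                score_sum[f] += cv_score
    freq = counts / n_runs
    mean_score = (score_sum / counts.replace(0, np.nan)).fillna(0.0)
    report = pd.DataFrame({"frequency": freq, "mean_cv_score": mean_score})
    # ordering: frequency desc, mean CV score desc, name asc
    report = report.loc[
        sorted(report.index,
               key=lambda f: (-report.frequency[f], -report.mean_cv_score[f], f))
    ]
    report["rank"] = np.arange(1, len(report) + 1)
    return report


class SubtypeTransferModel:
    """Correlation-gated, tier-transformed subtype classifier across layers.

    Parameters
    ----------
    train_values : features x samples continuous matrix of the training layer
        (e.g. normalized protein ratios on tumor samples).
    labels : sample -> subtype label.
    corr_table : per-feature cross-layer correlation values ('feature', 'rho');
        None skips gating (e.g. same-layer panels).
    rho_min : correlation gate threshold (inclusive).
    dedup_rho : when set, drop correlated training features at this |Spearman|.
    """

    def __init__(
        self,
        train_values: pd.DataFrame,
        labels: pd.Series,
        corr_table: pd.DataFrame | None = None,
        rho_min: float = 0.75,
        kernel: str = "rbf",
        dedup_rho: float | None = None,
        seed: int = 0,
    ):
        self.train_values = train_values
        self.labels = labels
        self.corr_table = corr_table
        self.rho_min = rho_min
        self.kernel = kernel
        self.dedup_rho = dedup_rho
        self.seed = seed

    def fit(self) -> "SubtypeTransferResults":
        feats = list(self.train_values.index)
        if self.corr_table is not None:
            feats = correlation_gate(feats, self.corr_table, self.rho_min)
        values = self.train_values.loc[feats]
        if self.dedup_rho is not None:
            feats = deduplicate_features(values, rho_max=self.dedup_rho, seed=self.seed)
            values = values.loc[feats]
        tiered = quartile_tier_transform(values)
        clf = train_transfer_classifier(tiered.tiers, self.labels,
                                        kernel=self.kernel, seed=self.seed)
        return SubtypeTransferResults(self, clf, feats, tiered)


class SubtypeTransferResults:
    """Fitted transfer classifier; predicts any layer tiered on its own quartiles."""

    def __init__(self, model: SubtypeTransferModel, classifier: SVC,
                 features: list[str], train_tiers: TierMatrix):
        self.model = model
        self.classifier = classifier
        self.features = features
        self.train_tiers = train_tiers

    def predict(self, target_values: pd.DataFrame, floor: float = 0.5) -> pd.DataFrame:
        """Tier the target layer per-feature on its own quartiles and classify."""
        missing = [f for f in self.features if f not in target_values.index]
        if missing:
            raise ValueError(f"target layer lacks training feature(s): {missing}")
        tiered = quartile_tier_transform(target_values.loc[self.features])
        return predict_with_floor(self.classifier, tiered.tiers, floor=floor)

    def classified_fraction(self, predictions: pd.DataFrame) -> float:
        return float((predictions.label != "unclassified").mean())

    def summary(self) -> pd.DataFrame:
        """Training-layer class balance and feature count."""
        counts = self.model.labels.value_counts().rename("n_train")
        out = counts.to_frame()
        out.attrs["n_features"] = len(self.features)
        return out
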