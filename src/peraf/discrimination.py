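"""Diagnostic evaluation of regional amplitude features.

Two evaluations of how well regional mean PerAF separates patients from
controls:

* per-region ROC analysis — empirical curve over all thresholds, trapezoid
  AUC (equal to the normalised Mann-Whitney U statistic, ties counted 1/2),
  DeLong 95% confidence interval, and the Youden-optimal operating point;
* a linear soft-margin SVM evaluated by leave-one-out cross-validation,
  with features z-scored inside each training fold only (no leakage), and a
  permutation test that shuffles group labels and reruns the *entire*
  LOO procedure to build the null accuracy distribution.

The ROC is oriented so AUC >= 0.5 and the direction (whether lower values
indicate disease) is recorded — the planted effect, like the regional
amplitude decreases this pipeline targets, makes patients' values lower.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .errors import ValidationError
from .images import AmplitudeMap

POSITIVE_LABEL = "patient"
NEGATIVE_LABEL = "control"


@dataclass
class FeatureTable:
    """Subjects x regions matrix of mean regional amplitudes with labels."""

    subjects: list
    labels: list
    features: np.ndarray
    region_names: list

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        n, r = self.features.shape
        if len(self.subjects) != n or len(self.labels) != n:
            raise ValidationError("subjects/labels length != feature rows")
        if len(self.region_names) != r:
            raise ValidationError("region_names length != feature columns")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("feature matrix contains missing values")
        present = set(self.labels)
        if not {POSITIVE_LABEL, NEGATIVE_LABEL} <= present:
            raise ValidationError(
                f"both labels '{POSITIVE_LABEL}' and '{NEGATIVE_LABEL}' must be "
                f"present, got {sorted(present)}")

    @property
    def y(self) -> np.ndarray:
        """Binary label vector: 1 = patient, 0 = control."""
        return np.array([1 if lab == POSITIVE_LABEL else 0 for lab in self.labels])

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("subject\tlabel\t" + "\t".join(self.region_names) + "\n")
            for sid, lab, row in zip(self.subjects, self.labels, self.features):
                fh.write(f"{sid}\t{lab}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FeatureTable":
        lines = Path(path).read_text().strip().split("\n")
        header = lines[0].split("\t")
        if header[:2] != ["subject", "label"]:
            raise ValidationError(f"{path}: expected 'subject<TAB>label<TAB>...' header")
        subjects, labels, rows = [], [], []
        for line in lines[1:]:
            parts = line.split("\t")
            subjects.append(parts[0])
            labels.append(parts[1])
            rows.append([float(v) for v in parts[2:]])
        return cls(subjects=subjects, labels=labels, features=np.array(rows),
                   region_names=header[2:])


def extract_regional_means(maps: list[AmplitudeMap], cluster_labels: np.ndarray,
                           subjects: list, labels: list,
                           region_names: list | None = None) -> FeatureTable:
    """Mean map value per labelled region for every subject.

    ``cluster_labels`` is an integer 3D volume; region r is the voxel set
    with value r (r >= 1).
    """
    cluster_labels = np.asarray(cluster_labels)
    region_ids = sorted(int(v) for v in np.unique(cluster_labels) if v > 0)
    if not region_ids:
        raise ValidationError("cluster label volume contains no regions")
    if region_names is None:
        region_names = [f"cluster_{r}" for r in region_ids]
    masks = []
    for r, name in zip(region_ids, region_names):
        m = cluster_labels == r
        if not m.any():
            raise ValidationError(f"region '{name}' (label {r}) is empty")
        masks.append(m)
    feats = np.array([[m.data[mask].mean() for mask in masks] for m in maps])
    return FeatureTable(subjects=subjects, labels=labels, features=feats,
                        region_names=region_names)


# --------------------------------------------------------------------------
# ROC analysis


def mann_whitney_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the normalised pair-counting U statistic (ties count 1/2)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def roc_points(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical ROC over all thresholds: (fpr, tpr, thresholds).

    Thresholds are the distinct score values in descending order; a subject
    is called positive when score >= threshold.
    """
    order = np.argsort(-scores, kind="stable")
    scores_s, y_s = scores[order], y[order]
    distinct = np.r_[np.diff(scores_s) != 0, True]
    tps = np.cumsum(y_s)[distinct]
    fps = np.cumsum(1 - y_s)[distinct]
    tpr = np.r_[0.0, tps / max(y.sum(), 1)]
    fpr = np.r_[0.0, fps / max((1 - y).sum(), 1)]
    thresholds = np.r_[np.inf, scores_s[distinct]]
    return fpr, tpr, thresholds


def _delong_ci(scores: np.ndarray, y: np.ndarray, auc: float,
               level: float = 0.95) -> tuple[float, float]:
    """DeLong variance of the AUC via placement values, normal CI."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0))


@dataclass
class RocResult:
    region: str
    auc: float
    ci95: tuple[float, float]
    direction: str  # 'lower_in_patients' or 'higher_in_patients'
    cutoff: float
    sensitivity: float
    specificity: float
    curve_fpr: np.ndarray = field(repr=False, default=None)
    curve_tpr: np.ndarray = field(repr=False, default=None)
    n_patients: int = 0
    n_controls: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["curve_fpr"] = [float(v) for v in self.curve_fpr]
        d["curve_tpr"] = [float(v) for v in self.curve_tpr]
        d["ci95"] = list(self.ci95)
        return d


def roc_analysis(values: np.ndarray, labels: list, region: str = "feature") -> RocResult:
    """ROC of one feature column against the patient/control labels.

    The score orientation is chosen so AUC >= 0.5 (recording which
    direction indicates disease); the operating point maximises the Youden
    index J = sensitivity + specificity - 1, ties broken toward higher
    specificity.
    """
    values = np.asarray(values, dtype=float).ravel()
    y = np.array([1 if lab == POSITIVE_LABEL else 0 for lab in labels])
    if y.sum() == 0 or y.sum() == y.size:
        raise ValidationError("ROC needs both classes present")
    if y.sum() < 2 or (y.size - y.sum()) < 2:
        raise ValidationError("ROC CI needs >= 2 subjects per class")
    raw_auc = mann_whitney_auc(values, y)
    if np.all(values == values[0]):
        warnings.warn("constant feature: degenerate ROC curve at AUC 0.5")
    if raw_auc >= 0.5:
        direction, scores = "higher_in_patients", values
    else:
        direction, scores = "lower_in_patients", -values
    auc = mann_whitney_auc(scores, y)
    ci = _delong_ci(scores, y, auc)
    fpr, tpr, thresholds = roc_points(scores, y)
    youden = tpr - fpr
    # ties toward higher specificity = smaller fpr; fpr is non-decreasing,
    # so the first argmax already prefers the more specific point
    k = int(np.argmax(youden))
    cutoff = float(thresholds[k]) * (1 if direction == "higher_in_patients" else -1)
    return RocResult(region=region, auc=auc, ci95=ci, direction=direction,
                     cutoff=cutoff, sensitivity=float(tpr[k]),
                     specificity=float(1.0 - fpr[k]), curve_fpr=fpr,
                     curve_tpr=tpr, n_patients=int(y.sum()),
                     n_controls=int(y.size - y.sum()))


def roc_per_region(table: FeatureTable) -> list[RocResult]:
    return [roc_analysis(table.features[:, j], table.labels, region=name)
            for j, name in enumerate(table.region_names)]


# --------------------------------------------------------------------------
# Leave-one-out SVM


@dataclass
class SvmResult:
    predictions: list          # per-subject predicted label
    decision_values: np.ndarray
    sensitivity: float
    specificity: float
    accuracy: float
    n: int
    confusion: dict            # tp / tn / fp / fn
    auc_decision: float        # AUC of the decision values

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decision_values"] = [float(v) for v in self.decision_values]
        return d


def _fold_zscore(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score using training-fold statistics only."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _loo_accuracy(features: np.ndarray, y: np.ndarray, c_param: float,
                  collect: bool = False):
    """Core LOO loop; returns accuracy (and details when ``collect``)."""
    n = y.size
    preds = np.empty(n, dtype=int)
    decisions = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        y_train = y[train]
        if y_train.min() == y_train.max():
            raise ValidationError(
                f"training fold for subject {i} contains a single class")
        x_train, x_test = _fold_zscore(features[train], features[[i]])
        clf = SVC(kernel="linear", C=c_param)
        clf.fit(x_train, y_train)
        preds[i] = int(clf.predict(x_test)[0])
        decisions[i] = float(clf.decision_function(x_test)[0])
    acc = float((preds == y).mean())
    if collect:
        return acc, preds, decisions
    return acc


def loo_svm(table: FeatureTable, c_param: float = 1.0) -> SvmResult:
    """Leave-one-out linear SVM on the feature table.

    Each held-out subject is predicted by an SVM fitted on the other N-1,
    with features z-scored by training-fold statistics only. Sensitivity,
    specificity and accuracy come from the aggregated confusion counts.
    """
    y = table.y
    if y.size < 4:
        raise ValidationError("LOO-SVM needs at least 4 subjects")
    if np.unique(table.features, axis=0).shape[0] == 1:
        warnings.warn("identical feature rows across classes: chance-level output")
    acc, preds, decisions = _loo_accuracy(table.features, y, c_param, collect=True)
    tp = int(((preds == 1) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return SvmResult(
        predictions=[POSITIVE_LABEL if p else NEGATIVE_LABEL for p in preds],
        decision_values=decisions, sensitivity=float(sens),
        specificity=float(spec), accuracy=float((tp + tn) / y.size), n=int(y.size),
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        auc_decision=mann_whitney_auc(decisions, y))


@dataclass
class PermutationResult:
    p_value: float
    observed_accuracy: float
    n_permutations: int
    null_mean: float
    null_quantiles: dict

    def to_dict(self) -> dict:
        return asdict(self)


def permutation_test(table: FeatureTable, n_permutations: int = 10000,
                     seed: int = 0, c_param: float = 1.0) -> PermutationResult:
    """Permutation null for the LOO-SVM accuracy.

    Each permutation shuffles the labels and reruns the entire LOO
    procedure (fold-wise z-scoring included); the p-value is
    ``(1 + #{null >= observed}) / (1 + n_permutations)``.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if n_permutations < 100:
        warnings.warn(f"n_permutations={n_permutations} gives coarse p resolution")
    y = table.y
    observed = _loo_accuracy(table.features, y, c_param)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        while True:
            y_perm = rng.permutation(y)
            # a permutation that empties a training fold's class is invalid;
            # with >= 2 per class LOO folds always keep both classes
            if 0 < y_perm.sum() < y_perm.size:
                break
        null[b] = _loo_accuracy(table.features, y_perm, c_param)
    p = float((1 + np.sum(null >= observed)) / (1 + n_permutations))
    qs = {f"q{int(100 * q)}": float(np.quantile(null, q))
          for q in (0.05, 0.5, 0.95)}
    return PermutationResult(p_value=p, observed_accuracy=float(observed),
                             n_permutations=int(n_permutations),
                             null_mean=float(null.mean()), null_quantiles=qs)


def save_roc_results(results: list[RocResult], path_prefix: str | Path) -> None:
    """RocResults as JSON plus curve-point TSVs for plotting."""
    prefix = Path(path_prefix)
    (prefix.parent / (prefix.name + ".json")).write_text(
        json.dumps([r.to_dict() for r in results], indent=2))
    for r in results:
        with open(prefix.parent / f"{prefix.name}_{r.region}_curve.tsv", "w") as fh:
            fh.write("fpr\ttpr\n")
            for a, b in zip(r.curve_fpr, r.curve_tpr):
                fh.write(f"{a:.6f}\t{b:.6f}\n")
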