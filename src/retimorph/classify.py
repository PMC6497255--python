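"""Age-cohort classification with leakage-safe grouped cross-validation.

Protocol: participants are assigned to age classes by configurable age
ranges; ten randomized twofold splits place *participants* (never single
images) in train or test, with per-class training pools balanced by
downsampling; per split, features are selected on the training half only
and three classifiers are scored on the held-out half:

* WND — a weighted-neighbour-distance classifier whose distance metric is
  the Fisher-score-weighted squared Euclidean distance over the top-75
  Fisher-ranked features, with similarity ``d**-5`` averaged per class;
* SVM (linear, C=1) on the top-30 mRMR features;
* SVM (linear, C=1) on the top-30 CMIM features.

Mutual information for mRMR/CMIM is estimated on 10 equal-frequency bins
fitted to the training data.  The reported aggregate accuracy is the mean
over (classifier, split, class) cells, i.e. the average per-class rate of
correct age-cohort calls, averaged over the three classifiers and the ten
splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score
from sklearn.svm import SVC

__all__ = [
    "SplitPlan",
    "ClassifierEnsembleResult",
    "fisher_scores",
    "select_features",
    "wnd_classify",
    "grouped_twofold_cv",
    "run_age_classification",
    "parse_class_ranges",
]

WND_EXPONENT = -5.0
N_FISHER = 75
N_SVM = 30
MI_BINS = 10
_FISHER_CAP = 1e12  # finite stand-in for infinite separation


@dataclass
class SplitPlan:
    """Participant-level twofold splits, grouped and class-balanced."""

    splits: list[dict[str, list]]  # per split: {"train": [...], "test": [...]} participant ids
    classes: list[str]
    seed: int

    def __len__(self) -> int:
        return len(self.splits)


@dataclass
class ClassifierEnsembleResult:
    """Per-cell accuracies and their aggregate."""

    cells: pd.DataFrame  # columns: classifier, split, cls, accuracy, n_test
    classes: list[str] = field(default_factory=list)

    @property
    def aggregate(self) -> float:
        return float(self.cells["accuracy"].mean())

    def per_classifier(self) -> pd.Series:
        return self.cells.groupby("classifier")["accuracy"].mean()


def fisher_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fisher discriminant score per feature.

    score = Var_k(class means) / mean_k(class variances), with the variance
    of class means taken over classes (divided by K).  Features separating
    classes with zero within-class variance get a large finite cap.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = np.unique(y)
    if labels.size < 2:
        raise ValueError("fisher_scores needs at least two classes")
    means = np.stack([X[y == c].mean(axis=0) for c in labels])
    wvars = np.stack([X[y == c].var(axis=0) for c in labels])
    between = means.var(axis=0)  # population variance over class means
    within = wvars.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(within > 0, between / within, np.where(between > 0, _FISHER_CAP, 0.0))
    return score


def _quantile_bins(x_train: np.ndarray, n_bins: int = MI_BINS) -> np.ndarray:
    """Equal-frequency bin edges fitted on training values."""
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    return np.unique(np.quantile(x_train, qs))


def _discretize(X: np.ndarray, edges: list[np.ndarray]) -> np.ndarray:
    return np.stack([np.searchsorted(e, X[:, j]) for j, e in enumerate(edges)], axis=1)


def _cond_mutual_info(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """I(a; b | c) from empirical counts of discrete variables."""
    total = 0.0
    n = len(c)
    for val in np.unique(c):
        sel = c == val
        w = sel.sum() / n
        if sel.sum() >= 2:
            total += w * mutual_info_score(a[sel], b[sel])
    return total


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    method: str = "fisher",
    n_bins: int = MI_BINS,
) -> np.ndarray:
    """Select ``k`` feature indices by Fisher score, mRMR, or CMIM.

    Fisher ranks features marginally.  mRMR greedily maximizes relevance
    I(f; y) minus mean redundancy I(f; g) over already-selected g.  CMIM
    greedily maximizes min_g I(f; y | g).  Mutual information uses
    equal-frequency discretization fitted on the given (training) data.
    ``k`` larger than the feature count is clamped.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_feat = X.shape[1]
    k = min(k, n_feat)
    if method == "fisher":
        scores = fisher_scores(X, y)
        return np.argsort(-scores, kind="stable")[:k]
    edges = [_quantile_bins(X[:, j], n_bins) for j in range(n_feat)]
    D = _discretize(X, edges)
    relevance = np.array([mutual_info_score(D[:, j], y) for j in range(n_feat)])
    selected: list[int] = [int(np.argmax(relevance))]
    if method == "mrmr":
        red_sum = np.zeros(n_feat)
        while len(selected) < k:
            last = selected[-1]
            red_sum += np.array(
                [mutual_info_score(D[:, j], D[:, last]) for j in range(n_feat)]
            )
            crit = relevance - red_sum / len(selected)
            crit[selected] = -np.inf
            selected.append(int(np.argmax(crit)))
        return np.asarray(selected)
    if method == "cmim":
        # running minimum of I(f; y | g) over selected g
        min_cmi = np.full(n_feat, np.inf)
        while len(selected) < k:
            last = selected[-1]
            for j in range(n_feat):
                if j in selected:
                    continue
                cmi = _cond_mutual_info(D[:, j], y, D[:, last])
                min_cmi[j] = min(min_cmi[j], cmi)
            crit = np.where(np.isinf(min_cmi), relevance, min_cmi)
            crit = crit.copy()
            crit[selected] = -np.inf
            selected.append(int(np.argmax(crit)))
        return np.asarray(selected)
    raise ValueError(f"unknown selection method {method!r}")


def wnd_classify(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    weights: np.ndarray,
    exponent: float = WND_EXPONENT,
) -> np.ndarray:
    """Weighted-neighbour-distance predictions for the test samples.

    For test sample x and class c, similarity is the mean over training
    samples t of class c of ``d(x, t) ** exponent`` with
    ``d = sum_f w_f * (x_f - t_f)^2``; the predicted class maximizes the
    similarity.  A zero distance (exact duplicate of a training sample)
    short-circuits to that sample's class.
    """
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    y_train = np.asarray(y_train)
    w = np.asarray(weights, float)
    classes = np.unique(y_train)
    if any((y_train == c).sum() == 0 for c in classes):  # pragma: no cover
        raise ValueError("every class needs at least one training sample")
    # weighted squared distances, (n_test, n_train)
    diff = X_test[:, None, :] - X_train[None, :, :]
    d = np.einsum("ijf,f->ij", diff**2, w)
    preds = np.empty(len(X_test), dtype=classes.dtype)
    with np.errstate(divide="ignore"):
        sim_terms = np.where(d > 0, d**exponent, np.inf)
    for i in range(len(X_test)):
        zero = np.flatnonzero(d[i] == 0)
        if zero.size:
            preds[i] = y_train[zero[0]]
            continue
        sims = [sim_terms[i, y_train == c].mean() for c in classes]
        preds[i] = classes[int(np.argmax(sims))]
    return preds


def parse_class_ranges(spec: str | Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Parse an age-class spec like ``"20-37,65-89"`` into range tuples."""
    if not isinstance(spec, str):
        return [(float(a), float(b)) for a, b in spec]
    out = []
    for token in spec.split(","):
        token = token.strip()
        parts = token.split("-")
        if len(parts) != 2:
            raise ValueError(f"malformed age-range token {token!r}; expected 'lo-hi'")
        try:
            lo, hi = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"malformed age-range token {token!r}: {exc}") from exc
        if hi <= lo:
            raise ValueError(f"empty age range {token!r}")
        out.append((lo, hi))
    if len(out) < 2:
        raise ValueError("need at least two age classes")
    return out


def _assign_classes(
    ages: pd.Series, ranges: Sequence[tuple[float, float]]
) -> pd.Series:
    labels = pd.Series(index=ages.index, dtype="object")
    for i, (lo, hi) in enumerate(ranges):
        labels[(ages >= lo) & (ages <= hi)] = f"{lo:g}-{hi:g}"
    return labels


def grouped_twofold_cv(
    participants: pd.DataFrame,
    n_splits: int = 10,
    seed: int = 0,
    participant_col: str = "participant_id",
    label_col: str = "age_class",
) -> SplitPlan:
    """Randomized twofold splits of participants, balanced across classes.

    Every participant (with all of their images) lands on exactly one side
    of each split; the per-class training pools are equalized by
    downsampling the larger classes to the smallest class's half size.
    """
    groups = participants.drop_duplicates(participant_col)
    classes = sorted(groups[label_col].dropna().unique())
    by_class = {c: groups.loc[groups[label_col] == c, participant_col].to_numpy() for c in classes}
    for c, ids in by_class.items():
        if len(ids) < 2:
            raise ValueError(f"age class {c!r} has fewer than 2 participants")
    n_train = min(len(ids) // 2 for ids in by_class.values())
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        train: list = []
        test: list = []
        for c in classes:
            ids = by_class[c].copy()
            rng.shuffle(ids)
            train.extend(ids[:n_train])
            test.extend(ids[n_train:])
        splits.append({"train": train, "test": test})
    return SplitPlan(splits=splits, classes=list(classes), seed=seed)


def run_age_classification(
    cohort: pd.DataFrame,
    class_ranges: str | Sequence[tuple[float, float]],
    features: Sequence[str] | None = None,
    n_splits: int = 10,
    seed: int = 0,
    age_col: str = "age",
    participant_col: str = "participant_id",
) -> ClassifierEnsembleResult:
    """The full three-classifier grouped-CV age classification protocol.

    ``cohort`` has one row per image with participant id, age, and trait
    columns.  Rows outside every age class are dropped; missing feature
    values are imputed with training means per split.  Returns per
    (classifier, split, class) accuracies and their mean.
    """
    ranges = parse_class_ranges(class_ranges)
    df = cohort.copy()
    df["age_class"] = _assign_classes(df[age_col], ranges)
    df = df.dropna(subset=["age_class"])
    if features is None:
        # default to the microvascular trait columns: identifiers, age/sex,
        # cardiovascular covariates and simulator ground truth are not
        # image-derived features and must not leak into the classifier
        reserved = {age_col, participant_col, "image_id", "sex", "age_class"}
        reserved |= {"sbp", "dbp", "waist", "hip", "weight", "height", "bmi", "imt"}
        reserved |= {"true_bifurcations", "true_endpoints"}
        features = [
            c for c in df.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(df[c])
        ]
    plan = grouped_twofold_cv(df, n_splits=n_splits, seed=seed, participant_col=participant_col)
    Xall = df[list(features)].to_numpy(dtype=float)
    yall = df["age_class"].to_numpy()
    pid = df[participant_col].to_numpy()

    rows = []
    for s_idx, split in enumerate(plan.splits):
        tr = np.isin(pid, split["train"])
        te = np.isin(pid, split["test"])
        assert not (set(pid[tr]) & set(pid[te])), "participant leakage across folds"
        Xtr, ytr = Xall[tr].copy(), yall[tr]
        Xte, yte = Xall[te].copy(), yall[te]
        # train-statistics imputation and z-normalization
        col_mean = np.nanmean(Xtr, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        inds = np.where(np.isnan(Xtr))
        Xtr[inds] = np.take(col_mean, inds[1])
        inds = np.where(np.isnan(Xte))
        Xte[inds] = np.take(col_mean, inds[1])
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Ztr, Zte = (Xtr - mu) / sd, (Xte - mu) / sd

        preds: dict[str, np.ndarray] = {}
        fidx = select_features(Ztr, ytr, N_FISHER, "fisher")
        weights = fisher_scores(Ztr[:, fidx], ytr)
        preds["WND"] = wnd_classify(Ztr[:, fidx], ytr, Zte[:, fidx], weights)
        for name, method in (("SVM-mRMR", "mrmr"), ("SVM-CMIM", "cmim")):
            sel = select_features(Ztr, ytr, N_SVM, method)
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(Ztr[:, sel], ytr)
            preds[name] = clf.predict(Zte[:, sel])

        for name, yhat in preds.items():
            for cls in plan.classes:
                m = yte == cls
                if m.sum() == 0:
                    continue
                rows.append(
                    {
                        "classifier": name,
                        "split": s_idx,
                        "cls": cls,
                        "accuracy": float((yhat[m] == cls).mean()),
                        "n_test": int(m.sum()),
                    }
                )
    return ClassifierEnsembleResult(cells=pd.DataFrame(rows), classes=plan.classes)
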