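"""Repeated double cross-validation random-forest classification (rdCV).

Two-class classification of samples (e.g. experimental groups from urinary
NMR profiles) with unbiased variable selection: an outer cross-validation
loop provides held-out performance estimates while an inner loop drives
recursive elimination of the least informative variables, ranked by random
forest mean decrease in Gini impurity. Repeating the whole procedure over
many random segmentations and averaging the held-out class probabilities
stabilises both the inner validation-error curve and the final predictions.

Model flavors follow the usual rdCV conventions: ``min`` is the variable
count minimising the averaged inner validation error, ``max`` the largest
count whose error stays within a tolerance band above the minimum (all
relevant predictors without compromising performance), and ``mid`` the
rounded geometric mean of the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier


class _GiniForest:
    """Minimal random forest: bootstrap-aggregated CART trees, Gini split
    criterion, sqrt(p) candidate features per split.

    A thin bagging loop over ``DecisionTreeClassifier`` kept deliberately
    lean (float32 inputs, input checks off) because the rdCV procedure fits
    tens of thousands of small forests. Importances are the mean decrease in
    Gini impurity averaged over trees.
    """

    def __init__(self, n_trees: int, seed: int):
        self.n_trees = n_trees
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []
        self.tree_classes_: list[np.ndarray] = []
        self.feature_importances_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_GiniForest":
        X = np.ascontiguousarray(X, dtype=np.float32)
        n = len(y)
        rng = np.random.default_rng(self.seed)
        imp = np.zeros(X.shape[1])
        self.trees_ = []
        self.tree_classes_ = []
        for t in range(self.n_trees):
            idx = rng.integers(0, n, n)
            tree = DecisionTreeClassifier(
                criterion="gini", max_features="sqrt",
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx], check_input=False)
            imp += tree.feature_importances_
            self.trees_.append(tree)
            self.tree_classes_.append(tree.classes_)
        self.feature_importances_ = imp / self.n_trees
        return self

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        """Mean over trees of P(class 1)."""
        X = np.ascontiguousarray(X, dtype=np.float32)
        out = np.zeros(len(X))
        for tree, cls in zip(self.trees_, self.tree_classes_):
            pp = tree.predict_proba(X, check_input=False)
            j = np.flatnonzero(cls == 1)
            if len(j):
                out += pp[:, j[0]]
        return out / self.n_trees


@dataclass
class RDCVConfig:
    n_outer: int = 5
    n_rep: int = 100
    var_ratio: float = 0.85
    n_trees: int = 500
    seed: int = 0
    # 'max' keeps the largest count with error <= min + this fraction of the
    # curve's error range above the minimum.
    max_tolerance_frac: float = 0.05
    min_vars: int = 2

    def __post_init__(self) -> None:
        if self.n_outer < 2:
            raise ValueError("n_outer must be >= 2")
        if not 0 < self.var_ratio < 1:
            raise ValueError("var_ratio must lie in (0, 1)")


@dataclass
class RDCVResult:
    classes: tuple[str, str]  # (negative, positive)
    var_counts: list[int]
    error_curve: pd.Series  # averaged inner validation error per count
    n_min: int
    n_mid: int
    n_max: int
    selected: dict[str, list[str]]  # flavor -> variable ids
    probabilities: pd.DataFrame  # samples x flavors, aggregated P(positive)
    predicted: pd.DataFrame  # samples x flavors, labels at 50% threshold
    misclassifications: dict[str, int]
    auc: dict[str, float]
    gini: pd.Series  # per-variable mean decrease in Gini over repetitions
    y: pd.Series


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / n if n else float("nan")


def _count_grid(p: int, var_ratio: float, min_vars: int) -> list[int]:
    counts = [p]
    while counts[-1] > min_vars:
        nxt = max(min_vars, math.ceil(var_ratio * counts[-1]))
        if nxt == counts[-1]:  # ceil stalls for small counts; step down by one
            nxt -= 1
        counts.append(nxt)
    return counts


def fit_rdcv(X: pd.DataFrame, y, config: RDCVConfig | None = None) -> RDCVResult:
    """Fit the repeated double-CV random forest with recursive elimination.

    ``X`` is samples x variables; ``y`` holds two class labels. Every outer
    segmentation is stratified so both classes appear in all segments.
    """
    config = config or RDCVConfig()
    y = pd.Series(np.asarray(y), index=X.index)
    classes = sorted(y.unique().tolist())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    if config.n_outer > len(X):
        raise ValueError("more outer segments than samples")
    neg, pos = classes
    ybin = (y == pos).to_numpy().astype(int)
    Xv = X.to_numpy(dtype=float)
    n_samples, p = Xv.shape
    counts = _count_grid(p, config.var_ratio, config.min_vars)

    rng = np.random.SeedSequence(config.seed)
    n_seeds = (config.n_outer + 5) * config.n_rep * config.n_outer * len(counts) + config.n_rep
    seeds = rng.generate_state(n_seeds) % (2**31 - 1)
    seed_iter = iter(seeds.tolist())

    err_sum = {c: 0.0 for c in counts}
    err_n = {c: 0 for c in counts}
    prob_sum = {c: np.zeros(n_samples) for c in counts}
    prob_n = {c: np.zeros(n_samples) for c in counts}
    gini_sum = np.zeros(p)
    gini_n = 0

    inner_splits = max(2, config.n_outer - 1)
    Xv32 = np.ascontiguousarray(Xv, dtype=np.float32)
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for rep in range(config.n_rep):
            outer = StratifiedKFold(
                n_splits=config.n_outer, shuffle=True, random_state=next(seed_iter)
            )
            for train_idx, test_idx in outer.split(Xv32, ybin):
                current = np.arange(p)
                for c in counts:
                    # inner leave-segment-out validation at the current
                    # variable set; the held-out outer segment is predicted
                    # by the average of the inner-fold forests
                    inner = StratifiedKFold(
                        n_splits=inner_splits, shuffle=True,
                        random_state=next(seed_iter),
                    )
                    Xtr = Xv32[train_idx][:, current]
                    ytr = ybin[train_idx]
                    Xte = Xv32[test_idx][:, current]
                    imp = np.zeros(len(current))
                    errs = []
                    prob = np.zeros(len(test_idx))
                    for itr, ival in inner.split(Xtr, ytr):
                        rf = _GiniForest(config.n_trees, next(seed_iter))
                        rf.fit(Xtr[itr], ytr[itr])
                        pred = (rf.predict_proba1(Xtr[ival]) >= 0.5).astype(int)
                        errs.append(float(np.mean(pred != ytr[ival])))
                        imp += rf.feature_importances_
                        prob += rf.predict_proba1(Xte)
                    err_sum[c] += float(np.mean(errs))
                    err_n[c] += 1
                    prob_sum[c][test_idx] += prob / inner_splits
                    prob_n[c][test_idx] += 1
                    if c == p:
                        gini_sum[current] += imp / inner_splits
                        gini_n += 1
                    # eliminate least informative variables
                    if c <= config.min_vars:
                        break
                    nxt = max(config.min_vars, math.ceil(config.var_ratio * c))
                    if nxt == c:
                        nxt -= 1
                    order = np.argsort(-imp, kind="stable")
                    current = current[np.sort(order[:nxt])]

    curve = pd.Series({c: err_sum[c] / err_n[c] for c in counts}).sort_index()
    e_min, e_max = curve.min(), curve.max()
    n_min = int(min(curve.index[curve == e_min]))
    band = e_min + config.max_tolerance_frac * (e_max - e_min)
    n_max = int(max(curve.index[curve <= band]))
    n_mid = int(round(math.sqrt(n_min * n_max)))

    gini = pd.Series(gini_sum / max(gini_n, 1), index=X.columns, name="mean_decrease_gini")
    ranked = rank_order(gini)
    flavors = {"min": n_min, "mid": n_mid, "max": n_max}
    selected = {f: ranked[:k] for f, k in flavors.items()}

    probs = pd.DataFrame(index=X.index)
    preds = pd.DataFrame(index=X.index)
    mis: dict[str, int] = {}
    aucs: dict[str, float] = {}
    for f, k in flavors.items():
        c = min(counts, key=lambda cc: abs(cc - k))
        pvec = prob_sum[c] / np.maximum(prob_n[c], 1)
        probs[f] = pvec
        preds[f] = np.where(pvec >= 0.5, pos, neg)
        mis[f] = int(np.sum(preds[f].to_numpy() != y.to_numpy()))
        aucs[f] = auc(ybin, pvec)

    return RDCVResult(
        classes=(neg, pos),
        var_counts=counts,
        error_curve=curve,
        n_min=n_min,
        n_mid=n_mid,
        n_max=n_max,
        selected=selected,
        probabilities=probs,
        predicted=preds,
        misclassifications=mis,
        auc=aucs,
        gini=gini,
        y=y,
    )


def rank_order(gini: pd.Series) -> list[str]:
    """Variable ids in descending Gini importance, ties broken by id."""
    df = gini.rename("g").reset_index()
    df.columns = ["var", "g"]
    df = df.sort_values(["g", "var"], ascending=[False, True], kind="stable")
    return df["var"].tolist()


def rank_variables(result: RDCVResult, flavor: str = "max") -> pd.DataFrame:
    """Ordered importance table for the selected variables of one flavor."""
    sel = result.selected[flavor]
    g = result.gini.loc[sel]
    df = pd.DataFrame({"variable": sel, "mean_decrease_gini": g.to_numpy()})
    df["rank"] = np.arange(1, len(df) + 1)
    df["tied"] = df["mean_decrease_gini"].duplicated(keep=False)
    return df


def confusion_metrics(actual, predicted, positive=None) -> ConfusionSummary:
    """Confusion counts and rates at the 50% probability threshold."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    labels = sorted(set(actual) | set(predicted))
    if len(labels) > 2:
        raise ValueError("two-class labels expected")
    pos = positive if positive is not None else labels[-1]
    tp = int(np.sum((actual == pos) & (predicted == pos)))
    fn = int(np.sum((actual == pos) & (predicted != pos)))
    fp = int(np.sum((actual != pos) & (predicted == pos)))
    tn = int(np.sum((actual != pos) & (predicted != pos)))
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def auc(labels, scores) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) statistic.

    Ties in the scores contribute one half; labels are binary with 1 the
    positive class.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
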