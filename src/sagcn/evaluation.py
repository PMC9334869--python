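"""Repeated stratified subject-level cross-validation and scoring.

The unit of splitting is the *subject*, never the window: windows of one
subject are near-duplicates, so any split that places them on both sides of a
train/test boundary leaks. A hard error guards this invariant on every fold.

Scoring is subject-level: each test subject's window probabilities are
averaged into one diagnosis, and six confusion-matrix metrics are computed
per (repeat, fold) cell and aggregated as mean +/- sd.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .graphs import GraphSample, build_graph_pairs
from .io import SubjectRecord
from .model import ModelConfig, TrainedModel, predict_proba, train_model
from .windowing import slide_windows

logger = logging.getLogger("sagcn")

METRIC_NAMES = ("ACC", "TPR", "TNR", "PPV", "NPV", "F1")

#: evaluation methods -> (kind, model view, pooling on)
METHODS: dict[str, tuple[str, str | None, bool]] = {
    "cbn": ("baseline", None, False),
    "fcn": ("baseline", None, False),
    "gcn-lo": ("model", "lo", False),
    "sagcn-lo": ("model", "lo", True),
    "gcn-ho": ("model", "ho", False),
    "sagcn-ho": ("model", "ho", True),
    "gcn-fused": ("model", "fused", False),
    "sagcn-fused": ("model", "fused", True),
}


@dataclass
class FoldPlan:
    repeats: int
    folds: int
    assignment: dict[tuple[int, int], list[str]]  # (repeat, fold) -> test subject ids
    seed: int = 0

    def test_subjects(self, repeat: int, fold: int) -> set[str]:
        return set(self.assignment[(repeat, fold)])


@dataclass
class MetricsReport:
    method: str
    rows: list[dict] = field(default_factory=list)  # one per (repeat, fold)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """mean +/- sd of each metric over all (repeat, fold) cells."""
        frame = self.to_frame()
        return {m: (float(frame[m].mean()), float(frame[m].std(ddof=1)) if len(frame) > 1 else 0.0)
                for m in METRIC_NAMES}

    def repeat_accuracies(self) -> np.ndarray:
        """Mean accuracy per repeat (the unit for between-method t-tests)."""
        frame = self.to_frame()
        return frame.groupby("repeat")["ACC"].mean().to_numpy()


def make_subject_folds(subjects: list[SubjectRecord], folds: int, repeats: int,
                       seed: int) -> FoldPlan:
    """Stratified-by-class partition of subjects, re-shuffled per repeat."""
    n = len(subjects)
    if folds > n:
        raise ValueError(f"{folds} folds for {n} subjects")
    labels = np.array([s.label for s in subjects])
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    ids = np.array([s.subject_id for s in subjects])
    assignment: dict[tuple[int, int], list[str]] = {}
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 9973 * rep)
        for fold, (_, test_idx) in enumerate(skf.split(ids, labels)):
            assignment[(rep, fold)] = ids[test_idx].tolist()
    return FoldPlan(repeats, folds, assignment, seed)


def aggregate_window_predictions(window_probs: np.ndarray) -> tuple[float, int]:
    """Mean positive-class probability over a subject's windows; ties -> positive."""
    probs = np.atleast_2d(np.asarray(window_probs, dtype=float))
    if probs.size == 0:
        raise ValueError("subject has no window predictions")
    p_pos = float(probs[:, 1].mean()) if probs.shape[1] == 2 else float(probs.mean())
    return p_pos, int(p_pos >= 0.5)


def compute_metrics(y_true, y_pred) -> dict[str, float]:
    """Six confusion-matrix metrics; zero-denominator ratios are 0 and flagged.

    Returns ACC, TPR (sensitivity), TNR (specificity), PPV, NPV, F1 plus an
    ``undefined`` list naming any metric whose denominator was empty.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not (set(yt.tolist()) | set(yp.tolist())) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    tp = int(((yt == 1) & (yp == 1)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / len(yt) if len(yt) else 0.0
    tpr = ratio(tp, tp + fn, "TPR")
    tnr = ratio(tn, tn + fp, "TNR")
    ppv = ratio(tp, tp + fp, "PPV")
    npv = ratio(tn, tn + fn, "NPV")
    if ppv + tpr == 0:
        undefined.append("F1")
        f1 = 0.0
    else:
        f1 = 2 * ppv * tpr / (ppv + tpr)
    return {"ACC": acc, "TPR": tpr, "TNR": tnr, "PPV": ppv, "NPV": npv, "F1": f1,
            "undefined": undefined}


def method_ttest(acc_a, acc_b) -> float:
    """Two-tailed paired t-test on per-repeat accuracies.

    Identical vectors return p = 1 by convention; a constant nonzero shift
    (zero variance of differences) is degenerate and returns p = 0.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D accuracy vectors")
    if len(a) < 2:
        raise ValueError("need at least two repeats for a t-test")
    diff = a - b
    if np.allclose(diff, 0.0):
        return 1.0
    if np.allclose(diff, diff[0]):
        logger.warning("paired t-test degenerate: constant nonzero difference, p=0")
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


# ---------------------------------------------------------------------------
# fold execution
# ---------------------------------------------------------------------------

def _check_no_leakage(train_pairs, test_subject_ids: set[str]) -> None:
    leaked = {p[0].subject_id for p in train_pairs} & test_subject_ids
    if leaked:
        raise RuntimeError(f"subject leakage: {sorted(leaked)} present in train and test")


def _score_subjects(probs: np.ndarray, pairs, majority_vote: bool = False):
    """Aggregate window probabilities into subject predictions."""
    by_subject: dict[str, list[int]] = {}
    labels: dict[str, int] = {}
    for i, (lo, _ho) in enumerate(pairs):
        by_subject.setdefault(lo.subject_id, []).append(i)
        labels[lo.subject_id] = lo.label
    sids = sorted(by_subject)
    y_true, y_pred, p_pos = [], [], []
    for sid in sids:
        rows = probs[by_subject[sid]]
        if majority_vote:
            votes = (rows[:, 1] >= 0.5).mean()
            p, lab = float(votes), int(votes >= 0.5)
        else:
            p, lab = aggregate_window_predictions(rows)
        y_true.append(labels[sid])
        y_pred.append(lab)
        p_pos.append(p)
    return np.array(y_true), np.array(y_pred), np.array(p_pos), sids


def baseline_features(pairs: list[tuple[GraphSample, GraphSample]], kind: str) -> np.ndarray:
    """Flat per-window feature vectors for the classical baselines.

    CBN: the 2R mean/variance node features. FCN: the R(R-1)/2 upper-triangle
    entries of the Pearson FC matrix (the Ho view's node-feature matrix).
    """
    if kind == "cbn":
        return np.stack([p[0].node_features.ravel() for p in pairs])
    if kind == "fcn":
        r = pairs[0][1].node_features.shape[0]
        iu = np.triu_indices(r, k=1)
        return np.stack([p[1].node_features[iu] for p in pairs])
    raise ValueError(f"unknown baseline kind {kind!r}")


def _run_baseline(kind: str, train_pairs, test_pairs, seed: int):
    x_train = baseline_features(train_pairs, kind)
    x_test = baseline_features(test_pairs, kind)
    y_train = np.array([p[0].label for p in train_pairs])
    mu, sd = x_train.mean(axis=0), x_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    clf = LinearSVC(C=1.0, random_state=seed, max_iter=5000)
    clf.fit((x_train - mu) / sd, y_train)
    pred = clf.predict((x_test - mu) / sd)
    # margin classifiers give no calibrated probability; hard labels act as 0/1 probs
    return np.column_stack([1 - pred, pred]).astype(float)


def windows_to_pairs(subjects: list[SubjectRecord], window_length: int, stride: int,
                     threshold: float, binary: bool = False):
    """Build the full windowed (Lo, Ho) graph dataset for a cohort."""
    pairs: list[tuple[GraphSample, GraphSample]] = []
    for subj in subjects:
        pairs.extend(build_graph_pairs(slide_windows(subj, window_length, stride),
                                       threshold, binary=binary))
    return pairs


def cross_validate(pairs: list[tuple[GraphSample, GraphSample]], plan: FoldPlan,
                   method: str = "sagcn-fused", model_config: ModelConfig | None = None,
                   seed: int = 0, majority_vote: bool = False,
                   collect_importance: bool = False, importance_layer: int = 1):
    """Run every (repeat, fold) cell of the plan for one method.

    Returns a MetricsReport (and, when ``collect_importance`` is set on an
    attention-pooled model method, a list of per-graph survivor index arrays
    pooled over all test cells, for ROI-importance ranking).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    kind, view, pool = METHODS[method]
    report = MetricsReport(method=method, meta={
        "method": method, "folds": plan.folds, "repeats": plan.repeats,
        "seed": seed, "majority_vote": majority_vote,
    })
    survivors: dict[str, list[np.ndarray]] = {"lo": [], "ho": []}
    for rep, fold in itertools.product(range(plan.repeats), range(plan.folds)):
        test_ids = plan.test_subjects(rep, fold)
        train_pairs = [p for p in pairs if p[0].subject_id not in test_ids]
        test_pairs = [p for p in pairs if p[0].subject_id in test_ids]
        if not test_pairs:
            raise ValueError(f"cell ({rep},{fold}) has no test subjects in the dataset")
        _check_no_leakage(train_pairs, test_ids)
        cell_seed = (seed + 1_000_003 * rep + 101 * fold) % (2**31)
        if kind == "baseline":
            probs = _run_baseline(method, train_pairs, test_pairs, cell_seed)
        else:
            cfg = model_config if model_config is not None else ModelConfig()
            cfg = ModelConfig(**{**cfg.__dict__, "view": view, "pool": pool, "seed": cell_seed})
            model = train_model(train_pairs, cfg, seed=cell_seed)
            if collect_importance and pool:
                probs, trace = predict_proba(model, test_pairs, collect_trace=True)
                for br in cfg.branches:
                    survivors[br].extend(trace[br][importance_layer - 1])
            else:
                probs = predict_proba(model, test_pairs)
        y_true, y_pred, p_pos, sids = _score_subjects(probs, test_pairs, majority_vote)
        metrics = compute_metrics(y_true, y_pred)
        row = {"repeat": rep, "fold": fold, "n_test_subjects": len(sids),
               **{m: metrics[m] for m in METRIC_NAMES},
               "undefined": ";".join(metrics["undefined"])}
        report.rows.append(row)
        logger.info("method=%s repeat=%d fold=%d ACC=%.3f", method, rep, fold, metrics["ACC"])
    if collect_importance:
        return report, survivors
    return report


def summarize_methods(reports: list[MetricsReport], reference: str = "sagcn-fused") -> pd.DataFrame:
    """Mean +/- sd table over methods plus paired-t p-values vs the reference."""
    by_name = {r.method: r for r in reports}
    rows = []
    ref_acc = by_name[reference].repeat_accuracies() if reference in by_name else None
    for rep in reports:
        agg = rep.aggregate()
        row: dict = {"method": rep.method}
        for m in METRIC_NAMES:
            mean, sd = agg[m]
            row[m] = f"{100 * mean:.1f} +/- {100 * sd:.1f}"
        if ref_acc is not None and rep.method != reference:
            row["p_vs_ref"] = method_ttest(rep.repeat_accuracies(), ref_acc)
        else:
            row["p_vs_ref"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
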