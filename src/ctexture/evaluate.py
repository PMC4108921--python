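"""Train/test splitting, confusion matrices and sensitivity/specificity.

Experiments follow the pattern-classification protocol: stratified random
splits at 50/50, 60/40 or 70/30 (or leave-one-out), z-score normalization
fitted on the training half only, per-sample k-NN classification of the test
half, and a row-normalized confusion matrix over the eight reporting
classes. Sensitivity is the unweighted mean, over diseased-class rows, of
the proportion mass falling in diseased-class columns (x100, rounded
half-up); specificity is the analogous mean over the non-diseased rows. The
diseased partition is the five attenuation patterns plus ischemia; benign
and control are non-diseased.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .classify import KnnConfig, fit_class_models, knn_classify, separability_classify
from .features import apply_normalization, fit_normalization
from .patterns import DEFAULT_CLASS_ORDER, LabeledPatternSet

__all__ = [
    "DISEASED_CLASSES",
    "NONDISEASED_CLASSES",
    "ConfusionMatrix",
    "SplitSpec",
    "split_train_test",
    "leave_one_out_folds",
    "merge_benign",
    "build_confusion",
    "sensitivity_from_confusion",
    "specificity_from_confusion",
    "run_experiment",
    "run_separability_experiment",
    "load_printed_table",
]

DISEASED_CLASSES = ("white", "gray", "water_halo", "fat_halo", "black", "ischemia")
NONDISEASED_CLASSES = ("benign", "control")

#: Trained benign sub-patterns reported merged as "benign".
BENIGN_SUBPATTERNS = {"benign_gray": "benign", "benign_control_like": "benign"}


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-normalized true x predicted proportions plus raw counts."""

    class_order: tuple[str, ...]
    counts: np.ndarray
    proportions: np.ndarray

    @classmethod
    def from_counts(cls, class_order, counts) -> "ConfusionMatrix":
        counts = np.asarray(counts, dtype=np.int64)
        sums = counts.sum(axis=1, keepdims=True)
        props = np.divide(counts, sums, where=sums > 0, out=np.zeros(counts.shape))
        return cls(tuple(class_order), counts, props)

    @classmethod
    def from_proportions(cls, class_order, proportions) -> "ConfusionMatrix":
        """Wrap an already row-normalized matrix (e.g. one read from a report)."""
        props = np.asarray(proportions, dtype=np.float64)
        return cls(tuple(class_order), np.zeros(props.shape, dtype=np.int64), props)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.class_order, columns=self.class_order)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified split fraction (or leave-one-out) and RNG seed."""

    train_fraction: float = 0.5
    leave_one_out: bool = False
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not self.leave_one_out and not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_train_test(data: LabeledPatternSet, spec: SplitSpec):
    """Stratified random split of a labeled pattern set.

    Each class contributes ``round(n_c * train_fraction)`` training samples
    (at least 1); a single-sample class goes train-only with a warning.
    Deterministic for a fixed seed.
    """
    if len(data) == 0:
        raise ValueError("empty pattern set")
    rng = np.random.default_rng(spec.seed)
    labels = np.asarray(data.labels)
    train_idx: list[int] = []
    test_idx: list[int] = []
    groups = (
        [(c, np.flatnonzero(labels == c)) for c in data.class_vocabulary if (labels == c).any()]
        if spec.stratified
        else [("__all__", np.arange(len(data)))]
    )
    for c, idx in groups:
        if len(idx) < 2:
            import warnings

            warnings.warn(f"class {c!r} has a single sample; kept train-only")
            train_idx.extend(idx)
            continue
        perm = rng.permutation(idx)
        n_train = min(max(int(round(len(idx) * spec.train_fraction)), 1), len(idx) - 1)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return data.subset(sorted(train_idx)), data.subset(sorted(test_idx))


def leave_one_out_folds(data: LabeledPatternSet):
    """Yield the N (train, test) folds with a single held-out sample each."""
    n = len(data)
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        yield data.subset(rest), data.subset([i])


def merge_benign(label: str) -> str:
    """Map trained benign sub-pattern labels onto the reported 'benign' class."""
    return BENIGN_SUBPATTERNS.get(label, label)


def build_confusion(true_labels, predicted_labels, class_order=DEFAULT_CLASS_ORDER) -> ConfusionMatrix:
    """Tally true x predicted counts and row-normalize; empty rows stay zero."""
    true_labels = [merge_benign(t) for t in true_labels]
    predicted_labels = [merge_benign(p) for p in predicted_labels]
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    bad = [l for l in set(true_labels) | set(predicted_labels) if l not in index]
    if bad:
        raise ValueError(f"labels outside class order: {sorted(bad)}")
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix.from_counts(class_order, counts)


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _group_rate(cm: ConfusionMatrix, rows, cols, weighted: bool) -> float:
    idx = {c: i for i, c in enumerate(cm.class_order)}
    missing = [c for c in (*rows, *cols) if c not in idx]
    if missing:
        raise ValueError(f"classes not in matrix: {missing}")
    r = [idx[c] for c in rows]
    c = [idx[c] for c in cols]
    if weighted:
        totals = cm.counts.sum(axis=1)
        if totals[r].sum() == 0:
            raise ValueError("sample-weighted rate needs raw counts")
        return float(cm.counts[np.ix_(r, c)].sum() / totals[r].sum())
    return float(cm.proportions[np.ix_(r, c)].sum(axis=1).mean())


def sensitivity_from_confusion(
    cm: ConfusionMatrix,
    diseased_classes=DISEASED_CLASSES,
    nondiseased_classes=NONDISEASED_CLASSES,
    weighted: bool = False,
) -> int:
    """True-positive rate: diseased rows staying in diseased columns, percent.

    Unweighted mean over diseased rows by default; ``weighted=True`` pools by
    sample counts instead. Returned as integer percent, round half-up.
    """
    if not diseased_classes:
        raise ValueError("no diseased classes given")
    rate = _group_rate(cm, diseased_classes, diseased_classes, weighted)
    return _round_half_up(rate * 100.0)


def specificity_from_confusion(
    cm: ConfusionMatrix,
    diseased_classes=DISEASED_CLASSES,
    nondiseased_classes=NONDISEASED_CLASSES,
    weighted: bool = False,
) -> int:
    """True-negative rate: non-diseased rows staying in non-diseased columns."""
    if not nondiseased_classes:
        raise ValueError("no non-diseased classes given")
    rate = _group_rate(cm, nondiseased_classes, nondiseased_classes, weighted)
    return _round_half_up(rate * 100.0)


def run_experiment(
    data: LabeledPatternSet,
    spec: SplitSpec = SplitSpec(),
    classifier_cfg: KnnConfig = KnnConfig(),
    class_order=DEFAULT_CLASS_ORDER,
):
    """Split, normalize on the training half only, classify, and tally.

    Returns ``(ConfusionMatrix, summary dict)``; the summary carries
    sensitivity, specificity, accuracy and full provenance (seed, configs).
    Leave-one-out issues one prediction per sample over N folds.
    """
    truths: list[str] = []
    preds: list[str] = []
    folds = (
        leave_one_out_folds(data)
        if spec.leave_one_out
        else [split_train_test(data, spec)]
    )
    for train, test in folds:
        if len(test) == 0:
            continue
        norm = fit_normalization(train)
        train_z = LabeledPatternSet(
            apply_normalization(norm, train.to_matrix()), train.labels, train.class_vocabulary
        )
        for vec, label in zip(test.to_matrix(), test.labels):
            z = apply_normalization(norm, vec)
            preds.append(knn_classify(z, train_z, classifier_cfg))
            truths.append(label)
    cm = build_confusion(truths, preds, class_order)
    merged_truths = [merge_benign(t) for t in truths]
    merged_preds = [merge_benign(p) for p in preds]
    accuracy = float(np.mean([t == p for t, p in zip(merged_truths, merged_preds)]))
    try:
        sens: int | None = sensitivity_from_confusion(cm)
        spc: int | None = specificity_from_confusion(cm)
    except ValueError:
        # class order without the diseased/non-diseased partition (e.g. a
        # purely synthetic vocabulary): rates are undefined, not an error
        sens = spc = None
    summary = {
        "n_test": len(truths),
        "accuracy": accuracy,
        "sensitivity": sens,
        "specificity": spc,
        "split": {
            "train_fraction": spec.train_fraction,
            "leave_one_out": spec.leave_one_out,
            "seed": spec.seed,
        },
        "classifier": {"k": classifier_cfg.k, "distance": classifier_cfg.distance},
    }
    return cm, summary


def run_separability_experiment(
    data: LabeledPatternSet,
    groups: dict[str, list[str]],
    spec: SplitSpec = SplitSpec(),
    repeats: int = 50,
    class_order=None,
):
    """Group-level Bhattacharyya assignment experiment.

    ``groups`` maps coarse group names (e.g. ischemia / benign / control) to
    the trained class labels they pool. For each of ``repeats`` random
    splits, class models are fitted to the pooled training vectors of each
    group and every group's test collection is assigned to its nearest model;
    assignment frequencies populate the confusion matrix, mirroring how a
    whole sample population, rather than one window, is classified.
    """
    if class_order is None:
        class_order = tuple(groups)
    group_of = {lab: g for g, labs in groups.items() for lab in labs}
    idx = {g: i for i, g in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for rep in range(repeats):
        train, test = split_train_test(
            data, SplitSpec(spec.train_fraction, False, spec.seed + rep, spec.stratified)
        )
        norm = fit_normalization(train)
        tr_mat = apply_normalization(norm, train.to_matrix())
        tr_groups = [group_of[l] for l in train.labels]
        pooled = LabeledPatternSet(tr_mat, tr_groups, list(groups))
        models = fit_class_models(pooled)
        te_mat = apply_normalization(norm, test.to_matrix())
        te_groups = np.asarray([group_of[l] for l in test.labels])
        for g in class_order:
            sel = te_mat[te_groups == g]
            if sel.shape[0] < 2:
                continue
            assigned = separability_classify(sel, models)
            counts[idx[g], idx[assigned]] += 1
    return ConfusionMatrix.from_counts(class_order, counts)


def load_printed_table(name: str) -> ConfusionMatrix:
    """Load one of the packaged reference confusion matrices (t1 ... t7).

    t1-t4 are the 8-class Euclidean/k-NN matrices (50/50, 60/40, 70/30 and
    leave-one-out splits); t5-t7 are the 3-group Bhattacharyya matrices.
    """
    ref = importlib.resources.files("ctexture").joinpath(f"data/tables/{name}.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col=0)
    return ConfusionMatrix.from_proportions(tuple(df.index), df.to_numpy(dtype=float))
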