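"""Metrics, record-wise fold plans, grid-search selection, repeated CV.

All evaluation is *record-wise*: whole patient records are assigned to folds
so no patient's segments ever appear on both sides of a split (a runtime
leakage guard asserts this for every executed split).  The four measures are
on the percent scale with the shockable class positive:

    Se  = 100 * TP / (TP + FN)         (sensitivity)
    Sp  = 100 * TN / (TN + FP)         (specificity)
    Ac  = 100 * (TP + TN) / total      (accuracy)
    BER = 100 - (Se + Sp) / 2          (balanced error rate)

Model selection runs a grid over the five CNN parameters (ns, nd, lr,
momentum, dropout) with an inner record-wise 5-fold CV on the training data;
per scoring route (the network's own softmax = fCNN, or a conventional
classifier on the first-FC features = CNNE) the configuration with minimum
mean BER wins, ties broken toward fewer parameters, then lower learning rate.

Validation repeats the record-wise k-fold CV with fresh fold plans and
reports mean +/- std of the measures over repetitions; the feature extractor
stays fixed (trained upstream, never on the evaluation records) and only the
conventional classifier is retrained per fold.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import classify as _classify
from .cnn import CnnConfig, CnnModel, build_cnne, count_parameters, extract_features, \
    predict_fcnn, train_cnne
from .records import ChannelStack

__all__ = [
    "MetricsReport",
    "FoldPlan",
    "GridSpec",
    "compute_metrics",
    "make_record_folds",
    "grid_search_select",
    "validate_cv",
    "best_by_accuracy",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    """Confusion counts and the four measures; optionally mean +/- std."""

    tp: int
    fn: int
    tn: int
    fp: int
    ac: float
    se: float | None
    sp: float | None
    ber: float
    ac_std: float = 0.0
    se_std: float = 0.0
    sp_std: float = 0.0
    ber_std: float = 0.0
    n_reps: int = 1
    rep_ac: list[float] = field(default_factory=list)

    def summary(self) -> str:
        def fmt(m, s):
            return "undefined" if m is None else f"{m:.2f} +/- {s:.2f}"

        return (
            f"Ac {fmt(self.ac, self.ac_std)} | Se {fmt(self.se, self.se_std)} | "
            f"Sp {fmt(self.sp, self.sp_std)} | BER {fmt(self.ber, self.ber_std)} "
            f"(TP={self.tp} FN={self.fn} TN={self.tn} FP={self.fp}, "
            f"{self.n_reps} rep{'s' if self.n_reps != 1 else ''})"
        )


def compute_metrics(true_labels, predicted_labels) -> MetricsReport:
    """Confusion counts and Ac/Se/Sp/BER from 0/1 label vectors."""
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty label vectors")
    if y.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be 0 (NSH) or 1 (SH)")
    tp = int(((y == 1) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    ac = 100.0 * (tp + tn) / len(y)
    se = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    sp = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    if se is None and sp is None:
        raise ValueError("cannot score an empty confusion table")
    if se is None or sp is None:
        warnings.warn(
            "one class absent from the truth; BER computed from the available "
            "class rate only", stacklevel=2,
        )
        ber = 100.0 - (se if se is not None else sp)
    else:
        ber = 100.0 - (se + sp) / 2.0
    return MetricsReport(tp=tp, fn=fn, tn=tn, fp=fp, ac=ac, se=se, sp=sp, ber=ber)


@dataclass
class FoldPlan:
    """record_id -> fold index; every record in exactly one fold."""

    k: int
    assignment: dict[str, int]
    seed: int

    def fold_records(self, fold: int) -> list[str]:
        return [r for r, f in self.assignment.items() if f == fold]

    def splits(self):
        """Yield (train_record_ids, test_record_ids) per fold."""
        for fold in range(self.k):
            test = set(self.fold_records(fold))
            train = set(self.assignment) - test
            _assert_no_overlap(train, test)
            yield train, test


def _assert_no_overlap(train_records: set, test_records: set) -> None:
    overlap = train_records & test_records
    if overlap:
        raise RuntimeError(f"record leakage between train and test: {sorted(overlap)}")


def make_record_folds(record_ids, k: int, seed: int = 0) -> FoldPlan:
    """Seeded near-equal partition of records into k folds."""
    ids = list(record_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("record ids must be unique")
    if len(ids) < k:
        raise ValueError(f"need at least {k} records for {k} folds, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    assignment = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for rid in chunk:
            assignment[str(rid)] = fold
    return FoldPlan(k=k, assignment=assignment, seed=seed)


@dataclass
class GridSpec:
    """Candidate values for the five CNN selection parameters."""

    ns: tuple[int, ...] = (1, 3)
    nd: tuple[int, ...] = (1, 2, 3)
    lr: tuple[float, ...] = (0.005, 0.01, 0.02)
    momentum: tuple[float, ...] = (0.7, 0.8, 0.9)
    dropout: tuple[float, ...] = (0.1, 0.15, 0.2)

    def __len__(self) -> int:
        return (len(self.ns) * len(self.nd) * len(self.lr) * len(self.momentum)
                * len(self.dropout))

    def configs(self, **common) -> list[CnnConfig]:
        out = []
        for ns, nd, lr, mo, re_ in itertools.product(
            self.ns, self.nd, self.lr, self.momentum, self.dropout
        ):
            out.append(CnnConfig(ns=ns, nd=nd, lr=lr, momentum=mo, dropout=re_,
                                 **common))
        return out

    @staticmethod
    def explicit(configs: list[CnnConfig]) -> "ExplicitGrid":
        return ExplicitGrid(list(configs))


@dataclass
class ExplicitGrid:
    """A grid given as an explicit config list (e.g. just the known winners)."""

    _configs: list[CnnConfig]

    def __len__(self) -> int:
        return len(self._configs)

    def configs(self, **common) -> list[CnnConfig]:
        import dataclasses
        return [dataclasses.replace(c, **common) for c in self._configs]


def _dataset_arrays(stacks: list[ChannelStack]):
    x = np.stack([s.as_array() for s in stacks]).astype(np.float32)
    y = np.array([s.label for s in stacks], dtype=int)
    rids = np.array([s.record_id for s in stacks])
    if (rids == "").any():
        raise ValueError("every ChannelStack needs a record_id for record-wise CV")
    return x, y, rids


@dataclass
class SelectionResult:
    scorer: str
    config: CnnConfig
    cv_ber: float
    per_config_ber: list[tuple[CnnConfig, float]]


def grid_search_select(
    train_stacks: list[ChannelStack],
    grid,
    selectors: tuple[str, ...] = ("SVM", "KNN", "RF"),
    k: int = 5,
    seed: int = 0,
    epochs: int | None = None,
    batch_size: int | None = None,
) -> dict[str, SelectionResult]:
    """Grid search with nested record-wise k-fold CV on the training data.

    For every config: train the network per inner fold; score (a) the fCNN by
    its own softmax predictions on the held-out fold and (b) each selector
    classifier trained on fold-train features and tested on fold-test
    features.  Returns per scoring route ('fCNN' plus each selector) the
    config minimizing mean BER (ties: fewer parameters, then lower lr).
    """
    configs = grid.configs() if not isinstance(grid, list) else list(grid)
    if not configs:
        raise ValueError("empty configuration grid")
    x, y, rids = _dataset_arrays(train_stacks)
    plan = make_record_folds(sorted(set(rids)), k, seed=seed)
    scorers = ("fCNN", *selectors)
    bers: dict[str, list[float]] = {s: [] for s in scorers}

    for ci, cfg in enumerate(configs):
        fold_bers: dict[str, list[float]] = {s: [] for s in scorers}
        for fi, (train_rec, test_rec) in enumerate(plan.splits()):
            tr = np.isin(rids, sorted(train_rec))
            te = ~tr
            model = build_cnne(cfg, seed=seed + 1000 * ci + fi)
            try:
                train_cnne(model, (x[tr], y[tr]), epochs=epochs,
                           batch_size=batch_size, seed=seed + 1000 * ci + fi)
            except RuntimeError as err:
                # divergent training (e.g. absurd learning rate): worst score
                logger.warning("config %s fold %d: %s", cfg, fi, err)
                for s in scorers:
                    fold_bers[s].append(100.0)
                continue
            pred, _ = predict_fcnn(model, x[te])
            fold_bers["fCNN"].append(compute_metrics(y[te], pred).ber)
            feats_tr = extract_features(model, x[tr])
            feats_te = extract_features(model, x[te])
            for name in selectors:
                clf = _classify.train_classifier(
                    _classify.ClassifierSpec(name=name, seed=seed), feats_tr, y[tr]
                )
                fold_bers[name].append(
                    compute_metrics(y[te], _classify.predict(clf, feats_te)).ber
                )
        for s in scorers:
            bers[s].append(float(np.mean(fold_bers[s])))

    results = {}
    for s in scorers:
        ranked = sorted(
            range(len(configs)),
            key=lambda i: (bers[s][i], count_parameters(configs[i]), configs[i].lr),
        )
        best = ranked[0]
        results[s] = SelectionResult(
            scorer=s,
            config=configs[best],
            cv_ber=bers[s][best],
            per_config_ber=list(zip(configs, bers[s])),
        )
    return results


def validate_cv(
    eval_stacks: list[ChannelStack],
    extractor: CnnModel,
    spec: "_classify.ClassifierSpec",
    k: int = 5,
    reps: int = 100,
    seed: int = 0,
) -> MetricsReport:
    """Repeated record-wise k-fold CV of a classifier on extractor features.

    Features are extracted once for all evaluation segments; each repetition
    draws a fresh record-wise fold plan (seed + rep index), retrains the
    conventional classifier per fold, and pools the five folds' predictions
    into one confusion table.  Returns mean +/- std of the measures over
    repetitions (counts are from the last repetition's pooled table).

    Raises if the extractor was trained on any evaluation record (leakage).
    """
    x, y, rids = _dataset_arrays(eval_stacks)
    overlap = set(extractor.train_record_ids) & set(rids.tolist())
    if overlap:
        raise RuntimeError(
            f"extractor saw evaluation records during training: {sorted(overlap)}"
        )
    feats = extract_features(extractor, x)
    per_rep: list[MetricsReport] = []
    for rep in range(reps):
        plan = make_record_folds(sorted(set(rids)), k, seed=seed + rep)
        pred = np.full(len(y), -1, dtype=int)
        for train_rec, test_rec in plan.splits():
            tr = np.isin(rids, sorted(train_rec))
            te = ~tr
            clf = _classify.train_classifier(
                _classify.ClassifierSpec(name=spec.name, params=spec.params,
                                         standardize=spec.standardize,
                                         seed=spec.seed + rep),
                feats[tr], y[tr],
            )
            pred[te] = _classify.predict(clf, feats[te])
        per_rep.append(compute_metrics(y, pred))

    def agg(attr):
        vals = [getattr(r, attr) for r in per_rep]
        if any(v is None for v in vals):
            return None, 0.0
        return float(np.mean(vals)), float(np.std(vals))

    ac, ac_s = agg("ac")
    se, se_s = agg("se")
    sp, sp_s = agg("sp")
    ber, ber_s = agg("ber")
    last = per_rep[-1]
    return MetricsReport(tp=last.tp, fn=last.fn, tn=last.tn, fp=last.fp,
                         ac=ac, se=se, sp=sp, ber=ber,
                         ac_std=ac_s, se_std=se_s, sp_std=sp_s, ber_std=ber_s,
                         n_reps=reps, rep_ac=[r.ac for r in per_rep])


def best_by_accuracy(reports: dict[str, MetricsReport]) -> str:
    """Final-algorithm choice: the route with the highest mean accuracy."""
    if not reports:
        raise ValueError("no reports to choose from")
    return max(reports, key=lambda name: reports[name].ac)


def validate_fcnn_cv(
    eval_stacks: list[ChannelStack],
    config: CnnConfig,
    k: int = 5,
    reps: int = 10,
    seed: int = 0,
    epochs: int | None = None,
) -> MetricsReport:
    """Repeated record-wise CV of the full CNN, retrained per fold."""
    x, y, rids = _dataset_arrays(eval_stacks)
    per_rep = []
    for rep in range(reps):
        plan = make_record_folds(sorted(set(rids)), k, seed=seed + rep)
        pred = np.full(len(y), -1, dtype=int)
        for fi, (train_rec, test_rec) in enumerate(plan.splits()):
            tr = np.isin(rids, sorted(train_rec))
            te = ~tr
            model = build_cnne(config, seed=seed + 97 * rep + fi)
            train_cnne(model, (x[tr], y[tr]), epochs=epochs,
                       seed=seed + 97 * rep + fi)
            pred[te], _ = predict_fcnn(model, x[te])
        per_rep.append(compute_metrics(y, pred))
    ac = [r.ac for r in per_rep]
    ber = [r.ber for r in per_rep]
    se = [r.se for r in per_rep]
    sp = [r.sp for r in per_rep]
    last = per_rep[-1]
    return MetricsReport(
        tp=last.tp, fn=last.fn, tn=last.tn, fp=last.fp,
        ac=float(np.mean(ac)), se=None if None in se else float(np.mean(se)),
        sp=None if None in sp else float(np.mean(sp)), ber=float(np.mean(ber)),
        ac_std=float(np.std(ac)), ber_std=float(np.std(ber)), n_reps=reps,
    )
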