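"""Cross-validation harnesses, metrics and report generation.

Protocols
---------
``loocv``
    Leave-one-out over the pooled baseline sample (study-A session 1 plus
    study-B): train on N-1 subjects, predict the held-out subject.
``loso``
    Leave-one-subject-out over all sessions: every session of the held-out
    subject is in the test side, so longitudinal data never leaks.
``cross_study``
    Train on one set of study sessions, test on another (e.g. A1+B -> A2),
    with subjects confined to one side by construction of the session splits.

Metrics are the standard confusion-matrix family (SEN, SPE, PPV, NPV), the
balanced accuracy BAC = (SEN+SPE)/2, and the area under the precision-recall
curve computed as step-wise average precision.  Multiclass tasks are scored
macro one-vs-rest, with BAC the mean of per-class recalls.  Every task is
benchmarked against the majority baseline (always predict the most frequent
class).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .cohort import CohortBundle
from .fusion import EnsembleConfig, fit_predict_feature_set, fuse_multiclass, late_fuse
from .labels import CutoffRegistry, median_cutoff, severity_labels

logger = logging.getLogger(__name__)

__all__ = [
    "TaskSpec",
    "MetricsReport",
    "run_task",
    "compute_metrics",
    "majority_baseline",
    "write_report",
    "read_report",
]

MULTICLASS_TIE_ORDER = ("SCZ", "MDD", "HC")


@dataclass(frozen=True)
class TaskSpec:
    """Definition of a classification or severity-prediction task.

    For ``kind="classification"``, ``classes`` lists the contrast; each entry
    is a diagnosis or a tuple of diagnoses pooled into one class.  The first
    entry is the positive class (patients before controls).  For
    ``kind="severity"``, ``sample`` restricts the diagnoses included and the
    task is Above-vs-Below ``threshold`` on ``scale`` (``"median"`` applies
    the median rule inside each training fold).
    """

    name: str
    kind: str = "classification"
    classes: tuple = ("SCZ", "HC")
    sample: tuple[str, ...] = ("SCZ", "MDD", "HC")
    scale: str | None = None
    threshold: float | str | None = None
    feature_sets: tuple[str, ...] = ("Conversational",)
    split: str | tuple = "loocv"

    def __post_init__(self) -> None:
        if self.kind not in ("classification", "severity"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.kind == "severity" and (self.scale is None or self.threshold is None):
            raise ValueError("severity tasks need a scale and threshold")


@dataclass
class MetricsReport:
    task: str
    n: int
    counts: dict[str, int] = field(default_factory=dict)
    sen: float | None = None
    spe: float | None = None
    ppv: float | None = None
    npv: float | None = None
    bac: float | None = None
    auprc: float | None = None
    mb: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(**d)


def majority_baseline(labels: Sequence) -> float:
    """Accuracy of always predicting the most frequent class."""
    lab = list(labels)
    if not lab:
        raise ValueError("empty labels")
    _, counts = np.unique(np.asarray(lab), return_counts=True)
    return float(np.max(counts) / len(lab))


def _safe_div(num: float, den: float) -> float | None:
    return float(num / den) if den > 0 else None


def compute_metrics(
    y_true,
    y_pred,
    scores=None,
    task: str = "",
    class_order: tuple[str, ...] | None = None,
) -> MetricsReport:
    """Confusion-matrix metrics for binary or multiclass predictions.

    Binary labels are 0/1 with 1 the positive class.  Multiclass labels are
    strings; ``scores`` is then an (n, n_classes) matrix in ``class_order``
    and the metrics are macro-averaged one-vs-rest, with BAC the mean of
    per-class recalls.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = np.unique(y_true)
    if classes.size > 2 or y_true.dtype.kind in "US":
        order = class_order or tuple(sorted(set(y_true)))
        sens, spes, ppvs, npvs, auprcs, recalls = [], [], [], [], [], []
        for k, cls in enumerate(order):
            t = (y_true == cls).astype(int)
            p = (y_pred == cls).astype(int)
            r = compute_metrics(t, p, None if scores is None else scores[:, k])
            for acc, v in (
                (sens, r.sen), (spes, r.spe), (ppvs, r.ppv),
                (npvs, r.npv), (auprcs, r.auprc),
            ):
                if v is not None:
                    acc.append(v)
            if r.sen is not None:
                recalls.append(r.sen)
        mean = lambda xs: float(np.mean(xs)) if xs else None  # noqa: E731
        return MetricsReport(
            task=task,
            n=int(y_true.size),
            counts={str(c): int(np.sum(y_true == c)) for c in order},
            sen=mean(sens),
            spe=mean(spes),
            ppv=mean(ppvs),
            npv=mean(npvs),
            bac=mean(recalls),
            auprc=mean(auprcs),
            mb=majority_baseline(y_true),
        )

    yt = y_true.astype(int)
    yp = y_pred.astype(int)
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    sen = _safe_div(tp, tp + fn)
    spe = _safe_div(tn, tn + fp)
    bac = (sen + spe) / 2.0 if sen is not None and spe is not None else None
    auprc = None
    if scores is not None and np.unique(yt).size == 2:
        auprc = float(average_precision_score(yt, np.asarray(scores, dtype=float)))
    return MetricsReport(
        task=task,
        n=int(yt.size),
        counts={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        sen=sen,
        spe=spe,
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
        bac=bac,
        auprc=auprc,
        mb=majority_baseline(yt),
    )


def _class_of(diagnosis: str, cls) -> bool:
    return diagnosis in cls if isinstance(cls, tuple) else diagnosis == cls


def _select_records(bundle: CohortBundle, spec: TaskSpec) -> pd.DataFrame:
    if spec.split == "loocv":
        rec = bundle.records_for("baseline")
    elif spec.split == "loso":
        rec = bundle.records_for("all")
    else:
        rec = bundle.records_for("all")
    if spec.kind == "classification":
        keep = rec.diagnosis.map(
            lambda d: any(_class_of(d, c) for c in spec.classes)
        )
    else:
        keep = rec.diagnosis.isin(spec.sample) & np.isfinite(rec[spec.scale])
    return rec[keep]


def _folds(rec: pd.DataFrame, spec: TaskSpec):
    """Yield (train_ids, test_ids) record-id index pairs per fold."""
    if spec.split in ("loocv", "loso"):
        for sid in rec.subject_id.unique():
            test = rec.index[rec.subject_id == sid]
            train = rec.index[rec.subject_id != sid]
            yield list(train), list(test)
    else:
        tag, train_splits, test_split = spec.split
        if tag != "cross_study":
            raise ValueError(f"unknown split {spec.split!r}")
        sess = rec["study"] + rec["session"].astype(str)
        sess = sess.where(rec["study"] == "A", "B")

        def in_split(names):
            return sess.isin([n if n.startswith("A") else "B" for n in names])

        train = rec.index[in_split(train_splits)]
        test = rec.index[in_split([test_split])]
        # A subject may never sit on both sides.  When the training sessions
        # include earlier visits of the test subjects (e.g. A1+B -> A2), the
        # harness goes subject-by-subject, excluding the held-out subject's
        # own records from the training side (leave-one-subject-out within
        # the session split).
        tr_subj = set(rec.loc[train, "subject_id"])
        te_subj = set(rec.loc[test, "subject_id"])
        if not tr_subj & te_subj:
            yield list(train), list(test)
        else:
            for sid in rec.loc[test, "subject_id"].unique():
                te_ids = [r for r in test if rec.loc[r, "subject_id"] == sid]
                tr_ids = [r for r in train if rec.loc[r, "subject_id"] != sid]
                yield tr_ids, te_ids


def _binary_labels(rec: pd.DataFrame, spec: TaskSpec, threshold: float | None,
                   registry: CutoffRegistry) -> np.ndarray:
    if spec.kind == "classification":
        return rec.diagnosis.map(lambda d: int(_class_of(d, spec.classes[0]))).to_numpy()
    return severity_labels(rec[spec.scale], spec.scale, threshold, registry)


def run_task(
    bundle: CohortBundle,
    spec: TaskSpec,
    config: EnsembleConfig | None = None,
    registry: CutoffRegistry | None = None,
) -> tuple[MetricsReport, pd.DataFrame, list[tuple[list, list]]]:
    """Run one task end to end; returns (report, predictions, folds).

    ``predictions`` has one row per evaluated record with the fused score and
    predicted/true labels; ``folds`` lists the (train, test) record ids of
    every fold for leakage auditing.
    """
    config = config or EnsembleConfig()
    registry = registry or CutoffRegistry()
    rec = _select_records(bundle, spec)
    multiclass = spec.kind == "classification" and len(spec.classes) > 2

    missing = [fs for fs in spec.feature_sets if fs not in bundle.tables]
    if missing:
        raise ValueError(f"feature sets not in cohort: {missing}")

    rows = []
    fold_log: list[tuple[list, list]] = []
    for train_ids, test_ids in _folds(rec, spec):
        fold_log.append((train_ids, test_ids))
        tr = rec.loc[train_ids]
        te = rec.loc[test_ids]
        thr = None
        if spec.kind == "severity":
            thr = spec.threshold
            if thr == "median":
                thr = median_cutoff(tr[spec.scale].to_numpy())
        if multiclass:
            per_class: dict[str, np.ndarray] = {}
            y_tr_dx = tr.diagnosis.to_numpy()
            skip = False
            for cls in spec.classes:
                y_tr = np.array([int(_class_of(d, cls)) for d in y_tr_dx])
                if np.unique(y_tr).size < 2:
                    skip = True
                    break
                set_scores = {
                    fs: fit_predict_feature_set(
                        bundle.tables[fs].loc[train_ids], y_tr,
                        bundle.tables[fs].loc[test_ids], config,
                    )
                    for fs in spec.feature_sets
                }
                fused = [
                    late_fuse({fs: set_scores[fs][i] for fs in spec.feature_sets},
                              mode=config.fusion)[0]
                    for i in range(len(test_ids))
                ]
                key = cls if isinstance(cls, str) else "+".join(cls)
                per_class[key] = np.asarray(fused)
            if skip:
                logger.warning("fold skipped: a class is absent from training")
                continue
            for i, rid in enumerate(test_ids):
                scores_i = {k: float(v[i]) for k, v in per_class.items()}
                pred = fuse_multiclass(scores_i, order=MULTICLASS_TIE_ORDER)
                rows.append(
                    {
                        "record_id": rid,
                        "subject_id": te.loc[rid, "subject_id"],
                        "y_true": te.loc[rid, "diagnosis"],
                        "y_pred": pred,
                        **{f"score_{k}": v for k, v in scores_i.items()},
                    }
                )
        else:
            y_tr = _binary_labels(tr, spec, thr, registry)
            y_te = _binary_labels(te, spec, thr, registry)
            ok_tr = y_tr >= 0
            if np.unique(y_tr[ok_tr]).size < 2:
                logger.warning("fold skipped: single-class training labels")
                continue
            tr_ids_ok = [rid for rid, ok in zip(train_ids, ok_tr) if ok]
            set_scores = {
                fs: fit_predict_feature_set(
                    bundle.tables[fs].loc[tr_ids_ok], y_tr[ok_tr],
                    bundle.tables[fs].loc[test_ids], config,
                )
                for fs in spec.feature_sets
            }
            for i, rid in enumerate(test_ids):
                if y_te[i] < 0:
                    continue  # missing score: subject excluded from the task
                score, pred = late_fuse(
                    {fs: float(set_scores[fs][i]) for fs in spec.feature_sets},
                    mode=config.fusion,
                )
                rows.append(
                    {
                        "record_id": rid,
                        "subject_id": te.loc[rid, "subject_id"],
                        "y_true": int(y_te[i]),
                        "y_pred": pred,
                        "score": score,
                    }
                )

    if not rows:
        raise ValueError("no evaluable folds for this task")
    pred_df = pd.DataFrame(rows).set_index("record_id")
    if multiclass:
        order = tuple(
            c if isinstance(c, str) else "+".join(c) for c in spec.classes
        )
        score_mat = pred_df[[f"score_{c}" for c in order]].to_numpy()
        report = compute_metrics(
            pred_df.y_true.to_numpy(), pred_df.y_pred.to_numpy(),
            score_mat, task=spec.name, class_order=order,
        )
    else:
        report = compute_metrics(
            pred_df.y_true.to_numpy().astype(int),
            pred_df.y_pred.to_numpy().astype(int),
            pred_df.score.to_numpy(),
            task=spec.name,
        )
    return report, pred_df, fold_log


REPORT_COLUMNS = ("task", "n", "sen", "spe", "ppv", "npv", "auprc", "bac", "mb")


def write_report(reports: Sequence[MetricsReport], csv_path=None, json_path=None) -> pd.DataFrame:
    """Tabulate reports (one row per task); optionally write CSV and JSON."""
    if not reports:
        raise ValueError("no reports to write")
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in REPORT_COLUMNS} for r in reports]
    )
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([r.to_dict() for r in reports], fh, indent=2)
    return df


def read_report(json_path) -> list[MetricsReport]:
    with open(json_path) as fh:
        return [MetricsReport.from_dict(d) for d in json.load(fh)]
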