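"""Dual 10-fold cross-validation: beat-based (stratified) and record-based
(subject-grouped) evaluation of the full pipeline.

Beat-based folds stratify individual beats over classes, so one
subject's beats can appear on both sides of a fold — the optimistic,
within-patient protocol.  Record-based folds group by record (subject):
every test beat comes from patients unseen in training, the protocol
that measures generalization to new individuals.

Per fold the pipeline is fitted strictly on the training side: wavelet
features are deterministic per beat and precomputed once, but the PCA
basis, the feature scaler and every pairwise SVM see training beats
only.  The test side is projected through the frozen models and scored.
Across folds, per-class and micro SEN/SPE/ACC are aggregated as mean and
standard deviation, skipping (and counting) folds where a rate is
undefined because a rare class missed the test set.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import ovo_svm, pca, wmra
from .errors import ConfigError, DataError
from .io import BeatAnnotation, EcgRecord, keep_labeled
from .metrics import MetricsReport, confusion, report
from .ovo_svm import OvoModel, SvmConfig
from .segment import SegmentationConfig, segment_record
from .wmra import WaveletConfig

logger = logging.getLogger(__name__)

#: Reproducibility anchor used by the CLI when no seed is given.
DEFAULT_SEED = 20170720


@dataclass(frozen=True)
class FoldSplit:
    """Train/test beat-index membership of one fold (1-based index)."""

    fold_index: int
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        train = np.asarray(self.train_idx, dtype=np.int64)
        test = np.asarray(self.test_idx, dtype=np.int64)
        object.__setattr__(self, "train_idx", train)
        object.__setattr__(self, "test_idx", test)
        if np.intersect1d(train, test).size:
            raise ValueError(f"fold {self.fold_index}: train/test overlap")


@dataclass(frozen=True)
class RecordAssignment:
    """Explicit fold -> test-record mapping (a record may repeat)."""

    test_records: Mapping[int, tuple[str, ...]]

    @property
    def n_folds(self) -> int:
        return len(self.test_records)


def mitdb_record_assignment() -> RecordAssignment:
    """The bundled MIT-BIH record division for record-based 10-fold CV."""
    text = resources.files("wavebeat.data").joinpath(
        "mitdb_record_folds.json").read_text()
    raw = json.loads(text)
    return RecordAssignment(test_records={
        int(k): tuple(v) for k, v in raw.items()
    })


class StratificationWarning(UserWarning):
    """A class has fewer beats than folds; some test folds will miss it."""


class CoverageWarning(UserWarning):
    """A fold's training records do not cover every class."""


def beat_folds(labels: Sequence[str], k: int, seed: int) -> list[FoldSplit]:
    """Stratified k-fold split over individual beats.

    Each class's beats are shuffled with the seed and dealt round-robin
    to the k test folds, so per-fold class counts differ by at most one
    from perfect proportionality.
    """
    if k < 2:
        raise ConfigError("k must be >= 2")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = y.shape[0]
    fold_of = np.empty(n, dtype=np.int64)
    for cls in sorted(set(y.tolist())):
        idx = np.nonzero(y == cls)[0]
        if idx.size < k:
            warnings.warn(
                f"class {cls!r} has {idx.size} beats < {k} folds; "
                "it will miss some test folds", StratificationWarning)
        perm = rng.permutation(idx)
        fold_of[perm] = np.arange(perm.size) % k
    all_idx = np.arange(n)
    return [
        FoldSplit(fold_index=f + 1,
                  train_idx=all_idx[fold_of != f],
                  test_idx=all_idx[fold_of == f])
        for f in range(k)
    ]


def record_folds(record_ids: Sequence[str], k: int, seed: int,
                 explicit: RecordAssignment | None = None,
                 labels: Sequence[str] | None = None) -> list[FoldSplit]:
    """Subject-grouped k-fold split: no record straddles a fold.

    With ``explicit`` the folds follow the given record assignment
    exactly (test = beats of the listed records, train = all other
    records' beats; a record may be tested in several folds).  Otherwise
    records are shuffled with the seed and dealt round-robin into k
    disjoint test groups.  If ``labels`` are supplied, each fold's
    training records are checked to cover every class; a failure emits a
    :class:`CoverageWarning` naming fold and class.
    """
    rid = np.asarray(record_ids)
    y = np.asarray(labels) if labels is not None else None
    if explicit is not None:
        folds = []
        for f in sorted(explicit.test_records):
            test_set = set(explicit.test_records[f])
            mask = np.isin(rid, list(test_set))
            folds.append(FoldSplit(fold_index=f,
                                   train_idx=np.nonzero(~mask)[0],
                                   test_idx=np.nonzero(mask)[0]))
    else:
        if k < 2:
            raise ConfigError("k must be >= 2")
        unique = sorted(set(rid.tolist()))
        if len(unique) < k:
            raise ConfigError(
                f"need >= {k} distinct records, got {len(unique)}")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(unique))
        group_of = {unique[j]: int(i % k) for i, j in enumerate(order)}
        fold_of = np.array([group_of[r] for r in rid])
        all_idx = np.arange(rid.shape[0])
        folds = [
            FoldSplit(fold_index=f + 1,
                      train_idx=all_idx[fold_of != f],
                      test_idx=all_idx[fold_of == f])
            for f in range(k)
        ]
    if y is not None:
        classes = sorted(set(y.tolist()))
        for fold in folds:
            train_classes = set(y[fold.train_idx].tolist())
            for cls in classes:
                if cls not in train_classes:
                    warnings.warn(
                        f"fold {fold.fold_index}: class {cls!r} absent from "
                        "training records", CoverageWarning)
    return folds


# --------------------------------------------------------------------------
# pipeline configuration and feature extraction

@dataclass(frozen=True)
class PipelineSettings:
    """Everything run_cv needs besides the data and the seed."""

    segmentation: SegmentationConfig = SegmentationConfig()
    wavelet: WaveletConfig = WaveletConfig()
    pca_components: int = 12
    pca_ratio_threshold: float | None = None  #: overrides pca_components
    svm: SvmConfig = SvmConfig()
    n_folds: int = 10


@dataclass(frozen=True)
class BeatTable:
    """Flat beat-level view of a dataset: raw features + bookkeeping."""

    raw_features: np.ndarray          # (n_beats, n_raw)
    labels: np.ndarray                # class label per beat
    record_ids: np.ndarray            # source record per beat
    skipped: int                      # boundary beats dropped

    @property
    def n_beats(self) -> int:
        return int(self.raw_features.shape[0])


def extract_beat_table(
    dataset: Sequence[tuple[EcgRecord, Sequence[BeatAnnotation]]],
    settings: PipelineSettings = PipelineSettings(),
) -> BeatTable:
    """Segment and wavelet-transform every labeled beat of every record."""
    rows, labels, rids = [], [], []
    skipped = 0
    for record, anns in dataset:
        labeled = keep_labeled(anns)
        segments, tally = segment_record(record, labeled, settings.segmentation)
        skipped += tally.total
        for seg in segments:
            result = wmra.decompose(seg, settings.wavelet)
            rows.append(wmra.assemble_raw_features(result))
            labels.append(seg.label)
            rids.append(seg.record_id)
    if not rows:
        raise DataError("dataset produced no feasible labeled beats")
    table = BeatTable(
        raw_features=np.vstack(rows),
        labels=np.asarray(labels),
        record_ids=np.asarray(rids),
        skipped=skipped,
    )
    logger.info("extracted %d beats (raw length %d, %d boundary beats skipped)",
                table.n_beats, table.raw_features.shape[1], skipped)
    return table


# --------------------------------------------------------------------------
# fold execution and aggregation

@dataclass(frozen=True)
class FoldModels:
    """The training-side fitted state of one fold (for leakage audits)."""

    pca_model: pca.PcaModel
    k_used: int
    ovo_model: OvoModel


@dataclass
class CvResult:
    """Per-fold reports plus mean/SD aggregation in Table-style blocks."""

    scheme: str
    classes: tuple[str, ...]
    folds: list[FoldSplit]
    reports: list[MetricsReport]
    models: list[FoldModels] | None = None

    def _collect(self, which: str, cls: str | None) -> np.ndarray:
        vals = []
        for rep in self.reports:
            rates = rep.micro if cls is None else rep.per_class[cls]
            vals.append(getattr(rates, which))
        return np.asarray(vals, dtype=np.float64)

    def mean_sd(self, which: str, cls: str | None = None) -> tuple[float, float, int]:
        """(mean, SD, n_undefined) of one rate across folds, skipping NaNs."""
        vals = self._collect(which, cls)
        defined = vals[~np.isnan(vals)]
        n_undef = int(np.isnan(vals).sum())
        if defined.size == 0:
            return _metrics.UNDEFINED, _metrics.UNDEFINED, n_undef
        sd = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
        return float(defined.mean()), sd, n_undef

    def summary_frame(self) -> pd.DataFrame:
        """Mean and SD blocks, rows = beat types + Total, like a report table."""
        rows = []
        for cls in list(self.classes) + [None]:
            name = cls if cls is not None else "Total"
            row: dict[str, object] = {"beat_type": name}
            for which in ("sen", "spe", "acc"):
                m, s, u = self.mean_sd(which, cls)
                row[f"{which}_mean"] = m
                row[f"{which}_sd"] = s
                row[f"{which}_undefined_folds"] = u
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "classes": list(self.classes),
            "n_folds": len(self.folds),
            "per_fold": [rep.to_dict() for rep in self.reports],
            "summary": self.summary_frame().to_dict(orient="records"),
        }


def _run_fold(table: BeatTable, fold: FoldSplit, settings: PipelineSettings,
              classes: tuple[str, ...]) -> tuple[MetricsReport, FoldModels]:
    X_train = table.raw_features[fold.train_idx]
    y_train = table.labels[fold.train_idx]
    X_test = table.raw_features[fold.test_idx]
    y_test = table.labels[fold.test_idx]

    pca_model = pca.fit_pca(X_train)
    if settings.pca_ratio_threshold is not None:
        k = pca.components_for_ratio(pca_model, settings.pca_ratio_threshold)
    else:
        k = min(settings.pca_components, pca_model.n_components)
    Z_train = pca.project(pca_model, X_train, k)
    Z_test = pca.project(pca_model, X_test, k)

    model = ovo_svm.train_ovo(Z_train, y_train, settings.svm)
    y_pred = ovo_svm.predict(model, Z_test)
    cm = confusion(list(y_test), list(y_pred), classes)
    return report(cm), FoldModels(pca_model=pca_model, k_used=k, ovo_model=model)


def run_cv_on_features(table: BeatTable, scheme: str,
                       settings: PipelineSettings, seed: int,
                       explicit: RecordAssignment | None = None,
                       keep_models: bool = False) -> CvResult:
    """Cross-validate a pre-extracted beat table (see :func:`run_cv`)."""
    if scheme not in ("beat", "record"):
        raise ConfigError(f"scheme must be 'beat' or 'record', got {scheme!r}")
    classes = tuple(sorted(set(table.labels.tolist())))
    if len(classes) < 2:
        raise DataError("dataset must contain at least 2 classes")
    if scheme == "beat":
        folds = beat_folds(table.labels, settings.n_folds, seed)
    else:
        folds = record_folds(table.record_ids, settings.n_folds, seed,
                             explicit=explicit, labels=table.labels)
    reports, models = [], []
    for fold in folds:
        rep, mdl = _run_fold(table, fold, settings, classes)
        reports.append(rep)
        models.append(mdl)
        logger.info("%s fold %d/%d: micro ACC %.4f", scheme, fold.fold_index,
                    len(folds), rep.micro.acc)
    return CvResult(scheme=scheme, classes=classes, folds=folds,
                    reports=reports, models=models if keep_models else None)


def run_cv(dataset: Sequence[tuple[EcgRecord, Sequence[BeatAnnotation]]],
           scheme: str, settings: PipelineSettings, seed: int,
           explicit: RecordAssignment | None = None,
           keep_models: bool = False) -> CvResult:
    """Run the full pipeline under k-fold CV with strict train-only fitting.

    Per fold: segment -> decompose -> assemble raw features (deterministic
    per beat, shared across folds) -> fit PCA on the training fold only ->
    project both sides -> standardize + train the one-vs-one SVM on the
    training fold only -> predict the test fold -> per-class and micro
    metrics.  Mean and SD are aggregated across folds.
    """
    table = extract_beat_table(dataset, settings)
    return run_cv_on_features(table, scheme, settings, seed,
                              explicit=explicit, keep_models=keep_models)


def default_sweep_values() -> list[int]:
    """Even component counts from 2 to 50."""
    return list(range(2, 51, 2))


def component_sweep(dataset, scheme: str, k_values: Sequence[int] | None,
                    settings: PipelineSettings, seed: int) -> pd.DataFrame:
    """Micro SEN/SPE/ACC as a function of the component count.

    Features are extracted once; each k re-runs the CV.  Returns a frame
    with columns (k, sen, spe, acc) sorted by k.
    """
    table = extract_beat_table(dataset, settings)
    if k_values is None:
        k_values = default_sweep_values()
    max_k = table.raw_features.shape[1]
    bad = [k for k in k_values if k > max_k]
    if bad:
        raise ConfigError(f"component counts {bad} exceed raw dimension {max_k}")
    rows = []
    for k in sorted(k_values):
        result = run_cv_on_features(
            table, scheme,
            settings=PipelineSettings(
                segmentation=settings.segmentation, wavelet=settings.wavelet,
                pca_components=k, pca_ratio_threshold=None,
                svm=settings.svm, n_folds=settings.n_folds),
            seed=seed)
        m, _, _ = result.mean_sd("sen")
        s, _, _ = result.mean_sd("spe")
        a, _, _ = result.mean_sd("acc")
        rows.append({"k": k, "sen": m, "spe": s, "acc": a})
    return pd.DataFrame(rows)
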