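"""Evaluation protocols: per-subject 5-fold CV, leave-one-subject-out CV,
and band/statistic/K sweeps.

Two regimes mirror how such decoders are validated:

* **subject-dependent** -- within each subject, stratified 5-fold
  cross-validation (80 % train / 20 % test per fold).  Channel statistics
  are fitted on the training folds only, so the ranking never sees test
  samples.  Subjects are evaluated independently and averaged with equal
  weight.
* **subject-independent** -- leave-one-subject-out (LOSO): each fold
  trains on all other subjects' segments (channel selection fitted on that
  training pool) and tests on the held-out subject.

Reported metrics are accuracy and macro-averaged F1 (unweighted mean of
the per-class F1 scores; a class with zero predicted and zero true
positives contributes 0).  The majority-class rate is reported alongside
as the chance reference, since the emotion classes are not balanced.
Wall time is recorded for context only, never asserted on.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold

from .channels import score_channels, select_top_k, apply_selection
from .errors import ValidationError
from .io import SegmentSet, concatenate_segments
from .models import ModelSpec, TrainConfig, TrainedModel, build_deep_model, build_model, predict, train
from .preprocess import BANDS, BandSpec, LabelScheme, bandpass, default_label_scheme, segment

__all__ = [
    "PipelineConfig",
    "EvalResult",
    "metrics",
    "kfold_subject_dependent",
    "evaluate_subjects",
    "loso_subject_independent",
    "sweep_k",
    "sweep_bands",
    "results_to_frame",
]


def metrics(y_true, y_pred) -> tuple[float, float]:
    """(accuracy, macro-F1) of binary predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 1:
        raise ValidationError("need at least one sample")
    acc = float(accuracy_score(y_true, y_pred))
    f1 = float(f1_score(y_true, y_pred, labels=[0, 1], average="macro", zero_division=0))
    return acc, f1


@dataclass(frozen=True)
class PipelineConfig:
    """Everything downstream of segmentation: selection + model + training.

    ``statistic=None`` disables channel selection (all-channels baseline).
    ``scale`` only sets the provenance field and the default epoch budget
    interpretation; the labels themselves are fixed at segmentation time.
    """

    statistic: str | None = "kurtosis"
    k: int | None = None
    scale: str = "valence"
    architecture: str = "shallow"
    train: TrainConfig = field(default_factory=TrainConfig)
    spec_overrides: dict = field(default_factory=dict)

    def model_spec(self, n_channels: int, n_timepoints: int) -> ModelSpec:
        return ModelSpec(
            n_channels=n_channels,
            n_timepoints=n_timepoints,
            architecture=self.architecture,
            **self.spec_overrides,
        )


@dataclass
class EvalResult:
    """Per-fold scores plus aggregates and provenance."""

    scheme: str
    scale: str
    band: str
    statistic: str
    k: object
    per_fold: list[tuple[float, float, int]]
    seed: int
    wall_time_s: float = 0.0
    majority_rate: float = float("nan")
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f[0] for f in self.per_fold]))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std([f[0] for f in self.per_fold]))

    @property
    def mean_f1(self) -> float:
        return float(np.mean([f[1] for f in self.per_fold]))

    def summary_row(self) -> dict:
        return {
            "scheme": self.scheme,
            "scale": self.scale,
            "band": self.band,
            "statistic": self.statistic,
            "k": self.k,
            "n_folds": len(self.per_fold),
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_f1": self.mean_f1,
            "majority_rate": self.majority_rate,
            "seed": self.seed,
        }  # wall_time_s stays off the summary so rerun files are identical


def _band_name(band) -> str:
    return band.name if isinstance(band, BandSpec) else str(band)


def _fold_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)).generate_state(1)[0] % (2**31))


def _fit_and_score(
    train_set: SegmentSet,
    test_set: SegmentSet,
    config: PipelineConfig,
    seed: int,
    fit_scope: str,
) -> tuple[float, float, int, TrainedModel]:
    """Select channels on the training data, train, score the test data."""
    if config.statistic is not None and config.statistic != "none":
        ranking = score_channels(train_set, config.statistic, scope="all", tolerate_degenerate=True)
        ranking = replace(ranking, fit_scope=fit_scope)
        k = config.k if config.k is not None else train_set.n_channels
        ranking = select_top_k(ranking, k)
        train_set = apply_selection(train_set, ranking)
        test_set = apply_selection(test_set, ranking)
    spec = config.model_spec(train_set.n_channels, train_set.n_timepoints)
    builder = build_model if config.architecture == "shallow" else build_deep_model
    model = builder(spec, seed=seed)
    model = train(model, train_set, replace(config.train, seed=seed))
    _, y_pred = predict(model, test_set)
    acc, f1 = metrics(test_set.labels, y_pred)
    return acc, f1, test_set.n_segments, model


def kfold_subject_dependent(
    segments: SegmentSet,
    config: PipelineConfig,
    n_folds: int = 5,
    seed: int = 0,
) -> EvalResult:
    """Stratified k-fold CV within one subject's segments.

    Channel statistics are fitted on the training folds only.  Each fold's
    model gets its own seed derived from ``seed``; the whole result is a
    pure function of (segments, config, n_folds, seed).
    """
    y = segments.labels
    if segments.n_segments < n_folds:
        raise ValidationError(f"need >= {n_folds} segments, got {segments.n_segments}")
    if len(np.unique(y)) < 2:
        raise ValidationError("subject has a single class; cannot cross-validate")
    t0 = time.perf_counter()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        acc, f1, n_test, _ = _fit_and_score(
            segments.subset(train_idx),
            segments.subset(test_idx),
            config,
            seed=_fold_seed(seed, fold),
            fit_scope="train_folds_only",
        )
        per_fold.append((acc, f1, n_test))
    counts = np.bincount(y, minlength=2)
    return EvalResult(
        scheme="subject_dependent",
        scale=config.scale,
        band=_band_name(segments.band),
        statistic=config.statistic or "none",
        k=config.k if config.statistic else "all",
        per_fold=per_fold,
        seed=seed,
        wall_time_s=time.perf_counter() - t0,
        majority_rate=float(counts.max() / counts.sum()),
    )


def evaluate_subjects(
    subject_segments: Sequence[SegmentSet],
    config: PipelineConfig,
    n_folds: int = 5,
    seed: int = 0,
) -> EvalResult:
    """Subject-dependent CV over several subjects, equal subject weight.

    Subjects that cannot be cross-validated (single class, too few
    segments) are skipped with the reason recorded, mirroring the exclusion
    of unusable subjects in the study protocol.  ``per_fold`` holds one
    entry per (subject, fold).
    """
    t0 = time.perf_counter()
    per_fold, skipped = [], []
    rates = []
    band = "broadband"
    for i, segs in enumerate(subject_segments):
        band = _band_name(segs.band)
        sid = str(segs.subject_ids[0]) if segs.n_segments else f"subject-{i}"
        try:
            res = kfold_subject_dependent(segs, config, n_folds=n_folds, seed=_fold_seed(seed, i))
        except ValidationError as exc:
            skipped.append((sid, str(exc)))
            continue
        per_fold.extend(res.per_fold)
        rates.append(res.majority_rate)
    if not per_fold:
        raise ValidationError(f"no usable subjects (skipped: {skipped})")
    return EvalResult(
        scheme="subject_dependent",
        scale=config.scale,
        band=band,
        statistic=config.statistic or "none",
        k=config.k if config.statistic else "all",
        per_fold=per_fold,
        seed=seed,
        wall_time_s=time.perf_counter() - t0,
        majority_rate=float(np.mean(rates)),
        skipped=skipped,
    )


def loso_subject_independent(
    subject_segments: Sequence[SegmentSet],
    config: PipelineConfig,
    seed: int = 0,
) -> EvalResult:
    """Leave-one-subject-out CV: one fold per subject.

    Channel selection is subject-independent: fitted on the pooled
    training subjects of each fold, never on the held-out subject.
    """
    if len(subject_segments) < 2:
        raise ValidationError("LOSO needs >= 2 subjects")
    t0 = time.perf_counter()
    per_fold = []
    all_labels = np.concatenate([s.labels for s in subject_segments])
    for i, held_out in enumerate(subject_segments):
        pool = concatenate_segments([s for j, s in enumerate(subject_segments) if j != i])
        acc, f1, n_test, _ = _fit_and_score(
            pool, held_out, config, seed=_fold_seed(seed, i), fit_scope="train_subjects_only"
        )
        per_fold.append((acc, f1, n_test))
    counts = np.bincount(all_labels, minlength=2)
    return EvalResult(
        scheme="subject_independent",
        scale=config.scale,
        band=_band_name(subject_segments[0].band),
        statistic=config.statistic or "none",
        k=config.k if config.statistic else "all",
        per_fold=per_fold,
        seed=seed,
        wall_time_s=time.perf_counter() - t0,
        majority_rate=float(counts.max() / counts.sum()),
    )


def sweep_k(
    segments: SegmentSet,
    statistic: str,
    k_values: Sequence[int],
    config: PipelineConfig,
    n_folds: int = 5,
    seed: int = 0,
    include_baseline: bool = True,
) -> list[EvalResult]:
    """Subject-dependent CV at each K, plus the all-channels baseline.

    Every K (and the baseline) is evaluated with the same seed, so rows are
    comparable; accuracy-vs-K curves plot straight from the result list.
    """
    results = []
    for k in k_values:
        cfg = replace(config, statistic=statistic, k=int(k))
        results.append(kfold_subject_dependent(segments, cfg, n_folds=n_folds, seed=seed))
    if include_baseline:
        cfg = replace(config, statistic=None, k=None)
        results.append(kfold_subject_dependent(segments, cfg, n_folds=n_folds, seed=seed))
    return results


def sweep_bands(
    recordings,
    bands: Sequence[str],
    config: PipelineConfig,
    scheme: LabelScheme | None = None,
    duration_s: float = 2.0,
    order: int = 4,
    n_folds: int = 5,
    seed: int = 0,
) -> list[EvalResult]:
    """Filter into each band, segment, and run subject-dependent CV.

    Identical seeds across bands make the rows directly comparable.
    ``recordings`` is one Recording or a list (one per subject).
    """
    from .io import Recording

    if isinstance(recordings, Recording):
        recordings = [recordings]
    if scheme is None:
        scheme = default_label_scheme(config.scale)
    results = []
    for band_name in bands:
        band = BANDS[band_name] if isinstance(band_name, str) else band_name
        subject_segments = [
            segment(bandpass(rec, band, order), duration_s, scheme, band=band) for rec in recordings
        ]
        results.append(evaluate_subjects(subject_segments, config, n_folds=n_folds, seed=seed))
    return results


def results_to_frame(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Summary table, one row per EvalResult."""
    return pd.DataFrame([r.summary_row() for r in results])


def folds_to_frame(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Long table, one row per fold of each result."""
    rows = []
    for r in results:
        for i, (acc, f1, n_test) in enumerate(r.per_fold):
            rows.append(
                {
                    "scheme": r.scheme,
                    "scale": r.scale,
                    "band": r.band,
                    "statistic": r.statistic,
                    "k": r.k,
                    "fold": i,
                    "accuracy": acc,
                    "f1": f1,
                    "n_test": n_test,
                    "seed": r.seed,
                }
            )
    return pd.DataFrame(rows)
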