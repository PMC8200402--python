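"""End-to-end orchestration: synthetic cohort -> features -> LOSO experiment.

Glue used by the command line, the test-suite and the acceptance script to
run the whole system on simulated cohorts.
"""

from __future__ import annotations

import numpy as np

from .classifiers import ClassifierSpec, LosoResult, SubjectData, loso_cross_validate
from .core import child_seed
from .features import compute_feature_table
from .features.engine import FeatureTable
from .labels import ScoreSeries
from .preprocess import preprocess_recording
from .simulate import (SimConfig, inject_artifacts, make_cohort,
                       simulate_raters, simulate_recording)

__all__ = ["build_subject", "build_cohort_dataset", "run_cohort_experiment"]


def build_subject(config: SimConfig, keep_per_channel: bool = False,
                  rater_confusion: float = 0.10,
                  rater_reject: float = 0.02) -> tuple[SubjectData, np.ndarray,
                                                       FeatureTable]:
    """Simulate, preprocess and featurize one subject.

    Returns the :class:`SubjectData` (with two simulated expert raters), the
    ground-truth score series and the feature table.
    """
    rec, truth = simulate_recording(config)
    if config.artifact_rate > 0:
        rec, _ = inject_artifacts(rec, config.artifact_rate,
                                  seed=child_seed(config.seed, "artifacts"))
    es = preprocess_recording(rec)
    ft = compute_feature_table(es, keep_per_channel=keep_per_channel)
    e1_scores, e2_scores = simulate_raters(
        truth, child_seed(config.seed, "raters"),
        confusion_prob=rater_confusion, reject_prob=rater_reject)
    data = SubjectData(
        subject_id=config.subject_id,
        features=ft.values,
        e1=ScoreSeries(config.subject_id, "E1", e1_scores),
        e2=ScoreSeries(config.subject_id, "E2", e2_scores),
        missing=ft.missing,
    )
    return data, truth, ft


def build_cohort_dataset(n_subjects: int = 10, hours: float = 3.0, seed: int = 0,
                         n_channels: int = 4, fs_native: float = 256.0,
                         artifact_rate: float = 0.0,
                         keep_per_channel: bool = False
                         ) -> tuple[list[SubjectData], dict[str, np.ndarray],
                                    list[FeatureTable]]:
    """Simulated cohort ready for LOSO cross-validation."""
    configs = make_cohort(n_subjects, hours, seed, n_channels, fs_native,
                          artifact_rate)
    dataset, truths, tables = [], {}, []
    for cfg in configs:
        data, truth, ft = build_subject(cfg, keep_per_channel=keep_per_channel)
        dataset.append(data)
        truths[cfg.subject_id] = truth
        tables.append(ft)
    return dataset, truths, tables


def run_cohort_experiment(n_subjects: int = 10, hours: float = 3.0,
                          seed: int = 0, spec: ClassifierSpec | None = None,
                          **cohort_kw) -> tuple[LosoResult, dict[str, np.ndarray]]:
    """Full experiment: simulate a cohort, extract features, run LOSO."""
    dataset, truths, _ = build_cohort_dataset(n_subjects, hours, seed, **cohort_kw)
    spec = spec or ClassifierSpec(seed=child_seed(seed, "clf"))
    return loso_cross_validate(dataset, spec), truths
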