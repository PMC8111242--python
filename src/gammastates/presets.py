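"""Preset configurations for the packaged recovery analyses.

The recovery cohort keeps the study-defining conditions (15 subjects, K=4
states, 250 Hz, 2-4 s baselines, planted between- and within-subject gamma
coupling) while running at desk scale: 8 parcels and 16 trials per subject,
so a full generate-fit-test cycle completes in well under a minute.
"""

from __future__ import annotations

from .pipeline import PipelineConfig
from .simulate import CohortConfig

__all__ = ["recovery_cohort_config", "recovery_pipeline_config"]


def recovery_cohort_config(seed: int, n_subjects: int = 15) -> CohortConfig:
    return CohortConfig(
        n_subjects=n_subjects,
        n_parcels=8,
        n_trials=16,
        rest_duration_s=0.0,
        roi_parcels=(6, 7),
        seed=seed,
    )


def recovery_pipeline_config(seed: int, n_perm: int = 2000, n_boot: int = 1000) -> PipelineConfig:
    return PipelineConfig(
        max_iter=30,
        n_restarts=1,
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
    )
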