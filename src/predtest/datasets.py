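"""Bundled worked example.

Summary statistics from a pre-post study of cerebral blood flow measured by
arterial spin labeling (ASL) in six brain regions of 11 older adults before
and after a 12-week exercise intervention.  The investigator predicted an
increase in every region; four of the six observed mean pre-post differences
were positive.  Only the published summary quantities (per-endpoint mean
differences, rounded endpoint weights and the prediction outcomes) are
available — the subject-level data are not deposited — so the example anchors
on the statistic T_m = 1.74 rather than on a re-derived p-value.
"""

from __future__ import annotations

import numpy as np

from .core import DirectionPredictions, PredictionOutcomes, WeightVector

__all__ = ["asl_example"]

_REGIONS = (
    "BA46",
    "FrontalMid",
    "Hippocampus",
    "M1",
    "SuperiorParietal",
    "Precuneus",
)
_MEAN_DIFFERENCES = (0.16, 0.44, -1.49, 1.07, 0.97, -0.24)
_WEIGHTS = (0.46, 0.41, 0.68, 0.48, 0.39, 0.40)


def asl_example() -> dict:
    """The six-region ASL worked example as ready-to-use objects.

    Returns a dict with ``endpoint_labels``, ``mean_differences`` (observed
    pre-post effect estimates), ``predictions`` (all +1), ``weights`` (the
    published rounded endpoint weights) and ``outcomes``
    (p = [1, 1, 0, 1, 1, 0]).
    """
    predictions = DirectionPredictions(
        np.ones(6, dtype=int), endpoint_labels=_REGIONS
    )
    return {
        "endpoint_labels": _REGIONS,
        "n_subjects": 11,
        "mean_differences": np.array(_MEAN_DIFFERENCES),
        "predictions": predictions,
        "weights": WeightVector(np.array(_WEIGHTS)),
        "outcomes": PredictionOutcomes(np.array([1, 1, 0, 1, 1, 0])),
    }
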