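"""SoftMax expert weights from per-detector mAP@0.5 scores.

Ensemble fusion follows a mixture-of-experts gating scheme: each detector
in the ensemble is scored once, globally, by its mAP@0.5 on validation
data, and the scores are turned into fusion weights with a plain SoftMax

    w_i = exp(mAP_i) / sum_j exp(mAP_j).

The weights are computed once per ensemble and reused for every cluster;
the fusion step then renormalizes over the members actually present in a
cluster.  mAP@0.5 itself is an *input* here — it is produced by whatever
detector framework trained the networks — so this module only validates
and transforms it.

Note that with mAP constrained to [0, 1] the SoftMax spreads weights only
mildly (the ratio of extreme weights is at most e ≈ 2.72); no temperature
or rescaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isfinite

import numpy as np
from scipy.special import softmax as _softmax

__all__ = ["DetectorProfile", "WeightVector", "softmax_weights", "read_profiles_csv"]


@dataclass(frozen=True)
class DetectorProfile:
    """A detector identity plus its global mAP@0.5 score in [0, 1]."""

    detector_id: str
    map50: float

    def __post_init__(self) -> None:
        if not isfinite(self.map50):
            raise ValueError(f"non-finite map50 for {self.detector_id!r}")
        if not (0.0 <= self.map50 <= 1.0):
            raise ValueError(
                f"map50 {self.map50} for {self.detector_id!r} outside [0, 1]"
            )


@dataclass(frozen=True)
class WeightVector:
    """Mapping detector_id -> positive weight; weights sum to one."""

    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(w <= 0.0 for w in self.weights.values()):
            raise ValueError("all weights must be strictly positive")
        total = sum(self.weights.values())
        if self.weights and abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {total}, not 1")

    def __getitem__(self, detector_id: str) -> float:
        return self.weights[detector_id]

    def __contains__(self, detector_id: str) -> bool:
        return detector_id in self.weights


def softmax_weights(profiles: list[DetectorProfile]) -> WeightVector:
    """SoftMax-normalize mAP@0.5 scores into fusion weights.

    Order-independent; a detector's weight is strictly increasing in its
    own score and strictly decreasing in every other score.  Raises
    ``ValueError`` on an empty profile list or duplicated detector ids.
    """
    if not profiles:
        raise ValueError("at least one detector profile is required")
    ids = [p.detector_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate detector_id in ensemble")
    scores = np.array([p.map50 for p in profiles], dtype=float)
    w = _softmax(scores)
    return WeightVector(dict(zip(ids, w.tolist())))


def read_profiles_csv(path) -> list[DetectorProfile]:
    """Read detector profiles from a CSV with header ``detector_id,map50``."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"detector_id": str})
    missing = {"detector_id", "map50"} - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV {path} missing columns {sorted(missing)}")
    return [
        DetectorProfile(str(r.detector_id), float(r.map50))
        for r in df.itertuples(index=False)
    ]
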