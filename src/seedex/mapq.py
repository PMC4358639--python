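"""Mapping-quality estimation.

MAPQ is -10*log10(p) where p estimates the probability that the read is
mapped to the wrong locus.  Two user-selectable models are provided:

* model A (range 0-60): p is driven by the gap between the best and
  second-best alignment scores, normalized by the attainable score range
  (perfect score down to the reporting threshold Vt), in the spirit of
  BWA-MEM's estimator.  k tied best mappings imply p >= 1 - 1/k, capping
  MAPQ at round(-10*log10(1 - 1/k)) <= 3.
* model B (range 0-44): a bucketed empirical mapping of the same
  quantities in the spirit of Bowtie 2's lookup logic; a unique
  high-scoring mapping gets 44, a tied best 0 or 1.

Both models are monotone: MAPQ never increases as the second-best score
rises toward the best.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

MAPQ_MAX_A = 60
MAPQ_MAX_B = 44


@dataclass(frozen=True)
class MapqInputs:
    best: int
    second: int | None          # None when no competitor was found
    tie_count: int              # mappings tied at the best score (>= 1)
    perfect: int                # 2 * aligned length under default scoring
    read_len: int
    vt: int | None = None       # reporting threshold; defaults to read_len

    def __post_init__(self):
        if self.second is not None and self.second > self.best:
            raise ValueError("second-best score exceeds best")
        if self.tie_count < 1:
            raise ValueError("tie_count must be >= 1")

    @property
    def threshold(self) -> int:
        return self.vt if self.vt is not None else self.read_len


def _gap_ratio(inputs: MapqInputs) -> float:
    """(best - second) / (perfect - Vt), clamped to [0, 1]; an absent
    second-best counts as a competitor at the reporting threshold."""
    span = max(1, inputs.perfect - inputs.threshold)
    second = inputs.second if inputs.second is not None else inputs.threshold
    return min(1.0, max(0.0, (inputs.best - second) / span))


def mapq_model_a(inputs: MapqInputs) -> int:
    """Score-gap model, range 0..60.

    The non-tied branch is 4 + 56*gap_ratio, so a barely-separated best
    mapping (4) still outranks any tied one (<= 3) and MAPQ is monotone in
    the score gap.
    """
    if inputs.tie_count >= 2:
        p = 1.0 - 1.0 / inputs.tie_count
        return min(3, round(-10.0 * math.log10(p)))
    return min(MAPQ_MAX_A, 4 + round((MAPQ_MAX_A - 4) * _gap_ratio(inputs)))


# (gap-ratio lower bound, MAPQ) buckets for model B with a competitor present
_B_BUCKETS = ((0.80, 40), (0.60, 34), (0.45, 27), (0.30, 20), (0.15, 12), (0.0, 5))


def mapq_model_b(inputs: MapqInputs) -> int:
    """Bucketed model, range 0..44."""
    span = max(1, inputs.perfect - inputs.threshold)
    best_over = (inputs.best - inputs.threshold) / span
    if inputs.tie_count >= 2:
        return 1 if best_over >= 0.67 else 0
    if inputs.second is None:
        if best_over >= 0.8:
            return MAPQ_MAX_B
        if best_over >= 0.6:
            return 40
        if best_over >= 0.4:
            return 32
        return 24
    g = _gap_ratio(inputs)
    if g == 0.0:
        return 1 if best_over >= 0.67 else 0
    for lo, q in _B_BUCKETS:
        if g >= lo and g > 0.0:
            return q
    return 0


def compute_mapq(inputs: MapqInputs, model: str = "a") -> int:
    if model == "a":
        return mapq_model_a(inputs)
    if model == "b":
        return mapq_model_b(inputs)
    raise ValueError(f"unknown MAPQ model {model!r}")
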