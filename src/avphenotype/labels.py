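"""Binarization of clinical assessment scores into severity classes.

Clinical rating scales (NSA-16, BPRS, PANSS, BACS) are continuous-ish ordinal
totals; classification tasks dichotomize them at clinically anchored cutoffs
linked to Clinical Global Impression severity levels.  The rule is
``Above`` iff score >= threshold; for cognition (BACS composite Z) severity
runs the other way, so the scale registry carries a polarity flag: a deficit
is a score *below* the cutoff (composite < -1 mild, < -2 severe).

Factor scores have no published cutoff; for those the threshold is the
observed value that splits the training subjects as evenly as possible
(the "median rule"), recomputed inside each training fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ABOVE",
    "BELOW",
    "CutoffRegistry",
    "DEFAULT_CUTOFFS",
    "binarize_score",
    "median_cutoff",
    "severity_labels",
]

ABOVE = "Above"
BELOW = "Below"

#: scale -> (sorted cutoffs, polarity). polarity "high" means higher scores are
#: more severe (positive class = Above); "low" means lower scores are more
#: severe (positive class = Below), as for the BACS composite Z-score.
DEFAULT_CUTOFFS: dict[str, tuple[tuple[float, ...], str]] = {
    "NSA-Total": ((39.75,), "high"),
    "BPRS-Total": ((24.0, 32.0), "high"),
    "PANSS-Total": ((38.0, 52.0), "high"),
    "PANSS-FSNS": ((9.5, 14.5), "high"),
    "BACS-Composite": ((-2.0, -1.0), "low"),
}


@dataclass
class CutoffRegistry:
    """Registry of clinically anchored cutoff scores per scale."""

    cutoffs: dict[str, tuple[tuple[float, ...], str]] = field(
        default_factory=lambda: dict(DEFAULT_CUTOFFS)
    )

    def thresholds(self, scale: str) -> tuple[float, ...]:
        return self.cutoffs[scale][0]

    def polarity(self, scale: str) -> str:
        return self.cutoffs.get(scale, ((), "high"))[1]

    def to_yaml(self, path) -> None:
        data = {
            scale: {"thresholds": list(thr), "polarity": pol}
            for scale, (thr, pol) in self.cutoffs.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "CutoffRegistry":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cutoffs = {
            scale: (tuple(sorted(d["thresholds"])), d.get("polarity", "high"))
            for scale, d in data.items()
        }
        return cls(cutoffs=cutoffs)


def binarize_score(score: float, threshold: float) -> str | None:
    """``Above`` iff score >= threshold, ``Below`` otherwise.

    A missing (NaN/None) score returns None: the subject is excluded from the
    task rather than silently assigned a class.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return None
    if not math.isfinite(score):
        raise ValueError(f"non-finite score {score!r}")
    return ABOVE if score >= threshold else BELOW


def median_cutoff(train_scores) -> float:
    """Observed-value threshold that splits the sample as evenly as possible.

    Candidates are the distinct observed scores; the one minimizing
    ``|#Above - #Below|`` wins, ties broken toward the sample median (then
    toward the smaller value).  Raises if all scores are identical, since the
    task would have a single class.
    """
    x = np.asarray([s for s in train_scores if not (s is None or np.isnan(s))], float)
    if x.size < 2:
        raise ValueError("median_cutoff needs at least 2 scores")
    candidates = np.unique(x)
    if candidates.size < 2:
        raise ValueError("all scores identical; binary task undefined")
    med = float(np.median(x))
    best = None
    for t in candidates:
        above = int(np.sum(x >= t))
        imbalance = abs(above - (x.size - above))
        key = (imbalance, abs(t - med), t)
        if best is None or key < best[0]:
            best = (key, float(t))
    return best[1]


def severity_labels(
    scores, scale: str, threshold: float, registry: CutoffRegistry | None = None
) -> np.ndarray:
    """Binary severity labels (1 = more severe) for an array of scores.

    Respects the scale's polarity: for "high" scales severe means
    score >= threshold; for "low" scales (BACS) severe means score < threshold.
    Missing scores yield -1 (excluded).
    """
    registry = registry or CutoffRegistry()
    pol = registry.polarity(scale)
    x = np.asarray(scores, dtype=float)
    lab = np.full(x.shape, -1, dtype=int)
    ok = np.isfinite(x)
    if pol == "low":
        lab[ok] = (x[ok] < threshold).astype(int)
    else:
        lab[ok] = (x[ok] >= threshold).astype(int)
    return lab
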