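"""Summarization of framewise descriptor streams into subject-level features.

Facial-analysis and acoustic toolkits emit one multivariate descriptor vector
per video frame or sliding window (emotion probabilities, action-unit
intensities, low-level acoustic descriptors).  Classifiers operate on one
vector per subject, so each stream is collapsed with a fixed list of
statistics, optionally after first-differencing ("delta" streams) to capture
how fast expressions change.

All moments use the population convention (divide by N); skewness and excess
kurtosis of a zero-variance stream are defined as 0 so that constant streams
produce finite features instead of NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSeries",
    "delta_series",
    "summarize_series",
    "fraction_above",
    "composite_lld",
    "affectiva_style_features",
    "openface_style_features",
    "STAT_NAMES",
]

STAT_NAMES = ("mean", "min", "max", "median", "skewness", "kurtosis")


@dataclass
class FrameSeries:
    """A framewise multivariate descriptor stream.

    times : strictly increasing timestamps in seconds, shape (n,)
    values : descriptor matrix, shape (n, d); NaN marks a missing frame
    names : the d descriptor labels
    """

    times: np.ndarray
    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("times and values must have the same number of frames")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one descriptor")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.names:
            self.names = [f"x{i}" for i in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names must match the number of descriptors")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]


def delta_series(f: FrameSeries) -> FrameSeries:
    """First differences across consecutive frames (length n-1)."""
    if f.n_frames < 2:
        raise ValueError("delta_series requires at least 2 frames")
    return FrameSeries(
        times=f.times[1:],
        values=np.diff(f.values, axis=0),
        names=[f"{n}__delta" for n in f.names],
    )


def _moments(x: np.ndarray) -> dict[str, float]:
    """Population moments of a 1-D array with NaNs already removed."""
    m = float(np.mean(x))
    sd = float(np.std(x))  # population (ddof=0)
    out = {
        "mean": m,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "median": float(np.median(x)),
    }
    if sd == 0.0:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    else:
        z = (x - m) / sd
        out["skewness"] = float(np.mean(z**3))
        # excess kurtosis: 0 for a Gaussian
        out["kurtosis"] = float(np.mean(z**4) - 3.0)
    return out


def summarize_series(
    f: FrameSeries, stats: tuple[str, ...] = STAT_NAMES
) -> tuple[np.ndarray, list[str]]:
    """Per-descriptor statistics, concatenated descriptor-major.

    Returns ``(vector, names)`` where the vector is ordered
    ``d0__stat0, d0__stat1, ..., d1__stat0, ...``.  Missing frames (NaN) are
    dropped per descriptor; an all-missing descriptor yields NaN statistics.
    """
    bad = set(stats) - set(STAT_NAMES)
    if bad:
        raise ValueError(f"unknown statistics: {sorted(bad)}")
    if f.n_frames < 1:
        raise ValueError("need at least one frame")
    values, names = [], []
    for j, dname in enumerate(f.names):
        col = f.values[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            mom = {s: float("nan") for s in STAT_NAMES}
        else:
            mom = _moments(col)
        for s in stats:
            values.append(mom[s])
            names.append(f"{dname}__{s}")
    return np.asarray(values), names


def fraction_above(f: FrameSeries, threshold: float) -> tuple[np.ndarray, list[str]]:
    """Percentage of frames strictly above ``threshold``, per descriptor.

    Used for bounded expression scores (0-100 scales) where the fraction of
    time an expression is active is more robust than its mean intensity.
    """
    out, names = [], []
    for j, dname in enumerate(f.names):
        col = f.values[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            out.append(float("nan"))
        else:
            out.append(100.0 * float(np.mean(col > threshold)))
        names.append(f"{dname}__pct_above_{threshold:g}")
    return np.asarray(out), names


def composite_lld(f: FrameSeries) -> tuple[np.ndarray, list[str]]:
    """Composite windowed low-level descriptors: max, min, mean, STD each.

    For a d-descriptor windowed stream the output has 4*d entries, ordered
    descriptor-major as ``<name>__max, __min, __mean, __std``.
    """
    if f.n_frames < 1:
        raise ValueError("need at least one window")
    v = f.values
    stats = np.stack(
        [np.max(v, axis=0), np.min(v, axis=0), np.mean(v, axis=0), np.std(v, axis=0)]
    )  # (4, d)
    names = [
        f"{dname}__{s}" for dname in f.names for s in ("max", "min", "mean", "std")
    ]
    return stats.T.reshape(-1), names


def affectiva_style_features(
    f: FrameSeries, threshold: float = 10.0
) -> tuple[np.ndarray, list[str]]:
    """Six statistics of raw and delta streams plus threshold fractions.

    Output length is ``d*6*2 + d``: the six moments of each raw descriptor,
    the six moments of its frame-to-frame delta, and the percentage of frames
    above ``threshold`` (raw stream only; deltas can be negative).
    """
    raw_v, raw_n = summarize_series(f)
    dl_v, dl_n = summarize_series(delta_series(f))
    fr_v, fr_n = fraction_above(f, threshold)
    return np.concatenate([raw_v, dl_v, fr_v]), raw_n + dl_n + fr_n


def openface_style_features(
    f: FrameSeries, au_classification: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Mean of binary AU-classification streams; six statistics of the rest."""
    au_idx = [i for i, n in enumerate(f.names) if n in au_classification]
    other_idx = [i for i, n in enumerate(f.names) if n not in au_classification]
    values: list[float] = []
    names: list[str] = []
    if au_idx:
        sub = FrameSeries(f.times, f.values[:, au_idx], [f.names[i] for i in au_idx])
        v, n = summarize_series(sub, stats=("mean",))
        values.extend(v)
        names.extend(n)
    if other_idx:
        sub = FrameSeries(
            f.times, f.values[:, other_idx], [f.names[i] for i in other_idx]
        )
        v, n = summarize_series(sub)
        values.extend(v)
        names.extend(n)
    return np.asarray(values), names
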