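"""Speech-activity decoding from per-channel energy envelopes.

Each interview is recorded on two lapel microphones (participant and
interviewer).  A two-state Gaussian HMM on the framewise log-energy of each
channel separates speech from silence; the Viterbi state path, with the
higher-mean state labelled "speaking", gives a binary activity mask.  A 1-D
morphological closing then fills short intra-utterance gaps so that speech
segments are cohesive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy import ndimage

__all__ = [
    "SpeechActivityMask",
    "decode_activity",
    "binary_closing",
    "default_closing_width",
    "read_mask_csv",
    "write_mask_csv",
]


@dataclass
class SpeechActivityMask:
    """Binary who-speaks-when masks for a two-channel recording."""

    frames_participant: np.ndarray
    frames_interviewer: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames_participant = np.asarray(self.frames_participant, dtype=np.int8)
        self.frames_interviewer = np.asarray(self.frames_interviewer, dtype=np.int8)
        if self.frames_participant.shape != self.frames_interviewer.shape:
            raise ValueError("channels must have equal length")
        for ch in (self.frames_participant, self.frames_interviewer):
            if not np.isin(ch, (0, 1)).all():
                raise ValueError("mask values must be 0/1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames_participant.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


def decode_activity(
    energy: np.ndarray,
    frame_rate: float,
    n_iter: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Decode a binary speaking mask from a log-energy envelope.

    A two-state diagonal-Gaussian HMM is fitted per recording with the state
    means initialized at the lower and upper energy quartiles, then the
    most-likely (Viterbi) state path is decoded and the higher-mean state is
    labelled speaking (1).  A constant envelope carries no speech/silence
    contrast; it decodes to all zeros with a warning.
    """
    x = np.asarray(energy, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("energy must be a 1-D sequence of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("energy must be finite")
    if np.std(x) == 0.0:
        warnings.warn("constant energy envelope: degenerate input, returning all-0")
        return np.zeros(x.size, dtype=np.int8)

    q1, q3 = np.quantile(x, [0.25, 0.75])
    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        n_iter=n_iter,
        random_state=seed,
        init_params="",  # all parameters initialized explicitly below
        params="stmc",
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
    model.means_ = np.array([[q1], [q3]])
    var = max(np.var(x) / 4.0, 1e-6)
    model.covars_ = np.array([[var], [var]])
    X = x[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # hmmlearn convergence chatter
        model.fit(X)
        states = model.predict(X)
    means = model.means_.ravel()
    pooled_sd = float(np.sqrt(np.mean(model.covars_)))
    if abs(means[1] - means[0]) < 3.0 * pooled_sd:
        # the two fitted states only partition the noise: no speech present
        warnings.warn("no speech/silence contrast found: returning all-0")
        return np.zeros(x.size, dtype=np.int8)
    speaking_state = int(np.argmax(means))
    return (states == speaking_state).astype(np.int8)


def binary_closing(mask: np.ndarray, width: int) -> np.ndarray:
    """1-D morphological closing (erosion of the dilation) of a binary mask.

    A flat structuring element of ``width`` frames fills gaps of up to
    ``width - 1`` frames inside speech.  The sequence is treated as embedded
    in silence (zero padding), so recordings that start or end mid-speech are
    not artificially extended.  ``width`` must be odd to keep the element
    centered.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask values must be 0/1")
    if width == 1:
        return m.astype(np.int8)
    padded = np.pad(m.astype(bool), width)
    closed = ndimage.binary_closing(padded, structure=np.ones(width, dtype=bool))
    return closed[width:-width].astype(np.int8)


def default_closing_width(frame_rate: float, close_s: float = 0.5) -> int:
    """Closing width in frames for a target duration, rounded to odd."""
    w = max(1, int(round(close_s * frame_rate)))
    return w if w % 2 == 1 else w + 1


def read_mask_csv(path) -> SpeechActivityMask:
    df = pd.read_csv(path)
    fr = float(df.attrs.get("frame_rate", 0)) or float(df["frame_rate"].iloc[0])
    return SpeechActivityMask(
        frames_participant=df["participant"].to_numpy(),
        frames_interviewer=df["interviewer"].to_numpy(),
        frame_rate=fr,
    )


def write_mask_csv(mask: SpeechActivityMask, path) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(mask.n_frames),
            "participant": mask.frames_participant,
            "interviewer": mask.frames_interviewer,
            "frame_rate": mask.frame_rate,
        }
    ).to_csv(path, index=False)
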