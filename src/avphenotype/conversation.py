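"""Dyadic conversational features from two-channel speech-activity masks.

Fourteen features quantify the turn-taking dynamics of a semi-structured
clinical interview: how much each party speaks, how quickly the participant
responds, how often they interject or interrupt, and how fluid the floor
exchanges are.  The event definitions the literature leaves informal are
pinned down here and exposed as parameters:

* a *speech segment* is a maximal run of 1-frames in one channel;
* segments of the same channel separated by a gap shorter than
  ``turn_merge_s`` (default 1.0 s) belong to one *turn*;
* an *interject* is a segment shorter than ``interject_max_s`` (default
  1.0 s); a *speaking interject* is one whose onset falls while the other
  channel is active;
* an *interruption* is a participant turn onset while the interviewer is
  speaking; it succeeds if the interviewer goes silent within
  ``interrupt_grace_s`` (default 2.0 s), otherwise it is a *failed
  interrupt*;
* a *natural turn* is a change of floor between consecutive turns with no
  overlap during the exchange;
* *response time* is the gap from an interviewer turn offset to the next
  participant turn onset (negative, i.e. overlapping, latencies count as 0).

All per-minute rates and the speaking rate use the full interview duration
as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .speech import SpeechActivityMask

__all__ = [
    "ConversationConfig",
    "ConversationFeatures",
    "SegmentList",
    "extract_segments",
    "conversational_features",
    "CONVERSATION_FEATURE_NAMES",
]

CONVERSATION_FEATURE_NAMES = (
    "interject",
    "interrupt",
    "response_time",
    "turn_duration",
    "speaking",
    "speech_gap",
    "difference_speaking",
    "difference_turn",
    "speaking_rate",
    "mutual_silence",
    "overlap",
    "failed_interrupt",
    "speaking_interject",
    "natural_turn",
)


@dataclass(frozen=True)
class ConversationConfig:
    """Thresholds for the under-specified event definitions (seconds)."""

    turn_merge_s: float = 1.0
    interject_max_s: float = 1.0
    interrupt_grace_s: float = 2.0


@dataclass
class ConversationFeatures:
    interject: float  # short utterances per minute
    interrupt: float  # successful interruptions per minute
    response_time: float  # mean response latency, s
    turn_duration: float  # mean participant turn duration, s
    speaking: float  # % frames participant speaking
    speech_gap: float  # mean within-participant pause, s
    difference_speaking: float  # speaking% participant - interviewer, points
    difference_turn: float  # participant turns - interviewer turns
    speaking_rate: float  # words per second of interview
    mutual_silence: float  # % frames both silent
    overlap: float  # % frames both speaking
    failed_interrupt: float  # failed interruptions per minute
    speaking_interject: float  # interjects starting in other's speech, /min
    natural_turn: float  # clean floor exchanges, count
    degenerate: bool = False  # participant never spoke

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in CONVERSATION_FEATURE_NAMES}

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CONVERSATION_FEATURE_NAMES])


@dataclass
class SegmentList:
    """Speech segments, pauses and merged turns for both channels (seconds)."""

    segments_participant: list[tuple[float, float]]
    segments_interviewer: list[tuple[float, float]]
    pauses_participant: list[tuple[float, float]]
    pauses_interviewer: list[tuple[float, float]]
    turns: list[tuple[str, float, float]]  # (speaker, onset, offset) by onset

    def turns_of(self, speaker: str) -> list[tuple[float, float]]:
        return [(a, b) for s, a, b in self.turns if s == speaker]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s as (start, stop) frame index pairs, stop exclusive."""
    m = np.asarray(mask).astype(bool)
    if m.size == 0:
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], m.view(np.int8), [0]])))
    return list(zip(edges[::2], edges[1::2]))


def _merge(segments: list[tuple[float, float]], gap_max: float) -> list[tuple[float, float]]:
    """Merge consecutive segments whose separating gap is < gap_max."""
    merged: list[list[float]] = []
    for a, b in segments:
        if merged and a - merged[-1][1] < gap_max:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def extract_segments(
    mask: SpeechActivityMask, config: ConversationConfig | None = None
) -> SegmentList:
    """Segment both channels into speech segments, pauses and merged turns."""
    config = config or ConversationConfig()
    fr = mask.frame_rate
    seg_p = [(a / fr, b / fr) for a, b in _runs(mask.frames_participant)]
    seg_i = [(a / fr, b / fr) for a, b in _runs(mask.frames_interviewer)]
    pauses_p = [(seg_p[k][1], seg_p[k + 1][0]) for k in range(len(seg_p) - 1)]
    pauses_i = [(seg_i[k][1], seg_i[k + 1][0]) for k in range(len(seg_i) - 1)]
    turns = [("participant", a, b) for a, b in _merge(seg_p, config.turn_merge_s)]
    turns += [("interviewer", a, b) for a, b in _merge(seg_i, config.turn_merge_s)]
    turns.sort(key=lambda t: (t[1], t[2]))
    return SegmentList(seg_p, seg_i, pauses_p, pauses_i, turns)


def conversational_features(
    mask: SpeechActivityMask,
    word_count_participant: int = 0,
    config: ConversationConfig | None = None,
) -> ConversationFeatures:
    """Compute the 14 conversational features for one interview."""
    config = config or ConversationConfig()
    if mask.n_frames == 0:
        raise ValueError("zero-length mask")
    if word_count_participant < 0:
        raise ValueError("word count must be >= 0")
    fr = mask.frame_rate
    P = mask.frames_participant.astype(bool)
    I = mask.frames_interviewer.astype(bool)
    duration_s = mask.n_frames / fr
    duration_min = duration_s / 60.0

    speaking_p = 100.0 * float(np.mean(P))
    speaking_i = 100.0 * float(np.mean(I))
    overlap = 100.0 * float(np.mean(P & I))
    mutual_silence = 100.0 * float(np.mean(~P & ~I))

    segs = extract_segments(mask, config)
    turns_p = segs.turns_of("participant")
    turns_i = segs.turns_of("interviewer")
    degenerate = len(segs.segments_participant) == 0

    # interjects: short participant segments; speaking-interjects start while
    # the interviewer channel is active
    interjects = [
        (a, b)
        for a, b in segs.segments_participant
        if (b - a) < config.interject_max_s
    ]
    n_speaking_interject = sum(
        1 for a, _ in interjects if I[min(int(round(a * fr)), mask.n_frames - 1)]
    )

    # interruptions: participant turn onsets strictly inside interviewer speech
    n_interrupt = n_failed = 0
    for a, _ in turns_p:
        onset = min(int(round(a * fr)), mask.n_frames - 1)
        if I[onset]:
            stop = min(int(round((a + config.interrupt_grace_s) * fr)), mask.n_frames)
            if not I[onset:stop].all():
                n_interrupt += 1
            else:
                n_failed += 1

    # response time: interviewer turn offset -> next participant turn onset
    latencies = []
    for _, b in turns_i:
        nxt = [a for a, _ in turns_p if a >= b]
        prev_overlapping = [a for a, bb in turns_p if a < b <= bb]
        if prev_overlapping:
            latencies.append(0.0)  # participant already speaking at handover
        elif nxt:
            latencies.append(nxt[0] - b)
    response_time = float(np.mean(latencies)) if latencies else 0.0

    # natural turns: floor changes with no overlap during the exchange
    n_natural = 0
    for (s1, _, b1), (s2, a2, _) in zip(segs.turns, segs.turns[1:]):
        if s1 != s2 and a2 >= b1:
            n_natural += 1

    turn_duration = (
        float(np.mean([b - a for a, b in turns_p])) if turns_p else 0.0
    )
    speech_gap = (
        float(np.mean([b - a for a, b in segs.pauses_participant]))
        if segs.pauses_participant
        else 0.0
    )

    return ConversationFeatures(
        interject=len(interjects) / duration_min,
        interrupt=n_interrupt / duration_min,
        response_time=response_time,
        turn_duration=turn_duration,
        speaking=speaking_p,
        speech_gap=speech_gap,
        difference_speaking=speaking_p - speaking_i,
        difference_turn=float(len(turns_p) - len(turns_i)),
        speaking_rate=word_count_participant / duration_s,
        mutual_silence=mutual_silence,
        overlap=overlap,
        failed_interrupt=n_failed / duration_min,
        speaking_interject=n_speaking_interject / duration_min,
        natural_turn=float(n_natural),
        degenerate=degenerate,
    )
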