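"""Synthetic experimental designs and their microtime rasterisation.

The task being emulated is a simple audio/visual sensorimotor paradigm:
on most trials a binaural tone (one of three frequencies) and bilateral
checkerboards are presented together (condition AV); a handful of trials
are audio-only (A) or visual-only (V).  Trials are separated by jittered
stimulus onset asynchronies (SOAs), which makes the haemodynamic
response estimable.  The design is rasterised onto a fine temporal grid
(microtime bins, several per scan) as a binary indicator matrix that
drives the neural model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "TONES_HZ",
    "ExperimentalDesign",
    "InputMatrix",
    "generate_design",
    "rasterize_inputs",
]

CONDITIONS: tuple[str, ...] = ("AV", "A", "V")
TONES_HZ: tuple[int, ...] = (300, 600, 1200)

#: stimulus durations (s), kept for documentation in event tables only —
#: inputs are encoded as events (single-bin indicators)
TONE_DURATION_S = 0.300
CHECKERBOARD_DURATION_S = 0.034


@dataclass(frozen=True)
class Trial:
    onset: float
    condition: str  # "AV" | "A" | "V"
    tone_hz: int | None  # None for visual-only trials


@dataclass
class ExperimentalDesign:
    """A list of trials with jittered SOAs.

    Invariants: onsets strictly increasing; successive SOAs within
    ``soa_bounds``; condition counts match the requested specification.
    """

    trials: list[Trial]
    session_length: float
    soa_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        onsets = [t.onset for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")
        lo, hi = self.soa_bounds
        for a, b in zip(onsets, onsets[1:]):
            if not (lo - 1e-9 <= b - a <= hi + 1e-9):
                raise ValueError(f"SOA {b - a:.3f}s outside bounds {self.soa_bounds}")

    def __len__(self) -> int:
        return len(self.trials)

    def condition_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for t in self.trials:
            counts[t.condition] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """BIDS-events-style table: onset, duration, trial_type, tone_hz."""
        rows = []
        for t in self.trials:
            dur = CHECKERBOARD_DURATION_S if t.condition == "V" else TONE_DURATION_S
            rows.append(
                {
                    "onset": t.onset,
                    "duration": dur,
                    "trial_type": t.condition,
                    "tone_hz": t.tone_hz if t.tone_hz is not None else "n/a",
                }
            )
        return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "tone_hz"])

    @staticmethod
    def from_frame(df: pd.DataFrame, soa_bounds: tuple[float, float],
                   session_length: float | None = None) -> "ExperimentalDesign":
        trials = []
        for _, row in df.iterrows():
            tone = row["tone_hz"]
            tone = None if (isinstance(tone, str) and tone == "n/a") or pd.isna(tone) else int(tone)
            trials.append(Trial(float(row["onset"]), str(row["trial_type"]), tone))
        if session_length is None:
            session_length = (trials[-1].onset + soa_bounds[1]) if trials else 0.0
        return ExperimentalDesign(trials, float(session_length), soa_bounds)


@dataclass
class InputMatrix:
    """Binary T × P indicator of condition onsets on the microtime grid."""

    values: np.ndarray  # (T, P) in {0, 1}
    bins_per_scan: int
    n_scans: int
    bin_width: float  # seconds
    conditions: tuple[str, ...] = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        T = self.n_scans * self.bins_per_scan
        if self.values.shape != (T, len(self.conditions)):
            raise ValueError(
                f"input matrix shape {self.values.shape} != ({T}, {len(self.conditions)})")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("input matrix entries must be 0 or 1")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def scan_period(self) -> float:
        return self.bin_width * self.bins_per_scan


def generate_design(
    n_per_tone: int,
    n_audio_only: int,
    n_visual_only: int,
    soa_bounds: tuple[float, float] = (2.0, 26.0),
    seed: int = 0,
    session_length: float | None = None,
    soa_distribution: str = "uniform",
    soa_scale: float = 1.6,
) -> ExperimentalDesign:
    """Randomised trial sequence with jittered SOAs.

    Parameters
    ----------
    n_per_tone : int
        Number of AV trials per tone frequency (three frequencies).
    n_audio_only, n_visual_only : int
        Counts for the rare unimodal conditions.
    soa_bounds : (float, float)
        Minimum and maximum onset asynchrony, seconds.
    seed : int
        Makes the design a pure function of its arguments.
    session_length : float, optional
        If given, designs whose last onset exceeds it are rejected.
    soa_distribution : {"uniform", "truncexp"}
        "uniform" draws SOAs uniformly within the bounds (the
        least-informative choice); "truncexp" draws from a shifted
        exponential (scale ``soa_scale``) truncated at the upper bound,
        emulating jitter produced by interspersed null trials — needed
        for many trials to fit a short session.
    """
    for name, v in [("n_per_tone", n_per_tone), ("n_audio_only", n_audio_only),
                    ("n_visual_only", n_visual_only)]:
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    lo, hi = float(soa_bounds[0]), float(soa_bounds[1])
    if lo <= 0 or lo > hi:
        raise ValueError(f"invalid SOA bounds {soa_bounds}: need 0 < min <= max")

    rng = np.random.default_rng(seed)
    labels: list[tuple[str, int | None]] = []
    for tone in TONES_HZ:
        labels += [("AV", tone)] * int(n_per_tone)
    # audio-only trials still play a tone; draw a frequency for each
    labels += [("A", int(rng.choice(TONES_HZ))) for _ in range(int(n_audio_only))]
    labels += [("V", None)] * int(n_visual_only)

    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    if soa_distribution == "uniform":
        def draw_soa() -> float:
            return float(rng.uniform(lo, hi))
    elif soa_distribution == "truncexp":
        def draw_soa() -> float:
            while True:
                x = lo + float(rng.exponential(soa_scale))
                if x <= hi:
                    return x
    else:
        raise ValueError(f"unknown soa_distribution {soa_distribution!r}")

    onsets = []
    t = draw_soa()
    for _ in labels:
        onsets.append(t)
        t += draw_soa()

    if session_length is not None and onsets and onsets[-1] >= session_length:
        raise ValueError(
            f"design overflows the session: last onset {onsets[-1]:.1f}s "
            f">= session length {session_length:.1f}s")
    sess = session_length if session_length is not None else (
        (onsets[-1] + hi) if onsets else 0.0)
    trials = [Trial(o, c, tone) for o, (c, tone) in zip(onsets, labels)]
    return ExperimentalDesign(trials, float(sess), (lo, hi))


def rasterize_inputs(
    design: ExperimentalDesign,
    n_scans: int,
    bins_per_scan: int = 16,
    scan_period: float = 2.0,
) -> InputMatrix:
    """Rasterise trial onsets onto the microtime grid.

    Each trial sets the indicator to 1 in the bin containing its onset
    (half-open bins ``[t, t + bin_width)``, 0-based) for its condition's
    column; AV trials set only the AV column.
    """
    if n_scans < 1 or bins_per_scan < 1:
        raise ValueError("n_scans and bins_per_scan must be >= 1")
    if scan_period <= 0:
        raise ValueError("scan_period must be positive")
    T = n_scans * bins_per_scan
    bin_width = scan_period / bins_per_scan
    U = np.zeros((T, len(CONDITIONS)), dtype=float)
    col = {c: j for j, c in enumerate(CONDITIONS)}
    session_end = n_scans * scan_period
    for trial in design.trials:
        if trial.onset < 0 or trial.onset >= session_end:
            raise ValueError(
                f"trial onset {trial.onset:.2f}s outside session [0, {session_end:.2f})")
        U[int(trial.onset // bin_width), col[trial.condition]] = 1.0
    return InputMatrix(U, bins_per_scan=bins_per_scan, n_scans=n_scans,
                       bin_width=bin_width)
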