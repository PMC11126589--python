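"""Real-time preprocessing of direct-RNA squiggles.

Direct RNA sequencing reads a molecule 3'->5', so every raw signal begins
with a sequencing-adapter segment, then the poly(A) tail, then the
transcript. The classifier must only ever see transcript signal, so the
live decision engine needs a boundary detector that works on *partial*
signals, in real time, with no second pass.

The detector exploits two robust facts about R9.4.1 direct-RNA squiggles:
the poly(A) tail is a homopolymer and therefore a low-dispersion,
elevated-mean segment, while the adapter before it has lower mean current
and much higher dispersion. Consecutive windows of fixed width ``R`` are
scanned; the poly(A) start is the first window whose mean has risen by at
least 20% over the two preceding windows and whose MAD is below a
threshold, and the trim position (transcript start) is the first later
window whose MAD rises back above 20 pA. If no boundary is found within
6.2 s of signal, a fixed 2.2 s trim is applied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: R9.4.1 direct-RNA sampling rate, samples per second. 1 s <=> 3012 samples.
SAMPLE_RATE = 3012

#: Admissible classifier input lengths, seconds.
MIN_INPUT_SECONDS = 2
MAX_INPUT_SECONDS = 4


def mad(x: np.ndarray) -> float:
    """Median absolute deviation (unscaled), the dispersion statistic used
    for both trimming criteria and normalization."""
    x = np.asarray(x)
    return float(np.median(np.abs(x - np.median(x))))


@dataclass(frozen=True)
class TrimConfig:
    """Configuration of the real-time adapter/poly(A) boundary search.

    Parameters
    ----------
    window_width:
        Width ``R`` of the consecutive scan windows, in samples. 500
        samples is ~10 nt for the R9.4.1 pore.
    polya_mad_max:
        MAD threshold ``T`` (pA) below which a window can qualify as
        poly(A) tail.
    mean_step_min:
        Minimum fractional increase of a candidate poly(A) window's mean
        over the mean of the two preceding windows (0.20 = "at least a 20%
        increase").
    end_mad_min:
        MAD (pA) above which a window after the poly(A) start is taken as
        transcript signal; its first sample is the trim position.
    fixed_trim:
        Fallback trim length in seconds, applied when no boundary is found.
    search_boundary:
        Accumulated signal duration (s) after which the search is abandoned
        in favour of the fixed trim. Equals fixed_trim + the maximum
        classifier input length (2.2 s + 4 s).
    """

    window_width: int = 500
    polya_mad_max: float = 20.0
    mean_step_min: float = 0.20
    end_mad_min: float = 20.0
    fixed_trim: float = 2.2
    search_boundary: float = 6.2
    sample_rate: int = SAMPLE_RATE

    def __post_init__(self):
        if self.window_width < 2:
            raise ValueError("window_width must be >= 2")
        if self.search_boundary < self.fixed_trim:
            raise ValueError("search_boundary must be >= fixed_trim")
        for name in ("polya_mad_max", "mean_step_min", "end_mad_min",
                     "fixed_trim", "search_boundary"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class TrimResult:
    """Outcome of the boundary search on a (possibly partial) signal.

    ``status`` is ``"detected"`` when both poly(A) start and end were
    found, ``"fixed"`` when the search was abandoned and the fallback trim
    applied, and ``"pending"`` when more signal is needed. ``trim_position``
    is the index of the first transcript sample (0-based, half-open).
    """

    status: str
    polya_start: int | None = None
    trim_position: int | None = None

    def __post_init__(self):
        if self.status not in ("detected", "fixed", "pending"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "detected" and not (
            self.polya_start is not None
            and self.trim_position is not None
            and self.polya_start < self.trim_position
        ):
            raise ValueError("detected result requires polya_start < trim_position")
        if self.status == "pending" and self.trim_position is not None:
            raise ValueError("pending result cannot carry a trim_position")


def find_trim_position(signal: np.ndarray, cfg: TrimConfig | None = None) -> TrimResult:
    """Locate the poly(A) tail and the transcript start on a partial signal.

    Scans non-overlapping consecutive windows of width ``R`` from the
    start of the signal. A window ``w`` (index >= 2) marks the poly(A)
    start when its mean is at least ``1 + mean_step_min`` times the mean
    of the two preceding windows combined and its MAD is below
    ``polya_mad_max``. The first subsequent window with MAD above
    ``end_mad_min`` marks the trim position (its first sample). The scan
    never inspects samples beyond ``search_boundary`` seconds; if the
    boundary is not found and at least that much signal has accumulated,
    the fixed trim is applied, otherwise the result is pending.

    The function is prefix-stable: once a result is detected on a prefix,
    any longer prefix of the same signal yields the same result.
    """
    if cfg is None:
        cfg = TrimConfig()
    signal = np.asarray(signal, dtype=np.float64)
    R = cfg.window_width
    boundary_samples = cfg.search_boundary * cfg.sample_rate
    # only windows fully inside the search boundary are ever inspected
    n_windows = min(signal.size, int(boundary_samples)) // R

    polya_start = None
    means = np.empty(n_windows)
    for w in range(n_windows):
        win = signal[w * R:(w + 1) * R]
        means[w] = win.mean()
        if polya_start is None:
            if w >= 2:
                prev = 0.5 * (means[w - 2] + means[w - 1])
                if means[w] >= (1.0 + cfg.mean_step_min) * prev and mad(win) < cfg.polya_mad_max:
                    polya_start = w * R
        else:
            if mad(win) > cfg.end_mad_min:
                return TrimResult("detected", polya_start=polya_start,
                                  trim_position=w * R)

    if signal.size >= boundary_samples:
        return TrimResult("fixed", polya_start=polya_start,
                          trim_position=round(cfg.fixed_trim * cfg.sample_rate))
    return TrimResult("pending", polya_start=polya_start)


def normalize(signal: np.ndarray, clip_k: float = 3.0) -> np.ndarray:
    """MAD-normalize a signal with outlier smoothing.

    Values are first clipped to ``median +- clip_k * MAD`` (the outlier
    smoothing step), then transformed to ``(x - median) / MAD`` using the
    median and MAD of the *unclipped* signal. A constant signal (MAD = 0)
    maps to all zeros.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValueError("cannot normalize an empty signal")
    med = np.median(signal)
    m = mad(signal)
    if m == 0:
        return np.zeros_like(signal)
    clipped = np.clip(signal, med - clip_k * m, med + clip_k * m)
    return (clipped - med) / m


def extract_window(signal: np.ndarray, trim: TrimResult, n_seconds: int,
                   sample_rate: int = SAMPLE_RATE) -> np.ndarray | None:
    """First ``n_seconds`` of transcript signal after the trim position.

    Returns ``None`` when fewer than ``n_seconds`` of signal remain after
    the trim. ``trim`` must not be pending.
    """
    if trim.status == "pending":
        raise ValueError("cannot extract a window from a pending trim result")
    signal = np.asarray(signal)
    n = n_seconds * sample_rate
    start = trim.trim_position
    if signal.size - start < n:
        return None
    return signal[start:start + n]
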