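"""Incremental accept/reject protocol and playback simulator.

The live system receives in-progress signals in 1 s chunks from the
sequencer's streaming interface. For each molecule it (1) trims the
adapter/poly(A) prefix in real time, (2) once at least 2 s of transcript
signal has accrued, normalizes it and asks each target-class model for a
probability, (3) translates probabilities into a command with a tuned
confidence threshold T = 0.9 — in deplete mode a reject is sent when any
target class exceeds T and the molecule is accepted when every target
probability is below 1 - T; enrich mode mirrors this for a single target —
and (4) if no confident call is made, retries on the longer signal at the
next chunk, up to 4 s of transcript signal, after which sequencing simply
continues (the molecule "escapes"). A molecule is sent at most one reject
command, ever: a failed ejection (e.g. trans-side secondary structure) is
let through rather than retried.

The playback simulator realizes the streaming-interface contract on
recorded or synthetic reads, including the split-flow-cell experimental
design (even channels treated, odd channels control) and the decisions
file that the command-line tool writes.

Assessments are made on whole seconds of transcript signal (2, 3 or 4 s),
which both matches how the threshold was tuned and lets the simulator
batch model calls across reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .preprocess import SAMPLE_RATE, TrimConfig, TrimResult, find_trim_position, normalize


def even_channels_treatment(channel: int) -> str:
    """The split-flow-cell rule: channels divisible by 2 are the treated
    condition, the rest are the control."""
    return "treatment" if channel % 2 == 0 else "control"


@dataclass(frozen=True)
class RunConfig:
    mode: str = "deplete"  # deplete | enrich
    targets: tuple[str, ...] = ("target",)
    threshold: float = 0.9
    chunk_seconds: float = 1.0
    min_assess_seconds: int = 2
    max_assess_seconds: int = 4
    duration_seconds: float | None = None
    channel_rule: Callable[[int], str] = even_channels_treatment
    eject_latency_chunks: int = 1
    reject_failure_prob: float = 0.0
    trim: TrimConfig = field(default_factory=TrimConfig)
    sample_rate: int = SAMPLE_RATE

    def __post_init__(self):
        if not 0.5 < self.threshold < 1:
            raise ValueError("threshold must lie in (0.5, 1)")
        if self.min_assess_seconds > self.max_assess_seconds:
            raise ValueError("min_assess must be <= max_assess")
        if self.chunk_seconds <= 0:
            raise ValueError("chunk must be > 0")
        if self.mode not in ("deplete", "enrich"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "enrich" and len(self.targets) != 1:
            raise ValueError("enrich mode supports a single target class")

    @property
    def chunk_samples(self) -> int:
        return int(self.chunk_seconds * self.sample_rate)


def decide(probabilities: dict[str, float], mode: str, threshold: float) -> str:
    """Translate per-target probabilities into accept/reject/wait.

    Deplete: reject iff any target probability strictly exceeds T, accept
    iff every target probability is below 1 - T, else wait. Enrich
    (single target): accept iff p > T, reject iff p < 1 - T, else wait.
    A probability exactly equal to a bound is never confident.
    """
    if not probabilities:
        raise ValueError("decide() needs at least one probability")
    ps = list(probabilities.values())
    if mode == "deplete":
        if any(p > threshold for p in ps):
            return "reject"
        if all(p < 1 - threshold for p in ps):
            return "accept"
        return "wait"
    if mode == "enrich":
        (p,) = ps
        if p > threshold:
            return "accept"
        if p < 1 - threshold:
            return "reject"
        return "wait"
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ReadState:
    """Mutable per-molecule streaming state."""

    read_id: str
    channel: int
    signal: np.ndarray = field(default_factory=lambda: np.empty(0))
    samples_seen: int = 0
    trim: TrimResult | None = None
    last_probabilities: dict[str, float] = field(default_factory=dict)
    last_assessed_seconds: int = 0
    rejects_sent: int = 0
    status: str = "streaming"  # streaming|accepted|rejected|reject_failed|undecided_complete
    decision_batch: int | None = None
    batches_seen: int = 0

    def transcript_samples(self) -> int:
        if self.trim is None or self.trim.status == "pending":
            return 0
        return self.samples_seen - self.trim.trim_position


@dataclass(frozen=True)
class DecisionRecord:
    """One row of the decisions file, per assessed read."""

    read_id: str
    batch: int
    channel: int
    samples_assessed: int
    probabilities: dict[str, float]
    threshold: float
    decision: str  # accept | reject | no_decision

    def __post_init__(self):
        for p in self.probabilities.values():
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def _predict(model, window: np.ndarray, read_id: str) -> float:
    """Model protocol: `predict_for_read(window, read_id)` if offered
    (oracles), else `predict(window).probability`."""
    if hasattr(model, "predict_for_read"):
        return float(model.predict_for_read(window, read_id))
    return float(model.predict(window).probability)


class OracleClassifier:
    """Perfect classifier for protocol audits: emits probability 1 for
    reads whose true class is the target, 0 otherwise."""

    def __init__(self, target_class: str, class_of_read: dict[str, str]):
        self.target_class = target_class
        self.class_of_read = class_of_read

    def predict_for_read(self, window, read_id: str) -> float:
        return 1.0 if self.class_of_read[read_id] == self.target_class else 0.0


def _assessment_seconds(state: ReadState, config: RunConfig) -> int | None:
    """Whole-second window length to assess now, or None."""
    if state.trim is None or state.trim.status == "pending":
        return None
    k = min(state.transcript_samples() // config.sample_rate,
            config.max_assess_seconds)
    if k >= config.min_assess_seconds and k > state.last_assessed_seconds:
        return int(k)
    return None


def _window(state: ReadState, seconds: int, config: RunConfig) -> np.ndarray:
    start = state.trim.trim_position
    return normalize(state.signal[start:start + seconds * config.sample_rate])


def step(state: ReadState, new_chunk: np.ndarray, models: dict,
         config: RunConfig) -> tuple[ReadState, str | None]:
    """Feed one chunk of one read through the protocol.

    Returns the updated state and an optional command ("reject" or
    "accept"; None while streaming continues). Chunks arriving after a
    terminal status are ignored.
    """
    if state.status != "streaming":
        return state, None
    state.signal = np.concatenate([state.signal, np.asarray(new_chunk, dtype=np.float64)])
    state.samples_seen = state.signal.size
    state.batches_seen += 1
    if state.trim is None or state.trim.status == "pending":
        state.trim = find_trim_position(state.signal, config.trim)
    k = _assessment_seconds(state, config)
    if k is None:
        return state, None
    probs = {t: _predict(models[t], _window(state, k, config), state.read_id)
             for t in config.targets}
    state.last_probabilities = probs
    state.last_assessed_seconds = k
    outcome = decide(probs, config.mode, config.threshold)
    if outcome == "reject":
        state.rejects_sent += 1
        state.status = "rejected"
        return state, "reject"
    if outcome == "accept":
        state.status = "accepted"
        return state, "accept"
    if k >= config.max_assess_seconds:
        state.status = "undecided_complete"
    return state, None


@dataclass
class RunResult:
    """Per-read outcome table plus the decision records of a playback run.

    ``table`` columns: read_id, channel, condition, status, input_samples,
    delivered_samples, trim_position, samples_assessed, decision_batch,
    plus truth columns (class, transcript_id, gene_id, biotype,
    delivered_transcript_samples) when the input reads carry truth.
    """

    table: pd.DataFrame
    decisions: list[DecisionRecord]
    config: RunConfig

    def decisions_frame(self) -> pd.DataFrame:
        return decisions_to_frame(self.decisions, self.config)


def playback_run(reads, models: dict, config: RunConfig,
                 seed: int = 0) -> RunResult:
    """Replay recorded/synthetic reads against the live protocol.

    Every read is streamed chunk by chunk in global batches (one iteration
    services all active reads). Control-channel reads are never assessed
    and always complete. A rejected read's delivered length is the signal
    received up to the decision plus ``eject_latency_chunks`` chunks of
    ejection latency (capped at the read's full length). Treatment reads
    with no confident call complete fully.
    """
    rng = np.random.default_rng(seed)
    chunk = config.chunk_samples
    max_batches = (None if config.duration_seconds is None
                   else int(config.duration_seconds / config.chunk_seconds))

    states = {r.read_id: ReadState(r.read_id, r.channel) for r in reads}
    conditions = {r.read_id: config.channel_rule(r.channel) for r in reads}
    decided: dict[str, tuple[int, int]] = {}  # read_id -> (batch, delivered at decision)
    decisions: list[DecisionRecord] = []
    # control reads and anything past `duration` stream to completion untouched
    active = {r.read_id: r for r in reads
              if conditions[r.read_id] == "treatment"}

    batch = 0
    while active and (max_batches is None or batch < max_batches):
        assess: dict[int, list] = {}
        done = []
        for rid, read in active.items():
            st = states[rid]
            lo = st.samples_seen
            hi = min(lo + chunk, read.signal.size)
            st.signal = read.signal[:hi].astype(np.float64)
            st.samples_seen = hi
            st.batches_seen = batch + 1
            if st.trim is None or st.trim.status == "pending":
                st.trim = find_trim_position(st.signal, config.trim)
            k = _assessment_seconds(st, config)
            if k is not None:
                assess.setdefault(k, []).append(rid)
            elif hi == read.signal.size:
                # escaped: the molecule finished before a confident call
                done.append(rid)
                st.status = "undecided_complete"
                if st.last_assessed_seconds >= config.min_assess_seconds:
                    decisions.append(DecisionRecord(
                        read_id=rid, batch=batch, channel=st.channel,
                        samples_assessed=st.last_assessed_seconds * config.sample_rate,
                        probabilities=st.last_probabilities,
                        threshold=config.threshold, decision="no_decision"))

        for k, rids in sorted(assess.items()):
            windows = np.stack([_window(states[rid], k, config) for rid in rids])
            probs_by_target = {}
            for t in config.targets:
                model = models[t]
                if hasattr(model, "predict_batch"):
                    probs_by_target[t] = model.predict_batch(windows)
                else:
                    probs_by_target[t] = np.array(
                        [_predict(model, w, rid) for w, rid in zip(windows, rids)])
            for i, rid in enumerate(rids):
                st = states[rid]
                probs = {t: float(probs_by_target[t][i]) for t in config.targets}
                st.last_probabilities = probs
                st.last_assessed_seconds = k
                outcome = decide(probs, config.mode, config.threshold)
                terminal = None
                if outcome == "reject":
                    st.rejects_sent = 1
                    terminal = ("reject_failed"
                                if rng.random() < config.reject_failure_prob
                                else "rejected")
                elif outcome == "accept":
                    terminal = "accepted"
                elif k >= config.max_assess_seconds:
                    terminal = "undecided_complete"
                if terminal is not None:
                    st.status = terminal
                    st.decision_batch = batch
                    decided[rid] = (batch, st.samples_seen)
                    decisions.append(DecisionRecord(
                        read_id=rid, batch=batch, channel=st.channel,
                        samples_assessed=k * config.sample_rate,
                        probabilities=probs, threshold=config.threshold,
                        decision={"rejected": "reject", "reject_failed": "reject",
                                  "accepted": "accept",
                                  "undecided_complete": "no_decision"}[terminal]))
                    done.append(rid)

        for rid in done:
            active.pop(rid, None)
        batch += 1

    rows = []
    latency = config.eject_latency_chunks * chunk
    for read in reads:
        st = states[read.read_id]
        cond = conditions[read.read_id]
        if st.status == "rejected":
            delivered = min(decided[read.read_id][1] + latency, read.signal.size)
        else:
            delivered = read.signal.size
        if cond == "control":
            st.status = "control_complete"
        elif st.status == "streaming":  # run ended (duration) before completion
            st.status = "undecided_complete"
        row = {"read_id": read.read_id, "channel": read.channel,
               "condition": cond, "status": st.status,
               "input_samples": read.signal.size,
               "delivered_samples": delivered,
               "trim_position": (st.trim.trim_position
                                 if st.trim is not None and st.trim.status != "pending"
                                 else None),
               "samples_assessed": st.last_assessed_seconds * config.sample_rate,
               "rejects_sent": st.rejects_sent,
               "decision_batch": st.decision_batch}
        if read.truth is not None:
            row.update({
                "class": read.truth.class_label,
                "transcript_id": read.truth.transcript_id,
                "gene_id": read.truth.gene_id,
                "biotype": read.truth.biotype,
                "delivered_transcript_samples": max(0, delivered - read.truth.polya_end),
                "transcript_samples": read.signal.size - read.truth.polya_end,
            })
        rows.append(row)
    return RunResult(table=pd.DataFrame(rows), decisions=decisions, config=config)


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------

def decisions_to_frame(records: list[DecisionRecord], config: RunConfig) -> pd.DataFrame:
    cols = (["read_id", "batch", "channel", "samples_assessed"]
            + [f"prob_{t}" for t in config.targets] + ["threshold", "decision"])
    rows = []
    for r in records:
        row = [r.read_id, r.batch, r.channel, r.samples_assessed]
        row += [r.probabilities.get(t, np.nan) for t in config.targets]
        row += [r.threshold, r.decision]
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def write_decisions(records: list[DecisionRecord], config: RunConfig, path) -> None:
    """One CSV row per assessed read (header-only for an empty run)."""
    decisions_to_frame(records, config).to_csv(path, index=False)


def write_log(result: RunResult, path) -> None:
    """Plain-text run log: settings summary plus decision tallies."""
    cfg = result.config
    tallies = pd.Series([d.decision for d in result.decisions]).value_counts() \
        if result.decisions else pd.Series(dtype=int)
    with open(path, "w") as f:
        f.write("# playback run log\n")
        f.write(f"mode: {cfg.mode}\n")
        f.write(f"targets: {', '.join(cfg.targets)}\n")
        f.write(f"threshold: {cfg.threshold}\n")
        f.write(f"chunk_seconds: {cfg.chunk_seconds}\n")
        f.write(f"assess window: {cfg.min_assess_seconds}-{cfg.max_assess_seconds} s\n")
        f.write(f"reads: {len(result.table)}\n")
        f.write(f"assessed reads: {len(result.decisions)}\n")
        for name, count in tallies.items():
            f.write(f"decisions[{name}]: {count}\n")
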