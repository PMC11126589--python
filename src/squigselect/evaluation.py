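"""Offline and run-level evaluation statistics.

Covers both stages of assessing a signal-based enrichment/depletion tool:

* model-level: accuracy / precision / TPR / FPR / their ratio / AUROC and
  per-biotype accuracy on held-out windows, plus replaying the incremental
  2-3-4 s protocol to pick the confidence threshold;
* run-level: the probability of superiority PS = U1/(x*y) comparing read
  lengths between the control and treated halves of a flow cell, percent
  change in per-transcript read and nucleotide counts under the abundance
  and count filters, relative transcript abundance with a Pearson
  correlation between conditions, a per-class/per-transcript bias audit of
  the decisions file, and 3'-anchored coverage profiles.

Rank-based tests are reported descriptively (one-tailed, continuity-
corrected normal approximation); no multiple-testing correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    tpr: float
    fpr: float
    tpr_fpr_ratio: float  # inf when FPR = 0
    auroc: float
    per_biotype_accuracy: pd.Series | None = None


def classification_metrics(probabilities: Sequence[float], labels: Sequence[int],
                           biotypes: Sequence[str] | None = None,
                           cut: float = 0.5) -> MetricReport:
    """Standard binary metrics at a probability cut, plus AUROC (the
    probability that a random positive outscores a random negative, ties
    counting one half) and, when biotypes are given, per-biotype accuracy."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    if np.unique(y).size < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    pred = p > cut
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    tpr = tp / (tp + fn)
    fpr = fp / (fp + tn)
    report = MetricReport(
        accuracy=(tp + tn) / y.size,
        precision=tp / (tp + fp) if tp + fp else float("nan"),
        tpr=tpr,
        fpr=fpr,
        tpr_fpr_ratio=tpr / fpr if fpr > 0 else float("inf"),
        auroc=float(roc_auc_score(y, p)),
        per_biotype_accuracy=(
            pd.Series(pred == (y == 1)).groupby(list(biotypes)).mean()
            if biotypes is not None else None),
    )
    return report


def threshold_selection(probs_by_length: dict[int, np.ndarray],
                        labels: Sequence[int],
                        candidates: Sequence[float] = (0.6, 0.75, 0.9)
                        ) -> pd.DataFrame:
    """Replay the incremental protocol per candidate threshold.

    ``probs_by_length`` maps window length (s) to the per-read target
    probability at that length (NaN where a read never reached the
    length). For each read and threshold the shortest length wins: the
    read is called positive at the first length where p > T, negative at
    the first length where p < 1 - T, and undecided if neither happens.
    Returns proportions {correct, incorrect, undecided} per candidate
    (each row sums to 1).
    """
    lengths = sorted(probs_by_length)
    y = np.asarray(labels, dtype=int)
    rows = {}
    for T in candidates:
        outcome = np.full(y.size, "undecided", dtype=object)
        for n in lengths:
            p = np.asarray(probs_by_length[n], dtype=float)
            open_ = outcome == "undecided"
            pos = open_ & (p > T)
            neg = open_ & (p < 1 - T)
            outcome[pos] = np.where(y[pos] == 1, "correct", "incorrect")
            outcome[neg] = np.where(y[neg] == 0, "correct", "incorrect")
        rows[T] = {k: float(np.mean(outcome == k))
                   for k in ("correct", "incorrect", "undecided")}
    return pd.DataFrame(rows).T.rename_axis("threshold")


# ---------------------------------------------------------------------------
# probability of superiority (rank-based effect size)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSize:
    """PS = U1 / (x*y): the probability that a random control value
    exceeds a random treatment value (ties count one half)."""

    u1: float
    x: int  # control sample size
    y: int  # treatment sample size
    ps: float
    p_value: float  # one-tailed (H1: control > treatment), descriptive

    def __post_init__(self):
        if not 0 <= self.ps <= 1 or self.u1 > self.x * self.y:
            raise ValueError("inconsistent effect size")


def probability_of_superiority(control: Sequence[float],
                               treatment: Sequence[float]) -> EffectSize:
    """Rank-sum construction of U1 and PS.

    U1 is computed from midranks of the pooled sample, which equals the
    pairwise count sum_{i,j} [control_i > treatment_j] + 0.5 * ties. The
    p-value uses a continuity-corrected normal approximation with tie
    correction and is descriptive.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treatment, dtype=float)
    if c.size == 0 or t.size == 0:
        raise ValueError("both samples must be non-empty")
    x, y = c.size, t.size
    pooled = np.concatenate([c, t])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:x].sum() - x * (x + 1) / 2)
    n = x + y
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = x * y / 12.0 * ((n + 1) - tie_term)
    if sigma2 > 0:
        z = (u1 - x * y / 2.0 - 0.5) / np.sqrt(sigma2)
        p_value = float(stats.norm.sf(z))
    else:
        p_value = 1.0
    return EffectSize(u1=u1, x=x, y=y, ps=u1 / (x * y), p_value=p_value)


# ---------------------------------------------------------------------------
# count-change and abundance analyses
# ---------------------------------------------------------------------------

def _intervals_overlap(exons, coding_exons) -> bool:
    for s, e in exons:
        for cs, ce in coding_exons:
            if s < ce and cs < e:
                return True
    return False


def percent_change_table(control_counts: Mapping[str, float],
                         treatment_counts: Mapping[str, float],
                         min_count: float = 30,
                         control_mass: float = 0.95,
                         biotypes: Mapping[str, str] | None = None,
                         exons: Mapping[str, Sequence[tuple[int, int]]] | None = None,
                         coding_exons: Sequence[tuple[int, int]] | None = None,
                         exclude_lncrna_overlap: bool = False) -> pd.DataFrame:
    """Per-transcript percent change in counts, treatment vs control.

    Filters, in order: (1) keep the smallest prefix of transcripts sorted
    by descending control count whose cumulative control count reaches
    ``control_mass`` of the total; (2) drop transcripts with fewer than
    ``min_count`` in both conditions; (3) optionally drop lncRNAs whose
    exons share any base with a coding exon (requires annotation for every
    retained transcript). Percent change = 100 * (treatment - control) /
    control. The result is independent of input ordering.
    """
    ctrl = pd.Series(dict(control_counts), dtype=float)
    trt = pd.Series(dict(treatment_counts), dtype=float)
    ctrl = ctrl.sort_index().sort_values(ascending=False, kind="stable")
    trt = trt.reindex(ctrl.index, fill_value=0.0)

    cum = ctrl.cumsum()
    total = ctrl.sum()
    # smallest prefix reaching the mass target (the crossing transcript included)
    n_keep = int(np.searchsorted(cum.values, control_mass * total) + 1)
    keep = ctrl.index[:min(n_keep, len(ctrl))]
    ctrl, trt = ctrl.loc[keep], trt.loc[keep]

    both_low = (ctrl < min_count) & (trt < min_count)
    ctrl, trt = ctrl[~both_low], trt[~both_low]

    if exclude_lncrna_overlap:
        if biotypes is None or exons is None or coding_exons is None:
            raise ValueError("the exon-overlap filter needs biotypes, exons "
                             "and coding_exons")
        kept = []
        for tid in ctrl.index:
            if tid not in biotypes:
                raise ValueError(f"transcript {tid!r} missing from the annotation")
            if biotypes[tid] == "lncRNA":
                if tid not in exons:
                    raise ValueError(f"transcript {tid!r} has no exon annotation")
                if _intervals_overlap(exons[tid], coding_exons):
                    continue
            kept.append(tid)
        ctrl, trt = ctrl.loc[kept], trt.loc[kept]

    out = pd.DataFrame({
        "control": ctrl,
        "treatment": trt,
        "percent_change": 100.0 * (trt - ctrl) / ctrl,
    }).rename_axis("transcript_id")
    if biotypes is not None:
        out.insert(0, "biotype", [biotypes.get(t) for t in out.index])
    return out


def relative_abundance(counts_a: Mapping[str, float], counts_b: Mapping[str, float],
                       min_reads: float = 10
                       ) -> tuple[pd.Series, pd.Series, float, float]:
    """Relative read counts per condition and their Pearson correlation.

    Transcripts with fewer than ``min_reads`` in each condition are
    excluded; fractions are renormalized to sum to 1 per condition over
    the retained transcripts. The correlation is computed over transcripts
    retained in both conditions (error if fewer than 3)."""
    a = pd.Series(dict(counts_a), dtype=float)
    b = pd.Series(dict(counts_b), dtype=float)
    idx = a.index.union(b.index)
    a = a.reindex(idx, fill_value=0.0)
    b = b.reindex(idx, fill_value=0.0)
    keep = ~((a < min_reads) & (b < min_reads))
    a, b = a[keep].sort_index(), b[keep].sort_index()
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("no reads left after filtering")
    fa, fb = a / a.sum(), b / b.sum()
    if len(fa) < 3:
        raise ValueError("correlation undefined: fewer than 3 shared transcripts")
    r, p = stats.pearsonr(fa.values, fb.values)
    return fa, fb, float(r), float(p)


def bias_audit(decisions: pd.DataFrame, targets: Sequence[str],
               mode: str = "deplete", group_by: str = "class") -> pd.DataFrame:
    """Proportions {correct, incorrect, no_decision} per group.

    ``decisions`` must carry a ``decision`` column (accept / reject /
    no_decision) and a truth ``class`` column; ``group_by`` is typically
    ``"class"`` or ``"transcript_id"``. In deplete mode a target-class
    read is correct when rejected and an off-target read when accepted
    (enrich mode mirrors this). The three proportions sum to 1 per group.
    """
    if "class" not in decisions or "decision" not in decisions:
        raise ValueError("decisions table needs 'decision' and 'class' columns")
    is_target = decisions["class"].isin(set(targets))
    wanted = np.where(is_target,
                      "reject" if mode == "deplete" else "accept",
                      "accept" if mode == "deplete" else "reject")
    outcome = np.where(decisions["decision"] == "no_decision", "no_decision",
                       np.where(decisions["decision"] == wanted,
                                "correct", "incorrect"))
    table = (pd.crosstab(decisions[group_by], outcome, normalize="index")
             .reindex(columns=["correct", "incorrect", "no_decision"], fill_value=0.0))
    table.columns.name = None
    return table


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def covered_fraction(span: tuple[int, int], transcript_length: int) -> float:
    """Fraction of the transcript covered by an aligned span, spans being
    0-based half-open in 3'->5' transcript coordinates."""
    s, e = span
    if not 0 <= s < e <= transcript_length:
        raise ValueError(f"span {span} outside transcript of length {transcript_length}")
    return (e - s) / transcript_length


def coverage_profile(spans: Sequence[tuple[int, int]], transcript_length: int
                     ) -> np.ndarray:
    """Percent read depth at each transcript position from the 3' end:
    100 * (reads covering the position) / (total reads)."""
    depth = np.zeros(transcript_length)
    for s, e in spans:
        if not 0 <= s < e <= transcript_length:
            raise ValueError(f"span {(s, e)} outside transcript of length "
                             f"{transcript_length}")
        depth[s:e] += 1
    return 100.0 * depth / max(len(spans), 1)


# ---------------------------------------------------------------------------
# glue: count tables from a playback run
# ---------------------------------------------------------------------------

def counts_from_run(table: pd.DataFrame, samples_per_nt: float,
                    unit: str = "reads",
                    min_mappable_seconds: float = 1.0,
                    sample_rate: int = 3012) -> tuple[pd.Series, pd.Series]:
    """Per-transcript (control, treatment) count tables from a playback
    result table.

    A truncated read still counts as a read provided it delivered at least
    ``min_mappable_seconds`` of transcript signal (shorter truncations
    would not map and are dropped). ``unit`` is ``"reads"`` or
    ``"nucleotides"`` (delivered transcript samples / samples per nt).
    """
    if unit not in ("reads", "nucleotides"):
        raise ValueError(f"unknown unit {unit!r}")
    df = table[table["delivered_transcript_samples"]
               >= min_mappable_seconds * sample_rate]
    if unit == "reads":
        values = pd.Series(1.0, index=df.index)
    else:
        values = df["delivered_transcript_samples"] / samples_per_nt
    out = []
    for cond in ("control", "treatment"):
        sub = df[df["condition"] == cond]
        out.append(values.loc[sub.index].groupby(sub["transcript_id"]).sum())
    return out[0], out[1]
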