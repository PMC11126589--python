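"""Dataset curation: label confirmation, balancing and leak-free splits.

Training a class-specific signal classifier requires a read table in which
(1) every read's biotype label is trustworthy, (2) the positive and
negative classes are the same size, (3) no single biotype or gene
dominates its class, and (4) train/validation/test sets are disjoint by
read. The rules implemented here:

* a read's label is confirmed only when its primary mapping biotype
  matches the most frequent secondary mapping biotype (reads with no
  secondary mappings are trivially confirmed; modal ties are discarded);
* designated biotype subgroups contribute equal read counts within their
  class, limited by the scarcest subgroup;
* reads for a gene can be capped at a fraction of its class;
* gene-level round-robin sampling (one read per gene per round) is used
  whenever a subset of a pool must be drawn, so highly abundant genes
  cannot dominate;
* the majority class is undersampled to a 50/50 balance, then each class
  is split 80/20 into train/test with 10% of train reserved for
  validation, keeping the class balance exact in every split.

Metadata tables are plain tab-separated text; split manifests are plain
read-id lists, one per line.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import find_trim_position, normalize
from .synthetic_data import RawRead


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    transcript_id: str
    gene_id: str
    primary_biotype: str
    secondary_biotypes: tuple[str, ...] = ()
    class_label: str = "excluded"  # positive | negative | excluded

    @property
    def biotype(self) -> str:
        return self.primary_biotype


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.20
    validation_fraction_of_train: float = 0.10
    balance_subgroups: tuple[str, ...] = ()
    per_gene_cap: float | None = None  # fraction of the class, or None
    seed: int = 0

    def __post_init__(self):
        for f in (self.test_fraction, self.validation_fraction_of_train):
            if not 0 < f < 1:
                raise ValueError("split fractions must lie in (0, 1)")


def confirm_label(record: ReadRecord) -> str:
    """``"keep"`` iff the read has no secondary mappings or the (unique)
    modal secondary biotype equals the primary biotype, else ``"discard"``."""
    if not record.secondary_biotypes:
        return "keep"
    counts = Counter(record.secondary_biotypes)
    top = max(counts.values())
    modal = [b for b, c in counts.items() if c == top]
    if len(modal) == 1 and modal[0] == record.primary_biotype:
        return "keep"
    return "discard"


def assign_classes(records: list[ReadRecord], positive_biotypes: set[str],
                   negative_biotypes: set[str],
                   exclude_biotypes: set[str] = frozenset()) -> list[ReadRecord]:
    """Label-confirm and classify records; excluded biotypes (for example
    pseudogenes, which share sequence with both classes) are dropped from
    both classes before labeling."""
    out = []
    for r in records:
        if r.primary_biotype in exclude_biotypes or confirm_label(r) == "discard":
            cls = "excluded"
        elif r.primary_biotype in positive_biotypes:
            cls = "positive"
        elif r.primary_biotype in negative_biotypes:
            cls = "negative"
        else:
            cls = "excluded"
        out.append(replace(r, class_label=cls))
    return out


def round_robin_sample(records: list[ReadRecord], k: int,
                       rng: np.random.Generator) -> list[ReadRecord]:
    """Draw ``k`` records, one per gene per round; gene order is
    randomized once, reads within each gene are shuffled once."""
    if k >= len(records):
        return list(records)
    by_gene: dict[str, list[ReadRecord]] = defaultdict(list)
    for r in records:
        by_gene[r.gene_id].append(r)
    genes = sorted(by_gene)
    rng.shuffle(genes)
    queues = {}
    for g in genes:
        pool = by_gene[g]
        order = rng.permutation(len(pool))
        queues[g] = [pool[i] for i in order]
    chosen: list[ReadRecord] = []
    while len(chosen) < k:
        for g in genes:
            if queues[g]:
                chosen.append(queues[g].pop())
                if len(chosen) == k:
                    break
    return chosen


def _split_counts(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    n_test = round(n * spec.test_fraction)
    n_train0 = n - n_test
    n_val = round(n_train0 * spec.validation_fraction_of_train)
    return n_train0 - n_val, n_val, n_test


def build_balanced_dataset(records: list[ReadRecord], spec: SplitSpec
                           ) -> tuple[list[ReadRecord], list[ReadRecord], list[ReadRecord]]:
    """Balance classes/subgroups/genes and split into (train, validation,
    test), deterministic per ``spec.seed``. See the module docstring for
    the order of operations."""
    rng = np.random.default_rng(spec.seed)
    pools = {
        "positive": [r for r in records if r.class_label == "positive"],
        "negative": [r for r in records if r.class_label == "negative"],
    }
    for cls, pool in pools.items():
        if not pool:
            raise ValueError(f"the {cls} class is empty")

    # subgroup equalization (within each class containing listed biotypes)
    if spec.balance_subgroups:
        present = {r.primary_biotype for p in pools.values() for r in p}
        for sub in spec.balance_subgroups:
            if sub not in present:
                raise ValueError(f"requested balance subgroup {sub!r} has no reads")
        for cls, pool in pools.items():
            by_bt: dict[str, list[ReadRecord]] = defaultdict(list)
            for r in pool:
                by_bt[r.primary_biotype].append(r)
            listed = [b for b in spec.balance_subgroups if b in by_bt]
            if len(listed) >= 2:
                m = min(len(by_bt[b]) for b in listed)
                new_pool = []
                for bt in sorted(by_bt):
                    group = by_bt[bt]
                    if bt in listed:
                        group = round_robin_sample(group, m, rng)
                    new_pool.extend(group)
                pools[cls] = new_pool

    # per-gene cap, a fraction of the read count of the gene's class
    if spec.per_gene_cap is not None:
        for cls, pool in pools.items():
            cap = max(1, int(spec.per_gene_cap * len(pool)))
            by_gene: dict[str, list[ReadRecord]] = defaultdict(list)
            for r in pool:
                by_gene[r.gene_id].append(r)
            new_pool = []
            for g in sorted(by_gene):
                group = by_gene[g]
                if len(group) > cap:
                    idx = rng.permutation(len(group))[:cap]
                    group = [group[i] for i in sorted(idx)]
                new_pool.extend(group)
            pools[cls] = new_pool

    # 50/50 class balance: undersample the majority class uniformly
    n = min(len(p) for p in pools.values())
    for cls, pool in pools.items():
        if len(pool) > n:
            idx = rng.permutation(len(pool))[:n]
            pools[cls] = [pool[i] for i in sorted(idx)]

    # disjoint splits with identical per-class counts -> exact balance
    n_train, n_val, n_test = _split_counts(n, spec)
    train, val, test = [], [], []
    for cls in ("positive", "negative"):
        pool = pools[cls]
        order = rng.permutation(n)
        shuffled = [pool[i] for i in order]
        test.extend(shuffled[:n_test])
        val.extend(shuffled[n_test:n_test + n_val])
        train.extend(shuffled[n_test + n_val:])
    return train, val, test


def make_training_windows(reads: list[RawRead], classes: dict[str, int],
                          lengths: tuple[int, ...] = (2, 3, 4),
                          apply_normalization: bool = True,
                          trim_source: str = "detected"
                          ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Cut each read's transcript signal into one window per requested
    length (seconds).

    ``classes`` maps a read's truth class label to its binary label
    (e.g. ``{"target": 1, "nontarget": 0}``); reads of other classes are
    skipped. Reads whose transcript signal is shorter than the longest
    requested length are discarded entirely, so every retained read
    contributes every length. Windows are MAD-normalized by default.

    ``trim_source`` selects where the transcript signal starts:
    ``"detected"`` (default) runs the package's own boundary search on the
    complete signal — the offline analogue of live trimming, so training
    windows carry the same boundary imprecision the model will see during
    a run — while ``"truth"`` uses the generator's exact poly(A) end.
    """
    if trim_source not in ("detected", "truth"):
        raise ValueError(f"unknown trim_source {trim_source!r}")
    n_max = max(lengths) if lengths else 0
    windows: dict[int, list[np.ndarray]] = {n: [] for n in lengths}
    labels: list[int] = []
    for read in reads:
        if read.truth is None or read.truth.class_label not in classes:
            continue
        if trim_source == "truth":
            start = read.truth.polya_end
        else:
            res = find_trim_position(read.signal)
            if res.trim_position is None:
                continue
            start = res.trim_position
        tx = read.signal[start:]
        if tx.size < n_max * read.sample_rate:
            continue
        labels.append(classes[read.truth.class_label])
        for n in lengths:
            w = tx[:n * read.sample_rate].astype(np.float64)
            windows[n].append(normalize(w) if apply_normalization else w)
    y = np.array(labels, dtype=np.float32)
    out = {}
    for n, ws in windows.items():
        if ws:
            out[n] = (np.array(ws, dtype=np.float32), y)
        else:
            out[n] = (np.empty((0, 0), dtype=np.float32), y)
    return out


# ---------------------------------------------------------------------------
# delimited-text interfaces
# ---------------------------------------------------------------------------

#: metadata table header. ``secondary_biotypes`` is a comma-joined list
#: (empty for none); ``class`` is positive/negative/excluded.
TABLE_COLUMNS = ("read_id", "transcript_id", "gene_id", "primary_biotype",
                 "secondary_biotypes", "class")


def records_to_table(records: list[ReadRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.read_id, r.transcript_id, r.gene_id, r.primary_biotype,
          ",".join(r.secondary_biotypes), r.class_label) for r in records],
        columns=list(TABLE_COLUMNS))


def records_from_table(df: pd.DataFrame) -> list[ReadRecord]:
    records = []
    for row in df.to_dict("records"):
        raw_sec = row.get("secondary_biotypes", "")
        sec = tuple(str(raw_sec).split(",")) if isinstance(raw_sec, str) and raw_sec else ()
        records.append(ReadRecord(
            read_id=str(row["read_id"]), transcript_id=str(row["transcript_id"]),
            gene_id=str(row["gene_id"]), primary_biotype=str(row["primary_biotype"]),
            secondary_biotypes=sec,
            class_label=str(row.get("class", "excluded"))))
    return records


def write_metadata_table(records: list[ReadRecord], path) -> None:
    records_to_table(records).to_csv(path, sep="\t", index=False)


def read_metadata_table(path) -> list[ReadRecord]:
    return records_from_table(pd.read_csv(path, sep="\t", keep_default_na=False))


def write_manifest(records: list[ReadRecord], path) -> None:
    with open(path, "w") as f:
        for r in records:
            f.write(r.read_id + "\n")
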