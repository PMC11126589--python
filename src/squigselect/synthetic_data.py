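"""Synthetic direct-RNA squiggle generation.

Real nanopore direct RNA sequencing reads a molecule 3'->5' and emits a
picoampere current trace with a stereotyped layout: a sequencing-adapter
segment (lower mean current, high dispersion), then the poly(A) tail (a
homopolymer, hence elevated mean and very low dispersion), then the
transcript signal whose local level is set by the k-mer occupying the
pore. This module generates signals with exactly that statistical
structure — enough for the trimmer, the classifiers and the run-level
statistics to be exercised end to end without any sequencing data — along
with a small transcript catalog standing in for a reference annotation.

What is deliberately *not* modelled: pore kinetics, dwell-time
distributions, current drift, or basecallable signal content. Class
identity is carried solely by the 3'-end k-mer composition (each class
draws its 3'-terminal sequence from a distinct motif pool over a shared
k-mer level table), mirroring the premise that RNA classes differ in
3'-end sequence composition rather than global signal level.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .preprocess import SAMPLE_RATE

#: Gaussian MAD -> standard deviation conversion (MAD = 0.6745 sigma).
_MAD_TO_SIGMA = 1.0 / 0.674489750196082

BASES = "ACGU"
KMER_SIZE = 5


def _stable_rng(*parts) -> np.random.Generator:
    """Deterministic, process-independent RNG keyed by the given parts."""
    key = zlib.crc32(":".join(str(p) for p in parts).encode())
    return np.random.default_rng(key)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    length: int  # nt
    exons: tuple[tuple[int, int], ...]  # 0-based half-open genomic intervals

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("transcript length must be >= 1 nt")
        prev_end = -1
        for s, e in self.exons:
            if s < 0 or e <= s:
                raise ValueError(f"invalid exon interval ({s}, {e})")
            if s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e


@dataclass(frozen=True)
class SyntheticCatalog:
    """Stand-in for a reference transcriptome annotation."""

    genes: tuple[tuple[str, str], ...]  # (gene_id, biotype)
    transcripts: tuple[Transcript, ...]
    class_of: dict[str, str]  # transcript_id -> class label

    def __post_init__(self):
        gene_ids = {g for g, _ in self.genes}
        for t in self.transcripts:
            if t.gene_id not in gene_ids:
                raise ValueError(f"{t.transcript_id} references unknown gene {t.gene_id}")

    def biotype_of(self, transcript_id: str) -> str:
        gene = {t.transcript_id: t.gene_id for t in self.transcripts}[transcript_id]
        return dict(self.genes)[gene]

    def get(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


#: biotype assigned to each synthetic class
CLASS_BIOTYPES = {"target": "mRNA", "nontarget": "lncRNA"}


def generate_catalog(n_genes_per_class: int, transcripts_per_gene: int,
                     length_dist: tuple, seed: int,
                     classes: tuple[str, ...] = ("target", "nontarget"),
                     shared_exon_fraction: float = 0.0) -> SyntheticCatalog:
    """Build a deterministic two-class (extensible) transcript catalog.

    ``length_dist`` is ``("fixed", n)`` or ``("uniform", lo, hi)`` in nt.
    ``shared_exon_fraction`` makes that fraction of non-coding genes reuse
    a coding gene's exon interval, so the exon-overlap exclusion filter in
    the evaluation module has something to exclude.
    """
    if n_genes_per_class < 1 or transcripts_per_gene < 1:
        raise ValueError("counts must be >= 1")
    if not length_dist or length_dist[0] not in ("fixed", "uniform"):
        raise ValueError(f"unknown length distribution {length_dist!r}")
    if length_dist[0] == "uniform" and not (1 <= length_dist[1] <= length_dist[2]):
        raise ValueError(f"invalid uniform bounds {length_dist!r}")
    if length_dist[0] == "fixed" and length_dist[1] < 1:
        raise ValueError("fixed length must be >= 1 nt")

    rng = np.random.default_rng(seed)
    genes, transcripts, class_of = [], [], {}
    coding_exons: list[tuple[int, int]] = []
    cursor = 0  # running genomic coordinate so exons do not overlap by default
    for cls in classes:
        biotype = CLASS_BIOTYPES.get(cls, cls)
        for g in range(n_genes_per_class):
            gene_id = f"G_{cls}_{g:03d}"
            genes.append((gene_id, biotype))
            for t in range(transcripts_per_gene):
                if length_dist[0] == "fixed":
                    length = int(length_dist[1])
                else:
                    length = int(rng.integers(length_dist[1], length_dist[2] + 1))
                tid = f"T_{cls}_{g:03d}_{t}"
                if (biotype != "mRNA" and coding_exons
                        and rng.random() < shared_exon_fraction):
                    exons = (coding_exons[int(rng.integers(len(coding_exons)))],)
                else:
                    exons = ((cursor, cursor + length),)
                    cursor += length + int(rng.integers(100, 1000))
                if biotype == "mRNA":
                    coding_exons.append(exons[0])
                transcripts.append(Transcript(tid, gene_id, length, exons))
                class_of[tid] = cls
    return SyntheticCatalog(tuple(genes), tuple(transcripts), class_of)


# ---------------------------------------------------------------------------
# signal parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentParams:
    duration: tuple[float, float]  # seconds, uniform range
    mean: float  # pA
    mad: float  # pA


def _default_kmer_table(seed: int) -> dict[str, float]:
    """Seed-fixed random 5-mer current levels, shared across classes."""
    rng = _stable_rng("kmer-table", seed)
    kmers = []

    def rec(prefix):
        if len(prefix) == KMER_SIZE:
            kmers.append(prefix)
            return
        for b in BASES:
            rec(prefix + b)

    rec("")
    levels = rng.uniform(60.0, 130.0, size=len(kmers))
    return dict(zip(kmers, levels))


def _default_class_motifs(seed: int, classes=("target", "nontarget"),
                          n_motifs: int = 12, motif_len: int = 8):
    """Disjoint per-class pools of 3'-end motifs with uniform weights."""
    rng = _stable_rng("class-motifs", seed)
    seen: set[str] = set()
    pools = {}
    for cls in classes:
        motifs = []
        while len(motifs) < n_motifs:
            m = "".join(BASES[i] for i in rng.integers(0, 4, size=motif_len))
            if m not in seen:
                seen.add(m)
                motifs.append(m)
        pools[cls] = (tuple(motifs), tuple([1.0 / n_motifs] * n_motifs))
    return pools


@dataclass(frozen=True)
class SignalParams:
    """Generator preset.

    Defaults encode the observed segment structure of R9.4.1 direct-RNA
    squiggles: adapter at 80 pA mean / 25 pA MAD for 1-3 s, poly(A) at
    110 pA mean / 5 pA MAD for 0.5-3 s (mean >= 1.25x the adapter so the
    trimmer's start criterion is satisfiable; MAD < 20 so its dispersion
    criterion is), transcript noise at 25 pA MAD (> 20 so the poly(A)-end
    criterion fires). ~43 samples per nucleotide (3012 samples/s over
    ~70 nt/s translocation) with +-10% multiplicative jitter.
    """

    sample_rate: int = SAMPLE_RATE
    samples_per_nt: int = 43
    samples_per_nt_jitter: float = 0.10
    adapter: SegmentParams = SegmentParams((1.0, 3.0), 80.0, 25.0)
    polya: SegmentParams = SegmentParams((0.5, 3.0), 110.0, 5.0)
    transcript_noise: float = 25.0  # MAD, pA
    motif_region_nt: int = 400  # 3'-end span composed from class motifs
    kmer_table: dict[str, float] = field(default_factory=lambda: _default_kmer_table(0))
    class_motifs: dict = field(default_factory=lambda: _default_class_motifs(0))
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.polya.mean < 1.25 * self.adapter.mean:
            raise ValueError("poly(A) mean must be >= 1.25x adapter mean "
                             "(trimmer start criterion unsatisfiable otherwise)")

    @classmethod
    def default(cls, seed: int = 0) -> "SignalParams":
        return cls(kmer_table=_default_kmer_table(seed),
                   class_motifs=_default_class_motifs(seed), seed=seed)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadTruth:
    class_label: str
    transcript_id: str
    gene_id: str
    biotype: str
    adapter_end: int  # sample index, half-open
    polya_end: int  # sample index, half-open (= trim position)
    full_length: int  # samples

    def __post_init__(self):
        if not (0 <= self.adapter_end <= self.polya_end <= self.full_length):
            raise ValueError("truth boundaries out of order")


@dataclass(frozen=True)
class RawRead:
    """One molecule's current trace plus (optionally) ground truth."""

    read_id: str
    channel: int
    signal: np.ndarray
    sample_rate: int = SAMPLE_RATE
    truth: ReadTruth | None = None

    def __post_init__(self):
        if self.channel < 1:
            raise ValueError("channel must be a positive integer")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal values must be finite")
        if self.truth is not None and self.truth.full_length != self.signal.size:
            raise ValueError("truth full_length must equal signal length")


def transcript_sequence(transcript: Transcript, class_label: str,
                        params: SignalParams) -> str:
    """Per-transcript synthetic sequence in signal (3'->5') order.

    Deterministic in (transcript_id, params.seed) so all copies of a
    transcript share a sequence. The 3'-terminal ``motif_region_nt``
    nucleotides are concatenated motifs drawn from the class pool; the
    remainder is uniform random.
    """
    rng = _stable_rng("seq", transcript.transcript_id, params.seed)
    motifs, weights = params.class_motifs[class_label]
    n_motif_nt = min(transcript.length, params.motif_region_nt)
    parts: list[str] = []
    n = 0
    while n < n_motif_nt:
        m = motifs[rng.choice(len(motifs), p=np.asarray(weights) / np.sum(weights))]
        parts.append(m)
        n += len(m)
    seq = "".join(parts)[:n_motif_nt]
    rest = transcript.length - n_motif_nt
    if rest > 0:
        seq += "".join(BASES[i] for i in rng.integers(0, 4, size=rest))
    return seq


def _segment(rng, seg: SegmentParams, sample_rate: int) -> np.ndarray:
    n = int(rng.uniform(*seg.duration) * sample_rate)
    return seg.mean + rng.standard_normal(n) * (seg.mad * _MAD_TO_SIGMA)


def synthesize_read(transcript: Transcript, class_label: str,
                    params: SignalParams, seed: int,
                    channel: int = 1, read_id: str | None = None,
                    gene_id: str | None = None, biotype: str | None = None) -> RawRead:
    """Generate one squiggle: adapter ++ poly(A) ++ transcript segment.

    The transcript segment slides a 5-mer window along the synthetic
    sequence (3'-end motifs first), emits the k-mer table level for
    ~``samples_per_nt`` samples per nucleotide, and adds Gaussian noise of
    ``transcript_noise`` MAD. Truth boundaries are recorded exactly.
    """
    rng = _stable_rng("read", transcript.transcript_id, seed)
    adapter = _segment(rng, params.adapter, params.sample_rate)
    polya = _segment(rng, params.polya, params.sample_rate)

    seq = transcript_sequence(transcript, class_label, params)
    padded = seq + seq[: KMER_SIZE - 1] if len(seq) >= KMER_SIZE - 1 else seq + "A" * KMER_SIZE
    levels = np.array([params.kmer_table[padded[i:i + KMER_SIZE]]
                       for i in range(len(seq))])
    if params.samples_per_nt_jitter > 0:
        dwell = np.round(params.samples_per_nt *
                         rng.uniform(1 - params.samples_per_nt_jitter,
                                     1 + params.samples_per_nt_jitter,
                                     size=len(seq))).astype(int)
    else:
        dwell = np.full(len(seq), params.samples_per_nt)
    tx = np.repeat(levels, dwell)
    tx = tx + rng.standard_normal(tx.size) * (params.transcript_noise * _MAD_TO_SIGMA)

    signal = np.concatenate([adapter, polya, tx]).astype(np.float32)
    truth = ReadTruth(
        class_label=class_label,
        transcript_id=transcript.transcript_id,
        gene_id=gene_id or transcript.gene_id,
        biotype=biotype or CLASS_BIOTYPES.get(class_label, class_label),
        adapter_end=adapter.size,
        polya_end=adapter.size + polya.size,
        full_length=signal.size,
    )
    return RawRead(read_id=read_id or f"sr{seed}-{transcript.transcript_id}",
                   channel=channel, signal=signal,
                   sample_rate=params.sample_rate, truth=truth)


def generate_run_set(catalog: SyntheticCatalog, n_reads: int,
                     class_mix: dict[str, float], n_channels: int,
                     params: SignalParams, seed: int,
                     abundance_dist: dict[str, float] | None = None) -> list[RawRead]:
    """Sample a sequencing library: reads over the catalog with the given
    class proportions, transcripts drawn within class by ``abundance_dist``
    weights (uniform if None), channels uniform in 1..n_channels."""
    classes = list(class_mix)
    mix = np.array([class_mix[c] for c in classes], dtype=float)
    if np.any(mix < 0) or mix.sum() == 0:
        raise ValueError("class mix weights must be non-negative and not all zero")
    mix = mix / mix.sum()

    by_class: dict[str, list[Transcript]] = {c: [] for c in classes}
    for t in catalog.transcripts:
        cls = catalog.class_of[t.transcript_id]
        if cls in by_class:
            by_class[cls].append(t)
    for c in classes:
        if not by_class[c]:
            raise ValueError(f"catalog has no transcripts of class {c!r}")

    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        cls = classes[int(rng.choice(len(classes), p=mix))]
        pool = by_class[cls]
        if abundance_dist:
            w = np.array([abundance_dist.get(t.transcript_id, 0.0) for t in pool])
            if w.sum() == 0:
                raise ValueError(f"abundance weights all zero for class {cls!r}")
            tx = pool[int(rng.choice(len(pool), p=w / w.sum()))]
        else:
            tx = pool[int(rng.integers(len(pool)))]
        channel = int(rng.integers(1, n_channels + 1))
        reads.append(synthesize_read(tx, cls, params,
                                     seed=int(rng.integers(2 ** 31)),
                                     channel=channel,
                                     read_id=f"sr{seed}-{i:06d}"))
    return reads


# ---------------------------------------------------------------------------
# fixture container (HDF5) and FAST5 loading
# ---------------------------------------------------------------------------

_TRUTH_FIELDS = ("class_label", "transcript_id", "gene_id", "biotype",
                 "adapter_end", "polya_end")


def run_metadata(reads: list[RawRead]) -> pd.DataFrame:
    """Companion metadata table for a run (one row per read)."""
    rows = []
    for r in reads:
        row = {"read_id": r.read_id, "channel": r.channel,
               "full_length": r.signal.size}
        if r.truth is not None:
            row.update({"class": r.truth.class_label,
                        "transcript_id": r.truth.transcript_id,
                        "gene_id": r.truth.gene_id,
                        "biotype": r.truth.biotype,
                        "adapter_end": r.truth.adapter_end,
                        "polya_end": r.truth.polya_end})
        rows.append(row)
    return pd.DataFrame(rows)


def save_run(path, reads: list[RawRead]) -> None:
    """Write a run fixture.

    HDF5 layout: one group ``/reads/<read_id>`` per read holding the
    ``signal`` dataset (float32, pA) with attrs ``channel``,
    ``sample_rate`` and, when truth is known, ``class_label``,
    ``transcript_id``, ``gene_id``, ``biotype``, ``adapter_end``,
    ``polya_end``.
    """
    with h5py.File(path, "w") as f:
        grp = f.create_group("reads")
        for r in reads:
            g = grp.create_group(r.read_id)
            g.create_dataset("signal", data=np.asarray(r.signal, dtype=np.float32))
            g.attrs["channel"] = r.channel
            g.attrs["sample_rate"] = r.sample_rate
            if r.truth is not None:
                for name in _TRUTH_FIELDS:
                    g.attrs[name] = getattr(r.truth, name)


def load_run(path) -> list[RawRead]:
    """Load a run fixture written by :func:`save_run`."""
    reads = []
    with h5py.File(path, "r") as f:
        for read_id, g in f["reads"].items():
            signal = g["signal"][()]
            truth = None
            if "class_label" in g.attrs:
                truth = ReadTruth(
                    class_label=str(g.attrs["class_label"]),
                    transcript_id=str(g.attrs["transcript_id"]),
                    gene_id=str(g.attrs["gene_id"]),
                    biotype=str(g.attrs["biotype"]),
                    adapter_end=int(g.attrs["adapter_end"]),
                    polya_end=int(g.attrs["polya_end"]),
                    full_length=signal.size,
                )
            reads.append(RawRead(read_id=read_id, channel=int(g.attrs["channel"]),
                                 signal=signal,
                                 sample_rate=int(g.attrs["sample_rate"]),
                                 truth=truth))
    reads.sort(key=lambda r: r.read_id)
    return reads


def load_fast5(path, sample_rate: int = SAMPLE_RATE) -> list[RawRead]:
    """Load raw signals from a FAST5 file (signal + read id only).

    FAST5 files are HDF5 containers; both the multi-read layout
    (``/read_<id>/Raw/Signal``) and the legacy single-read layout
    (``/Raw/Reads/Read_<n>/Signal``) are understood. Signals are converted
    to pA when ``channel_id`` calibration attrs (digitisation, range,
    offset) are present, and returned with no truth fields.
    """
    reads = []
    with h5py.File(path, "r") as f:
        def to_pa(raw, grp):
            if "channel_id" in grp:
                a = grp["channel_id"].attrs
                try:
                    scale = float(a["range"]) / float(a["digitisation"])
                    return (raw.astype(np.float32) + float(a["offset"])) * scale
                except KeyError:
                    pass
            return raw.astype(np.float32)

        if "Raw" in f:  # legacy single-read file
            for name, rd in f["Raw"]["Reads"].items():
                rid = rd.attrs.get("read_id", name)
                rid = rid.decode() if isinstance(rid, bytes) else str(rid)
                reads.append(RawRead(read_id=rid, channel=1,
                                     signal=to_pa(rd["Signal"][()], f),
                                     sample_rate=sample_rate))
        else:  # multi-read file
            for name, grp in f.items():
                if not name.startswith("read"):
                    continue
                rid = grp.attrs.get("read_id", name.removeprefix("read_"))
                rid = rid.decode() if isinstance(rid, bytes) else str(rid)
                reads.append(RawRead(read_id=rid, channel=1,
                                     signal=to_pa(grp["Raw"]["Signal"][()], grp),
                                     sample_rate=sample_rate))
    reads.sort(key=lambda r: r.read_id)
    return reads
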