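"""Normalized k-mer spectra and sliding-window composition scans.

Oligonucleotide composition is a genome-wide signature: a segment whose
tetranucleotide spectrum deviates strongly from the genome average is a
candidate for horizontal acquisition or for misattribution (e.g. host
contamination in a metagenomic bin).  The scan computes the L1 distance
between each window's normalized k-mer frequency vector and the whole-genome
vector; the defaults (4-mers, 1 kb windows, 500 bp steps) follow common
practice for prokaryote-sized genomes.

Windows are emitted only where a full window fits, on a 0-based half-open
coordinate system; k-mers containing N are not counted, and windows that are
mostly N are reported as missing rather than scored.  Flagging anomalous
windows (robust z-score on the per-window deviation with merged intervals)
is a convenience on top of the scan, which is otherwise purely descriptive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "NucleotideSequence",
    "KmerSpectrum",
    "Window",
    "ScanResult",
    "kmer_spectrum",
    "sliding_scan",
    "flag_anomalies",
    "read_genome_fasta",
    "scan_to_tsv",
    "intervals_to_bed",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class NucleotideSequence:
    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases) - set("ACGTN")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid bases {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class KmerSpectrum:
    """L1-normalized k-mer frequencies in lexicographic order (4^k entries)."""

    k: int
    freqs: np.ndarray
    n_counted: int

    @staticmethod
    def kmers(k: int) -> list[str]:
        return ["".join(p) for p in product(_BASES, repeat=k)]


@dataclass(frozen=True)
class Window:
    start: int       # 0-based inclusive
    end: int         # exclusive
    score: float
    flagged: bool = False
    missing: bool = False   # skipped (mostly N)


@dataclass
class ScanResult:
    genome_id: str
    k: int
    window: int
    step: int
    genome_spectrum: KmerSpectrum
    windows: list[Window]
    threshold: float | None = None
    merged_intervals: list[tuple[int, int]] = field(default_factory=list)

    def scores(self) -> np.ndarray:
        return np.array([w.score for w in self.windows if not w.missing])


def _encode(bases: str) -> np.ndarray:
    """Base -> 0..3 integer codes, -1 for N."""
    arr = np.frombuffer(bases.encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for b, c in _CODE.items():
        codes[arr == ord(b)] = c
    return codes


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Per-position k-mer index in [0, 4^k); -1 where the k-mer contains N."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes >= 0
    idx = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        idx = idx * 4 + np.where(valid[j:j + n], codes[j:j + n], 0)
        ok &= valid[j:j + n]
    idx[~ok] = -1
    return idx


def _spectrum_from_codes(kcodes: np.ndarray, k: int) -> KmerSpectrum:
    counted = kcodes[kcodes >= 0]
    if counted.size == 0:
        raise ValueError("no countable k-mers (sequence shorter than k or all N)")
    counts = np.bincount(counted, minlength=4 ** k)
    return KmerSpectrum(k, counts / counted.size, int(counted.size))


def kmer_spectrum(seq: NucleotideSequence | str, k: int,
                  norm: str = "l1") -> KmerSpectrum:
    """Normalized k-mer frequency vector of a sequence.

    ``norm='l1'`` divides counts by the total number of counted words (the
    default); ``'l2'`` scales the vector to unit Euclidean length instead.
    """
    bases = seq.bases if isinstance(seq, NucleotideSequence) else seq
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(bases) < k:
        raise ValueError(f"sequence length {len(bases)} < k={k}")
    spec = _spectrum_from_codes(_kmer_codes(_encode(bases), k), k)
    if norm == "l2":
        v = spec.freqs * spec.n_counted
        spec = KmerSpectrum(k, v / np.linalg.norm(v), spec.n_counted)
    elif norm != "l1":
        raise ValueError("norm must be 'l1' or 'l2'")
    return spec


def sliding_scan(
    genome: NucleotideSequence,
    k: int = 4,
    window: int = 1000,
    step: int = 500,
    max_n_fraction: float = 0.5,
) -> ScanResult:
    """Per-window L1 deviation of the local k-mer spectrum from the genome's.

    The window count is floor((L - window)/step) + 1: only full windows are
    scored, no partial tail.  Windows with more than ``max_n_fraction`` N are
    reported as missing.  Per-window counts are maintained by a rolling
    update (subtract the k-mers leaving, add those entering), which is
    exactly equivalent to recounting each window.
    """
    L = len(genome)
    if window < k:
        raise ValueError("window must be >= k")
    if window > L:
        raise ValueError(f"window {window} exceeds genome length {L}")
    if step < 1:
        raise ValueError("step must be >= 1")

    codes = _encode(genome.bases)
    kcodes = _kmer_codes(codes, k)
    genome_spec = _spectrum_from_codes(kcodes, k)
    nvec = 4 ** k

    starts = range(0, L - window + 1, step)
    windows: list[Window] = []
    counts = np.zeros(nvec, dtype=np.int64)
    prev: tuple[int, int] | None = None   # previous window's k-mer code span
    n_is_n = np.cumsum(np.concatenate([[0], (codes < 0).astype(np.int64)]))

    for s in starts:
        e = s + window
        span = (s, e - k + 1)    # k-mer start positions in [s, e-k]
        if prev is None or span[0] - prev[0] >= prev[1] - prev[0]:
            counts[:] = 0
            seg = kcodes[span[0]:span[1]]
            seg = seg[seg >= 0]
            np.add.at(counts, seg, 1)
        else:
            out = kcodes[prev[0]:span[0]]
            out = out[out >= 0]
            np.subtract.at(counts, out, 1)
            inc = kcodes[prev[1]:span[1]]
            inc = inc[inc >= 0]
            np.add.at(counts, inc, 1)
        prev = span

        n_frac = (n_is_n[e] - n_is_n[s]) / window
        total = counts.sum()
        if n_frac > max_n_fraction or total == 0:
            windows.append(Window(s, e, float("nan"), missing=True))
            continue
        score = float(np.abs(counts / total - genome_spec.freqs).sum())
        windows.append(Window(s, e, score))

    return ScanResult(genome.id, k, window, step, genome_spec, windows)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def flag_anomalies(
    scan: ScanResult,
    method: str = "robust_z",
    cutoff: float = 5.0,
    quantile: float = 0.99,
) -> ScanResult:
    """Flag outlying windows and merge them into candidate intervals.

    ``robust_z`` flags windows whose score exceeds the median by more than
    ``cutoff`` normalized MADs; when the MAD is zero (near-constant scores)
    it falls back to the ``quantile`` method, which flags scores strictly
    above the given quantile of the score distribution.
    """
    scored = [w for w in scan.windows if not w.missing]
    if len(scored) < 5:
        raise ValueError("need at least 5 scored windows to flag anomalies")
    scores = np.array([w.score for w in scored])

    if method == "robust_z":
        med = np.median(scores)
        mad = float(np.median(np.abs(scores - med))) * 1.4826
        if mad == 0.0:
            warnings.warn("MAD of window scores is zero; falling back to "
                          "quantile flagging", stacklevel=2)
            return flag_anomalies(scan, "quantile", cutoff, quantile)
        thr = float(med + cutoff * mad)
    elif method == "quantile":
        thr = float(np.quantile(scores, quantile))
    else:
        raise ValueError("method must be 'robust_z' or 'quantile'")

    flagged_windows = [
        replace(w, flagged=(not w.missing and w.score > thr))
        for w in scan.windows
    ]
    intervals = _merge([(w.start, w.end) for w in flagged_windows if w.flagged])
    return ScanResult(scan.genome_id, scan.k, scan.window, scan.step,
                      scan.genome_spectrum, flagged_windows, thr, intervals)


# ---------------------------------------------------------------------------
# I/O


def read_genome_fasta(path: str | Path) -> list[NucleotideSequence]:
    seqs = [NucleotideSequence(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def scan_to_tsv(scan: ScanResult) -> Iterator[str]:
    yield "chrom\tstart\tend\tscore\tflagged"
    for w in scan.windows:
        score = "NA" if w.missing else f"{w.score:.6g}"
        yield f"{scan.genome_id}\t{w.start}\t{w.end}\t{score}\t{int(w.flagged)}"


def intervals_to_bed(scan: ScanResult, name: str = "anomaly") -> Iterator[str]:
    for i, (s, e) in enumerate(scan.merged_intervals, 1):
        yield f"{scan.genome_id}\t{s}\t{e}\t{name}_{i}"
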