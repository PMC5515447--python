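"""Read filtering, adapter trimming, and pair merging.

Mirrors the pre-processing applied to 2x300 bp amplicon libraries before
haplotype calling: drop reads shorter than 250 bases or with mean Phred
quality below 30 (a pair is dropped when either mate fails), trim
adapter read-through from 3' ends, and merge each overlapping pair into
one amplicon-spanning sequence, taking the higher-quality base wherever
the mates disagree.

The quality criterion is interpreted as a minimum *mean* Phred score per
read: a per-base floor of Q30 would discard nearly every 2x300 run,
which is incompatible with the retained-read counts such protocols
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simdata import reverse_complement

__all__ = [
    "ReadRecord",
    "MergedRead",
    "FilterStats",
    "read_fastq",
    "read_fastq_pairs",
    "trim_adapters",
    "filter_reads",
    "filter_pairs",
    "merge_pair",
    "merge_pairs",
]

DEFAULT_MIN_LENGTH = 250
DEFAULT_MIN_MEAN_QUALITY = 30.0
DEFAULT_MIN_OVERLAP = 30
DEFAULT_MAX_OVERLAP_MISMATCH = 0.1

_ADAPTER_MIN_MATCH = 8
_ADAPTER_MAX_MISMATCH = 1


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.id}: bases/qualities length mismatch")
        if self.qualities and not all(0 <= q <= 60 for q in self.qualities):
            raise ValueError(f"read {self.id}: Phred scores must lie in [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities)) if self.qualities else 0.0


@dataclass(frozen=True)
class MergedRead:
    """An amplicon-spanning consensus built from one read pair."""

    id: str
    bases: str
    qualities: tuple[int, ...]
    overlap_length: int


@dataclass
class FilterStats:
    """Bookkeeping for a filtering pass."""

    n_input: int = 0
    n_passed: int = 0
    n_failed_length: int = 0
    n_failed_quality: int = 0
    n_failed_mate: int = 0  # mate failed, this read was otherwise fine

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a Phred+33 FASTQ file as ReadRecords."""
    n_records = 0
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                n_records += 1
                yield ReadRecord(
                    id=title.split()[0],
                    bases=seq.upper(),
                    qualities=tuple(ord(c) - 33 for c in qual),
                )
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ in {path} after record {n_records} "
                f"(near byte offset {handle.tell()}): {exc}"
            ) from exc


def read_fastq_pairs(
    r1: str | Path, r2: str | Path
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Stream synchronized mate pairs from two FASTQ files."""
    for fwd, rev in zip(read_fastq(r1), read_fastq(r2), strict=True):
        yield fwd, rev


def trim_adapters(read: ReadRecord, adapter_sequences: Iterable[str]) -> ReadRecord:
    """Remove 3' read-through into an adapter.

    A read suffix matching a prefix of any adapter, with at least 8
    matching columns and at most 1 mismatch, is removed (the longest
    such suffix wins); qualities are truncated in lockstep. Reads with
    no adapter content are returned unchanged.
    """
    adapters = [a.upper() for a in adapter_sequences if a]
    if not adapters:
        raise ValueError("adapter list must be non-empty")
    bases = read.bases
    best_cut = len(bases)
    for adapter in adapters:
        # With <=1 mismatch over >=8 columns, one of the first two 4-mers
        # of the adapter must match exactly; scan those as seeds instead
        # of testing every start position.
        starts: set[int] = set()
        for k, seed in ((0, adapter[:4]), (4, adapter[4:8])):
            pos = bases.find(seed)
            while pos != -1:
                if pos - k >= 0:
                    starts.add(pos - k)
                pos = bases.find(seed, pos + 1)
        for start in sorted(starts):
            if start >= best_cut:
                break
            n = min(len(bases) - start, len(adapter))
            if n < _ADAPTER_MIN_MATCH:
                continue
            mismatches = sum(
                1 for x, y in zip(bases[start : start + n], adapter[:n]) if x != y
            )
            if mismatches <= _ADAPTER_MAX_MISMATCH:
                best_cut = start  # earliest admissible start = longest suffix
                break
    if best_cut == len(bases):
        return read
    return ReadRecord(read.id, bases[:best_cut], read.qualities[:best_cut])


def _passes(
    read: ReadRecord, min_length: int, min_mean_quality: float
) -> str | None:
    """Return the failure reason, or None when the read passes."""
    if len(read) < min_length:
        return "length"
    if read.mean_quality < min_mean_quality:
        return "quality"
    return None


def filter_reads(
    reads: Iterable[ReadRecord],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
    stats: FilterStats | None = None,
) -> Iterator[ReadRecord]:
    """Yield reads meeting the length and mean-quality thresholds."""
    if min_length < 0 or min_mean_quality < 0:
        raise ValueError("thresholds must be non-negative")
    stats = stats if stats is not None else FilterStats()
    for read in reads:
        stats.n_input += 1
        reason = _passes(read, min_length, min_mean_quality)
        if reason is None:
            stats.n_passed += 1
            yield read
        elif reason == "length":
            stats.n_failed_length += 1
        else:
            stats.n_failed_quality += 1


def filter_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
    stats: FilterStats | None = None,
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Yield pairs where both mates pass; drop the pair otherwise."""
    if min_length < 0 or min_mean_quality < 0:
        raise ValueError("thresholds must be non-negative")
    stats = stats if stats is not None else FilterStats()
    for fwd, rev in pairs:
        stats.n_input += 2
        r_f = _passes(fwd, min_length, min_mean_quality)
        r_r = _passes(rev, min_length, min_mean_quality)
        if r_f is None and r_r is None:
            stats.n_passed += 2
            yield fwd, rev
            continue
        for mine, other in ((r_f, r_r), (r_r, r_f)):
            if mine == "length":
                stats.n_failed_length += 1
            elif mine == "quality":
                stats.n_failed_quality += 1
            elif other is not None:
                stats.n_failed_mate += 1


def merge_pair(
    forward: ReadRecord,
    reverse: ReadRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_overlap_mismatch_fraction: float = DEFAULT_MAX_OVERLAP_MISMATCH,
) -> MergedRead | None:
    """Merge one pair into an amplicon-spanning consensus, or return None.

    The reverse read is taken in sequencer orientation and is
    reverse-complemented internally. Among candidate overlap offsets the
    one maximizing overlap length subject to the mismatch-fraction
    threshold wins; equal overlap lengths break ties by fewer
    mismatches, then by smaller offset. Within the overlap the
    higher-quality base is taken (forward wins ties) and the consensus
    quality is the max of the two.
    """
    if not forward.bases or not reverse.bases:
        raise ValueError("cannot merge an empty read")
    fwd = np.frombuffer(forward.bases.encode(), dtype="S1")
    rev = np.frombuffer(
        reverse_complement(reverse.bases).encode(), dtype="S1"
    )
    fq = np.asarray(forward.qualities, dtype=np.int16)
    rq = np.asarray(reverse.qualities[::-1], dtype=np.int16)
    m, n = len(fwd), len(rev)

    best: tuple[int, int, int] | None = None  # (overlap, mismatches, offset)
    for offset in range(0, m - min_overlap + 1):
        overlap = min(m - offset, n)
        if overlap < min_overlap:
            break
        if best is not None and overlap < best[0]:
            break  # overlaps only shrink from here; best cannot improve
        mism = int(np.count_nonzero(fwd[offset : offset + overlap] != rev[:overlap]))
        if mism > max_overlap_mismatch_fraction * overlap:
            continue
        cand = (overlap, mism, offset)
        if best is None or (cand[0], -cand[1], -cand[2]) > (
            best[0],
            -best[1],
            -best[2],
        ):
            best = cand
    if best is None:
        return None
    overlap, _, offset = best

    f_ov = fwd[offset : offset + overlap]
    r_ov = rev[:overlap]
    fq_ov = fq[offset : offset + overlap]
    rq_ov = rq[:overlap]
    take_rev = rq_ov > fq_ov  # forward base wins ties
    cons = np.where(take_rev, r_ov, f_ov)
    cons_q = np.maximum(fq_ov, rq_ov)

    bases = (
        fwd[:offset].tobytes().decode()
        + cons.tobytes().decode()
        + rev[overlap:].tobytes().decode()
    )
    quals = tuple(fq[:offset].tolist()) + tuple(cons_q.tolist()) + tuple(
        rq[overlap:].tolist()
    )
    return MergedRead(
        id=forward.id.removesuffix("/1"),
        bases=bases,
        qualities=quals,
        overlap_length=overlap,
    )


def merge_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_overlap_mismatch_fraction: float = DEFAULT_MAX_OVERLAP_MISMATCH,
) -> tuple[list[MergedRead], int]:
    """Merge a stream of pairs; returns (merged reads, n_failed).

    Identical (bases, qualities) pairs share one merge computation, which
    makes high-depth amplicon libraries cheap to process.
    """
    merged: list[MergedRead] = []
    n_failed = 0
    cache: dict[tuple, MergedRead | None] = {}
    for fwd, rev in pairs:
        key = (fwd.bases, fwd.qualities, rev.bases, rev.qualities)
        if key in cache:
            template = cache[key]
        else:
            template = merge_pair(
                fwd, rev, min_overlap, max_overlap_mismatch_fraction
            )
            cache[key] = template
        if template is None:
            n_failed += 1
        else:
            merged.append(
                MergedRead(
                    id=fwd.id.removesuffix("/1"),
                    bases=template.bases,
                    qualities=template.qualities,
                    overlap_length=template.overlap_length,
                )
            )
    return merged, n_failed
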