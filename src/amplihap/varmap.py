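"""Alignment of merged amplicon reads to the reference and variant extraction.

Each merged read is globally aligned to the single amplicon reference
under affine-gap scoring (match +1, mismatch -2, gap open -5, gap
extend -2; a gap of length k costs 5 + 2(k-1)). From the alignment a
canonical variant profile is extracted:

* runs of mismatches at consecutive reference sites collapse into one
  substitution event, so adjacent SNVs become a single DNP/MNV;
* insertions and deletions are left-aligned to their lowest-position
  equivalent placement (a deterministic convention replacing the
  otherwise arbitrary placement of indels in repeats);
* reads whose divergence from the reference exceeds a threshold, or
  whose alignment leaves long terminal gaps, are flagged unmapped and
  carry no events.

Coordinates are 1-based reference sites; insertions anchor to the
preceding site.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align

from .simdata import AmpliconReference
from .variants import (
    VariantEvent,
    deletion,
    format_events,
    insertion,
    sort_events,
    substitution,
)

__all__ = [
    "VariantProfile",
    "make_aligner",
    "align_to_reference",
    "extract_variant_profile",
    "profile_read",
    "profile_reads",
    "write_profiles_tsv",
]

DEFAULT_MAX_DIVERGENCE = 0.25
MAX_TERMINAL_GAP = 5

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN_SCORE = -5
GAP_EXTEND_SCORE = -2


@dataclass(frozen=True)
class VariantProfile:
    """The canonical event set of one read against the reference."""

    read_id: str
    events: tuple[VariantEvent, ...]
    mapped: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", sort_events(self.events))
        if not self.mapped and self.events:
            raise ValueError("unmapped profiles carry no events")


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=MATCH_SCORE,
        mismatch_score=MISMATCH_SCORE,
        open_gap_score=GAP_OPEN_SCORE,
        extend_gap_score=GAP_EXTEND_SCORE,
    )
    return aligner


_ALIGNER = make_aligner()


def align_to_reference(
    read: str, reference: AmpliconReference | str
) -> Align.Alignment:
    """Optimal global alignment of a read to the reference.

    The first optimal alignment of biopython's deterministic traceback
    order is returned, so identical inputs always yield the identical
    alignment.
    """
    ref_seq = reference.sequence if isinstance(reference, AmpliconReference) else reference
    if not read or not ref_seq:
        raise ValueError("cannot align empty sequences")
    return _ALIGNER.align(ref_seq, read)[0]


def _left_align_deletion(ref: str, pos: int, allele: str) -> tuple[int, str]:
    """Shift a deletion to its lowest equivalent 1-based start position."""
    k = len(allele)
    while pos > 1 and ref[pos - 2] == ref[pos + k - 2]:
        pos -= 1
    return pos, ref[pos - 1 : pos - 1 + k]

def _left_align_insertion(ref: str, anchor: int, allele: str) -> tuple[int, str]:
    """Shift an insertion to its lowest equivalent anchor site."""
    while anchor > 0 and ref[anchor - 1] == allele[-1]:
        allele = allele[-1] + allele[:-1]
        anchor -= 1
    return anchor, allele


def extract_variant_profile(
    alignment: Align.Alignment,
    read_id: str = "",
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
) -> VariantProfile:
    """Collapse an alignment into a canonical, ordered variant-event set."""
    ref = str(alignment.sequences[0])
    read = str(alignment.sequences[1])
    ref_aln, read_aln = alignment[0], alignment[1]

    events: list[VariantEvent] = []
    n_mismatch = 0
    n_gap_cols = 0
    ref_pos = 0  # 1-based position of the last consumed reference base
    run_start = 0
    run_ref: list[str] = []
    run_alt: list[str] = []
    pending_ins: list[str] = []
    pending_ins_anchor = -1
    pending_del: list[str] = []
    pending_del_start = -1
    lead_gap = 0
    first_col = True

    def flush_sub() -> None:
        nonlocal run_ref, run_alt
        if run_ref:
            events.append(
                substitution(run_start, "".join(run_ref), "".join(run_alt))
            )
            run_ref, run_alt = [], []

    def flush_indels() -> None:
        nonlocal pending_ins, pending_del, pending_ins_anchor, pending_del_start
        if pending_del:
            pos, allele = _left_align_deletion(
                ref, pending_del_start, "".join(pending_del)
            )
            events.append(deletion(pos, allele))
            pending_del = []
        if pending_ins:
            anchor, allele = _left_align_insertion(
                ref, pending_ins_anchor, "".join(pending_ins)
            )
            events.append(insertion(anchor, allele))
            pending_ins = []

    for a, b in zip(ref_aln, read_aln):
        if a == "-" and b == "-":  # pragma: no cover - aligner never emits
            continue
        if a == "-":
            n_gap_cols += 1
            if first_col:
                lead_gap += 1
            flush_sub()
            if not pending_ins:
                pending_ins_anchor = ref_pos
            pending_ins.append(b)
            continue
        if b == "-":
            n_gap_cols += 1
            if first_col:
                lead_gap += 1
            ref_pos += 1
            flush_sub()
            if not pending_del:
                pending_del_start = ref_pos
            pending_del.append(a)
            continue
        first_col = False
        ref_pos += 1
        flush_indels()
        if a == b:
            flush_sub()
        else:
            n_mismatch += 1
            if not run_ref:
                run_start = ref_pos
            run_ref.append(a)
            run_alt.append(b)
    flush_sub()
    flush_indels()

    # trailing-gap length: columns of the final run that are gaps
    tail_gap = 0
    for a, b in zip(reversed(ref_aln), reversed(read_aln)):
        if a == "-" or b == "-":
            tail_gap += 1
        else:
            break

    divergence = (n_mismatch + n_gap_cols) / len(ref)
    mapped = (
        divergence <= max_divergence
        and lead_gap <= MAX_TERMINAL_GAP
        and tail_gap <= MAX_TERMINAL_GAP
    )
    return VariantProfile(
        read_id=read_id,
        events=tuple(events) if mapped else (),
        mapped=mapped,
    )


def profile_read(
    read: str,
    reference: AmpliconReference | str,
    read_id: str = "",
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
) -> VariantProfile:
    """Align one read and extract its canonical variant profile."""
    alignment = align_to_reference(read, reference)
    return extract_variant_profile(alignment, read_id, max_divergence)


def profile_reads(
    reads: Iterable[tuple[str, str]],
    reference: AmpliconReference | str,
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
) -> list[VariantProfile]:
    """Profile many (read_id, sequence) pairs.

    Profiles are a pure function of the sequence, so identical sequences
    share one alignment; amplicon libraries are dominated by a handful
    of distinct sequences, which makes this pass cheap at depth.
    """
    ref_seq = reference.sequence if isinstance(reference, AmpliconReference) else reference
    cache: dict[str, tuple[tuple[VariantEvent, ...], bool]] = {}
    profiles: list[VariantProfile] = []
    for read_id, seq in reads:
        hit = cache.get(seq)
        if hit is None:
            prof = profile_read(seq, ref_seq, read_id, max_divergence)
            hit = (prof.events, prof.mapped)
            cache[seq] = hit
        profiles.append(VariantProfile(read_id=read_id, events=hit[0], mapped=hit[1]))
    return profiles


def write_profiles_tsv(profiles: Sequence[VariantProfile], path) -> None:
    """Export profiles as TSV: read_id, compact event list, mapped flag."""
    with open(path, "w") as out:
        out.write("read_id\tevents\tmapped\n")
        for p in profiles:
            out.write(f"{p.read_id}\t{format_events(p.events)}\t{int(p.mapped)}\n")
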