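"""Variant events on an amplicon reference.

A haplotype of a multi-copy amplicon is identified by its set of
polymorphisms relative to a single reference sequence: substitutions of
length >= 1 (length-2 substitutions are the classic DNP/MNV), insertions,
and deletions. Coordinates are 1-based reference sites, matching the site
numbering used when reporting intragenomic variants ("a T at site 61",
"an inserted C after site 224"). An insertion is anchored to the site
*after which* its bases are inserted (anchor 0 = before the first site).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "VariantEvent",
    "substitution",
    "insertion",
    "deletion",
    "sort_events",
    "check_compatible",
    "apply_variants",
    "format_event",
    "format_events",
    "parse_event",
    "parse_events",
    "VariantConflictError",
]

_KINDS = ("substitution", "insertion", "deletion")
_KIND_ORDER = {"substitution": 0, "deletion": 1, "insertion": 2}


class VariantConflictError(ValueError):
    """Raised when variant events overlap on the reference."""


@dataclass(frozen=True, order=False)
class VariantEvent:
    """One polymorphism at a 1-based reference site.

    kind
        ``"substitution"`` (ref and alt alleles of equal length >= 1),
        ``"insertion"`` (empty ref allele, alt bases inserted after
        ``position``), or ``"deletion"`` (ref bases removed starting at
        ``position``, empty alt allele).
    """

    kind: str
    position: int
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown variant kind: {self.kind!r}")
        if self.kind == "substitution":
            if not self.ref_allele or len(self.ref_allele) != len(self.alt_allele):
                raise ValueError(
                    "substitution requires equal-length non-empty alleles"
                )
            if self.position < 1:
                raise ValueError("substitution position must be >= 1")
        elif self.kind == "insertion":
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion carries alt bases only")
            if self.position < 0:
                raise ValueError("insertion anchor must be >= 0")
        else:  # deletion
            if self.alt_allele or not self.ref_allele:
                raise ValueError("deletion carries ref bases only")
            if self.position < 1:
                raise ValueError("deletion position must be >= 1")

    @property
    def span(self) -> tuple[int, int]:
        """Closed interval of reference sites consumed by this event.

        Insertions consume no site; they are represented as the empty
        interval just after the anchor.
        """
        if self.kind == "insertion":
            return (self.position + 1, self.position)
        return (self.position, self.position + len(self.ref_allele) - 1)

    def sort_key(self) -> tuple[int, int, str, str]:
        return (self.position, _KIND_ORDER[self.kind], self.ref_allele, self.alt_allele)


def substitution(position: int, ref: str, alt: str) -> VariantEvent:
    return VariantEvent("substitution", position, ref, alt)


def insertion(position: int, alt: str) -> VariantEvent:
    return VariantEvent("insertion", position, "", alt)


def deletion(position: int, ref: str) -> VariantEvent:
    return VariantEvent("deletion", position, ref, "")


def sort_events(events: Iterable[VariantEvent]) -> tuple[VariantEvent, ...]:
    """Canonical ordering: by position, then substitution < deletion < insertion."""
    return tuple(sorted(events, key=VariantEvent.sort_key))


def check_compatible(
    events: Sequence[VariantEvent], reference_length: int | None = None
) -> None:
    """Validate that events are pairwise non-overlapping and in bounds.

    Two substitution/deletion events conflict when their reference
    intervals intersect; an insertion conflicts with a multi-site event
    whose interval straddles the insertion point, and two insertions at
    the same anchor conflict.
    """
    ordered = sort_events(events)
    if reference_length is not None:
        for ev in ordered:
            lo, hi = ev.span
            if ev.kind == "insertion":
                if ev.position > reference_length:
                    raise IndexError(
                        f"insertion anchor {ev.position} beyond reference "
                        f"length {reference_length}"
                    )
            elif hi > reference_length:
                raise IndexError(
                    f"event at site {ev.position} extends past reference "
                    f"length {reference_length}"
                )
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.kind == "insertion" and cur.kind == "insertion":
            if prev.position == cur.position:
                raise VariantConflictError(
                    f"two insertions anchored at site {prev.position}"
                )
            continue
        prev_hi = prev.span[1]
        cur_lo = cur.span[0]
        if cur.kind == "insertion":
            # insertion inside a consumed interval: anchor strictly
            # within [lo, hi) of a substitution/deletion
            if prev.span[0] <= cur.position < prev_hi + 1 and cur.position < prev_hi:
                raise VariantConflictError(
                    f"insertion at {cur.position} inside event at {prev.position}"
                )
            continue
        if prev.kind == "insertion":
            continue
        if cur_lo <= prev_hi:
            raise VariantConflictError(
                f"events at sites {prev.position} and {cur.position} overlap"
            )


def apply_variants(reference: str, events: Iterable[VariantEvent]) -> str:
    """Realize the full-length sequence of a haplotype.

    The empty event set returns the reference itself. Events must be
    non-overlapping and within bounds; substitution ref alleles must
    match the reference.
    """
    ordered = sort_events(events)
    check_compatible(ordered, len(reference))
    out: list[str] = []
    cursor = 0  # 0-based index into reference of next unconsumed base
    for ev in ordered:
        if ev.kind == "insertion":
            out.append(reference[cursor : ev.position])
            cursor = ev.position
            out.append(ev.alt_allele)
            continue
        start = ev.position - 1
        out.append(reference[cursor:start])
        ref_slice = reference[start : start + len(ev.ref_allele)]
        if ref_slice != ev.ref_allele:
            raise ValueError(
                f"reference mismatch at site {ev.position}: "
                f"expected {ev.ref_allele!r}, found {ref_slice!r}"
            )
        if ev.kind == "substitution":
            out.append(ev.alt_allele)
        cursor = start + len(ev.ref_allele)
    out.append(reference[cursor:])
    return "".join(out)


# -- compact text form, used in TSV reports ---------------------------------

def format_event(ev: VariantEvent) -> str:
    if ev.kind == "substitution":
        return f"{ev.position}{ev.ref_allele}>{ev.alt_allele}"
    if ev.kind == "insertion":
        return f"{ev.position}+{ev.alt_allele}"
    return f"{ev.position}-{ev.ref_allele}"


def format_events(events: Iterable[VariantEvent]) -> str:
    ordered = sort_events(events)
    if not ordered:
        return "."
    return ";".join(format_event(ev) for ev in ordered)


def parse_event(text: str) -> VariantEvent:
    text = text.strip()
    i = 0
    while i < len(text) and text[i].isdigit():
        i += 1
    if i == 0:
        raise ValueError(f"cannot parse variant {text!r}")
    pos = int(text[:i])
    rest = text[i:]
    if rest.startswith("+"):
        return insertion(pos, rest[1:])
    if rest.startswith("-"):
        return deletion(pos, rest[1:])
    if ">" in rest:
        ref, alt = rest.split(">", 1)
        return substitution(pos, ref, alt)
    raise ValueError(f"cannot parse variant {text!r}")


def parse_events(text: str) -> tuple[VariantEvent, ...]:
    text = text.strip()
    if not text or text == ".":
        return ()
    return sort_events(parse_event(part) for part in text.split(";"))
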