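"""Haplotype calling by repeated random subsampling.

The estimation procedure at the heart of the package:

1. all merged reads are mapped once and their variant profiles kept;
2. several replicate subsamples (default five of 10,000 reads) are
   drawn uniformly without replacement from the mapped profiles;
3. within each subsample reads are grouped by their canonical variant
   set and every group's frequency (group size / subsample size) is
   recorded;
4. frequencies are averaged across subsamples; individual variant
   events whose averaged site frequency reaches the reporting threshold
   (default 1%, inclusive) are the *demonstrable* variants;
5. each read is then characterized by the subset of its variants that
   are demonstrable — a haplotype is a unique set of demonstrable
   variants — and haplotype frequencies are re-averaged over the same
   subsamples. Haplotypes at or above the threshold are retained and
   labelled H1, H2, ... by descending averaged frequency; sub-threshold
   combinations are pooled into a single background bucket.

Step 5 is what makes the estimator robust to sequencing error: a read
carrying a private sub-threshold miscall still counts toward the
haplotype defined by its demonstrable variants, so retained frequencies
are unbiased and sum to ~1, while spurious variants never reach the
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .simdata import AmpliconReference
from .variants import VariantEvent, apply_variants, format_events, sort_events
from .varmap import VariantProfile

__all__ = [
    "HaplotypeCall",
    "HaplotypeProfile",
    "subsample_profiles",
    "call_haplotypes",
    "build_profile",
    "dominant_haplotype",
    "write_profile_tsv",
    "write_retained_fasta",
]

logger = logging.getLogger(__name__)

DEFAULT_SUBSAMPLE_SIZE = 10_000
DEFAULT_N_SUBSAMPLES = 5
DEFAULT_THRESHOLD = 0.01
DEFAULT_CODOMINANCE_MARGIN = 0.05

EventKey = tuple[VariantEvent, ...]


@dataclass(frozen=True)
class HaplotypeCall:
    """One retained haplotype: label, defining variants, realized sequence."""

    haplotype_id: str
    events: EventKey
    sequence: str | None = None


@dataclass
class HaplotypeProfile:
    """Averaged haplotype frequency spectrum of one sample."""

    sample_id: str
    n_subsamples: int
    subsample_size: int
    seed: int
    threshold: float
    haplotypes: list[HaplotypeCall]
    per_subsample_frequencies: dict[EventKey, list[float]]
    averaged_frequency: dict[EventKey, float]
    retained: dict[EventKey, bool]
    site_frequencies: dict[VariantEvent, float]
    background_frequency: float

    def retained_calls(self) -> list[HaplotypeCall]:
        return list(self.haplotypes)

    def frequency_of(self, haplotype_id: str) -> float:
        for call in self.haplotypes:
            if call.haplotype_id == haplotype_id:
                return self.averaged_frequency[call.events]
        raise KeyError(haplotype_id)


def subsample_profiles(
    profiles: Sequence[VariantProfile],
    subsample_size: int = DEFAULT_SUBSAMPLE_SIZE,
    n_subsamples: int = DEFAULT_N_SUBSAMPLES,
    seed: int = 0,
) -> list[list[VariantProfile]]:
    """Draw replicate subsets of mapped profiles, without replacement.

    Replicate i uses the derived seed ``seed + i``, so subsets are
    independent across replicates yet exactly repeatable. When fewer
    than ``subsample_size`` mapped profiles exist the full set is used
    once per replicate and a warning is logged.
    """
    mapped = [p for p in profiles if p.mapped]
    if not mapped:
        raise ValueError("no mapped profiles to subsample")
    if subsample_size < 1 or n_subsamples < 1:
        raise ValueError("subsample_size and n_subsamples must be >= 1")
    subsets: list[list[VariantProfile]] = []
    if len(mapped) < subsample_size:
        logger.warning(
            "only %d mapped reads available (< subsample size %d); "
            "using the full set in every replicate",
            len(mapped),
            subsample_size,
        )
        return [list(mapped) for _ in range(n_subsamples)]
    for i in range(n_subsamples):
        rng = np.random.default_rng(seed + i)
        idx = rng.choice(len(mapped), size=subsample_size, replace=False)
        subsets.append([mapped[j] for j in idx])
    return subsets


def call_haplotypes(subset: Sequence[VariantProfile]) -> dict[EventKey, float]:
    """Group a subsample by canonical event set; frequency = share of reads.

    Every observed group is reported; no threshold is applied here.
    """
    if not subset:
        raise ValueError("cannot call haplotypes on an empty subsample")
    counts: dict[EventKey, int] = {}
    for prof in subset:
        key = prof.events
        counts[key] = counts.get(key, 0) + 1
    total = len(subset)
    return {key: n / total for key, n in counts.items()}


def _event_frequencies(
    calls: Mapping[EventKey, float]
) -> dict[VariantEvent, float]:
    """Per-variant site frequency: total share of reads carrying the event."""
    freqs: dict[VariantEvent, float] = {}
    for key, f in calls.items():
        for ev in key:
            freqs[ev] = freqs.get(ev, 0.0) + f
    return freqs


def build_profile(
    per_subsample_calls: Sequence[Mapping[EventKey, float]],
    threshold: float = DEFAULT_THRESHOLD,
    reference: AmpliconReference | None = None,
    sample_id: str = "sample",
    subsample_size: int = DEFAULT_SUBSAMPLE_SIZE,
    seed: int = 0,
) -> HaplotypeProfile:
    """Average replicate haplotype calls and apply the reporting threshold.

    The threshold (inclusive >=) is applied to *averaged* frequencies,
    first to individual variant events and then to haplotypes defined as
    unique sets of demonstrable events. A haplotype absent from a
    subsample counts as frequency 0 there.
    """
    if not per_subsample_calls:
        raise ValueError("need at least one subsample")
    n_sub = len(per_subsample_calls)

    # averaged per-event site frequencies -> demonstrable variants
    event_avg: dict[VariantEvent, float] = {}
    for calls in per_subsample_calls:
        for ev, f in _event_frequencies(calls).items():
            event_avg[ev] = event_avg.get(ev, 0.0) + f / n_sub
    demonstrable = {ev for ev, f in event_avg.items() if f >= threshold}

    # project each raw event set onto its demonstrable subset and
    # re-aggregate frequencies per subsample
    projected: dict[EventKey, list[float]] = {}
    for i, calls in enumerate(per_subsample_calls):
        for key, f in calls.items():
            pkey = sort_events(ev for ev in key if ev in demonstrable)
            per = projected.setdefault(pkey, [0.0] * n_sub)
            per[i] += f
    averaged = {key: float(np.mean(per)) for key, per in projected.items()}

    retained = {key: f >= threshold for key, f in averaged.items()}
    background = sum(f for key, f in averaged.items() if not retained[key])

    order = sorted(
        (key for key, keep in retained.items() if keep),
        key=lambda key: (-averaged[key], tuple(ev.sort_key() for ev in key)),
    )
    haplotypes = [
        HaplotypeCall(
            haplotype_id=f"H{rank + 1}",
            events=key,
            sequence=apply_variants(reference.sequence, key) if reference else None,
        )
        for rank, key in enumerate(order)
    ]
    return HaplotypeProfile(
        sample_id=sample_id,
        n_subsamples=n_sub,
        subsample_size=subsample_size,
        seed=seed,
        threshold=threshold,
        haplotypes=haplotypes,
        per_subsample_frequencies=projected,
        averaged_frequency=averaged,
        retained=retained,
        site_frequencies=event_avg,
        background_frequency=background,
    )


def dominant_haplotype(
    profile: HaplotypeProfile,
    codominance_margin: float = DEFAULT_CODOMINANCE_MARGIN,
) -> tuple[HaplotypeCall, bool]:
    """The retained haplotype with the highest averaged frequency.

    Two haplotypes are co-dominant when at least two are retained and
    the top two averaged frequencies differ by less than the margin.
    """
    calls = profile.retained_calls()
    if not calls:
        raise ValueError("profile has no retained haplotypes")
    top = calls[0]
    co_dominant = False
    if len(calls) >= 2:
        f1 = profile.averaged_frequency[calls[0].events]
        f2 = profile.averaged_frequency[calls[1].events]
        co_dominant = abs(f1 - f2) < codominance_margin
    return top, co_dominant


def write_profile_tsv(profile: HaplotypeProfile, path: str | Path) -> None:
    """Haplotype report: per-replicate frequencies, mean, defining variants."""
    with open(path, "w") as out:
        reps = "\t".join(f"R{i + 1}" for i in range(profile.n_subsamples))
        out.write(f"Haplotype\tVariants\t{reps}\tMean\n")
        for call in profile.haplotypes:
            per = profile.per_subsample_frequencies[call.events]
            per_str = "\t".join(f"{f:.6f}" for f in per)
            out.write(
                f"{call.haplotype_id}\t{format_events(call.events)}\t"
                f"{per_str}\t{profile.averaged_frequency[call.events]:.6f}\n"
            )
        zeros = "\t".join("-" for _ in range(profile.n_subsamples))
        out.write(
            f"background\t.\t{zeros}\t{profile.background_frequency:.6f}\n"
        )


def write_retained_fasta(profile: HaplotypeProfile, path: str | Path) -> None:
    """Realized sequences of retained haplotypes, one FASTA record each."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for call in profile.haplotypes:
        if call.sequence is None:
            raise ValueError(
                "profile was built without a reference; sequences unavailable"
            )
        records.append(
            SeqRecord(
                Seq(call.sequence),
                id=f"{profile.sample_id}_{call.haplotype_id}",
                description=format_events(call.events),
            )
        )
    SeqIO.write(records, str(path), "fasta")
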