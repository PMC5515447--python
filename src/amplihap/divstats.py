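"""Diversity and reproducibility statistics for haplotype sets.

Covers the descriptive layer of an intragenomic-variation study:

* uncorrected p-distances between haplotype sequences (proportion of
  differing sites among compared sites, gapped columns excluded
  pairwise);
* within-group and between-group mean p-distances over labelled
  sequence sets, with unweighted grand means over the group-level
  values;
* two-sample t-tests (pooled and Welch unequal-variance forms) for
  comparing sets of group means;
* replicate reproducibility summaries: per-haplotype mean, sample
  standard deviation (n-1 denominator), and standard error of the mean
  across independent sequencing runs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .varmap import align_to_reference

__all__ = [
    "LabeledSequenceSet",
    "DistanceSummary",
    "TwoSampleTestResult",
    "p_distance",
    "group_mean_distances",
    "compare_groups_ttest",
    "replicate_summary",
    "values_grand_mean",
]


@dataclass(frozen=True)
class LabeledSequenceSet:
    """Sequences with one group label each (lineage or isolate)."""

    sequences: Mapping[str, str]
    group_of: Mapping[str, str]
    aligned: bool = False

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("need at least two sequences")
        missing = set(self.sequences) ^ set(self.group_of)
        if missing:
            raise ValueError(f"ids without matching group or sequence: {sorted(missing)}")
        if self.aligned:
            lengths = {len(s) for s in self.sequences.values()}
            if len(lengths) > 1:
                raise ValueError("aligned sequences must share one length")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_of.values():
            seen.setdefault(g)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return [i for i, g in self.group_of.items() if g == group]


@dataclass(frozen=True)
class DistanceSummary:
    """Within/between-group mean p-distances and their grand means."""

    within_group_mean: dict[str, float]  # NaN marks singleton groups
    between_group_mean: dict[tuple[str, str], float]
    grand_within_mean: float
    grand_between_mean: float

    def within_table(self) -> pd.DataFrame:
        rows = [
            {"Group": g, "Within Group Mean P-Distance": v}
            for g, v in self.within_group_mean.items()
        ]
        rows.append(
            {"Group": "Mean", "Within Group Mean P-Distance": self.grand_within_mean}
        )
        return pd.DataFrame(rows)

    def between_table(self) -> pd.DataFrame:
        rows = [
            {"Group 1": a, "Group 2": b, "Between Group Mean P-Distance": v}
            for (a, b), v in self.between_group_mean.items()
        ]
        rows.append(
            {
                "Group 1": "",
                "Group 2": "Mean",
                "Between Group Mean P-Distance": self.grand_between_mean,
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TwoSampleTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    variant: str  # "pooled" | "unequal-variance"


def p_distance(a: str, b: str, pairwise_aligned: bool = False) -> float:
    """Proportion of differing sites among compared sites.

    Columns with a gap (``-``) in either sequence are excluded (pairwise
    deletion). Unaligned inputs are first pairwise-aligned globally with
    the same affine-gap scheme used for read mapping.
    """
    if not pairwise_aligned:
        if a == b:
            return 0.0
        aln = align_to_reference(b, a)
        a, b = aln[0], aln[1]
    elif len(a) != len(b):
        raise ValueError("pre-aligned sequences must have equal length")
    compared = 0
    diff = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            diff += 1
    if compared == 0:
        raise ValueError("no comparable (gap-free) sites between sequences")
    return diff / compared


def group_mean_distances(seq_set: LabeledSequenceSet) -> DistanceSummary:
    """All-pairs within/between group mean p-distances.

    Within-group means average over all unordered pairs inside a group
    (NaN for singleton groups); between-group means average over all
    cross pairs of the two groups. Grand means are unweighted averages
    of the listed group-level values.
    """
    seqs = seq_set.sequences
    groups = seq_set.groups

    def pair_mean(ids_a: Sequence[str], ids_b: Sequence[str] | None) -> float:
        if ids_b is None:
            pairs = list(itertools.combinations(ids_a, 2))
        else:
            pairs = [(i, j) for i in ids_a for j in ids_b]
        vals = [
            p_distance(seqs[i], seqs[j], pairwise_aligned=seq_set.aligned)
            for i, j in pairs
        ]
        return float(np.mean(vals)) if vals else math.nan

    within = {g: pair_mean(seq_set.members(g), None) for g in groups}
    between = {
        (a, b): pair_mean(seq_set.members(a), seq_set.members(b))
        for a, b in itertools.combinations(groups, 2)
    }
    within_vals = [v for v in within.values() if not math.isnan(v)]
    between_vals = list(between.values())
    return DistanceSummary(
        within_group_mean=within,
        between_group_mean=between,
        grand_within_mean=float(np.mean(within_vals)) if within_vals else math.nan,
        grand_between_mean=float(np.mean(between_vals)) if between_vals else math.nan,
    )


def values_grand_mean(values: Sequence[float]) -> float:
    """Unweighted grand mean of group-level values (values-only mode)."""
    if not values:
        raise ValueError("no values given")
    return float(np.mean(values))


def compare_groups_ttest(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "unequal-variance",
) -> TwoSampleTestResult:
    """Two-sided two-sample t-test on two sets of real values.

    ``variant="pooled"`` is the classic equal-variance Student form;
    ``variant="unequal-variance"`` (default) is Welch's form, which is
    the one that reproduces published group-mean comparisons for this
    kind of data.
    """
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two values")
    if variant not in ("pooled", "unequal-variance"):
        raise ValueError(f"unknown test variant: {variant!r}")
    if (
        np.var(x, ddof=1) == 0
        and np.var(y, ddof=1) == 0
        and np.mean(x) == np.mean(y)
    ):
        raise ValueError("degenerate test: zero variance and equal means")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TwoSampleTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        variant=variant,
    )


def replicate_summary(
    frequencies_by_run: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """Per-haplotype mean, SD, and SE across replicate sequencing runs.

    SD uses the sample (n-1) denominator and SE = SD/sqrt(n); both are
    NaN when a haplotype was measured in a single run only.
    """
    rows = []
    for hap, values in frequencies_by_run.items():
        values = [float(v) for v in values]
        if not values:
            raise ValueError(f"haplotype {hap!r} has no values")
        n = len(values)
        mean = float(np.mean(values))
        if n >= 2:
            sd = float(np.std(values, ddof=1))
            se = sd / math.sqrt(n)
        else:
            sd = math.nan
            se = math.nan
        rows.append(
            {"Haplotype": hap, "n": n, "Mean": mean, "SD": sd, "SE": se}
        )
    return pd.DataFrame(rows).set_index("Haplotype")
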