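"""End-to-end orchestration: simulate, profile, stats.

Library-level entry points behind the command-line interface. Every run
writes a small JSON log recording the tool version, a hash of the
effective configuration, and the seeds used, so any report can be
regenerated byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .config import PipelineConfig
from .divstats import LabeledSequenceSet, group_mean_distances
from .haplo import (
    HaplotypeProfile,
    build_profile,
    call_haplotypes,
    dominant_haplotype,
    subsample_profiles,
    write_profile_tsv,
    write_retained_fasta,
)
from .phylo import attach_supports, bootstrap_supports, nj_tree, pdistance_matrix, write_newick
from .readprep import FilterStats, filter_pairs, merge_pairs, read_fastq_pairs, trim_adapters
from .simdata import (
    AmpliconReference,
    SimulatedLibrary,
    TruthMixture,
    read_reference_fasta,
    simulate_library,
    write_reference_fasta,
)
from .varmap import profile_reads, write_profiles_tsv

__all__ = ["run_simulate", "run_profile", "run_stats", "ProfileRunResult"]

logger = logging.getLogger(__name__)


def _write_manifest(out_dir: Path, name: str, config: PipelineConfig, extra: dict) -> None:
    manifest = {
        "tool": "amplihap",
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.as_dict(),
        **extra,
    }
    (out_dir / name).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_simulate(
    reference: AmpliconReference,
    mixture: TruthMixture,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> SimulatedLibrary:
    """Write a synthetic paired library, reference FASTA, and manifest."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    library = simulate_library(reference, mixture, out_dir, adapters=config.adapters)
    write_reference_fasta(reference, out_dir / "reference.fasta")
    _write_manifest(
        out_dir,
        "simulate_manifest.json",
        config,
        {
            "seed": mixture.seed,
            "n_pairs": mixture.n_pairs,
            "true_frequencies": list(mixture.frequencies),
            "pair_counts": list(library.pair_counts),
        },
    )
    return library


@dataclass
class ProfileRunResult:
    profile: HaplotypeProfile
    filter_stats: FilterStats
    n_merged: int
    n_merge_failed: int
    n_mapped: int
    n_unmapped: int


def run_profile(
    r1: str | Path,
    r2: str | Path,
    reference: AmpliconReference | str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    sample_id: str = "sample",
) -> ProfileRunResult:
    """Filter, trim, merge, map, subsample, and call haplotypes.

    Writes the haplotype report TSV, a FASTA of retained haplotypes,
    per-read variant profiles, and filter/merge/map statistics.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(reference, AmpliconReference):
        reference = read_reference_fasta(reference)

    stats = FilterStats()
    pairs = filter_pairs(
        read_fastq_pairs(r1, r2),
        min_length=config.min_length,
        min_mean_quality=config.min_mean_quality,
        stats=stats,
    )
    trimmed = (
        (
            trim_adapters(fwd, config.adapters),
            trim_adapters(rev, config.adapters[::-1]),
        )
        for fwd, rev in pairs
    )
    merged, n_failed = merge_pairs(
        trimmed,
        min_overlap=config.min_overlap,
        max_overlap_mismatch_fraction=config.max_overlap_mismatch_fraction,
    )
    if not merged:
        raise RuntimeError(
            "pipeline failure: no read pairs could be merged — check that the "
            "mates overlap and the quality/length filters are appropriate"
        )

    profiles = profile_reads(
        ((m.id, m.bases) for m in merged),
        reference,
        max_divergence=config.max_divergence,
    )
    n_mapped = sum(p.mapped for p in profiles)
    write_profiles_tsv(profiles, out_dir / f"{sample_id}_profiles.tsv")

    subsets = subsample_profiles(
        profiles,
        subsample_size=config.subsample_size,
        n_subsamples=config.n_subsamples,
        seed=config.seed,
    )
    calls = [call_haplotypes(subset) for subset in subsets]
    profile = build_profile(
        calls,
        threshold=config.threshold,
        reference=reference,
        sample_id=sample_id,
        subsample_size=config.subsample_size,
        seed=config.seed,
    )
    write_profile_tsv(profile, out_dir / f"{sample_id}_haplotypes.tsv")
    write_retained_fasta(profile, out_dir / f"{sample_id}_haplotypes.fasta")

    result = ProfileRunResult(
        profile=profile,
        filter_stats=stats,
        n_merged=len(merged),
        n_merge_failed=n_failed,
        n_mapped=n_mapped,
        n_unmapped=len(profiles) - n_mapped,
    )
    top, co_dom = dominant_haplotype(profile, config.codominance_margin)
    _write_manifest(
        out_dir,
        f"{sample_id}_profile_manifest.json",
        config,
        {
            "sample_id": sample_id,
            "seed": config.seed,
            "filter_stats": stats.as_dict(),
            "n_merged": len(merged),
            "n_merge_failed": n_failed,
            "n_mapped": n_mapped,
            "n_unmapped": len(profiles) - n_mapped,
            "n_retained_haplotypes": len(profile.haplotypes),
            "dominant_haplotype": top.haplotype_id,
            "co_dominant": co_dom,
            "background_frequency": profile.background_frequency,
        },
    )
    return result


def run_stats(
    sequences: Mapping[str, str],
    group_of: Mapping[str, str],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    aligned: bool = False,
    build_tree: bool = True,
):
    """Distance summaries and (optionally) a bootstrapped NJ tree.

    Sequence ids present in the grouping but absent from the FASTA (or
    vice versa) raise a reference error listing the offending ids.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = set(group_of) - set(sequences)
    extra = set(sequences) - set(group_of)
    if missing or extra:
        raise KeyError(
            f"grouping/sequence id mismatch: missing from FASTA {sorted(missing)}, "
            f"missing from grouping {sorted(extra)}"
        )
    seq_set = LabeledSequenceSet(sequences, group_of, aligned=aligned)
    summary = group_mean_distances(seq_set)
    summary.within_table().to_csv(out_dir / "within_group_pdistance.tsv", sep="\t", index=False)
    summary.between_table().to_csv(out_dir / "between_group_pdistance.tsv", sep="\t", index=False)

    tree = None
    if build_tree and len(sequences) >= 3:
        matrix = pdistance_matrix(sequences, aligned=aligned)
        tree = nj_tree(matrix)
        if aligned:
            supports = bootstrap_supports(
                sequences, n_replicates=config.bootstrap_replicates, seed=config.seed
            )
            attach_supports(tree, supports)
        write_newick(tree, out_dir / "nj_tree.nwk")
    _write_manifest(
        out_dir,
        "stats_manifest.json",
        config,
        {
            "seed": config.seed,
            "n_sequences": len(sequences),
            "groups": seq_set.groups,
            "grand_within_mean": summary.grand_within_mean,
            "grand_between_mean": summary.grand_between_mean,
        },
    )
    return summary, tree
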