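"""Segment-based genomic-scar scores of homologous-recombination deficiency.

Two scores are computed from allele-specific copy-number segments:

* **LST** (large-scale state transitions): per chromosome arm, segments
  shorter than 3 Mb are dropped and adjacent segments with identical
  allele-specific state are merged (iterated to a fixed point, gaps left by
  dropped segments are smoothed over); every adjacent pair of segments that
  both span >= 10 Mb and differ in (total, minor) copy-number state then
  counts one transition.  The score is the autosomal sum.

* **NtAI** (numerical telomeric allelic imbalance): the number of allelic-
  imbalance runs (total - minor != minor) that include the telomeric
  terminal segment of an arm, do not cross the centromere, and do not span
  the whole chromosome.  At most one count per arm; autosomal sum.

Sex chromosomes are excluded from both scores and from the fraction of
genome altered to avoid single-X ploidy ambiguity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .model import Arm, AssemblySpec, Segment, SegmentProfile, is_autosome

MIN_SEGMENT_BP = 3_000_000   # sub-3 Mb segments are noise-filtered
LST_SEGMENT_BP = 10_000_000  # both flanking segments of a transition must span >= 10 Mb


@dataclass(frozen=True)
class ScarScores:
    sample_id: str
    lst: int
    ntai: int
    fga: float


def _clip_to_arm(segments: list[Segment], arm: Arm) -> list[Segment]:
    out = []
    for s in segments:
        if s.chrom != arm.chrom or s.end < arm.start or s.start > arm.end:
            continue
        out.append(
            replace(s, start=max(s.start, arm.start), end=min(s.end, arm.end))
        )
    return sorted(out, key=lambda s: s.start)


def _smooth_arm(segments: list[Segment]) -> list[Segment]:
    """Drop sub-3 Mb segments and merge same-state neighbours, to a fixed point.

    Merging spans the gap left by dropped segments (start of the first member
    to end of the last), mirroring the smoothing step of the LST definition.
    """
    segs = list(segments)
    while True:
        kept = [s for s in segs if s.length >= MIN_SEGMENT_BP]
        merged: list[Segment] = []
        for s in kept:
            if merged and merged[-1].state == s.state:
                merged[-1] = replace(merged[-1], end=s.end)
            else:
                merged.append(s)
        if merged == segs:
            return merged
        segs = merged


def _check_chromosomes(profile: SegmentProfile, assembly: AssemblySpec) -> None:
    for s in profile.segments:
        if not assembly.has_chromosome(s.chrom):
            raise ValueError(f"segment on unknown chromosome {s.chrom}")


def compute_lst(profile: SegmentProfile, assembly: AssemblySpec) -> int:
    """Count large-scale state transitions over the autosomes."""
    profile = profile.canonicalize()
    _check_chromosomes(profile, assembly)
    if not profile.segments:
        warnings.warn("empty segment profile: LST score 0", stacklevel=2)
        return 0
    count = 0
    for arm in assembly.arms(autosomes_only=True):
        segs = _smooth_arm(_clip_to_arm(profile.segments, arm))
        for a, b in zip(segs, segs[1:]):
            if (
                a.length >= LST_SEGMENT_BP
                and b.length >= LST_SEGMENT_BP
                and a.state != b.state
            ):
                count += 1
    return count


def compute_ntai(profile: SegmentProfile, assembly: AssemblySpec) -> int:
    """Count telomeric allelic-imbalance events over the autosomes."""
    profile = profile.canonicalize()
    _check_chromosomes(profile, assembly)
    if not profile.segments:
        warnings.warn("empty segment profile: NtAI score 0", stacklevel=2)
        return 0
    arms_by_chrom: dict[str, list[Arm]] = {}
    for arm in assembly.arms(autosomes_only=True):
        arms_by_chrom.setdefault(arm.chrom, []).append(arm)
    count = 0
    for chrom, arms in arms_by_chrom.items():
        chrom_segs: dict[str, list[Segment]] = {}
        for arm in arms:
            chrom_segs[arm.name] = _smooth_arm(_clip_to_arm(profile.segments, arm))
        all_segs = [s for segs in chrom_segs.values() for s in segs]
        if not all_segs:
            continue
        # whole-chromosome imbalance is not a telomeric event
        if all(s.allelic_imbalance for s in all_segs):
            continue
        for arm_name, segs in chrom_segs.items():
            if not segs:
                continue
            telomeric = segs[0] if arm_name == "p" else segs[-1]
            if telomeric.allelic_imbalance:
                count += 1
    return count


def fraction_genome_altered(profile: SegmentProfile) -> float:
    """Fraction of the autosomal segmented genome away from the modal ploidy.

    The copy-number baseline is round(ploidy), so whole-genome-doubled
    samples are scored against their own modal state rather than against 2.
    """
    profile = profile.canonicalize()
    baseline = round(profile.ploidy)
    total = 0
    altered = 0
    for s in profile.segments:
        if not is_autosome(s.chrom):
            continue
        total += s.length
        if s.total_cn != baseline:
            altered += s.length
    if total == 0:
        raise ValueError("zero autosomal segmented length: FGA undefined")
    return altered / total


def score_sample(profile: SegmentProfile, assembly: AssemblySpec) -> ScarScores:
    """All scar scores for one sample."""
    return ScarScores(
        sample_id=profile.sample_id,
        lst=compute_lst(profile, assembly),
        ntai=compute_ntai(profile, assembly),
        fga=fraction_genome_altered(profile),
    )
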