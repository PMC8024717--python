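"""Small-deletion length statistics and microhomology-mediated deletion calls.

A deletion junction shows microhomology when the deleted sequence shares an
identical prefix with the 3' flank or an identical suffix with the 5' flank;
error-prone end joining under homologous-recombination deficiency leaves
such junctions.  A deletion whose entire sequence matches an adjacent block
(i.e. it sits inside a longer perfect repeat) is classified repeat-mediated
instead and never counted as microhomology.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import MutationRecord, normalize_chrom

SMALL_DELETION_MAX_BP = 50  # WES indel callers rarely emit larger events
MH_MIN_BP = 2               # a 1 bp junction match occurs by chance ~1/4 of the time


@dataclass(frozen=True)
class MicrohomologyCall:
    """Junction classification for one deletion.

    ``mh_length`` is None when the call is missing (flank unavailable) or the
    deletion is repeat-mediated.
    """

    mh_length: int | None
    repeat_mediated: bool = False
    missing: bool = False

    @property
    def is_mh(self) -> bool:
        return (
            not self.missing
            and not self.repeat_mediated
            and self.mh_length is not None
            and self.mh_length >= MH_MIN_BP
        )


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def detect_microhomology(
    deletion: MutationRecord, reference: Mapping[str, str]
) -> MicrohomologyCall:
    """Microhomology length at a deletion junction.

    MH length = max(longest common prefix of the deleted sequence with the
    3' flank, longest common suffix with the 5' flank), capped at deletion
    length - 1.  A full-length match on either side means the deletion lies
    inside a longer perfect repeat -> repeat-mediated.  Unavailable flanks
    (chromosome edge) yield a missing call, not zero.
    """
    if deletion.variant_class != "deletion":
        raise ValueError("detect_microhomology requires a deletion record")
    seq = {normalize_chrom(k): v for k, v in reference.items()}.get(deletion.chrom)
    if seq is None:
        raise ValueError(f"no reference sequence for chromosome {deletion.chrom}")
    deleted = deletion.deleted_bases.upper()
    length = len(deleted)
    start0 = deletion.deletion_start - 1  # 0-based index of first deleted base
    end0 = start0 + length
    if end0 > len(seq):
        raise ValueError(
            f"deletion {deletion.chrom}:{deletion.pos} extends past the reference"
        )
    observed = seq[start0:end0].upper()
    if observed != deleted:
        raise ValueError(
            f"deleted bases disagree with the reference at "
            f"{deletion.chrom}:{deletion.pos}: {observed} vs {deleted}"
        )
    three_flank = seq[end0 : end0 + length].upper()
    five_flank = seq[max(0, start0 - length) : start0].upper()
    if len(three_flank) < length or len(five_flank) < length:
        return MicrohomologyCall(mh_length=None, missing=True)
    prefix_match = _lcp(deleted, three_flank)
    suffix_match = _lcp(deleted[::-1], five_flank[::-1])
    if prefix_match >= length or suffix_match >= length:
        return MicrohomologyCall(mh_length=None, repeat_mediated=True)
    return MicrohomologyCall(mh_length=min(max(prefix_match, suffix_match), length - 1))


@dataclass
class IndelFeatureSet:
    """Per-sample small-deletion summary.

    Statistics are None when the sample has no small deletions (missing,
    not zero).  ``mh_calls`` is empty when no reference was supplied.
    """

    n_deletions: int
    mean_deletion_length: float | None
    median_deletion_length: float | None
    fraction_ge5bp: float | None
    n_mh_deletions: int
    mh_calls: list[MicrohomologyCall]
    sample_id: str | None = None


def deletion_length_stats(
    mutations: Sequence[MutationRecord],
    reference: Mapping[str, str] | None = None,
    mh_min: int = MH_MIN_BP,
    max_deletion_bp: int = SMALL_DELETION_MAX_BP,
    sample_id: str | None = None,
) -> IndelFeatureSet:
    """Summarize small-deletion lengths and microhomology for one sample.

    Input may mix variant classes; only deletions up to ``max_deletion_bp``
    deleted bases are used.  Microhomology is assessed only when a reference
    is supplied.
    """
    deletions = [
        m
        for m in mutations
        if m.variant_class == "deletion" and m.deletion_length <= max_deletion_bp
    ]
    if not deletions:
        return IndelFeatureSet(0, None, None, None, 0, [], sample_id=sample_id)
    lengths = [m.deletion_length for m in deletions]
    calls: list[MicrohomologyCall] = []
    n_mh = 0
    if reference is not None:
        for m in deletions:
            call = detect_microhomology(m, reference)
            calls.append(call)
            if (
                not call.missing
                and not call.repeat_mediated
                and call.mh_length is not None
                and call.mh_length >= mh_min
            ):
                n_mh += 1
    return IndelFeatureSet(
        n_deletions=len(deletions),
        mean_deletion_length=statistics.fmean(lengths),
        median_deletion_length=float(statistics.median(lengths)),
        fraction_ge5bp=sum(l >= 5 for l in lengths) / len(lengths),
        n_mh_deletions=n_mh,
        mh_calls=calls,
        sample_id=sample_id,
    )
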