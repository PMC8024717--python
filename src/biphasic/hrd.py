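"""Per-sample HRD feature flags and composite call; MSI and hypermutation gates.

The composite HRD call is keyed to a dominant substitution signature 3, with
the genomic-scar and deletion flags reported alongside as supporting
evidence; an optional any-k-of-n voting mode is exposed for sensitivity
analyses.  Flag boundaries: LST high at >= 15, NtAI high strictly > 16,
long deletions at mean length >= 5 bp, MSI high at score >= 3.5, and
hypermutation at >= 1000 somatic mutations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .indels import IndelFeatureSet
from .model import RunConfig
from .scars import ScarScores
from .signatures import SignatureExposure, dominant_signature_group


@dataclass(frozen=True)
class HrdFeatureSet:
    """Flags plus the raw values they were derived from (auditability)."""

    sample_id: str
    lst: int
    ntai: int
    mean_deletion_length: float | None
    n_mh_deletions: int
    lst_high: bool
    ntai_high: bool
    long_deletions: bool
    mh_deletions_present: bool
    dominant_group: str  # HRD | aging | other | insufficient
    hrd_call: bool


def call_hrd_features(
    scars: ScarScores,
    indels: IndelFeatureSet,
    exposure: SignatureExposure,
    config: RunConfig | None = None,
    sample_id: str | None = None,
    composite_k_of_n: int | None = None,
) -> HrdFeatureSet:
    """Assemble the per-sample HRD feature set.

    ``composite_k_of_n``: when given, the HRD call is instead "at least k of
    the 4 supporting flags true" (sensitivity-analysis mode); by default the
    call is dominant-signature-3.
    """
    config = config or RunConfig()
    sid = sample_id or scars.sample_id
    for other in (indels.sample_id, exposure.sample_id):
        if other is not None and other != sid:
            raise ValueError(
                f"sample-id mismatch across HRD inputs: {sid} vs {other}"
            )
    lst_high = scars.lst >= config.lst_high_cutoff
    ntai_high = scars.ntai > config.ntai_support_cutoff
    long_dels = (
        indels.mean_deletion_length is not None
        and indels.mean_deletion_length >= config.deletion_length_cutoff
    )
    mh_present = indels.n_mh_deletions >= 1
    group = dominant_signature_group(exposure)
    if composite_k_of_n is None:
        hrd_call = group == "HRD"
    else:
        hrd_call = sum([lst_high, ntai_high, long_dels, mh_present]) >= composite_k_of_n
    return HrdFeatureSet(
        sample_id=sid,
        lst=scars.lst,
        ntai=scars.ntai,
        mean_deletion_length=indels.mean_deletion_length,
        n_mh_deletions=indels.n_mh_deletions,
        lst_high=lst_high,
        ntai_high=ntai_high,
        long_deletions=long_dels,
        mh_deletions_present=mh_present,
        dominant_group=group,
        hrd_call=hrd_call,
    )


def classify_msi(msi_score: float, config: RunConfig | None = None) -> bool:
    """MSI-high iff the precomputed instability score is >= 3.5."""
    config = config or RunConfig()
    if msi_score < 0:
        raise ValueError(f"MSI score must be >= 0, got {msi_score}")
    return msi_score >= config.msi_high_cutoff


def flag_hypermutated(
    total_mutation_count: int, config: RunConfig | None = None
) -> bool:
    """Hypermutated iff the sample carries >= 1000 somatic mutations."""
    config = config or RunConfig()
    if total_mutation_count < 0:
        raise ValueError("mutation count must be >= 0")
    return total_mutation_count >= config.hypermutation_cutoff
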