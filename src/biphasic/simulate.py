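"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline has a generator here that emits
inputs with the statistical structure the stage assumes, together with a
:class:`SimTruth` record of the planted values, so recovery can be scored
without re-simulation.  All generators are bit-reproducible for a fixed
seed.

What is emulated: mutation catalogs drawn from known signature mixtures
and placed at matching trinucleotide contexts; deletion sets with planted
lengths and junction microhomology; allele-specific segment profiles with
a planted number of large-scale transitions and telomeric allelic-
imbalance events (plus sub-3 Mb noise segments that must not move either
score); and paired-component read counts generated from a planted clone
tree with beta-binomial noise matched to the clustering model's precision.
Not emulated: germline variation, chromatin/replication-timing covariates
of mutation placement, or raw reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decompose import expected_vaf
from .indels import detect_microhomology
from .model import AssemblySpec, Arm, MutationRecord, Segment, SegmentProfile
from .signatures import (
    BASES,
    CHANNELS,
    COMPLEMENT,
    channel_of,
    revcomp,
)

BALANCED_A = (2, 1)   # baseline state (total - minor == minor after fold? no: 2-1=1=1 yes)
BALANCED_B = (4, 2)   # alternate balanced state for LST planting
AI_STATE = (3, 1)     # allelic-imbalance state for NtAI planting
NOISE_STATE = (5, 2)  # state used for sub-3 Mb noise inserts

MIN_BLOCK_BP = 3_000_000
LST_BLOCK_BP = 10_000_000
NTAI_BLOCK_BP = 5_000_000  # >= 3 Mb (survives filtering) but < 10 Mb (no LST)

SEQ_NOISE_RATE = 1e-3  # alt reads at absent sites: binomial sequencing-noise floor


@dataclass
class SimTruth:
    """Planted ground truth for one simulation run."""

    rng_seed: int
    signature_weights: dict[str, float] | None = None
    channel_counts: np.ndarray | None = None
    lst: int | None = None
    ntai: int | None = None
    deletion_lengths: list[int] = field(default_factory=list)
    mh_lengths: list[int] = field(default_factory=list)
    clusters: list[tuple[float, float, int]] = field(default_factory=list)
    cluster_assignment: list[int] = field(default_factory=list)
    purities: dict[str, float] = field(default_factory=dict)


def simulate_reference(
    seed: int, n_chrom: int = 3, length_bp: int = 1_000_000
) -> tuple[dict[str, str], AssemblySpec]:
    """Uniform-random A/C/G/T reference with centromeres at 45-55% of length."""
    if length_bp < 1_000:
        raise ValueError("chromosome length must be >= 1 kb")
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    reference = {
        str(i + 1): "".join(bases[rng.integers(0, 4, size=length_bp)])
        for i in range(n_chrom)
    }
    cen = (int(length_bp * 0.45), int(length_bp * 0.55))
    assembly = AssemblySpec(
        [(str(i + 1), length_bp) for i in range(n_chrom)],
        {str(i + 1): cen for i in range(n_chrom)},
    )
    return reference, assembly


def _context_index(reference: Mapping[str, str]) -> dict[str, list[tuple[str, int]]]:
    """Map each pyrimidine-folded trinucleotide to its (chrom, 1-based pos) sites."""
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in reference.items():
        s = seq.upper()
        for i in range(1, len(s) - 1):
            tri = s[i - 1 : i + 2]
            if any(b not in COMPLEMENT for b in tri):
                continue
            folded = tri if tri[1] in ("C", "T") else revcomp(tri)
            index.setdefault(folded, []).append((chrom, i + 1))
    return index


def simulate_snv_catalog(
    weights: Mapping[str, float],
    n_snv: int,
    signature_matrix: pd.DataFrame,
    reference: Mapping[str, str],
    seed: int,
    sample_id: str = "SIM",
    depth_mean: int = 100,
    max_retries: int = 100,
) -> tuple[list[MutationRecord], SimTruth]:
    """Draw SNVs whose 96-channel contexts follow a signature mixture.

    Each SNV's channel is drawn from sum_k w_k S_k and the variant is placed
    at a reference position whose trinucleotide matches the drawn channel
    (reverse-strand placements emit the purine representation).  Positions
    are unique; a channel with no matching context raises after bounded
    retries.
    """
    if n_snv < 1:
        raise ValueError("n_snv must be >= 1")
    w = np.array([weights.get(c, 0.0) for c in signature_matrix.columns], dtype=float)
    if (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValueError("signature weights must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    mixture = signature_matrix.to_numpy(dtype=float) @ w
    mixture = mixture / mixture.sum()
    index = _context_index(reference)
    used: set[tuple[str, int]] = set()
    records: list[MutationRecord] = []
    channel_counts = np.zeros(96)
    channel_ids = rng.choice(96, size=n_snv, p=mixture)
    for ch_id in channel_ids:
        label = CHANNELS[ch_id]
        five, sub, three = label[0], label[2:5], label[6]
        folded = five + sub[0] + three
        alt_pyr = sub[2]
        sites = index.get(folded)
        if not sites:
            raise ValueError(f"no reference position matches channel {label}")
        for attempt in range(max_retries):
            chrom, pos = sites[rng.integers(0, len(sites))]
            if (chrom, pos) not in used:
                break
        else:
            raise ValueError(f"could not place channel {label} after {max_retries} retries")
        used.add((chrom, pos))
        ref_base = reference[chrom][pos - 1].upper()
        alt_base = alt_pyr if ref_base in ("C", "T") else COMPLEMENT[alt_pyr]
        depth = max(1, int(rng.poisson(depth_mean)))
        t_alt = int(rng.binomial(depth, 0.5))
        records.append(
            MutationRecord(
                sample_id=sample_id,
                component_id="bulk",
                chrom=chrom,
                pos=pos,
                ref=ref_base,
                alt=alt_base,
                variant_class="SNV",
                t_ref=depth - t_alt,
                t_alt=t_alt,
                n_ref=depth,
                n_alt=0,
            )
        )
        channel_counts[ch_id] += 1
    truth = SimTruth(
        rng_seed=seed,
        signature_weights=dict(weights),
        channel_counts=channel_counts,
    )
    return records, truth


def simulate_indel_set(
    n_del: int,
    length_distribution: Sequence[int],
    mh_fraction: float,
    reference: Mapping[str, str],
    seed: int,
    mh_length_range: tuple[int, int] = (2, 5),
    sample_id: str = "SIM",
    max_retries: int = 50_000,
) -> tuple[list[MutationRecord], SimTruth]:
    """Plant deletions with chosen lengths and junction microhomology.

    Deletion lengths are drawn from ``length_distribution``; a fraction
    ``mh_fraction`` of deletions is placed where the junction microhomology
    (as measured by :func:`biphasic.indels.detect_microhomology`) equals a
    planted value from ``mh_length_range``, the rest where it is exactly 0.
    Placement is by rejection sampling over reference positions; an
    unplaceable target raises after ``max_retries`` draws.
    """
    if not 0.0 <= mh_fraction <= 1.0:
        raise ValueError("mh_fraction must be in [0, 1]")
    if n_del < 1:
        raise ValueError("n_del must be >= 1")
    lengths = [int(l) for l in length_distribution]
    if any(l < 1 for l in lengths):
        raise ValueError("deletion lengths must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = sorted(reference)
    records: list[MutationRecord] = []
    truth = SimTruth(rng_seed=seed)
    used: set[tuple[str, int]] = set()
    for _ in range(n_del):
        length = lengths[rng.integers(0, len(lengths))]
        if rng.random() < mh_fraction and length >= 3:
            lo, hi = mh_length_range
            target = int(rng.integers(lo, min(hi, length - 1) + 1))
        else:
            target = 0
        placed = False
        for _attempt in range(max_retries):
            chrom = chroms[rng.integers(0, len(chroms))]
            seq = reference[chrom]
            if len(seq) < 3 * length + 2:
                continue
            # 1-based position of the first deleted base; keep full flanks
            del_start = int(rng.integers(length + 2, len(seq) - 2 * length + 1))
            anchor_pos = del_start - 1
            if (chrom, anchor_pos) in used:
                continue
            anchor = seq[anchor_pos - 1]
            deleted = seq[del_start - 1 : del_start - 1 + length]
            rec = MutationRecord(
                sample_id=sample_id,
                component_id="bulk",
                chrom=chrom,
                pos=anchor_pos,
                ref=anchor + deleted,
                alt=anchor,
                variant_class="deletion",
                t_ref=50,
                t_alt=50,
                n_ref=100,
                n_alt=0,
            )
            call = detect_microhomology(rec, reference)
            if call.missing or call.repeat_mediated or call.mh_length != target:
                continue
            used.add((chrom, anchor_pos))
            records.append(rec)
            truth.deletion_lengths.append(length)
            truth.mh_lengths.append(target)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place a {length} bp deletion with microhomology "
                f"{target} after {max_retries} draws"
            )
    return records, truth


def _allocate_events(
    arms: list[Arm], n_lst: int, n_ntai: int
) -> tuple[dict[Arm, int], list[Arm]]:
    """Assign NtAI arms (one event each) and spread LST counts over the rest."""
    min_ntai_arm = NTAI_BLOCK_BP + MIN_BLOCK_BP
    ntai_candidates = [a for a in arms if a.length >= min_ntai_arm]
    if len(ntai_candidates) < n_ntai:
        raise ValueError(
            f"cannot plant {n_ntai} telomeric-imbalance events: only "
            f"{len(ntai_candidates)} arms are long enough"
        )
    ntai_arms = ntai_candidates[:n_ntai]
    remaining = [a for a in arms if a not in ntai_arms]
    lst_alloc: dict[Arm, int] = {}
    todo = n_lst
    for arm in sorted(remaining, key=lambda a: -a.length):
        if todo == 0:
            break
        capacity = arm.length // LST_BLOCK_BP - 1  # k events need k+1 blocks >= 10 Mb
        if capacity <= 0:
            continue
        take = min(capacity, todo)
        lst_alloc[arm] = take
        todo -= take
    if todo > 0:
        raise ValueError(
            f"cannot plant {n_lst} large-scale transitions on the available "
            f"arms (short by {todo}); use a larger assembly"
        )
    return lst_alloc, ntai_arms


def simulate_segment_profile(
    n_lst_events: int,
    n_ntai_events: int,
    noise_segments_lt3mb: int,
    assembly: AssemblySpec,
    seed: int,
    sample_id: str = "SIM",
    purity: float = 0.8,
    ploidy: float = 2.0,
) -> tuple[SegmentProfile, SimTruth]:
    """Segment profile with planted LST and NtAI counts plus sub-3 Mb noise.

    LST events are chains of alternating *balanced* >= 10 Mb states
    ((2,1) vs (4,2)) confined to arm interiors, so they add transitions
    without creating allelic imbalance; NtAI events are 5 Mb imbalanced
    (3,1) blocks at telomeres of arms not used for LST chains.  Noise
    segments shorter than 3 Mb are carved out of blocks wide enough that
    both remnants stay >= 3 Mb, so filtering restores the planted scores
    exactly.
    """
    if min(n_lst_events, n_ntai_events, noise_segments_lt3mb) < 0:
        raise ValueError("event counts must be >= 0")
    rng = np.random.default_rng(seed)
    arms = assembly.arms(autosomes_only=True)
    lst_alloc, ntai_arms = _allocate_events(arms, n_lst_events, n_ntai_events)

    segments: list[Segment] = []
    for arm in arms:
        if arm in ntai_arms:
            # imbalanced telomeric block + balanced remainder
            if arm.name == "p":
                tel_start, tel_end = arm.start, arm.start + NTAI_BLOCK_BP - 1
                rest = (tel_end + 1, arm.end)
            else:
                tel_start, tel_end = arm.end - NTAI_BLOCK_BP + 1, arm.end
                rest = (arm.start, tel_start - 1)
            segments.append(Segment(arm.chrom, tel_start, tel_end, *AI_STATE))
            if rest[1] >= rest[0]:
                segments.append(Segment(arm.chrom, rest[0], rest[1], *BALANCED_A))
        elif arm in lst_alloc:
            k = lst_alloc[arm]
            n_blocks = k + 1
            bounds = np.linspace(arm.start - 1, arm.end, n_blocks + 1).astype(int)
            for b in range(n_blocks):
                state = BALANCED_A if b % 2 == 0 else BALANCED_B
                segments.append(
                    Segment(arm.chrom, int(bounds[b]) + 1, int(bounds[b + 1]), *state)
                )
        else:
            segments.append(Segment(arm.chrom, arm.start, arm.end, *BALANCED_A))

    # carve noise segments out of blocks, keeping both remnants >= 3 Mb
    for _ in range(noise_segments_lt3mb):
        noise_len = int(rng.integers(100_000, MIN_BLOCK_BP - 1))
        candidates = [
            i for i, s in enumerate(segments)
            if s.length >= noise_len + 2 * MIN_BLOCK_BP and s.state != NOISE_STATE
        ]
        if not candidates:
            raise ValueError("no block wide enough to host a noise segment")
        i = candidates[rng.integers(0, len(candidates))]
        host = segments[i]
        noise_start = int(
            rng.integers(host.start + MIN_BLOCK_BP, host.end - MIN_BLOCK_BP - noise_len + 2)
        )
        left = Segment(host.chrom, host.start, noise_start - 1, *host.state)
        noise = Segment(host.chrom, noise_start, noise_start + noise_len - 1, *NOISE_STATE)
        right = Segment(host.chrom, noise.end + 1, host.end, *host.state)
        segments[i : i + 1] = [left, noise, right]

    profile = SegmentProfile(
        sample_id=sample_id, segments=segments, purity=purity, ploidy=ploidy
    ).canonicalize()
    truth = SimTruth(rng_seed=seed, lst=n_lst_events, ntai=n_ntai_events)
    return profile, truth


def flat_segment_profile(
    sample_id: str,
    assembly: AssemblySpec,
    purity: float,
    total_cn: int = 2,
    minor_cn: int = 1,
    ploidy: float = 2.0,
) -> SegmentProfile:
    """One segment per chromosome at a constant copy-number state."""
    segments = [
        Segment(chrom, 1, length, total_cn, minor_cn)
        for chrom, length in assembly.chromosomes
    ]
    return SegmentProfile(sample_id, segments, purity, ploidy).canonicalize()


def simulate_paired_components(
    clusters: Sequence[tuple[float, float, int]],
    purity_a: float,
    purity_b: float,
    depth_mean: int,
    seed: int,
    cn_profile: Mapping[tuple[str, int], tuple[int, int]] | None = None,
    components: tuple[str, str] = ("epithelial", "mesenchymal"),
    sample_id: str = "SIM",
    precision: float = 500.0,
    chrom: str = "1",
) -> tuple[list[MutationRecord], SimTruth]:
    """Paired-component read counts from a planted clone tree.

    ``clusters`` is a list of (ccf_A, ccf_B, n_mutations).  For each
    mutation the expected VAF in component c is
    ``ccf_c * purity_c * m / (purity_c * CN_t + (1 - purity_c) * 2)``
    (CN_t = 2, m = 1 unless overridden via ``cn_profile`` keyed by
    (chrom, pos)); alternate counts are beta-binomial around it at the
    given precision, with a binomial sequencing-noise floor for absent
    mutations.  A truncal cluster is simply one with ccf_A = ccf_B = 1.
    """
    if depth_mean < 1:
        raise ValueError("depth_mean must be >= 1")
    for ccf_a, ccf_b, n_mut in clusters:
        if not (0.0 <= ccf_a <= 1.0 and 0.0 <= ccf_b <= 1.0):
            raise ValueError("cluster CCFs must be in [0, 1]")
        if n_mut < 1:
            raise ValueError("each cluster needs >= 1 mutation")
    rng = np.random.default_rng(seed)
    purities = dict(zip(components, (purity_a, purity_b)))
    records: list[MutationRecord] = []
    truth = SimTruth(
        rng_seed=seed, clusters=[tuple(c) for c in clusters], purities=purities
    )
    pos = 1000
    for k, (ccf_a, ccf_b, n_mut) in enumerate(clusters):
        ccfs = dict(zip(components, (ccf_a, ccf_b)))
        for _ in range(n_mut):
            pos += 1000
            total_cn, mult = (cn_profile or {}).get((chrom, pos), (2, 1))
            for comp in components:
                xi = expected_vaf(ccfs[comp], purities[comp], total_cn, mult)
                if xi > 1.0:
                    raise ValueError(
                        f"expected VAF {xi:.3f} > 1 under multiplicity {mult}"
                    )
                depth = max(1, int(rng.poisson(depth_mean)))
                if xi <= 0.0:
                    t_alt = int(rng.binomial(depth, SEQ_NOISE_RATE))
                else:
                    xi_c = min(xi, 1.0 - 1e-9)
                    p = rng.beta(xi_c * precision, (1.0 - xi_c) * precision)
                    t_alt = int(rng.binomial(depth, p))
                n_depth = max(1, int(rng.poisson(depth_mean)))
                n_alt = int(rng.binomial(n_depth, SEQ_NOISE_RATE))
                records.append(
                    MutationRecord(
                        sample_id=sample_id,
                        component_id=comp,
                        chrom=chrom,
                        pos=pos,
                        ref="A",
                        alt="C",
                        variant_class="SNV",
                        t_ref=depth - t_alt,
                        t_alt=t_alt,
                        n_ref=n_depth - n_alt,
                        n_alt=n_alt,
                    )
                )
            truth.cluster_assignment.append(k)
    return records, truth
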