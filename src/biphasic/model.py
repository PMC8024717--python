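"""Core domain types for somatic mutation and copy-number data.

Coordinate convention: 1-based, fully closed intervals for both mutations
and segments (MAF/SEG style); all length arithmetic is ``end - start + 1``.
Chromosome names are accepted with or without a ``chr`` prefix and are
normalized internally to the prefix-free form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

VARIANT_CLASSES = ("SNV", "insertion", "deletion")
EFFECTS = (
    "synonymous",
    "nonsynonymous_missense",
    "nonsense",
    "frameshift",
    "splice",
    "other",
)

AUTOSOMES = tuple(str(i) for i in range(1, 23))


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix; ``chr1`` and ``1`` are the same axis."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if not name:
        raise ValueError("empty chromosome name")
    return name


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in AUTOSOMES or normalize_chrom(chrom).isdigit()


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant with per-component read counts.

    Indels use anchored allele strings (VCF style): a deletion carries
    ``ref = anchor + deleted bases`` with ``alt = anchor``; an insertion the
    converse.  ``variant_class`` must be consistent with the allele lengths.
    """

    sample_id: str
    component_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    gene: str = ""
    effect: str = "other"
    t_ref: int = 0
    t_alt: int = 0
    n_ref: int = 0
    n_alt: int = 0
    hotspot_flag: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("t_ref", "t_alt", "n_ref", "n_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty allele strings")
        lr, la = len(self.ref), len(self.alt)
        if self.variant_class == "SNV" and not (lr == la == 1):
            raise ValueError(f"SNV requires single-base ref/alt, got {self.ref}>{self.alt}")
        if self.variant_class == "deletion" and not (lr > la and self.ref.startswith(self.alt)):
            raise ValueError(
                f"deletion requires ref = alt + deleted bases, got {self.ref}>{self.alt}"
            )
        if self.variant_class == "insertion" and not (la > lr and self.alt.startswith(self.ref)):
            raise ValueError(
                f"insertion requires alt = ref + inserted bases, got {self.ref}>{self.alt}"
            )

    @property
    def t_depth(self) -> int:
        return self.t_ref + self.t_alt

    @property
    def n_depth(self) -> int:
        return self.n_ref + self.n_alt

    @property
    def vaf(self) -> float:
        """Tumor variant allele fraction; 0.0 at zero depth."""
        d = self.t_depth
        return self.t_alt / d if d > 0 else 0.0

    @property
    def normal_vaf(self) -> float:
        d = self.n_depth
        return self.n_alt / d if d > 0 else 0.0

    @property
    def deleted_bases(self) -> str:
        if self.variant_class != "deletion":
            raise ValueError("deleted_bases only defined for deletions")
        return self.ref[len(self.alt):]

    @property
    def deletion_length(self) -> int:
        return len(self.deleted_bases)

    @property
    def deletion_start(self) -> int:
        """1-based position of the first deleted base."""
        return self.pos + len(self.alt)

    def key(self) -> tuple:
        """Identity for cross-component matching: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad segment interval {self.chrom}:{self.start}-{self.end}")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.minor_cn > self.total_cn:
            raise ValueError("minor_cn cannot exceed total_cn")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def state(self) -> tuple[int, int]:
        return (self.total_cn, self.minor_cn)

    @property
    def allelic_imbalance(self) -> bool:
        """Major allele copy number differs from minor (total - minor != minor)."""
        return self.total_cn - self.minor_cn != self.minor_cn


@dataclass
class SegmentProfile:
    """Allele-specific copy-number segments plus purity and ploidy for one sample."""

    sample_id: str
    segments: list[Segment]
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be > 0, got {self.ploidy}")

    def canonicalize(self) -> "SegmentProfile":
        """Sorted, minor allele folded to min(minor, total - minor); validates non-overlap."""
        segs = [
            replace(s, minor_cn=min(s.minor_cn, s.total_cn - s.minor_cn))
            for s in self.segments
        ]
        segs.sort(key=lambda s: (_chrom_sort_key(s.chrom), s.start))
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValueError(
                    f"overlapping segments on chromosome {a.chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        return SegmentProfile(self.sample_id, segs, self.purity, self.ploidy)

    def segment_at(self, chrom: str, pos: int) -> Segment | None:
        chrom = normalize_chrom(chrom)
        for s in self.segments:
            if s.chrom == chrom and s.start <= pos <= s.end:
                return s
        return None


def _chrom_sort_key(name: str) -> tuple[int, str]:
    name = normalize_chrom(name)
    if name.isdigit():
        return (int(name), "")
    return (100, name)


@dataclass(frozen=True)
class Arm:
    chrom: str
    name: str  # "p" or "q"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AssemblySpec:
    """Chromosome lengths and centromere intervals; arms are derived.

    p arm = [1, centromere.start), q arm = (centromere.end, length].
    """

    chromosomes: list[tuple[str, int]]
    centromeres: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.chromosomes = [(normalize_chrom(n), int(l)) for n, l in self.chromosomes]
        self.centromeres = {
            normalize_chrom(k): (int(a), int(b)) for k, (a, b) in self.centromeres.items()
        }
        lengths = dict(self.chromosomes)
        for chrom, length in self.chromosomes:
            if chrom not in self.centromeres:
                raise ValueError(f"chromosome {chrom} has no centromere interval")
            a, b = self.centromeres[chrom]
            if not (1 <= a <= b <= length):
                raise ValueError(
                    f"centromere {a}-{b} outside chromosome {chrom} (length {length})"
                )
        for chrom in self.centromeres:
            if chrom not in lengths:
                raise ValueError(f"centromere given for unknown chromosome {chrom}")

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def has_chromosome(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.chromosome_lengths

    def arms(self, autosomes_only: bool = False) -> list[Arm]:
        out: list[Arm] = []
        for chrom, length in self.chromosomes:
            if autosomes_only and not is_autosome(chrom):
                continue
            cen_start, cen_end = self.centromeres[chrom]
            if cen_start > 1:
                out.append(Arm(chrom, "p", 1, cen_start - 1))
            if cen_end < length:
                out.append(Arm(chrom, "q", cen_end + 1, length))
        return out


@dataclass
class RunConfig:
    """Analysis thresholds and sampler settings.

    Defaults are the thresholds used throughout the pipeline: the LST-high
    cutoff (>= 15), the strict NtAI support cutoff (> 16), the long-deletion
    boundary (mean length >= 5 bp), the 20-SNV minimum for signature
    refitting, the hypermutation boundary (>= 1000 somatic mutations), the
    MSI-high score boundary (>= 3.5), and the clonal-decomposition read-depth
    filters (normal >= 20x, tumor 50-1500x, VAF >= 5x normal VAF).
    """

    lst_high_cutoff: int = 15
    ntai_support_cutoff: int = 16  # strict >
    deletion_length_cutoff: float = 5.0
    min_snvs_for_signatures: int = 20
    hypermutation_cutoff: int = 1000
    msi_high_cutoff: float = 3.5
    min_normal_depth: int = 20
    min_tumor_depth: int = 50
    max_tumor_depth: int = 1500
    vaf_multiplier: float = 5.0
    mcmc_iterations: int = 20000
    mcmc_burn_in: int = 10000
    beta_binomial_precision: float = 500.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "lst_high_cutoff", "ntai_support_cutoff", "deletion_length_cutoff",
            "min_snvs_for_signatures", "hypermutation_cutoff", "msi_high_cutoff",
            "min_normal_depth", "min_tumor_depth", "max_tumor_depth",
            "vaf_multiplier", "mcmc_iterations", "beta_binomial_precision",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.mcmc_burn_in < self.mcmc_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
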