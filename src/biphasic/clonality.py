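"""Clonality index for two lesions from shared versus private mutations.

Two lesions sharing somatic mutations that are individually improbable are
unlikely to have acquired them independently.  Under an independence model
each shared mutation j carries a probability q_j of arising by chance in a
second tumor of the same type; the chance probability of the observed
sharing is the product of the q_j, and the clonality index is its negative
log10.  The background model supplying q_j is pluggable: the default table
model uses hotspot population frequencies for hotspot mutations and
per-gene cohort frequency spread over the gene's coding length otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .model import MutationRecord


def left_align(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Trim shared allele bases (suffix first, then prefix) to a canonical form."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def _match_key(m: MutationRecord) -> tuple[str, int, str, str]:
    return left_align(m.chrom, m.pos, m.ref, m.alt)


class TableBackgroundModel:
    """q_j from a hotspot frequency table and per-gene cohort frequencies.

    For hotspot-flagged mutations q is the hotspot's recurrence frequency;
    otherwise q = (cohort frequency of the gene) / (gene coding length in
    bp), i.e. the chance of an independent second hit at the same base.
    Unknown genes fall back to ``default_gene_frequency`` over
    ``default_gene_length_bp``.
    """

    def __init__(
        self,
        hotspot_frequency: Mapping[str, float] | None = None,
        gene_frequency: Mapping[str, float] | None = None,
        gene_length_bp: Mapping[str, int] | None = None,
        default_gene_frequency: float = 0.01,
        default_gene_length_bp: int = 1500,
    ) -> None:
        self.hotspot_frequency = dict(hotspot_frequency or {})
        self.gene_frequency = dict(gene_frequency or {})
        self.gene_length_bp = dict(gene_length_bp or {})
        self.default_gene_frequency = default_gene_frequency
        self.default_gene_length_bp = default_gene_length_bp

    def occurrence_probability(self, m: MutationRecord) -> float:
        if m.hotspot_flag and m.gene in self.hotspot_frequency:
            q = self.hotspot_frequency[m.gene]
        else:
            freq = self.gene_frequency.get(m.gene, self.default_gene_frequency)
            length = self.gene_length_bp.get(m.gene, self.default_gene_length_bp)
            q = freq / length
        if not (0.0 < q <= 1.0):
            raise ValueError(f"background probability must be in (0, 1], got {q}")
        return q


@dataclass(frozen=True)
class ClonalityResult:
    n_shared: int
    n_private_a: int
    n_private_b: int
    log_prob_chance: float  # log10 P(observed sharing | independence)
    ci: float               # clonality index, -log_prob_chance
    related: bool
    alpha: float


def clonality_index(
    mutations_a: Sequence[MutationRecord],
    mutations_b: Sequence[MutationRecord],
    background: TableBackgroundModel | None = None,
    alpha: float = 0.05,
    q_of: Callable[[MutationRecord], float] | None = None,
) -> ClonalityResult:
    """Clonality assessment of two mutation lists from the same case.

    Mutations are matched on (chrom, pos, ref, alt) after indel
    left-alignment.  ``q_of`` overrides the background model when supplied.
    The verdict is symmetric in A and B.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if q_of is None:
        model = background or TableBackgroundModel()
        q_of = model.occurrence_probability
    if not mutations_a or not mutations_b:
        warnings.warn("empty mutation list: lesions treated as unrelated", stacklevel=2)
        return ClonalityResult(
            n_shared=0,
            n_private_a=len(mutations_a),
            n_private_b=len(mutations_b),
            log_prob_chance=0.0,
            ci=0.0,
            related=False,
            alpha=alpha,
        )
    by_key_a = {_match_key(m): m for m in mutations_a}
    keys_b = {_match_key(m) for m in mutations_b}
    shared_keys = set(by_key_a) & keys_b
    log_prob = sum(math.log10(q_of(by_key_a[k])) for k in shared_keys)
    related = 10.0 ** log_prob < alpha if shared_keys else False
    return ClonalityResult(
        n_shared=len(shared_keys),
        n_private_a=len(by_key_a) - len(shared_keys),
        n_private_b=len(keys_b) - len(shared_keys),
        log_prob_chance=log_prob,
        ci=-log_prob,
        related=related,
        alpha=alpha,
    )
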