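"""96-channel mutational catalogs and signature exposure refitting.

Single-nucleotide variants are tallied into the standard 96 trinucleotide
channels (6 pyrimidine-centred substitution types x 16 flanking contexts);
purine-reference sites are reverse-complemented onto the pyrimidine strand.
Exposures to a fixed signature dictionary are then refit by nonnegative
least squares with iterative pruning of sub-floor weights (default floor
0.06 of the normalized exposure), the same objective and constraint set as
the standard refitting tools, and the dominant signature is reported.
Samples with fewer than 20 SNVs are flagged ``insufficient_snvs`` and not
refit.

The packaged 30-signature dictionary is a deterministic *synthetic*
stand-in whose leading signatures mimic the qualitative shapes of the
well-known processes (signature 1: C>T at NpCpG, aging; signatures 2/13:
C>T / C>G at TpCpN, APOBEC; signature 3: near-flat, HRD; signature 5:
flat with a T>C lean, aging); it is not the COSMIC v2 matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .model import MutationRecord, normalize_chrom

PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def channel_labels() -> list[str]:
    """The 96 channel labels in canonical order, e.g. ``A[C>A]A``."""
    out = []
    for sub in PYRIMIDINE_SUBS:
        for five in BASES:
            for three in BASES:
                out.append(f"{five}[{sub}]{three}")
    return out


CHANNELS = channel_labels()
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def channel_of(trinucleotide: str, alt: str) -> str:
    """Map a reference trinucleotide and alternate base to its pyrimidine channel."""
    tri = trinucleotide.upper()
    alt = alt.upper()
    if len(tri) != 3 or any(b not in COMPLEMENT for b in tri) or alt not in COMPLEMENT:
        raise ValueError(f"bad trinucleotide/alt {trinucleotide!r}/{alt!r}")
    if tri[1] in ("A", "G"):  # fold purines onto the pyrimidine strand
        tri = revcomp(tri)
        alt = COMPLEMENT[alt]
    label = f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"
    if label not in _CHANNEL_INDEX:
        raise ValueError(f"ref equals alt in {label}")
    return label


@dataclass
class TrinucleotideCatalog:
    counts: np.ndarray  # length 96, canonical channel order
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("catalog must have 96 channels")
        if (self.counts < 0).any():
            raise ValueError("channel counts must be >= 0")

    @property
    def n_snv(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=CHANNELS, name="count")


def build_catalog(
    mutations: list[MutationRecord], reference: Mapping[str, str]
) -> TrinucleotideCatalog:
    """Tally SNVs into the 96 channels using +/-1 bp reference context.

    Non-SNVs are ignored; sites whose context is unavailable (chromosome
    edge or unknown chromosome) are skipped with a warning and counted in
    ``n_skipped``.
    """
    ref_by_chrom = {normalize_chrom(k): v for k, v in reference.items()}
    counts = np.zeros(96)
    skipped = 0
    for m in mutations:
        if m.variant_class != "SNV":
            continue
        seq = ref_by_chrom.get(m.chrom)
        if seq is None or m.pos < 2 or m.pos > len(seq) - 1:
            skipped += 1
            continue
        tri = seq[m.pos - 2 : m.pos + 1].upper()
        if tri[1] != m.ref.upper():
            raise ValueError(
                f"reference base mismatch at {m.chrom}:{m.pos}: "
                f"sequence has {tri[1]}, record says {m.ref}"
            )
        counts[_CHANNEL_INDEX[channel_of(tri, m.alt)]] += 1
    if skipped:
        warnings.warn(f"skipped {skipped} SNV(s) without reference context", stacklevel=2)
    return TrinucleotideCatalog(counts, n_skipped=skipped)


def synthetic_signature_matrix(n_signatures: int = 30) -> pd.DataFrame:
    """Deterministic synthetic 96 x n dictionary of substitution signatures.

    Columns are probability vectors named ``Signature_1`` ... ``Signature_n``.
    This is a synthetic stand-in (see module docstring), suitable for
    simulation, refitting, and dominant-signature grouping.
    """
    if n_signatures < 1:
        raise ValueError("need at least one signature")
    rng = np.random.default_rng(961996)  # fixed: the matrix is package data
    cols = {}
    for k in range(1, n_signatures + 1):
        name = f"Signature_{k}"
        base = rng.dirichlet(np.full(96, 0.3))
        profile = np.asarray(base)
        if k == 1:  # aging: C>T at NpCpG
            profile = 0.1 * base
            for five in BASES:
                profile[_CHANNEL_INDEX[f"{five}[C>T]G"]] += 0.9 / 4
        elif k in (2, 13):  # APOBEC: C>T (2) / C>G (13) at TpCpN
            sub = "C>T" if k == 2 else "C>G"
            profile = 0.15 * base
            for three in BASES:
                profile[_CHANNEL_INDEX[f"T[{sub}]{three}"]] += 0.85 / 4
        elif k == 3:  # HRD: near-flat
            profile = 0.9 / 96 + 0.1 * rng.dirichlet(np.full(96, 5.0))
        elif k == 5:  # aging: flat with a T>C lean
            profile = 0.5 / 96 * np.ones(96)
            lean = np.zeros(96)
            for five in BASES:
                for three in BASES:
                    lean[_CHANNEL_INDEX[f"{five}[T>C]{three}"]] = 1 / 16
            profile = profile + 0.5 * lean
        cols[name] = profile / profile.sum()
    return pd.DataFrame(cols, index=CHANNELS)


def signature_number(name: str) -> int:
    """Numeric id of a signature column name like ``Signature_3``."""
    return int(str(name).rsplit("_", 1)[-1])


@dataclass
class SignatureExposure:
    """Nonnegative per-signature weights from 96-channel refitting."""

    weights: dict[str, float]
    residual: float
    dominant: str
    n_snv: int
    sample_id: str | None = None

    @property
    def insufficient(self) -> bool:
        return self.dominant == "insufficient_snvs"


def fit_exposures(
    catalog: TrinucleotideCatalog,
    signature_matrix: pd.DataFrame,
    min_snvs: int = 20,
    weight_floor: float = 0.06,
    sample_id: str | None = None,
) -> SignatureExposure:
    """Refit signature exposures by nonnegative least squares with pruning.

    Minimizes ``|| c/sum(c) - S w ||_2`` over ``w >= 0``, zeroes out
    normalized weights below ``weight_floor``, refits on the retained
    support until stable, and renormalizes to sum 1.  Catalogs with fewer
    than ``min_snvs`` SNVs are not fit.  Dominant-signature ties break to
    the lower signature number.
    """
    if catalog.n_snv == 0:
        raise ValueError("degenerate catalog: all channel counts are zero")
    if catalog.n_snv < min_snvs:
        return SignatureExposure(
            weights={}, residual=float("nan"), dominant="insufficient_snvs",
            n_snv=catalog.n_snv, sample_id=sample_id,
        )
    S = signature_matrix.to_numpy(dtype=float)
    names = list(signature_matrix.columns)
    c = catalog.counts / catalog.counts.sum()

    support = list(range(len(names)))
    while True:
        w_sub, rnorm = nnls(S[:, support], c)
        total = w_sub.sum()
        if total <= 0:
            raise ValueError("refit collapsed to zero exposure")
        keep = [i for i, w in zip(support, w_sub) if w / total >= weight_floor]
        if not keep:  # retain the single largest contributor
            keep = [support[int(np.argmax(w_sub))]]
        if keep == support:
            break
        support = keep

    weights_raw = dict(zip([names[i] for i in support], w_sub))
    residual = float(rnorm)
    norm = sum(weights_raw.values())
    weights = {k: v / norm for k, v in weights_raw.items() if v > 0}
    dominant = min(
        weights, key=lambda k: (-weights[k], signature_number(k))
    )
    return SignatureExposure(
        weights=weights, residual=residual, dominant=dominant,
        n_snv=catalog.n_snv, sample_id=sample_id,
    )


def dominant_signature_group(exposure: SignatureExposure) -> str:
    """Group the dominant signature: HRD (3), aging (1 or 5), other, insufficient."""
    if exposure.insufficient:
        return "insufficient"
    num = signature_number(exposure.dominant)
    if num == 3:
        return "HRD"
    if num in (1, 5):
        return "aging"
    return "other"
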