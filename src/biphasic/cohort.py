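"""Cohort-level burden, alteration-frequency, pathway, and comparison statistics.

Two-group comparisons use Fisher's exact test (categorical) and the
Mann-Whitney U test (continuous), with Benjamini-Hochberg false-discovery-
rate control across the family of tests run in one invocation; FDR < 0.05
is the significance convention.  Hypermutated samples (>= 1000 somatic
mutations) must be excluded before any comparison; cohort-level wrappers
enforce this.

Pathway summaries are deterministic alteration fractions over curated
canonical gene sets (p53, PI3K/AKT/mTOR, Wnt, Notch) shipped as package
data and user-replaceable.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import MutationRecord

logger = logging.getLogger(__name__)

ALTERATION_CLASSES = ("mutation", "amplification", "homozygous_deletion")

# above this group size the Mann-Whitney p switches to the tie-corrected
# normal approximation; below it (and without ties) the exact null is used
EXACT_MW_MAX_N = 25


def mutation_burden(
    total_count: int, nonsyn_count: int, capture_mb: float
) -> tuple[float, float]:
    """Somatic mutations per Mb of capture footprint (total, nonsynonymous)."""
    if capture_mb <= 0:
        raise ValueError(f"capture_mb must be > 0, got {capture_mb}")
    if total_count < 0 or nonsyn_count < 0:
        raise ValueError("mutation counts must be >= 0")
    return total_count / capture_mb, nonsyn_count / capture_mb


def classify_pathogenic(
    record: MutationRecord, gene_role: Mapping[str, str] | None = None
) -> bool:
    """Pathogenic iff hotspot, or loss-of-function in a tumor suppressor."""
    if record.hotspot_flag:
        return True
    roles = gene_role or {}
    role = roles.get(record.gene, "other")
    if role not in ("oncogene", "tumor_suppressor", "other"):
        raise ValueError(f"unknown gene role {role!r}")
    if record.gene not in roles:
        logger.info("gene %s has no annotated role; treating as 'other'", record.gene)
    return role == "tumor_suppressor" and record.effect in (
        "nonsense",
        "frameshift",
        "splice",
    )


def fisher_test(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table -> (odds ratio, p)."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("Fisher test requires a 2x2 table")
    if (arr < 0).any():
        raise ValueError("table counts must be >= 0")
    res = stats.fisher_exact(arr, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values for one family of tests."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def compare_frequency(
    tables: Mapping[str, Sequence[Sequence[int]]]
) -> pd.DataFrame:
    """Fisher tests over one family of 2x2 tables with BH correction.

    ``tables`` maps a feature/gene name to ((altered_A, unaltered_A),
    (altered_B, unaltered_B)).  Returns a DataFrame with odds_ratio, p, q.
    The FDR family is exactly the tables passed in one call; families are
    never merged across invocations.
    """
    if not tables:
        raise ValueError("no tables to test")
    names = list(tables)
    ors, ps = [], []
    for name in names:
        orr, p = fisher_test(tables[name])
        ors.append(orr)
        ps.append(p)
    return pd.DataFrame(
        {"name": names, "odds_ratio": ors, "p": ps, "q": benjamini_hochberg(ps)}
    )


def compare_continuous(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test -> (U statistic, p).

    Exact null distribution when both groups are small (n <= 25) and
    tie-free; tie-corrected normal approximation with continuity correction
    otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CohortTable:
    """Per-sample cohort annotations plus a long-form alteration table.

    ``samples``: DataFrame indexed by sample_id with columns ``group``,
    ``total_mutations``, ``nonsyn_mutations``, ``capture_mb``,
    ``hypermutated`` (and optionally ``fga`` and HRD columns).
    ``alterations``: DataFrame with columns ``sample_id``, ``gene``,
    ``alteration_class``, ``pathogenic``.
    """

    samples: pd.DataFrame
    alterations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "gene", "alteration_class", "pathogenic"]
        )
    )

    def __post_init__(self) -> None:
        required = {"group", "total_mutations", "nonsyn_mutations", "capture_mb", "hypermutated"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"samples table missing columns: {', '.join(sorted(missing))}")
        bad = set(self.alterations["alteration_class"]) - set(ALTERATION_CLASSES)
        if bad:
            raise ValueError(f"unknown alteration classes: {', '.join(sorted(map(str, bad)))}")
        unknown = set(self.alterations["sample_id"]) - set(self.samples.index)
        if unknown:
            raise ValueError(f"alterations for unknown samples: {', '.join(sorted(unknown))}")

    @property
    def groups(self) -> list[str]:
        return sorted(self.samples["group"].unique())

    def exclude_hypermutated(self) -> "CohortTable":
        keep = self.samples.index[~self.samples["hypermutated"].astype(bool)]
        return CohortTable(
            samples=self.samples.loc[keep],
            alterations=self.alterations[self.alterations["sample_id"].isin(keep)].copy(),
        )

    def _require_comparable(self) -> tuple[str, str]:
        if self.samples["hypermutated"].astype(bool).any():
            raise ValueError(
                "hypermutated samples present: call exclude_hypermutated() "
                "before running comparisons"
            )
        groups = self.groups
        if len(groups) != 2 or (self.samples["group"].value_counts() < 1).any():
            raise ValueError("comparisons require exactly two nonempty groups")
        return groups[0], groups[1]

    def burden_per_mb(self) -> pd.DataFrame:
        rows = {}
        for sid, row in self.samples.iterrows():
            total, nonsyn = mutation_burden(
                int(row["total_mutations"]), int(row["nonsyn_mutations"]), float(row["capture_mb"])
            )
            rows[sid] = {"group": row["group"], "total_per_mb": total, "nonsyn_per_mb": nonsyn}
        return pd.DataFrame.from_dict(rows, orient="index")

    def altered_samples(self, genes: Sequence[str], pathogenic_only: bool = False) -> set[str]:
        alt = self.alterations[self.alterations["gene"].isin(set(genes))]
        if pathogenic_only:
            alt = alt[alt["pathogenic"].astype(bool)]
        return set(alt["sample_id"])

    def gene_frequency_comparison(self, genes: Sequence[str]) -> pd.DataFrame:
        """Per-gene alteration-frequency Fisher tests between the two groups."""
        ga, gb = self._require_comparable()
        in_a = self.samples.index[self.samples["group"] == ga]
        in_b = self.samples.index[self.samples["group"] == gb]
        tables = {}
        for gene in genes:
            hit = self.altered_samples([gene])
            a_alt = sum(s in hit for s in in_a)
            b_alt = sum(s in hit for s in in_b)
            tables[gene] = ((a_alt, len(in_a) - a_alt), (b_alt, len(in_b) - b_alt))
        out = compare_frequency(tables)
        out.insert(1, f"frac_{ga}", [t[0][0] / len(in_a) for t in tables.values()])
        out.insert(2, f"frac_{gb}", [t[1][0] / len(in_b) for t in tables.values()])
        return out

    def continuous_comparison(self, column: str) -> tuple[float, float]:
        """Mann-Whitney comparison of a per-sample numeric column between groups."""
        ga, gb = self._require_comparable()
        a = self.samples.loc[self.samples["group"] == ga, column].astype(float)
        b = self.samples.loc[self.samples["group"] == gb, column].astype(float)
        return compare_continuous(a.to_numpy(), b.to_numpy())


def load_pathway_gene_sets(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load the packaged (or a user-supplied) pathway -> gene-list table."""
    if path is None:
        ref = importlib.resources.files("biphasic.data").joinpath("pathway_gene_sets.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, list[str]] = {}
    for pathway, sub in df.groupby("pathway"):
        out[str(pathway)] = sorted(sub["gene"].astype(str).unique())
    return out


def pathway_alteration_summary(
    cohort: CohortTable, gene_sets: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-pathway, per-group fractions of samples with >= 1 (pathogenic) alteration."""
    rows = []
    for pathway, genes in gene_sets.items():
        if not list(genes):
            raise ValueError(f"empty gene set for pathway {pathway!r}")
        hit_any = cohort.altered_samples(genes)
        hit_path = cohort.altered_samples(genes, pathogenic_only=True)
        for group in cohort.groups:
            members = cohort.samples.index[cohort.samples["group"] == group]
            n = len(members)
            n_any = sum(s in hit_any for s in members)
            n_path = sum(s in hit_path for s in members)
            rows.append(
                {
                    "pathway": pathway,
                    "group": group,
                    "n": n,
                    "frac_altered": n_any / n if n else float("nan"),
                    "frac_pathogenic": n_path / n if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)
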