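"""Clonal decomposition of paired histologic components.

Pipeline: depth/VAF filters -> per-mutation cancer-cell-fraction (CCF)
estimation -> Dirichlet-process beta-binomial clustering of CCFs shared
across the two components -> truncal/branch labeling -> clonal-selection
detection -> two-leaf clone tree.

The clustering model follows the PyClone formulation: each cluster carries
one CCF per component; a mutation's alternate read count in component c is
beta-binomial around the expected VAF

    xi = ccf_c * purity_c * m / (purity_c * CN_t + (1 - purity_c) * 2)

with fixed precision (default 500) and a total-copy-number prior for the
multiplicity m.  Inference is blocked Gibbs on a truncated stick-breaking
representation of the DP with cluster CCFs on a uniform grid; the
concentration parameter gets a Gamma(1, 1) prior.  Hard clusters are the
connected components of the posterior co-clustering graph at probability
0.5, which is deterministic given the chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp
from scipy.stats import betabinom

from .model import MutationRecord, RunConfig, SegmentProfile

# expected-VAF floor: sequencing error keeps the alt fraction off exact zero
VAF_FLOOR = 1e-3

# prior odds of each additional mutant copy in the multiplicity marginal
MULTIPLICITY_TILT = 0.25

FILTER_RULES = ("a", "b", "c", "d")


@dataclass(frozen=True)
class PairedMutation:
    """One somatic mutation with records from every tumor component."""

    key: tuple  # (chrom, pos, ref, alt)
    records: Mapping[str, MutationRecord]  # component_id -> record

    @property
    def components(self) -> list[str]:
        return sorted(self.records)


def pair_mutations(mutations: Sequence[MutationRecord]) -> list[PairedMutation]:
    """Group a flat mutation list by site across components.

    Every mutation must carry read counts in every component present in the
    input (the upstream pileup-style cross-query is assumed done).
    """
    components = sorted({m.component_id for m in mutations})
    grouped: dict[tuple, dict[str, MutationRecord]] = {}
    for m in mutations:
        grouped.setdefault(m.key(), {})[m.component_id] = m
    out = []
    for key in sorted(grouped, key=lambda k: (k[0], k[1], k[2], k[3])):
        recs = grouped[key]
        missing = [c for c in components if c not in recs]
        if missing:
            raise ValueError(
                f"mutation {key[0]}:{key[1]} {key[2]}>{key[3]} is missing read "
                f"counts for component(s): {', '.join(missing)}"
            )
        out.append(PairedMutation(key=key, records=recs))
    return out


def filter_for_decomposition(
    paired: Sequence[PairedMutation], config: RunConfig | None = None
) -> tuple[list[PairedMutation], dict[str, int]]:
    """Apply the decomposition depth/VAF filters.

    A mutation is retained iff (a) matched-normal depth >= 20, (b) tumor
    depth >= 50 in every component, (c) at least one component's VAF is
    >= 5x the normal VAF, and (d) tumor depth <= 1500 in every component.
    The rejection tally attributes each rejected mutation to the first
    failing rule in (a)-(d) order; retention itself is order-independent.
    """
    config = config or RunConfig()
    tally = {r: 0 for r in FILTER_RULES}
    retained: list[PairedMutation] = []
    for pm in paired:
        recs = list(pm.records.values())
        normal_vaf = max(r.normal_vaf for r in recs)
        failing = None
        if any(r.n_depth < config.min_normal_depth for r in recs):
            failing = "a"
        elif any(r.t_depth < config.min_tumor_depth for r in recs):
            failing = "b"
        elif all(
            r.vaf < config.vaf_multiplier * normal_vaf for r in recs
        ) and normal_vaf > 0:
            failing = "c"
        elif any(r.t_depth > config.max_tumor_depth for r in recs):
            failing = "d"
        if failing is None:
            retained.append(pm)
        else:
            tally[failing] += 1
    return retained, tally


@dataclass(frozen=True)
class CcfEstimate:
    mutation_key: tuple
    component_id: str
    vaf: float
    multiplicity: int
    total_cn: int
    ccf: float
    clipped_ccf: float


def expected_vaf(ccf: float, purity: float, total_cn: int, multiplicity: int) -> float:
    """Expected alt-allele fraction given CCF, purity, local CN and multiplicity."""
    denom = purity * total_cn + (1.0 - purity) * 2.0
    return ccf * purity * multiplicity / denom


def estimate_ccf(
    record: MutationRecord,
    profile: SegmentProfile | None = None,
    purity: float | None = None,
    total_cn: int | None = None,
) -> CcfEstimate:
    """Closed-form CCF with a total-copy-number prior on multiplicity.

    For each multiplicity m in 1..CN_t, invert the expected-VAF relation and
    choose the m whose candidate CCF lies closest to [0, 1] (ties break to
    the smaller m).  The local total copy number comes from the overlapping
    segment; mutations outside any segment default to CN_t = 2 with a
    warning.
    """
    if purity is None:
        if profile is None:
            raise ValueError("either a profile or an explicit purity is required")
        purity = profile.purity
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if total_cn is None:
        seg = profile.segment_at(record.chrom, record.pos) if profile else None
        if seg is None:
            warnings.warn(
                f"mutation {record.chrom}:{record.pos} outside any segment; "
                "defaulting to total copy number 2",
                stacklevel=2,
            )
            total_cn = 2
        else:
            total_cn = seg.total_cn
    if total_cn < 1:
        warnings.warn(
            f"mutation {record.chrom}:{record.pos} in a zero-copy region; "
            "defaulting to total copy number 2",
            stacklevel=2,
        )
        total_cn = 2
    vaf = record.vaf
    denom = purity * total_cn + (1.0 - purity) * 2.0
    best_m, best_ccf, best_dist = 1, 0.0, float("inf")
    for m in range(1, total_cn + 1):
        ccf = vaf * denom / (purity * m)
        dist = max(0.0, ccf - 1.0)  # candidates are never negative
        if dist < best_dist:  # strict: ties keep the smaller m
            best_m, best_ccf, best_dist = m, ccf, dist
    return CcfEstimate(
        mutation_key=record.key(),
        component_id=record.component_id,
        vaf=vaf,
        multiplicity=best_m,
        total_cn=total_cn,
        ccf=best_ccf,
        clipped_ccf=min(1.0, max(0.0, best_ccf)),
    )


@dataclass
class CloneCluster:
    cluster_id: int
    member_keys: list[tuple]
    size: int
    ccf: dict[str, float]                       # component -> posterior mean CCF
    ccf_ci: dict[str, tuple[float, float]]      # component -> 95% credible interval


class CcfClusterModel:
    """Dirichlet-process beta-binomial mixture over per-mutation cluster CCFs.

    Built from filtered paired mutations plus per-component segment profiles
    and purities; ``fit()`` runs the Gibbs sampler and returns a
    :class:`CcfClusterResults`.
    """

    def __init__(
        self,
        paired: Sequence[PairedMutation],
        profiles: Mapping[str, SegmentProfile],
        purities: Mapping[str, float] | None = None,
        config: RunConfig | None = None,
        max_clusters: int = 20,
        grid_size: int = 101,
    ) -> None:
        if not paired:
            raise ValueError("no retained mutations to cluster")
        self.paired = list(paired)
        self.config = config or RunConfig()
        self.components = self.paired[0].components
        self.max_clusters = max(2, min(max_clusters, len(paired) + 1))
        self.grid = np.linspace(0.0, 1.0, grid_size)
        purities = dict(purities or {})
        self.purities = {
            c: purities.get(c, profiles[c].purity) for c in self.components
        }
        self.ccf_estimates: dict[str, list[CcfEstimate]] = {c: [] for c in self.components}
        # Per-component N x G log-likelihood over the CCF grid.  The mutation
        # multiplicity is marginalized over 1..CN_t (total-copy-number prior)
        # with a geometric tilt toward single-copy states: most somatic point
        # mutations sit on one chromatid, and a flat prior leaves a ccf vs
        # ccf/2 degeneracy at even copy numbers.
        self._loglik: dict[str, np.ndarray] = {}
        precision = self.config.beta_binomial_precision
        for c in self.components:
            rows = []
            for pm in self.paired:
                rec = pm.records[c]
                est = estimate_ccf(rec, profiles[c], purity=self.purities[c])
                self.ccf_estimates[c].append(est)
                per_m = []
                log_prior = []
                for m in range(1, est.total_cn + 1):
                    xi = expected_vaf(self.grid, self.purities[c], est.total_cn, m)
                    xi = np.clip(xi, VAF_FLOOR, 1.0 - VAF_FLOOR)
                    per_m.append(
                        betabinom.logpmf(
                            rec.t_alt, rec.t_depth, xi * precision, (1.0 - xi) * precision
                        )
                    )
                    log_prior.append((m - 1) * np.log(MULTIPLICITY_TILT))
                log_prior = np.asarray(log_prior) - logsumexp(log_prior)
                rows.append(logsumexp(np.asarray(per_m) + log_prior[:, None], axis=0))
            self._loglik[c] = np.asarray(rows)

    def fit(self, seed: int | None = None, thin: int = 10) -> "CcfClusterResults":
        """Run blocked Gibbs for the configured iterations and summarize."""
        cfg = self.config
        rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
        N = len(self.paired)
        K = self.max_clusters
        G = len(self.grid)
        comps = self.components
        L = [self._loglik[c] for c in comps]  # each N x G

        # state
        z = rng.integers(0, K, size=N)
        param_idx = [rng.integers(0, G, size=K) for _ in comps]
        alpha = 1.0
        log_w = np.full(K, -np.log(K))

        kept_z: list[np.ndarray] = []
        kept_ccf: list[np.ndarray] = []  # per sample: n_components x N mutation-level CCF

        for it in range(cfg.mcmc_iterations):
            # 1. assignments (jointly, given weights and cluster params)
            loglik_nk = np.zeros((N, K))
            for Lc, idx in zip(L, param_idx):
                loglik_nk += Lc[:, idx]
            logp = log_w[None, :] + loglik_nk
            gumbel = rng.gumbel(size=(N, K))
            z = np.argmax(logp + gumbel, axis=1)

            # 2. stick-breaking weights
            n_k = np.bincount(z, minlength=K)
            tail = np.concatenate([np.cumsum(n_k[::-1])[::-1][1:], [0]])
            v = rng.beta(1.0 + n_k[:-1], alpha + tail[:-1])
            v = np.clip(v, 1e-12, 1.0 - 1e-12)
            log1mv = np.log1p(-v)
            log_w = np.concatenate([[0.0], np.cumsum(log1mv)])
            log_w[:-1] += np.log(v)

            # 3. cluster CCFs on the grid (uniform base measure)
            onehot = np.zeros((K, N))
            onehot[z, np.arange(N)] = 1.0
            for ci in range(len(comps)):
                cluster_grid = onehot @ L[ci]  # K x G
                gumbel_g = rng.gumbel(size=(K, G))
                param_idx[ci] = np.argmax(cluster_grid + gumbel_g, axis=1)

            # 4. DP concentration, Gamma(1, 1) prior (stick-breaking conjugacy)
            alpha = rng.gamma(1.0 + (K - 1), 1.0 / (1.0 - log1mv.sum()))
            alpha = max(alpha, 1e-3)

            if it >= cfg.mcmc_burn_in and (it - cfg.mcmc_burn_in) % thin == 0:
                kept_z.append(z.copy())
                kept_ccf.append(
                    np.stack([self.grid[param_idx[ci]][z] for ci in range(len(comps))])
                )

        return CcfClusterResults(self, np.asarray(kept_z), np.asarray(kept_ccf))


class CcfClusterResults:
    """Posterior summaries of the DP CCF clustering.

    Hard clusters are connected components of the pairwise co-assignment
    graph thresholded at posterior probability 0.5.
    """

    def __init__(
        self, model: CcfClusterModel, z_samples: np.ndarray, ccf_samples: np.ndarray
    ) -> None:
        self.model = model
        self.z_samples = z_samples        # S x N
        self.ccf_samples = ccf_samples    # S x n_components x N
        N = z_samples.shape[1]
        same = (z_samples[:, :, None] == z_samples[:, None, :]).mean(axis=0)
        self.coclustering = same
        adjacency = csr_matrix(same >= 0.5)
        n_clusters, labels = connected_components(adjacency, directed=False)
        self.assignments = labels
        comps = model.components
        clusters = []
        for k in range(n_clusters):
            members = np.flatnonzero(labels == k)
            ccf_mean: dict[str, float] = {}
            ccf_ci: dict[str, tuple[float, float]] = {}
            for ci, c in enumerate(comps):
                draws = self.ccf_samples[:, ci, :][:, members].ravel()
                ccf_mean[c] = float(draws.mean())
                lo, hi = np.quantile(draws, [0.025, 0.975])
                ccf_ci[c] = (float(lo), float(hi))
            clusters.append(
                CloneCluster(
                    cluster_id=k,
                    member_keys=[model.paired[i].key for i in members],
                    size=len(members),
                    ccf=ccf_mean,
                    ccf_ci=ccf_ci,
                )
            )
        # stable presentation: largest mean CCF first
        clusters.sort(key=lambda cl: -np.mean(list(cl.ccf.values())))
        for new_id, cl in enumerate(clusters):
            cl.cluster_id = new_id
        self.clusters = clusters

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def summary(self) -> pd.DataFrame:
        rows = []
        for cl in self.clusters:
            row = {"cluster": cl.cluster_id, "size": cl.size}
            for c in self.model.components:
                row[f"ccf_{c}"] = round(cl.ccf[c], 4)
                lo, hi = cl.ccf_ci[c]
                row[f"ccf_{c}_ci"] = f"[{lo:.2f}, {hi:.2f}]"
            rows.append(row)
        return pd.DataFrame(rows)


def classify_truncal(
    clusters: Sequence[CloneCluster], tolerance: float = 0.1
) -> dict[int, str]:
    """Label clusters truncal or branch.

    A cluster is truncal iff, in every component, its mean CCF is within
    ``tolerance`` of that component's maximum cluster CCF (the modal clonal
    frequency); all other clusters are branch.
    """
    if not clusters:
        raise ValueError("no clusters to classify")
    components = sorted(clusters[0].ccf)
    max_ccf = {c: max(cl.ccf[c] for cl in clusters) for c in components}
    labels = {}
    for cl in clusters:
        truncal = all(cl.ccf[c] >= max_ccf[c] - tolerance for c in components)
        labels[cl.cluster_id] = "truncal" if truncal else "branch"
    return labels


def detect_clonal_selection(
    clusters: Sequence[CloneCluster],
    minor_cutoff: float = 0.3,
    dominant_cutoff: float = 0.7,
    labeling: Mapping[int, str] | None = None,
) -> tuple[str, CloneCluster | None]:
    """Detect a minor subclone of one component becoming dominant in the other.

    For components (A, B) in sorted name order, returns ``selection_in_B``
    when some non-truncal cluster has CCF <= ``minor_cutoff`` in A and
    >= ``dominant_cutoff`` in B (symmetrically for A), together with the
    evidence cluster; ``none`` otherwise.
    """
    if not clusters:
        raise ValueError("no clusters")
    components = sorted(clusters[0].ccf)
    if len(components) != 2:
        raise ValueError("clonal-selection detection requires exactly two components")
    a, b = components
    labeling = labeling or classify_truncal(clusters)
    for cl in clusters:
        if labeling[cl.cluster_id] == "truncal":
            continue
        if cl.ccf[a] <= minor_cutoff and cl.ccf[b] >= dominant_cutoff:
            return "selection_in_B", cl
        if cl.ccf[b] <= minor_cutoff and cl.ccf[a] >= dominant_cutoff:
            return "selection_in_A", cl
    return "none", None


@dataclass
class CloneTree:
    """Two-leaf clone tree: trunk = shared mutations, leaves = private counts."""

    trunk_length: int
    branch_lengths: dict[str, int]

    def to_newick(self) -> str:
        leaves = ",".join(
            f"{name}:{length}" for name, length in sorted(self.branch_lengths.items())
        )
        return f"({leaves})trunk:{self.trunk_length};"


def build_component_tree(
    clusters: Sequence[CloneCluster], labeling: Mapping[int, str]
) -> CloneTree:
    """Aggregate cluster sizes into trunk/branch lengths.

    A branch cluster is assigned to the component where its CCF is higher
    (ties to the alphabetically first component).
    """
    if not clusters:
        raise ValueError("no clusters")
    components = sorted(clusters[0].ccf)
    trunk = 0
    branches = {c: 0 for c in components}
    for cl in clusters:
        if labeling[cl.cluster_id] == "truncal":
            trunk += cl.size
        else:
            target = max(components, key=lambda c: (cl.ccf[c], -components.index(c)))
            branches[target] += cl.size
    return CloneTree(trunk_length=trunk, branch_lengths=branches)
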