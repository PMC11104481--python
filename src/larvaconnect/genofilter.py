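"""Sample- and locus-level genotype filtering.

The rules mirror standard RAD-seq quality control for admixed mussel
collections: drop individuals whose coverage is an extreme low outlier
(more than 3 SDs below the cohort mean fraction of loci at depth >= 5),
collapse technical replicates and close relatives by clustering the
identity-by-state (IBS) distance matrix and keeping one representative
per cluster below the distance threshold, drop poorly called or
near-monomorphic loci, and assign individuals to ancestry clusters with
a minimum admixture-coefficient threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .genotypes import GenotypeDataset, MISSING

__all__ = [
    "FilterConfig",
    "coverage_filter",
    "ibs_distance",
    "prune_relatives",
    "locus_filters",
    "assign_lineages",
    "filter_report",
]


@dataclass(frozen=True)
class FilterConfig:
    ibs_prune_threshold: float = 0.15
    coverage_sd_threshold: float = 3.0
    depth_fraction_min_depth: int = 5  # reads; documents what depth_fraction measures
    locus_presence_min: float = 0.5
    minor_allele_count_min: int = 5
    admixture_assign_threshold: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.ibs_prune_threshold < 1:
            raise ValueError("ibs_prune_threshold must be in (0, 1)")
        if not 0 < self.locus_presence_min <= 1:
            raise ValueError("locus_presence_min must be in (0, 1]")
        if not 0 <= self.admixture_assign_threshold <= 1:
            raise ValueError("admixture_assign_threshold must be in [0, 1]")


def coverage_filter(
    depth_fractions, config: FilterConfig = FilterConfig()
) -> tuple[np.ndarray, np.ndarray, float]:
    """Single-pass low-coverage outlier removal.

    Discards individual ``i`` iff ``depth_fraction(i) < mean - k*SD``
    (population SD over all individuals, computed once — removing a
    passing individual never changes another's verdict).  Returns
    (kept indices, discarded indices, cutoff).
    """
    df = np.asarray(depth_fractions, dtype=float)
    if df.size < 2:
        raise ValueError("need at least 2 individuals")
    cutoff = df.mean() - config.coverage_sd_threshold * df.std()
    discard = df < cutoff
    return np.nonzero(~discard)[0], np.nonzero(discard)[0], float(cutoff)


def ibs_distance(
    genotypes: GenotypeDataset | np.ndarray,
    mode: str = "expected",
    seed: int = 0,
) -> np.ndarray:
    """Pairwise identity-by-state distance matrix in [0, 1].

    ``expected`` (default, deterministic): for each pair the mean over
    co-called loci of ``p_i(1-p_j) + p_j(1-p_i)`` with ``p = dosage/2``
    — the probability that one allele sampled from each individual
    differs.  Two heterozygotes therefore contribute 0.5 even when the
    dosages are identical.  ``sampled``: one allele is drawn per
    individual per locus (seeded) and the distance is the mismatch
    fraction, mimicking single-read IBS sampling.  Missing loci are
    excluded pairwise; a pair with no co-called locus is an error.
    """
    d = genotypes.dosages if isinstance(genotypes, GenotypeDataset) else np.asarray(genotypes)
    called = (d != MISSING).astype(float)
    p = np.where(d == MISSING, 0.0, d / 2.0)
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        p = (rng.random(p.shape) < p).astype(float) * called
    elif mode != "expected":
        raise ValueError("mode must be 'expected' or 'sampled'")

    A = p * called
    N = called @ called.T
    if np.any(N[~np.eye(N.shape[0], dtype=bool)] == 0):
        i, j = np.argwhere((N == 0) & ~np.eye(N.shape[0], dtype=bool))[0]
        raise ValueError(f"individuals {i} and {j} share no co-called locus")
    cross = A @ A.T
    s1 = A @ called.T
    dist = (s1 + s1.T - 2 * cross) / np.maximum(N, 1)
    np.fill_diagonal(dist, 0.0)
    return dist


def prune_relatives(
    ibs: np.ndarray,
    coverage,
    threshold: float = 0.15,
    ids: list[str] | None = None,
) -> tuple[np.ndarray, list[list[int]]]:
    """Collapse replicate/relative clusters to one representative each.

    Single-linkage hierarchical clustering of the IBS distances, cut so
    that individuals joined below ``threshold`` share a cluster; within
    each multi-member cluster the individual with the highest coverage
    metric is kept (ties broken by lexicographically smallest ID).
    Returns (kept indices, list of pruned clusters as index lists).
    """
    ibs = np.asarray(ibs, dtype=float)
    n = ibs.shape[0]
    cov = np.asarray(coverage, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(n)]
    condensed = squareform(ibs, checks=False)
    Z = sch.linkage(condensed, method="single")
    # strict "distance < threshold" merge rule
    labels = sch.fcluster(Z, t=np.nextafter(threshold, 0.0), criterion="distance")
    kept = []
    pruned_clusters: list[list[int]] = []
    for c in np.unique(labels):
        members = np.nonzero(labels == c)[0]
        if members.size == 1:
            kept.append(int(members[0]))
            continue
        order = sorted(members, key=lambda i: (-cov[i], ids[i]))
        kept.append(int(order[0]))
        pruned_clusters.append([int(i) for i in members])
    return np.array(sorted(kept)), pruned_clusters


def locus_filters(
    genotypes: GenotypeDataset | np.ndarray, config: FilterConfig = FilterConfig()
) -> np.ndarray:
    """Boolean keep-mask over loci.

    A locus survives iff it is called in at least ``locus_presence_min``
    of the individuals and its minor allele count — over called
    individuals — is at least ``minor_allele_count_min``.  Idempotent:
    re-filtering the kept loci keeps them all.
    """
    d = genotypes.dosages if isinstance(genotypes, GenotypeDataset) else np.asarray(genotypes)
    called = d != MISSING
    n = d.shape[0]
    called_frac = called.sum(axis=0) / n
    alt = np.where(called, d, 0).sum(axis=0)
    n_called = called.sum(axis=0)
    mac = np.minimum(alt, 2 * n_called - alt)
    return (called_frac >= config.locus_presence_min) & (mac >= config.minor_allele_count_min)


def filter_report(
    data: GenotypeDataset, config: FilterConfig = FilterConfig()
) -> tuple[pd.DataFrame, list[str]]:
    """Run the coverage and locus filters and log every discard with its
    triggering rule.  Returns (per-individual table, log lines)."""
    _, discarded, cutoff = coverage_filter(data.depth_fraction, config)
    lines = []
    for i in discarded:
        lines.append(
            f"individual {data.individuals[i]} discarded: coverage "
            f"{data.depth_fraction[i]:.3f} < cutoff {cutoff:.3f} "
            f"(mean - {config.coverage_sd_threshold:g} SD)"
        )
    called = data.called
    called_frac = called.mean(axis=0)
    alt = np.where(called, data.dosages, 0).sum(axis=0)
    mac = np.minimum(alt, 2 * called.sum(axis=0) - alt)
    keep = locus_filters(data, config)
    for j in np.nonzero(~keep)[0]:
        reasons = []
        if called_frac[j] < config.locus_presence_min:
            reasons.append(f"called fraction {called_frac[j]:.2f} < {config.locus_presence_min}")
        if mac[j] < config.minor_allele_count_min:
            reasons.append(f"minor allele count {mac[j]} < {config.minor_allele_count_min}")
        lines.append(f"locus {j} discarded: " + "; ".join(reasons))
    table = pd.DataFrame(
        {
            "individual": data.individuals,
            "depth_fraction": data.depth_fraction,
            "discarded_low_coverage": np.isin(np.arange(data.n_individuals), discarded),
        }
    )
    return table, lines


def assign_lineages(
    admixture: pd.DataFrame | np.ndarray,
    target: str | int,
    config: FilterConfig = FilterConfig(),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Threshold-based cluster membership and the pure-target subset.

    An individual is a member of every cluster whose coefficient is at
    least the assignment threshold (1 to K memberships).  The
    "pure-target" subset keeps individuals whose summed non-target
    ancestry is below the same threshold — i.e. minimal introgression
    from the other lineages.  Returns (membership booleans, pure row
    indices).
    """
    q = pd.DataFrame(admixture).astype(float)
    rows = q.to_numpy()
    if np.any(rows < -1e-9) or np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("admixture rows must be non-negative and sum to 1")
    thr = config.admixture_assign_threshold
    membership = q >= thr
    tcol = target if target in q.columns else q.columns[int(target)]
    non_target = 1.0 - q[tcol].to_numpy()
    pure = np.nonzero(non_target < thr)[0]
    return membership, pure
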