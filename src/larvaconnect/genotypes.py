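"""Synthetic genotype datasets with known population structure.

Simulates K divergent source populations under the F-model (population
allele frequencies drawn around a common ancestral frequency with drift
parameter F), admixed individuals with recorded true ancestry
proportions, planted technical replicates and close-relative pairs, and
per-individual coverage profiles driving missingness — the structure the
sample-filtering rules are designed to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeSimConfig", "GenotypeDataset", "simulate_genotypes", "hudson_fst"]

MISSING = -1


@dataclass
class GenotypeDataset:
    """Individuals x loci dosage matrix with synthetic truth attached.

    ``dosages`` hold alternate-allele counts in {0, 1, 2} with -1 for
    missing; ``depth_fraction`` is each individual's fraction of loci
    with sequencing depth >= 5 reads (the coverage metric);
    ``true_admixture`` rows are the planted ancestry proportions;
    ``replicate_of``/``relative_of`` point to the partner individual's
    index (-1 when none); ``pop_freqs`` are the simulated per-population
    allele frequencies (truth for oracle checks).
    """

    individuals: list[str]
    dosages: np.ndarray  # (n, L) int8, -1 missing
    depth_fraction: np.ndarray  # (n,)
    pop_label: list[str]
    true_admixture: np.ndarray  # (n, K)
    replicate_of: np.ndarray  # (n,) int, index or -1
    relative_of: np.ndarray  # (n,) int, index or -1
    pop_freqs: np.ndarray = None  # (K, L) synthetic truth
    ancestral_freqs: np.ndarray = None  # (L,)

    def __post_init__(self) -> None:
        d = self.dosages
        if not np.isin(d, [MISSING, 0, 1, 2]).all():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        if np.any(np.abs(self.true_admixture.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("true admixture rows must sum to 1")
        if np.any((self.depth_fraction < 0) | (self.depth_fraction > 1)):
            raise ValueError("depth_fraction must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def called(self) -> np.ndarray:
        return self.dosages != MISSING


@dataclass(frozen=True)
class GenotypeSimConfig:
    """Defaults emulate a strongly structured mussel-like dataset.

    ``drift_f`` controls divergence from the ancestral frequencies
    (F-model; 0 = identical populations).  Coverage is Beta-distributed
    around the mean fraction-of-loci-at-depth>=5 with the given SD, and
    an individual's missing-call rate is one minus its coverage
    fraction.  ``low_coverage_outliers`` individuals get a coverage
    fraction far below the cohort for the coverage filter to catch.
    """

    n_pops: int = 4
    drift_f: tuple[float, ...] | float = 0.3
    n_loci: int = 5000
    n_per_pop: int = 25
    #: (ancestry proportions over K, count) pairs appended as admixed individuals
    admixed: tuple[tuple[tuple[float, ...], int], ...] = (
        ((0.5, 0.5, 0.0, 0.0), 4),
        ((0.8, 0.1, 0.06, 0.04), 4),
    )
    n_replicate_pairs: int = 3
    n_close_relative_pairs: int = 3
    coverage_mean: float = 0.814
    coverage_sd: float = 0.0851
    low_coverage_outliers: int = 0
    low_coverage_value: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValueError("need K >= 2 populations")
        if self.n_loci < 100:
            raise ValueError("need at least 100 loci")
        for q, _ in self.admixed:
            if len(q) != self.n_pops or abs(sum(q) - 1.0) > 1e-9 or min(q) < 0:
                raise ValueError(f"invalid admixture proportions {q}")


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    v = sd**2
    common = mean * (1 - mean) / v - 1.0
    return mean * common, (1 - mean) * common


def simulate_genotypes(config: GenotypeSimConfig = GenotypeSimConfig()) -> GenotypeDataset:
    """Draw a genotype dataset with planted structure; deterministic per seed.

    Ancestral allele frequencies are Uniform(0.05, 0.95); population
    frequencies follow the F-model Beta draw; individual genotypes are
    two Bernoulli gametes at the ancestry-weighted frequency (so dosages
    are Binomial(2, q·p)).  Technical replicates copy their partner's
    genotypes exactly; close relatives share one gamete.  Missingness is
    applied per copy, so replicates differ in which loci are called.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    K, L = cfg.n_pops, cfg.n_loci
    F = np.broadcast_to(np.asarray(cfg.drift_f, dtype=float), (K,))

    p_anc = rng.uniform(0.05, 0.95, size=L)
    pop_freqs = np.empty((K, L))
    for k in range(K):
        if F[k] == 0:
            pop_freqs[k] = p_anc
        else:
            a = p_anc * (1 - F[k]) / F[k]
            b = (1 - p_anc) * (1 - F[k]) / F[k]
            pop_freqs[k] = rng.beta(a, b)
    pop_freqs = np.clip(pop_freqs, 1e-6, 1 - 1e-6)

    Q_rows: list[np.ndarray] = []
    labels: list[str] = []
    names: list[str] = []
    for k in range(K):
        for i in range(cfg.n_per_pop):
            Q_rows.append(np.eye(K)[k])
            labels.append(f"pop{k}")
            names.append(f"pop{k}_{i:03d}")
    for j, (q, count) in enumerate(cfg.admixed):
        for i in range(count):
            Q_rows.append(np.asarray(q, dtype=float))
            labels.append("admixed")
            names.append(f"adm{j}_{i:03d}")
    Q = np.vstack(Q_rows)
    n_base = Q.shape[0]

    ind_freq = Q @ pop_freqs  # (n_base, L)
    gam1 = (rng.random((n_base, L)) < ind_freq).astype(np.int8)
    gam2 = (rng.random((n_base, L)) < ind_freq).astype(np.int8)

    replicate_of = [-1] * n_base
    relative_of = [-1] * n_base
    # replicates/relatives are planted on source-population individuals:
    # admixed genomes have markedly higher heterozygosity, which lifts the
    # expected-IBS distance of even an exact duplicate toward the pruning
    # threshold and would blur the planted structure
    pool = np.array([i for i in range(n_base) if labels[i] != "admixed"])
    rep_parents = rng.choice(pool, size=cfg.n_replicate_pairs, replace=False)
    extra_g1, extra_g2 = [], []
    for r, par in enumerate(rep_parents):
        extra_g1.append(gam1[par])
        extra_g2.append(gam2[par])
        names.append(f"{names[par]}_rep")
        labels.append(labels[par])
        Q = np.vstack([Q, Q[par]])
        replicate_of.append(int(par))
        relative_of.append(-1)
    # close relatives: share one gamete with the parent individual
    rel_parents = rng.choice(
        [i for i in pool if i not in set(rep_parents)],
        size=cfg.n_close_relative_pairs,
        replace=False,
    )
    for par in rel_parents:
        extra_g1.append(gam1[par])  # shared gamete
        own_freq = ind_freq[par]
        extra_g2.append((rng.random(L) < own_freq).astype(np.int8))
        names.append(f"{names[par]}_kin")
        labels.append(labels[par])
        Q = np.vstack([Q, Q[par]])
        replicate_of.append(-1)
        relative_of.append(int(par))

    if extra_g1:
        gam1 = np.vstack([gam1] + [g[None, :] for g in extra_g1])
        gam2 = np.vstack([gam2] + [g[None, :] for g in extra_g2])
    dosages = (gam1 + gam2).astype(np.int8)
    n = dosages.shape[0]

    a, b = _beta_params(cfg.coverage_mean, cfg.coverage_sd)
    depth_fraction = np.clip(rng.beta(a, b, size=n), 0.01, 0.999)
    if cfg.low_coverage_outliers > 0:
        idx = rng.choice(n, size=cfg.low_coverage_outliers, replace=False)
        depth_fraction[idx] = cfg.low_coverage_value
    miss = rng.random((n, L)) > depth_fraction[:, None]
    dosages[miss] = MISSING

    return GenotypeDataset(
        individuals=names,
        dosages=dosages,
        depth_fraction=depth_fraction,
        pop_label=labels,
        true_admixture=Q,
        replicate_of=np.asarray(replicate_of, dtype=int),
        relative_of=np.asarray(relative_of, dtype=int),
        pop_freqs=pop_freqs,
        ancestral_freqs=p_anc,
    )


def hudson_fst(p1: np.ndarray, p2: np.ndarray, n1=None, n2=None) -> float:
    """Hudson's FST from per-locus allele frequencies of two populations.

    With sample sizes ``n1``/``n2`` (haploid counts) the numerator is
    bias-corrected; without them the raw parametric form is used (for
    frequency truth from the simulator).  Ratio-of-averages estimator.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2
    if n1 is not None:
        num = num - p1 * (1 - p1) / (np.asarray(n1) - 1) - p2 * (1 - p2) / (np.asarray(n2) - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())
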