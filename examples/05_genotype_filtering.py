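"""Run the genomic sample-filtering rules on a simulated dataset.

The simulator plants the structure the filters are designed to catch:
four divergent source populations, admixed individuals, technical
replicate pairs (identical genotypes), close-relative pairs (one shared
gamete) and Beta-distributed per-individual coverage with two planted
low-coverage outliers.
"""

import numpy as np

from larvaconnect import (
    GenotypeSimConfig,
    assign_lineages,
    coverage_filter,
    ibs_distance,
    locus_filters,
    prune_relatives,
    simulate_genotypes,
)
import pandas as pd

data = simulate_genotypes(GenotypeSimConfig(seed=1, low_coverage_outliers=2))
print(f"{data.n_individuals} individuals x {data.n_loci} loci")

kept, dropped, cutoff = coverage_filter(data.depth_fraction)
print(f"coverage filter: cutoff {cutoff:.3f}, discarded {dropped.size} individuals")

dist = ibs_distance(data)
kept_ids, clusters = prune_relatives(dist, data.depth_fraction, ids=data.individuals)
pruned = data.n_individuals - kept_ids.size
print(f"IBS pruning (<0.15): {pruned} replicates pruned in {len(clusters)} clusters")

keep_loci = locus_filters(data)
print(f"locus filters (called >=50%, MAC >=5): kept {keep_loci.sum()} of {data.n_loci}")

q = pd.DataFrame(data.true_admixture, columns=["skagerrak", "northsea", "trossulus", "gallo"])
membership, pure = assign_lineages(q, "skagerrak")
print(f"admixture threshold 0.25: {int(membership.sum().sum())} memberships, "
      f"{pure.size} pure-skagerrak individuals")
# the pure subset is what a fine-scale dispersal analysis would keep:
# individuals with < 25% ancestry from the other lineages.
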