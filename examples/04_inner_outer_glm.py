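"""Compare inner- vs outer-archipelago sites with quasi-likelihood GLMs.

Five per-site responses (sites donated to, sites received from, larvae
donated, larvae received, retained vs failed) are contrasted between
enclosed (inner) and open-coast (outer) sites.  Dispersion is estimated
from the Pearson chi-square, so overdispersed counts get conservative
standard errors (quasi-Poisson / quasi-binomial).
"""

from larvaconnect import fit_group_comparison, summarize_sites
from larvaconnect.scenarios import archipelago_domain, run_connectivity

# two fjords so both categories have >= 2 sites for inference
scenario = archipelago_domain(n_sites=14, fjord_lats=(58.25, 58.85))
matrix, _, _ = run_connectivity(scenario, n_per_site=150, release_days=6)
summary = summarize_sites(matrix, {s.site_id: s.category for s in scenario.sites})
print(summary[["category", "n_donated_to", "n_received_from", "retained"]].to_string())

cats = summary["category"].to_numpy()
r = fit_group_comparison(summary["n_donated_to"].to_numpy(), cats, "quasipoisson")
print("\nsites donated to:", r.report())
retained = summary[["retained", "failed"]].to_numpy()
r2 = fit_group_comparison(retained, cats, "quasibinomial")
print("retention:       ", r2.report())
# the retention contrast is strongly positive: enclosed sites keep far
# more larvae locally.  The donated-to contrast sits on the boundary
# (inner sites export to zero sites), so its log-scale estimate diverges
# with an enormous quasi-Poisson SE — the conservative dispersion-based
# errors correctly refuse to call that contrast significant.
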