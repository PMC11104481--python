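"""Inner- vs outer-archipelago comparisons of connectivity summaries.

Five per-site responses are derived from a connectivity matrix — number
of sites donated to, number received from, larvae donated, larvae
received, and locally retained vs. failed — and compared between inner
(land-enclosed) and outer (open-coast) sites with overdispersion-robust
GLMs: Poisson or binomial point estimates with the dispersion estimated
from the Pearson chi-square, i.e. quasi-Poisson / quasi-binomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .settlement import ConnectivityMatrix

__all__ = ["summarize_sites", "GroupComparison", "fit_group_comparison"]


def summarize_sites(matrix: ConnectivityMatrix, categories: dict[int, str]) -> pd.DataFrame:
    """Per-site connectivity summaries.

    Degree counts (``n_donated_to``, ``n_received_from``) use the
    two-decimal display threshold, matching how degrees are read off a
    printed matrix; larval masses are full precision, converted from
    percentages to larva-equivalents via the released counts.
    """
    ids = list(matrix.values.index)
    for i in ids:
        if i not in categories:
            raise KeyError(f"no inner/outer category for site {i}")
    vals = matrix.values.to_numpy()
    released = matrix.released.reindex(ids).to_numpy().astype(float)
    off = vals.copy()
    np.fill_diagonal(off, 0.0)
    larvae_out = off * released[:, None] / 100.0  # larvae i -> j
    retained = np.diag(vals) * released / 100.0
    return pd.DataFrame(
        {
            "site_id": ids,
            "category": [categories[i] for i in ids],
            "n_donated_to": matrix.recipients_per_site.reindex(ids).to_numpy(),
            "n_received_from": matrix.donors_per_site.reindex(ids).to_numpy(),
            "larvae_donated": larvae_out.sum(axis=1),
            "larvae_received": larvae_out.sum(axis=0),
            "retained": retained,
            "failed": released - retained,
            "released": released,
        }
    ).set_index("site_id")


@dataclass(frozen=True)
class GroupComparison:
    """Inner-vs-outer contrast from a quasi-likelihood GLM."""

    estimate: float  # log- (or logit-) scale difference, inner relative to outer
    se: float
    t: float
    p: float
    dispersion: float
    df_resid: int
    family: str

    def report(self) -> str:
        return (
            f"inner - outer = {self.estimate:.3f} ± {self.se:.3f}, "
            f"t = {self.t:.3f}, p = {self.p:.4g} "
            f"({self.family}, dispersion {self.dispersion:.2f}, df {self.df_resid})"
        )


def fit_group_comparison(
    response,
    category,
    family: str = "quasipoisson",
) -> GroupComparison:
    """Fit ``response ~ category`` with a quasi-Poisson or quasi-binomial GLM.

    ``response`` is a per-site count vector (quasi-Poisson) or an
    ``(n, 2)`` array of (successes, failures) (quasi-binomial).
    ``category`` holds the "inner"/"outer" label per site.  The point
    estimates equal the plain Poisson/binomial GLM estimates; the
    dispersion (Pearson chi-square over residual df) only inflates the
    standard errors.  p-values are two-sided on a t distribution with
    n - 2 residual df.
    """
    cat = np.asarray(category)
    y = np.asarray(response, dtype=float)
    if set(np.unique(cat)) - {"inner", "outer"}:
        raise ValueError("categories must be 'inner' or 'outer'")
    if np.unique(cat).size < 2:
        raise ValueError("need both inner and outer sites for a contrast")
    if not np.any(y.sum(axis=-1) > 0):
        raise ValueError("all-zero response cannot be fitted")

    inner = (cat == "inner").astype(float)
    X = sm.add_constant(inner)
    if family == "quasipoisson":
        fam = sm.families.Poisson()
    elif family == "quasibinomial":
        fam = sm.families.Binomial()
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("quasibinomial response must be (successes, failures) pairs")
    else:
        raise ValueError(f"family must be 'quasipoisson' or 'quasibinomial', got {family!r}")

    model = sm.GLM(y, X, family=fam)
    res = model.fit()
    df = int(res.df_resid)
    # Pearson chi^2 / df dispersion -> quasi-likelihood SE inflation
    dispersion = float(res.pearson_chi2) / df if df > 0 else np.nan
    est = float(res.params[1])
    se = float(res.bse[1]) * np.sqrt(dispersion)
    if dispersion < 1e-12:
        # numerically perfect fit: zero dispersion, contrast is null (or
        # degenerate) rather than a 0/0 artefact
        t = 0.0 if abs(est) < 1e-8 else np.sign(est) * np.inf
    else:
        t = est / se
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return GroupComparison(
        estimate=est,
        se=se,
        t=t,
        p=float(p),
        dispersion=dispersion,
        df_resid=df,
        family=family,
    )
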