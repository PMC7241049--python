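"""Associations among kinetics, gas concentrations and MOB abundances.

Ordinary least-squares regressions between per-site quantities (e.g. V_max
vs streamwater CH4) with exact t-based p-values for the slope, explicit
per-analysis site exclusions (outlier sites such as a wetland-draining
stream are excluded by configuration, never hard-coded), the K_S-to-porewater
comparison, and the pmoA contribution to total cell abundance. p-values are
reported raw, matching single-hypothesis usage; a Benjamini–Hochberg helper
is available but off by default.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import AssociationResult, KineticFit, Site

__all__ = [
    "fit_linear",
    "ks_vs_porewater_ratio",
    "pmoa_fraction",
    "benjamini_hochberg",
]


def fit_linear(
    x: pd.Series,
    y: pd.Series,
    exclude: Sequence[str] = (),
    predictor: Optional[str] = None,
    response: Optional[str] = None,
    log_x: bool = False,
    log_y: bool = False,
) -> AssociationResult:
    """OLS of y on x across sites, with explicit exclusions.

    ``log_x``/``log_y`` apply log10 transforms (pmoA counts are conventionally
    log-transformed). p is the exact two-sided t-test for the slope.
    """
    common = x.index.intersection(y.index).difference(pd.Index(exclude))
    xv = x.loc[common].astype(float)
    yv = y.loc[common].astype(float)
    mask = xv.notna() & yv.notna()
    xv, yv = xv[mask], yv[mask]
    if len(xv) < 3:
        raise ValueError("need at least 3 sites after exclusion")
    if log_x:
        xv = np.log10(xv)
    if log_y:
        yv = np.log10(yv)
    if np.std(xv) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(xv, yv)
    return AssociationResult(
        predictor=predictor or (x.name or "x"),
        response=response or (y.name or "y"),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue ** 2),
        p=float(res.pvalue),
        n=len(xv),
        excluded_sites=sorted(set(exclude) & set(x.index)),
    )


def ks_vs_porewater_ratio(
    fits: Sequence[KineticFit],
    sites: Sequence[Site],
    exclude: Sequence[str] = (),
) -> dict:
    """Per-site K_S as a percentage of porewater CH4, plus mean and range.

    Sites with V_max = 0 (no detectable MOX) are excluded automatically;
    additional exclusions (e.g. a site with near-zero porewater CH4 that
    would explode the percentage) are explicit.
    """
    pore = {s.site_id: s.ch4_pore for s in sites}
    per_site = {}
    for fit in fits:
        if fit.site_id in exclude or fit.v_max == 0.0:
            continue
        p = pore.get(fit.site_id)
        if p is None:
            continue
        if p <= 0:
            raise ValueError(f"site {fit.site_id}: porewater CH4 must be > 0")
        per_site[fit.site_id] = 100.0 * fit.k_s / p
    if not per_site:
        raise ValueError("all sites excluded from the K_S/porewater comparison")
    vals = np.array(list(per_site.values()))
    return {
        "per_site_pct": per_site,
        "mean_pct": float(vals.mean()),
        "min_pct": float(vals.min()),
        "max_pct": float(vals.max()),
    }


def pmoa_fraction(pmoa, cells, censored=None):
    """pmoA-harbouring cells as a percentage of total cell abundance.

    Assumes one pmoA copy per genome, so copies m⁻² are read as cells m⁻².
    Censored (below-detection) pmoA values propagate as NaN percent.
    """
    pmoa = pd.Series(pmoa) if not isinstance(pmoa, pd.Series) else pmoa
    cells = pd.Series(cells) if not isinstance(cells, pd.Series) else cells
    if (cells <= 0).any():
        raise ValueError("total cell abundance must be positive")
    pct = 100.0 * pmoa / cells
    if censored is not None:
        pct = pct.where(~pd.Series(censored, index=pct.index), np.nan)
    return pct


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; raw p is the default
    reporting convention here)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
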