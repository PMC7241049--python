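"""Community-landscape analysis of OTU tables.

The landscape procedure (enterotype-style community typing applied to OTU
scores): ordinate sites by non-metric multidimensional scaling (nMDS) of
Bray–Curtis dissimilarities on relative abundances, place every OTU in the
ordination plane as the relative-abundance-weighted average of the scores of
the sites it occurs in, estimate a 2-D Gaussian kernel density over those
species scores ("community landscape"), call peaks as connected regions
above a density cutoff, cluster the methanotroph (MOB) OTU scores with
k-means (k = 2, with a distance-based outlier rule for unassignable OTUs),
draw a convex hull around each MOB cluster, and report the non-MOB OTUs
co-occurring inside each hull together with their taxonomic
overrepresentation relative to the whole community.

Also provides the environmental ordination: PCA of site variables with
envfit-style vector fitting (permutation p-values) and a smooth surface fit
of a per-site variable over ordination scores.

nMDS is implemented as SMACOF majorization with Kruskal's monotone (isotonic)
regression and stress-1, best of several seeded restarts, because the
per-iteration stress trace and the stress-1 normalisation are part of this
module's contract; scikit-learn's non-metric MDS is used as an independent
cross-check in the test-suite only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RBFInterpolator
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.isotonic import isotonic_regression

from .types import LandscapeResult, OrdinationResult, OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_MOB_TAXA",
    "relative_abundance",
    "bray_curtis",
    "nmds",
    "species_scores",
    "pca_env",
    "fit_vectors",
    "fit_surface",
    "density_landscape",
    "find_peaks",
    "cluster_mob",
    "hull_members",
    "overrepresentation",
    "mob_flags_from_taxonomy",
    "exclude_sparse_sites",
    "community_landscape",
]

DEFAULT_MOB_TAXA = ("Methylococcaceae",)


def relative_abundance(table) -> pd.DataFrame:
    """Per-site relative abundances (rows sum to 1)."""
    counts = table.counts if isinstance(table, OtuTable) else pd.DataFrame(table)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0])
        raise ValueError(f"sites with zero total counts: {empty}")
    return counts.div(totals, axis=0)


def bray_curtis(abundances: pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis dissimilarity between site rows (in [0, 1])."""
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    if np.any(x.sum(axis=1) == 0):
        raise ValueError("all-zero row has undefined Bray-Curtis dissimilarity")
    d = squareform(pdist(x, metric="braycurtis"))
    idx = abundances.index if isinstance(abundances, pd.DataFrame) else None
    return pd.DataFrame(d, index=idx, columns=idx)


# ---------------------------------------------------------------------------
# nMDS (SMACOF + isotonic regression, Kruskal stress-1)
# ---------------------------------------------------------------------------

def _stress1_iterate(x: np.ndarray, d_flat: np.ndarray, order: np.ndarray):
    """One stress evaluation + disparity computation for configuration x."""
    dist = pdist(x)
    dhat = np.empty_like(dist)
    dhat[order] = isotonic_regression(dist[order])
    ss_dist = np.sum(dist ** 2)
    stress = np.sqrt(np.sum((dist - dhat) ** 2) / ss_dist)
    # rescale disparities to the distances' sum of squares: keeps the
    # configuration from shrinking to a point across majorization steps
    ss_dhat = np.sum(dhat ** 2)
    if ss_dhat > 0:
        dhat = dhat * np.sqrt(ss_dist / ss_dhat)
    return dist, dhat, stress


def _guttman(x: np.ndarray, dist: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, dhat / dist, 0.0)
    b = -squareform(ratio)
    np.fill_diagonal(b, -b.sum(axis=1))
    return b @ x / n


def nmds(
    d,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1 by SMACOF majorization.

    The first restart is initialised from classical (metric) scaling, the
    rest from seeded random configurations; the lowest-stress solution is
    returned, centred and rotated to its principal axes. Per-restart stress
    traces are kept in ``stress_history``.
    """
    dm = d.values if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    n = dm.shape[0]
    if dm.shape != (n, n) or not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("d must be a square symmetric dissimilarity matrix")
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for {k}-D nMDS")
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    d_flat = squareform(dm, checks=False)
    # sort by dissimilarity, ties broken stably
    order = np.argsort(d_flat, kind="stable")
    rng = np.random.default_rng(seed)

    # classical-scaling start
    j = np.eye(n) - np.ones((n, n)) / n
    b0 = -0.5 * j @ (dm ** 2) @ j
    evals, evecs = np.linalg.eigh(b0)
    idx = np.argsort(evals)[::-1][:k]
    x_cmds = evecs[:, idx] * np.sqrt(np.maximum(evals[idx], 1e-12))

    best_x, best_stress, histories, best_conv = None, np.inf, [], False
    for start in range(n_starts):
        x = x_cmds.copy() if start == 0 else rng.normal(size=(n, k))
        hist = []
        converged = False
        dist, dhat, stress = _stress1_iterate(x, d_flat, order)
        hist.append(stress)
        for _ in range(max_iter):
            x = _guttman(x, dist, dhat)
            rms = np.sqrt(np.mean(np.sum(x ** 2, axis=1)))
            if rms > 0:
                x = x / rms
            dist, dhat, new_stress = _stress1_iterate(x, d_flat, order)
            hist.append(new_stress)
            if abs(stress - new_stress) < tol:
                converged = True
                stress = new_stress
                break
            stress = new_stress
        histories.append(np.array(hist))
        if stress < best_stress:
            best_stress, best_x, best_conv = stress, x, converged
    if not best_conv:
        logger.warning("nMDS best restart did not converge within %d iterations",
                       max_iter)
    # centre and rotate to principal axes
    x = best_x - best_x.mean(axis=0)
    rot = PCA(n_components=k).fit(x)
    x = rot.transform(x)
    scores = pd.DataFrame(x, index=index,
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(sample_scores=scores, species_scores=None,
                            stress=float(best_stress), explained=None,
                            method="nmds", converged=best_conv,
                            stress_history=histories)


def species_scores(ord_result: OrdinationResult,
                   abundances: pd.DataFrame) -> pd.DataFrame:
    """OTU scores: relative-abundance-weighted averages of the sample scores."""
    x = ord_result.sample_scores
    ab = abundances.loc[x.index]
    totals = ab.sum(axis=0)
    keep = totals[totals > 0].index
    w = ab[keep] / totals[keep]
    return pd.DataFrame(w.T.values @ x.values, index=keep, columns=x.columns)


# ---------------------------------------------------------------------------
# environment ordination
# ---------------------------------------------------------------------------

def pca_env(env: pd.DataFrame, scale: bool = True) -> OrdinationResult:
    """PCA of site-level environmental variables (centred, optionally scaled)."""
    x = env.values.astype(float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = list(env.columns[sd == 0])
            raise ValueError(f"constant columns cannot be scaled: {bad}")
        x = x / sd
    k = min(x.shape[0] - 1, x.shape[1])
    p = PCA(n_components=k).fit(x)
    scores = pd.DataFrame(p.transform(x), index=env.index,
                          columns=[f"PC{i + 1}" for i in range(k)])
    loadings = pd.DataFrame(p.components_.T, index=env.columns,
                            columns=scores.columns)
    return OrdinationResult(sample_scores=scores, species_scores=loadings,
                            stress=float("nan"),
                            explained=p.explained_variance_ratio_, method="pca")


def fit_vectors(
    ord_result: OrdinationResult,
    variables: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    k: int = 2,
) -> pd.DataFrame:
    """envfit-style vector fitting of variables onto ordination scores.

    Each variable is regressed on the first ``k`` score axes; the direction
    is the unit regression vector, R² the squared multiple correlation, and
    the p-value comes from permuting the variable across sites.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    x = ord_result.sample_scores.iloc[:, :k].values
    xc = x - x.mean(axis=0)
    rng = np.random.default_rng(seed)
    rows = {}
    for name in variables.columns:
        y = variables[name].loc[ord_result.sample_scores.index].values.astype(float)
        if np.std(y) == 0:
            raise ValueError(f"variable {name!r} is constant")
        yc = y - y.mean()

        def r2_of(yv):
            beta, *_ = np.linalg.lstsq(xc, yv, rcond=None)
            fitted = xc @ beta
            ss = np.sum(yv ** 2)
            return (np.sum(fitted * yv) ** 2 / (np.sum(fitted ** 2) * ss)
                    if np.sum(fitted ** 2) > 0 else 0.0), beta

        r2, beta = r2_of(yc)
        exceed = 0
        for _ in range(n_perm):
            yp = rng.permutation(yc)
            r2p, _ = r2_of(yp)
            if r2p >= r2:
                exceed += 1
        direction = beta / np.linalg.norm(beta) if np.linalg.norm(beta) > 0 else beta
        rows[name] = {
            **{f"axis{i + 1}": direction[i] for i in range(k)},
            "r2": float(r2),
            "p": (exceed + 1) / (n_perm + 1),
        }
    return pd.DataFrame(rows).T


@dataclass
class SurfaceFit:
    """Penalised thin-plate surface over 2-D ordination scores."""

    interpolator: RBFInterpolator
    smoothing: float
    loo_r2: float

    def predict(self, points: np.ndarray) -> np.ndarray:
        return self.interpolator(np.asarray(points, dtype=float))


def fit_surface(
    ord_result: OrdinationResult,
    values: pd.Series,
    smoothing_grid: Optional[Sequence[float]] = None,
) -> SurfaceFit:
    """Fit a smooth surface of a per-site variable over the ordination plane.

    A thin-plate-spline radial basis with a ridge (smoothing) penalty chosen
    by leave-one-out cross-validation; the reported ``loo_r2`` is the LOO R²
    at the selected penalty. A simplification of a full generalized additive
    model, adequate for the ~14-site panels this package targets.
    """
    x = ord_result.sample_scores.iloc[:, :2].values
    y = values.loc[ord_result.sample_scores.index].values.astype(float)
    n = len(y)
    if n < 6:
        raise ValueError("need at least 6 sites for a surface fit")
    if smoothing_grid is None:
        smoothing_grid = [0.0, 1e-6, 1e-4, 1e-2, 1e-1, 1.0, 10.0]
    var_y = np.var(y)
    best = None
    for s in smoothing_grid:
        preds = np.empty(n)
        try:
            for i in range(n):
                mask = np.arange(n) != i
                rbf = RBFInterpolator(x[mask], y[mask], kernel="thin_plate_spline",
                                      smoothing=s)
                preds[i] = rbf(x[i:i + 1])[0]
        except np.linalg.LinAlgError:
            continue
        press = np.sum((preds - y) ** 2)
        loo_r2 = 1.0 - press / (n * var_y) if var_y > 0 else 1.0
        if best is None or press < best[0]:
            best = (press, s, loo_r2)
    _, s_best, loo_r2 = best
    final = RBFInterpolator(x, y, kernel="thin_plate_spline", smoothing=s_best)
    return SurfaceFit(interpolator=final, smoothing=s_best,
                      loo_r2=float(max(loo_r2, 0.0) if var_y > 0 else 1.0))


# ---------------------------------------------------------------------------
# density landscape
# ---------------------------------------------------------------------------

def density_landscape(
    scores: pd.DataFrame,
    bandwidth="scott",
    grid_n: int = 150,
    margin: float = 0.05,
):
    """2-D Gaussian kernel density of OTU scores on a regular grid.

    Returns ``(grid_x, grid_y, density)`` with the grid covering the scores
    plus a 5 % margin; density is a probability density (integrates to ~1).
    """
    pts = np.asarray(scores, dtype=float)[:, :2]
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 OTUs for a density landscape")
    if np.allclose(pts.std(axis=0), 0):
        raise ValueError("degenerate (all-identical) scores")
    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    # margin covers at least the kernel tails so the grid captures ~all mass
    bw = 3.0 * np.sqrt(np.diag(kde.covariance))
    pad = np.maximum(margin * span, bw)
    lo, hi = lo - pad, hi + pad
    gx = np.linspace(lo[0], hi[0], grid_n)
    gy = np.linspace(lo[1], hi[1], grid_n)
    xx, yy = np.meshgrid(gx, gy)
    z = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return gx, gy, z


def find_peaks(grid_x, grid_y, density, cutoff: float = 0.5) -> list[dict]:
    """Peaks: 8-connected components of {density > cutoff}.

    Each peak is reported at its grid maximum with its height; an empty list
    when the cutoff exceeds the global maximum.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    mask = density > cutoff
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    peaks = []
    for lab in range(1, n + 1):
        comp = np.where(labels == lab, density, -np.inf)
        iy, ix = np.unravel_index(np.argmax(comp), comp.shape)
        peaks.append({"x": float(grid_x[ix]), "y": float(grid_y[iy]),
                      "height": float(density[iy, ix])})
    peaks.sort(key=lambda p: -p["height"])
    return peaks


# ---------------------------------------------------------------------------
# MOB clustering and co-occurrence
# ---------------------------------------------------------------------------

def cluster_mob(
    mob_scores: pd.DataFrame,
    k: int = 2,
    n_init: int = 20,
    seed: int = 0,
    outlier_rule: float = 3.0,
) -> pd.Series:
    """k-means clustering of MOB OTU scores with a distance-based outlier rule.

    OTUs farther from every centroid than ``outlier_rule`` × the cluster's
    median member-to-centroid radius are labelled 0 (unassigned), mirroring
    low-abundance methanotrophs that fall outside both co-occurrence
    clusters. Clusters are relabelled 1..k by decreasing size.
    """
    x = np.asarray(mob_scores, dtype=float)[:, :2]
    if x.shape[0] < k:
        raise ValueError(f"need at least {k} MOB OTUs for k={k} clustering")

    def robust_rule(raw):
        """Flag points far from their cluster's robust core.

        The cluster centre is the coordinate-wise median of its members
        (insensitive to a minority of stray points that k-means may have
        attached) and the radius is the median distance of the closer half
        of the members to that centre; a floor tied to the centre
        separation keeps very tight blobs from flagging themselves.
        """
        centres = np.array([np.median(x[raw == c], axis=0) for c in range(k)])
        if k > 1:
            sep = min(np.linalg.norm(a - b)
                      for i, a in enumerate(centres) for b in centres[i + 1:])
        else:
            sep = 0.0
        flags = np.zeros(len(x), dtype=bool)
        if outlier_rule <= 0 or k < 2:
            return flags
        for c in range(k):
            member = raw == c
            d = np.linalg.norm(x[member] - centres[c], axis=1)
            half = np.sort(d)[: max(1, (len(d) + 1) // 2)]
            rad = np.median(half)
            scale = max(rad, 0.05 * sep, 1e-12)
            flags[member] = d > outlier_rule * scale
        return flags

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    raw = km.labels_
    flags = robust_rule(raw)
    if outlier_rule > 0 and k > 1:
        # a cluster with fewer than 3 members is a stray coalition, not a
        # co-occurrence group; treat its members as outlier candidates
        sizes = np.bincount(raw, minlength=k)
        flags |= sizes[raw] < 3
    if flags.any() and (~flags).sum() >= k:
        # refit on the retained OTUs so strays cannot drag the centroids,
        # then re-apply the distance rule against the refined clusters
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x[~flags])
        raw = km.predict(x)
        flags = robust_rule(raw)
    labels = raw + 1
    labels[flags] = 0
    # relabel by decreasing cluster size (after outlier removal)
    sizes = {c: int(np.sum((labels == c))) for c in range(1, k + 1)}
    order = sorted(sizes, key=lambda c: -sizes[c])
    remap = {old: new + 1 for new, old in enumerate(order)}
    remap[0] = 0
    out = pd.Series([remap[l] for l in labels], index=mob_scores.index,
                    name="mob_cluster")
    return out


def _points_in_hull(points: np.ndarray, hull_points: np.ndarray) -> np.ndarray:
    """Boolean mask of points inside (boundary included) the convex hull."""
    try:
        hull = ConvexHull(hull_points)
        tri = Delaunay(hull_points[hull.vertices])
        return tri.find_simplex(points) >= 0
    except QhullError:
        # collinear cluster: buffered segment fallback
        warnings.warn("degenerate (collinear) hull; using buffered segment",
                      stacklevel=2)
        a = hull_points[np.argmin(hull_points[:, 0] + hull_points[:, 1])]
        b = hull_points[np.argmax(hull_points[:, 0] + hull_points[:, 1])]
        seg = b - a
        seg_len2 = max(np.dot(seg, seg), 1e-300)
        rel = points - a
        t = np.clip(rel @ seg / seg_len2, 0.0, 1.0)
        proj = a + t[:, None] * seg
        dist = np.linalg.norm(points - proj, axis=1)
        buffer = 1e-6 * max(np.sqrt(seg_len2), 1.0)
        return dist <= buffer


def hull_members(
    cluster_scores: pd.DataFrame,
    all_scores: pd.DataFrame,
    mob_flags: pd.Series,
) -> list[str]:
    """Non-MOB OTUs inside the convex hull of a MOB cluster's scores."""
    if len(cluster_scores) < 3:
        raise ValueError("need at least 3 cluster points for a hull")
    inside = _points_in_hull(np.asarray(all_scores, dtype=float)[:, :2],
                             np.asarray(cluster_scores, dtype=float)[:, :2])
    flags = mob_flags.reindex(all_scores.index).fillna(False).astype(bool)
    return [otu for otu, inc, mob in zip(all_scores.index, inside, flags)
            if inc and not mob]


def _taxon_at_rank(lineage: str, rank: int) -> str:
    parts = [p.strip() for p in str(lineage).split(";")]
    if len(parts) <= rank or not parts[rank] or parts[rank].startswith("g__"):
        return "unclassified"
    return parts[rank]


def overrepresentation(
    members: Sequence[str],
    taxonomy: pd.Series,
    background: Sequence[str],
    rank: int = 2,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Taxonomic overrepresentation of a member OTU set vs the background.

    For every taxon at ``rank`` (0 = domain, 2 = class by default): its share
    among member OTUs, its share in the background, and the ratio of the two.
    With ``n_perm`` > 0, a one-sided permutation p (random member sets of
    equal size drawn from the background) is added.
    """
    members = list(members)
    background = list(background)
    if not members:
        raise ValueError("empty member list")
    if not set(members) <= set(background):
        raise ValueError("members must be a subset of the background")
    tax_bg = pd.Series({o: _taxon_at_rank(taxonomy.loc[o], rank)
                        for o in background})
    tax_mem = tax_bg.loc[members]
    share_bg = tax_bg.value_counts(normalize=True)
    share_in = tax_mem.value_counts(normalize=True).reindex(share_bg.index,
                                                            fill_value=0.0)
    out = pd.DataFrame({"share_in": share_in, "share_bg": share_bg})
    out["ratio"] = out["share_in"] / out["share_bg"]
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        bg_arr = tax_bg.values
        m = len(members)
        exceed = pd.Series(0, index=out.index, dtype=float)
        for _ in range(n_perm):
            perm = pd.Series(rng.choice(bg_arr, size=m, replace=False))
            ps = perm.value_counts(normalize=True).reindex(out.index,
                                                           fill_value=0.0)
            exceed += (ps >= share_in).astype(float)
        out["p"] = (exceed + 1) / (n_perm + 1)
    return out.sort_values("ratio", ascending=False)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def mob_flags_from_taxonomy(
    taxonomy: pd.Series, markers: Sequence[str] = DEFAULT_MOB_TAXA
) -> pd.Series:
    """Flag OTUs whose lineage mentions any methanotroph marker taxon."""
    return taxonomy.astype(str).apply(
        lambda s: any(m in s for m in markers)).rename("is_mob")


def exclude_sparse_sites(table: OtuTable, min_mob_otus: int = 2):
    """Drop sites with fewer MOB OTUs than ``min_mob_otus`` (the landscape
    exclusion rule for extremely oligotrophic samples)."""
    mob_cols = table.is_mob[table.is_mob].index
    present = (table.counts[mob_cols] > 0).sum(axis=1)
    keep = present >= min_mob_otus
    excluded = list(table.counts.index[~keep])
    sub = OtuTable(counts=table.counts.loc[keep].copy(),
                   taxonomy=table.taxonomy, is_mob=table.is_mob)
    return sub, excluded


def community_landscape(
    table: OtuTable,
    k: int = 2,
    cutoff: float = 0.5,
    seed: int = 0,
    bandwidth="scott",
    grid_n: int = 150,
    outlier_rule: float = 3.0,
    min_mob_otus: int = 2,
    n_starts: int = 20,
    overrep_rank: int = 2,
) -> tuple[LandscapeResult, OrdinationResult]:
    """Run the full community-landscape pipeline on an OTU table."""
    sub, excluded = exclude_sparse_sites(table, min_mob_otus)
    if excluded:
        logger.info("excluded sites with <%d MOB OTUs: %s", min_mob_otus, excluded)
    ab = relative_abundance(sub)
    d = bray_curtis(ab)
    ordn = nmds(d, k=2, n_starts=n_starts, seed=seed)
    sp = species_scores(ordn, ab)
    ordn.species_scores = sp
    gx, gy, dens = density_landscape(sp, bandwidth=bandwidth, grid_n=grid_n)
    peaks = find_peaks(gx, gy, dens, cutoff=cutoff)
    mob_ids = [o for o in sp.index if table.is_mob.get(o, False)]
    clusters = cluster_mob(sp.loc[mob_ids], k=k, seed=seed,
                           outlier_rule=outlier_rule)
    hulls: dict[int, list[str]] = {}
    overrep: dict[int, pd.DataFrame] = {}
    for c in sorted(set(clusters) - {0}):
        members_scores = sp.loc[clusters.index[clusters == c]]
        if len(members_scores) < 3:
            logger.warning("cluster %d has <3 members; no hull", c)
            continue
        hulls[c] = hull_members(members_scores, sp, table.is_mob)
        if hulls[c]:
            overrep[c] = overrepresentation(hulls[c], table.taxonomy,
                                            list(sp.index), rank=overrep_rank)
    result = LandscapeResult(grid_x=gx, grid_y=gy, density=dens, peaks=peaks,
                             mob_clusters=clusters, hull_members=hulls,
                             overrep=overrep, excluded_sites=excluded)
    return result, ordn
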