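"""Population structure: dosage PCA, AIC-based k-means clustering, karyotype
and allozyme-genotype labeling, heterozygosity, Weir-Cockerham F_ST, LD r².

Karyotype inference follows the clustering logic for a polymorphic inversion:
whole-linkage-group PCA separates the two homokaryotype groups along PC1 with
heterokaryotypes intermediate; the heterokaryotype cluster is the one with
clearly elevated mean observed heterozygosity (expected about twice the
homokaryotype level), and the L vs D homokaryotype labels key on mean body
size (the L arrangement rides with the large ecotype) with a manual override.
The designated allozyme contig shows six clusters (three divergent haplotypes
in all diploid combinations) forming a triangle in PC space: homozygotes in
the corners, heterozygotes at mid-edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genio import MISSING, GenotypeMatrix

__all__ = [
    "PcaResult",
    "ClusterResult",
    "KaryotypeCall",
    "pca",
    "cluster_genotypes",
    "call_karyotypes",
    "call_ak_genotypes",
    "observed_heterozygosity",
    "individual_heterozygosity",
    "wc_fst",
    "ld_r2",
    "summarize_region",
]


@dataclass
class PcaResult:
    scores: np.ndarray  # individuals x components
    explained_variance_ratio: np.ndarray
    mean_dosage: np.ndarray


def pca(g: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Dosage PCA: per-site mean imputation of missing calls, mean centering,
    no variance scaling."""
    if g.n_samples < 2 or g.n_sites < 1:
        raise ValueError("need at least 2 individuals and 1 site")
    X = g.dosages.T.astype(float)  # individuals x sites
    miss = X == MISSING
    site_mean = np.where(miss, 0.0, X).sum(axis=0) / np.maximum(
        (~miss).sum(axis=0), 1)
    X = np.where(miss, site_mean[None, :], X)
    X -= X.mean(axis=0, keepdims=True)
    total_var = np.sum(X**2) / (g.n_samples - 1)
    if total_var < 1e-12:
        raise ValueError("zero-variance genotype matrix")
    n_components = min(n_components, g.n_samples - 1, g.n_sites)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    evr = (S[:n_components] ** 2 / (g.n_samples - 1)) / total_var
    # deterministic orientation: largest-magnitude loading positive
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return PcaResult(scores, evr, site_mean)


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    aic_by_k: dict[int, float]
    centers: np.ndarray


def cluster_genotypes(scores: np.ndarray, k_candidates=range(1, 11),
                      seed: int = 0, n_restarts: int = 20,
                      delta: float = 4.0,
                      criterion: str = "aic") -> ClusterResult:
    """k-means over ``k_candidates`` with k chosen by an information score.

    The score is n ln(WSS/n) + penalty, from the total within-cluster sum of
    squares (spherical-Gaussian within-cluster likelihood profiled over its
    single variance): penalty 2k for ``criterion="aic"``, k ln(n) for
    ``"bic"``.  The smallest k whose score is within ``delta`` units of the
    minimum is retained — the same more-parameters-must-earn-their-keep rule
    the cline model competition uses.  AIC's per-cluster penalty of 2 is
    weak when clusters are near-discrete (it keeps paying for splitting off
    small clumps such as mean-imputed individuals); BIC is the usual remedy
    and the default of the reference clustering workflow.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    ks = sorted(set(int(k) for k in k_candidates))
    if not all(1 <= k <= 10 for k in ks):
        raise ValueError("k_candidates must lie in 1..10")
    if n < max(ks):
        raise ValueError("fewer observations than the largest candidate k")
    aic_by_k: dict[int, float] = {}
    fits = {}
    for k in ks:
        if k == 1:
            labels = np.zeros(n, dtype=int)
            centers = X.mean(axis=0, keepdims=True)
            wss = float(np.sum((X - centers) ** 2))
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            labels = km.fit_predict(X)
            centers = km.cluster_centers_
            wss = float(km.inertia_)
        pen = 2.0 * k if criterion == "aic" else k * np.log(n)
        aic_by_k[k] = n * np.log(max(wss, 1e-12) / n) + pen
        fits[k] = (labels, centers)
    best_aic = min(aic_by_k.values())
    k = min(kk for kk, v in aic_by_k.items() if v <= best_aic + delta)
    labels, centers = fits[k]
    # stable label order: clusters renumbered by their PC1 center
    order = np.argsort(centers[:, 0], kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(k)
    return ClusterResult(remap[labels], k, aic_by_k, centers[order])


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------


def observed_heterozygosity(g: GenotypeMatrix, group=None) -> float:
    """Mean observed heterozygosity across SNPs for one group of individuals.

    Per site, H_obs is the fraction of non-missing genotypes that are
    heterozygous; sites with no calls in the group are excluded.
    """
    sub = g if group is None else g.take_samples(np.asarray(group))
    if sub.n_samples == 0:
        raise ValueError("empty group")
    h = sub.hobs_per_site()
    return float(np.nanmean(h))


def individual_heterozygosity(g: GenotypeMatrix) -> np.ndarray:
    """Per-individual fraction of called sites that are heterozygous."""
    called = g.called()
    n = np.maximum(called.sum(axis=0), 1)
    return (g.dosages == 1).sum(axis=0) / n


# ---------------------------------------------------------------------------
# karyotype and allozyme-genotype labeling
# ---------------------------------------------------------------------------


@dataclass
class KaryotypeCall:
    karyotype: pd.Series  # per individual: L/L, L/D, D/D
    cluster_labels: np.ndarray
    cluster_to_karyotype: dict[int, str]
    cluster_hobs: dict[int, float]


def call_karyotypes(g: GenotypeMatrix, clusters: ClusterResult,
                    samples: pd.DataFrame, size_col: str = "size_mm",
                    het_tolerance: float = 0.03,
                    large_cluster: int | None = None) -> KaryotypeCall:
    """Label the three whole-LG clusters as L/L, L/D, D/D.

    The heterokaryotype cluster is the one with the highest mean observed
    heterozygosity; an ordering margin below ``het_tolerance`` raises (manual
    labels required).  Between the homokaryotype clusters, L/L is the one
    with larger mean body size unless ``large_cluster`` overrides.
    """
    if clusters.k != 3:
        raise ValueError("karyotype calling expects a k=3 clustering")
    labels = clusters.labels
    hobs = {c: observed_heterozygosity(g, labels == c) for c in range(3)}
    ranked = sorted(hobs, key=hobs.get, reverse=True)
    if hobs[ranked[0]] - hobs[ranked[1]] < het_tolerance:
        raise ValueError(
            "ambiguous heterozygosity ordering among clusters "
            f"({hobs}); provide manual labels")
    het_c = ranked[0]
    homo = [c for c in range(3) if c != het_c]
    if large_cluster is not None:
        if large_cluster not in homo:
            raise ValueError("large_cluster override must be a homokaryotype "
                             "cluster")
        ll_c = large_cluster
    else:
        sizes = samples[size_col].to_numpy(float)
        mean_size = {c: float(np.nanmean(sizes[labels == c])) for c in homo}
        ll_c = max(mean_size, key=mean_size.get)
    dd_c = next(c for c in homo if c != ll_c)
    mapping = {ll_c: "L/L", het_c: "L/D", dd_c: "D/D"}
    karyo = pd.Series([mapping[c] for c in labels], index=samples["id"].values,
                      name="karyotype")
    return KaryotypeCall(karyo, labels, mapping, hobs)


def call_ak_genotypes(g_ak: GenotypeMatrix, clusters: ClusterResult,
                      karyotypes: pd.Series) -> pd.Series:
    """Label the six allozyme-contig clusters with their allele pairs.

    Geometry + karyotype constraints: the corner (low-H_obs) cluster made of
    D/D snails is 120/120; each mid-edge (high-H_obs) cluster is the
    heterozygote between the two corners whose centroid midpoint it sits
    nearest; of the two L corners, the rarer allele is 80.
    """
    if clusters.k != 6:
        raise ValueError("allozyme genotype calling expects a k=6 clustering")
    labels = clusters.labels
    hobs = {c: observed_heterozygosity(g_ak, labels == c) for c in range(6)}
    ranked = sorted(hobs, key=hobs.get)
    corners, mids = ranked[:3], ranked[3:]
    kt = karyotypes.to_numpy()
    # corner carrying the D/D individuals is the 120 homozygote
    dd_frac = {c: np.mean(kt[labels == c] == "D/D") for c in corners}
    c120 = max(dd_frac, key=dd_frac.get)
    l_corners = [c for c in corners if c != c120]
    centers = clusters.centers
    # match each mid-edge cluster to its corner pair by centroid midpoints
    mid_pair: dict[int, tuple[int, int]] = {}
    for m in mids:
        best, best_d = None, np.inf
        for i, a in enumerate(corners):
            for b in corners[i + 1:]:
                dist = np.linalg.norm(centers[m]
                                      - 0.5 * (centers[a] + centers[b]))
                if dist < best_d:
                    best, best_d = (a, b), dist
        mid_pair[m] = best
    # allele counts to find the rarer L allele
    counts = {c: 2 * int(np.sum(labels == c)) for c in l_corners}
    for m, (a, b) in mid_pair.items():
        n = int(np.sum(labels == m))
        for c in (a, b):
            if c in counts:
                counts[c] += n
    rare = min(counts, key=counts.get)
    corner_allele = {c120: "120", rare: "80",
                     next(c for c in l_corners if c != rare): "100"}
    name: dict[int, str] = {c: f"{a}/{a}" for c, a in corner_allele.items()}
    for m, (a, b) in mid_pair.items():
        al = sorted((corner_allele[a], corner_allele[b]), key=int)
        name[m] = "/".join(al)
    return pd.Series([name[c] for c in labels], index=karyotypes.index,
                     name="ak_genotype")


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


def wc_fst(g: GenotypeMatrix, group_a, group_b) -> tuple[np.ndarray, float]:
    """Per-site Weir & Cockerham theta-hat between two groups, plus its mean.

    Two-population variance-components estimator a/(a+b+c) with sample-size
    and observed-heterozygosity corrections; sites where the denominator is
    zero (or with fewer than 2 calls in a group) come back as NaN.  The mean
    ignores undefined sites.
    """
    ia = np.asarray(group_a)
    ib = np.asarray(group_b)
    if ia.dtype == bool:
        ia = np.flatnonzero(ia)
    if ib.dtype == bool:
        ib = np.flatnonzero(ib)
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups overlap")
    r = 2.0
    theta = np.full(g.n_sites, np.nan)
    da, db = g.dosages[:, ia], g.dosages[:, ib]
    ca, cb = da != MISSING, db != MISSING
    na = ca.sum(axis=1).astype(float)
    nb = cb.sum(axis=1).astype(float)
    ok = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(ca, da, 0).sum(axis=1) / (2 * na)
        pb = np.where(cb, db, 0).sum(axis=1) / (2 * nb)
        ha = (da == 1).sum(axis=1) / na
        hb = (db == 1).sum(axis=1) / nb
        nbar = (na + nb) / r
        nc = (na + nb - (na**2 + nb**2) / (na + nb)) / (r - 1)
        pbar = (na * pa + nb * pb) / (na + nb)
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (na * ha + nb * hb) / (na + nb)
        pq = pbar * (1 - pbar)
        a = nbar / nc * (s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (pq - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        denom = a + b + c
        val = np.where(np.abs(denom) > 1e-12, a / denom, np.nan)
    theta[ok] = val[ok]
    mean = float(np.nanmean(theta)) if np.any(~np.isnan(theta)) else np.nan
    return theta, mean


# ---------------------------------------------------------------------------
# LD r^2
# ---------------------------------------------------------------------------


def ld_r2(g: GenotypeMatrix, maf_min: float = 0.10) -> tuple[np.ndarray,
                                                             np.ndarray]:
    """Composite LD: squared Pearson correlation of dosages between all site
    pairs passing the MAF threshold, over individuals called at both sites.

    Returns ``(r2_matrix, site_index)`` where ``site_index`` maps matrix rows
    back to sites of ``g``.  Zero-variance pairs come back as NaN.
    """
    keep = np.flatnonzero(g.maf() >= maf_min)
    sub = g.take_sites(keep)
    X = sub.dosages.astype(float)
    M = (X != MISSING).astype(float)
    A = np.where(X == MISSING, 0.0, X)
    n = M @ M.T
    sx = A @ M.T
    sxx = (A * A) @ M.T
    sxy = A @ A.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        denom = varx * varx.T
        r2 = np.where(denom > 1e-12, cov**2 / denom, np.nan)
    r2[n < 2] = np.nan
    return r2, keep


# ---------------------------------------------------------------------------
# region summaries
# ---------------------------------------------------------------------------


def summarize_region(per_site_fst: np.ndarray, site_cm: np.ndarray,
                     interval: tuple[float, float],
                     r2: np.ndarray | None = None,
                     r2_site_cm: np.ndarray | None = None) -> dict:
    """Mean F_ST (and mean pairwise r² when given) inside the interval,
    outside it, and over the whole linkage group, with site counts."""
    fst = np.asarray(per_site_fst, dtype=float)
    cm = np.asarray(site_cm, dtype=float)
    lo, hi = interval
    if lo > hi:
        raise ValueError("empty interval")
    inside = (cm >= lo) & (cm <= hi)
    out: dict = {}
    for name, mask in (("inside", inside), ("outside", ~inside),
                       ("whole", np.ones_like(inside))):
        vals = fst[mask]
        defined = vals[~np.isnan(vals)]
        out[f"fst_{name}"] = float(defined.mean()) if defined.size else np.nan
        out[f"n_sites_{name}"] = int(defined.size)
    if r2 is not None:
        r2 = np.asarray(r2, dtype=float)
        cm2 = np.asarray(r2_site_cm, dtype=float)
        ins2 = (cm2 >= lo) & (cm2 <= hi)
        for name, mask in (("inside", ins2), ("outside", ~ins2),
                           ("whole", np.ones_like(ins2))):
            idx = np.flatnonzero(mask)
            if idx.size < 2:
                out[f"r2_{name}"] = np.nan
                continue
            block = r2[np.ix_(idx, idx)]
            iu = np.triu_indices(idx.size, k=1)
            vals = block[iu]
            vals = vals[~np.isnan(vals)]
            out[f"r2_{name}"] = float(vals.mean()) if vals.size else np.nan
    return out
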