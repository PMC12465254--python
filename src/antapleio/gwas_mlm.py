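"""Kinship, PCA, mixed-linear-model association, region calling and LD decay.

The association scan follows the EMMAX strategy: the ratio of residual to
genetic variance is estimated once under the null model (covariates only) by
profile REML on the eigendecomposed kinship matrix, then every variant is
tested by generalized least squares with the variance components held fixed.
The effect sign convention is that beta > 0 means the ALT allele increases
the trait.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from antapleio.io_core import GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# kinship and structure
# ---------------------------------------------------------------------------


def compute_grm(G: GenotypeMatrix) -> np.ndarray:
    """VanRaden centered genomic relationship matrix.

    ``K = Z Z' / (2 * sum p(1-p))`` with ``Z`` the per-variant ALT-dosage
    deviation from ``2p``.  Missing dosages are mean-imputed per variant;
    monomorphic variants contribute nothing.
    """
    X = G.imputed_dosage()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all variants are monomorphic; GRM undefined")
    Z = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return (Z @ Z.T) / denom


def compute_pca(G: GenotypeMatrix, k: int = 10) -> np.ndarray:
    """Top-k principal component scores of the centered-standardized dosages.

    Scores are scaled by the singular values; each component's sign is fixed
    so its largest-magnitude variant loading is positive.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= min(G.n_samples, G.n_variants):
        raise ValueError("k must be < min(n_samples, n_variants)")
    X = G.imputed_dosage()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    Z = (X[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] *= -1.0
    return scores


# ---------------------------------------------------------------------------
# EMMAX-style mixed-model scan
# ---------------------------------------------------------------------------


def _reml_neg_loglik(log_delta: float, yt: np.ndarray, Xt: np.ndarray,
                     lam: np.ndarray) -> float:
    """Negative restricted log-likelihood profiled over sigma2_g.

    ``yt``, ``Xt`` are the phenotype/covariates rotated by the kinship
    eigenvectors; ``lam`` are the kinship eigenvalues; the variance of the
    rotated observation i is ``sigma2_g * (lam_i + delta)`` with
    ``delta = sigma2_e / sigma2_g``.
    """
    delta = 10.0 ** log_delta
    w = lam + delta
    n, p = Xt.shape
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yt)
    r = yt - Xt @ beta
    rss = float(r @ (r / w))
    sigma2 = rss / (n - p)
    _, ld_xwx = np.linalg.slogdet(XtWX)
    _, ld_xx = np.linalg.slogdet(Xt.T @ Xt)
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma2)
        + (n - p)
        + np.sum(np.log(w))
        + ld_xwx
        - ld_xx
    )
    return -ll


def estimate_null_delta(y: np.ndarray, X0: np.ndarray, lam: np.ndarray,
                        U: np.ndarray) -> float:
    """Grid + golden-section REML estimate of delta = sigma2_e / sigma2_g."""
    yt = U.T @ y
    Xt = U.T @ X0
    grid = np.linspace(-5.0, 5.0, 61)
    vals = [_reml_neg_loglik(g, yt, Xt, lam) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(yt, Xt, lam), method="bounded"
    )
    return float(10.0 ** res.x)


def mlm_scan(
    G: GenotypeMatrix,
    phenotype: pd.Series,
    grm: np.ndarray | None = None,
    pcs: np.ndarray | None = None,
    n_pcs: int = 1,
) -> pd.DataFrame:
    """Mixed-linear-model association scan (EMMAX strategy).

    Parameters
    ----------
    phenotype
        Per-accession values indexed by accession ID; missing accessions are
        dropped pairwise.
    grm, pcs
        Optional precomputed kinship matrix / PC-score covariates aligned to
        ``G.samples``; computed on the fly otherwise.

    Returns one record per variant with ``beta`` (trait units per ALT copy),
    ``se``, ``p``, ``neg_log10_p``, ``maf`` and ``n``.
    """
    keep = np.array([s in phenotype.index and np.isfinite(phenotype.get(s, np.nan))
                     for s in G.samples])
    if keep.sum() < 30:
        raise ValueError("phenotype available for fewer than 30 genotyped accessions")
    if grm is None:
        grm = compute_grm(G)
    if pcs is None and n_pcs > 0:
        pcs = compute_pca(G, k=n_pcs)

    idx = np.flatnonzero(keep)
    y = phenotype.loc[[G.samples[i] for i in idx]].to_numpy(float)
    K = grm[np.ix_(idx, idx)]
    X0 = np.ones((len(idx), 1))
    if pcs is not None:
        X0 = np.column_stack([X0, pcs[idx]])

    lam, U = np.linalg.eigh(K)
    if lam.min() < 1e-8:
        warnings.warn("kinship matrix not PSD; clipping small eigenvalues at 1e-8",
                      stacklevel=2)
        lam = np.maximum(lam, 1e-8)
    delta = estimate_null_delta(y, X0, lam, U)
    logger.info("null REML delta (s2e/s2g) = %.4g", delta)

    w = lam + delta
    sw = 1.0 / np.sqrt(w)
    yt = (U.T @ y) * sw
    X0t = (U.T @ X0) * sw[:, None]

    # variants: mean-imputed dosages rotated once
    Xg = G.imputed_dosage()[idx, :]
    p_alt = Xg.mean(axis=0) / 2.0
    Gt = (U.T @ Xg) * sw[:, None]

    # GLS with fixed weights == OLS on the whitened data; per-variant solve
    # via the Schur complement of the covariate block.
    A00 = X0t.T @ X0t
    A00_inv = np.linalg.inv(A00)
    b0 = X0t.T @ yt
    rss0 = float(yt @ yt - b0 @ A00_inv @ b0)

    a = X0t.T @ Gt                      # (p0, m)
    gg = np.sum(Gt * Gt, axis=0)        # (m,)
    gy = Gt.T @ yt                      # (m,)
    Ainv_a = A00_inv @ a
    s_schur = gg - np.sum(a * Ainv_a, axis=0)
    num = gy - a.T @ (A00_inv @ b0)
    ok = s_schur > 1e-12
    beta = np.full(Xg.shape[1], np.nan)
    beta[ok] = num[ok] / s_schur[ok]
    n_used, p0 = X0t.shape
    dof = n_used - p0 - 1
    rss = rss0 - beta**2 * s_schur
    sigma2 = rss / dof
    se = np.sqrt(np.where(ok, sigma2 / np.where(ok, s_schur, 1.0), np.nan))
    tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    maf = np.minimum(p_alt, 1.0 - p_alt)
    out = G.variants.copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = pval
    out["neg_log10_p"] = -np.log10(pval)
    out["maf"] = maf
    out["n"] = n_used
    return out


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------


@dataclass
class AssociatedRegion:
    """Clumped interval of significant SNPs with its lead (minimum-P) SNP."""

    trait: str
    chrom: str
    start: int
    end: int
    n_snps: int
    lead_chrom: str
    lead_pos: int
    lead_p: float
    member_index: list[int] = field(default_factory=list, repr=False)
    env_support: int = 0

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


def call_regions(
    assoc: pd.DataFrame,
    threshold_log10p: float = 5.0,
    merge_bp: int = 1_000_000,
    min_snps: int = 6,
    trait: str = "",
) -> list[AssociatedRegion]:
    """Clump significant SNPs into associated genomic regions.

    Consecutive significant SNPs within ``merge_bp`` of each other join one
    cluster; clusters with more than five members (``min_snps`` defaults to
    6) become regions.  The lead SNP is the minimum-P member (ties broken by
    smaller position).
    """
    sig = assoc[assoc["neg_log10_p"] > threshold_log10p]
    regions: list[AssociatedRegion] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values(["pos", "p"])
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            cluster = grp.iloc[s:e + 1]
            if len(cluster) < min_snps:
                continue
            lead = cluster.sort_values(["p", "pos"]).iloc[0]
            regions.append(
                AssociatedRegion(
                    trait=trait,
                    chrom=str(chrom),
                    start=int(cluster["pos"].min()),
                    end=int(cluster["pos"].max()),
                    n_snps=len(cluster),
                    lead_chrom=str(chrom),
                    lead_pos=int(lead["pos"]),
                    lead_p=float(lead["p"]),
                    member_index=list(cluster.index),
                )
            )
    return regions


def environment_support(
    region: AssociatedRegion,
    assoc_by_env: dict[str, pd.DataFrame],
    threshold_log10p: float = 5.0,
) -> int:
    """Number of environments (incl. BLUE) with >=1 significant member SNP
    inside the region's interval."""
    count = 0
    for env, assoc in assoc_by_env.items():
        inside = assoc[
            (assoc["chrom"] == region.chrom)
            & (assoc["pos"] >= region.start)
            & (assoc["pos"] <= region.end)
            & (assoc["neg_log10_p"] > threshold_log10p)
        ]
        if len(inside):
            count += 1
    return count


def regions_to_frame(regions: list[AssociatedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_snps": r.n_snps,
                "lead_pos": r.lead_pos,
                "lead_p": r.lead_p,
                "env_support": r.env_support,
            }
            for r in regions
        ],
        columns=["trait", "chrom", "start", "end", "n_snps", "lead_pos",
                 "lead_p", "env_support"],
    )


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


def ld_decay(
    G: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    bin_bp: int = 50_000,
) -> tuple[pd.DataFrame, float]:
    """Binned mean pairwise r-squared by distance and the half-decay distance.

    r-squared is the squared Pearson correlation of dosage vectors for SNP
    pairs on the same chromosome within ``max_dist_bp``.  The half-decay
    distance is the midpoint of the first distance bin whose mean r-squared
    drops to half the maximum bin mean.
    """
    X = G.imputed_dosage()
    sd = X.std(axis=0)
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for chrom, grp in G.variants.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        Z = X[:, cols] - X[:, cols].mean(axis=0)
        s = sd[cols]
        for i in range(len(cols) - 1):
            j_hi = np.searchsorted(pos, pos[i] + max_dist_bp, side="right")
            js = np.arange(i + 1, j_hi)
            if len(js) == 0 or s[i] == 0:
                continue
            usable = s[js] > 0
            js = js[usable]
            if len(js) == 0:
                continue
            r = (Z[:, i] @ Z[:, js]) / (len(Z) * s[i] * s[js])
            d = pos[js] - pos[i]
            b = np.minimum((d - 1) // bin_bp, n_bins - 1)
            np.add.at(sums, b, r * r)
            np.add.at(counts, b, 1)
    if counts.sum() == 0:
        raise ValueError("no SNP pair within max_dist_bp")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_bp,
            "bin_end": (np.arange(n_bins) + 1) * bin_bp,
            "mean_r2": means,
            "n_pairs": counts,
        }
    )
    peak = np.nanmax(means)
    half = peak / 2.0
    half_dist = np.nan
    for k in range(n_bins):
        if counts[k] > 0 and means[k] <= half:
            half_dist = (k + 0.5) * bin_bp
            break
    if np.isnan(half_dist):
        # flat curve: LD has already decayed to its asymptote within the
        # first populated bin
        first = int(np.argmax(counts > 0))
        half_dist = (first + 0.5) * bin_bp
    return table, float(half_dist)
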