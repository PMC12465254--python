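"""Multi-environment phenotype modelling.

Implements the trial-analysis layer for an unbalanced multi-environment
design ``Y_ijkl = mu + G_i + L_j + Y_k + (GL)_ij + (GY)_ik + (LY)_jk + e_ijkl``:

- per-accession BLUEs (genotype fixed; genotype-by-location and
  genotype-by-year interactions random; environment main effects sum-coded),
- variance components by Henderson's Method III (sequential sums of squares
  with exact expected values, solved as a linear system, negative estimates
  truncated at zero),
- broad-sense heritability
  ``H2 = s2G / (s2G + s2GL/L + s2GY/Y + s2E/(Y*R*L))``,
- phenotypic Pearson correlations, Haseman-Elston genetic correlations from
  a GRM, and Welch two-group comparisons.

Method-of-moments variance components were chosen over iterative REML: they
are deterministic, exact in expectation for arbitrary unbalanced layouts, and
fast at panel scale.  Genotype-by-location-by-year interaction variance is
not modelled separately; it folds into the residual.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.linalg import spsolve

from antapleio.io_core import PhenotypeTable, parse_environment

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """ANOVA variance components for one trait (squared trait units)."""

    sigma2_g: float
    sigma2_gl: float
    sigma2_gy: float
    sigma2_e: float
    n_locations: int
    n_years: int
    n_replicates: int

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_gl", "sigma2_gy", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_locations", "n_years", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def estimate_h2(vc: VarianceComponents) -> float:
    """Broad-sense heritability on an entry-mean basis.

    ``H2 = s2G / (s2G + s2GL/L + s2GY/Y + s2E/(Y*R*L))``.
    """
    if vc.sigma2_g == 0:
        warnings.warn("sigma2_g is zero; H2 set to 0", stacklevel=2)
        return 0.0
    L, Y, R = vc.n_locations, vc.n_years, vc.n_replicates
    denom = vc.sigma2_g + vc.sigma2_gl / L + vc.sigma2_gy / Y + vc.sigma2_e / (Y * R * L)
    return vc.sigma2_g / denom


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------


def _one_hot(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


def _interaction(codes_a, n_a, codes_b, n_b) -> sp.csr_matrix:
    combo = codes_a * n_b + codes_b
    uniq, inv = np.unique(combo, return_inverse=True)
    return _one_hot(inv, len(uniq))


def _trait_design(df: pd.DataFrame):
    acc, acc_levels = pd.factorize(df["accession"], sort=True)
    locs_years = [parse_environment(e) for e in df["environment"]]
    loc, loc_levels = pd.factorize(pd.Series([x[0] for x in locs_years]), sort=True)
    yr, yr_levels = pd.factorize(pd.Series([x[1] for x in locs_years]), sort=True)
    return acc, acc_levels, loc, loc_levels, yr, yr_levels


# ---------------------------------------------------------------------------
# variance components (Henderson's Method III)
# ---------------------------------------------------------------------------


class _Projector:
    """Orthogonal projector onto the column space of a sparse design."""

    def __init__(self, X: sp.csr_matrix):
        self.X = X
        XtX = np.asarray((X.T @ X).todense())
        lam, V = np.linalg.eigh(XtX)
        tol = max(lam.max(), 1.0) * 1e-9
        keep = lam > tol
        self.rank = int(keep.sum())
        self.W = V[:, keep] / np.sqrt(lam[keep])  # X W has orthonormal columns

    def fit_ss(self, y: np.ndarray) -> float:
        t = self.W.T @ (self.X.T @ y)
        return float(t @ t)

    def trace_zpz(self, Z: sp.csr_matrix) -> float:
        B = np.asarray((self.X.T @ Z).todense())
        M = self.W.T @ B
        return float(np.sum(M * M))


def estimate_variance_components(obs: PhenotypeTable, trait: str) -> VarianceComponents:
    """Method-of-moments (Henderson III) estimates of s2G, s2GL, s2GY, s2E.

    Genotype, genotype-by-location and genotype-by-year effects are treated
    as random; location, year and location-by-year enter the base model.
    Components whose stratum is missing (single location / year / replicate)
    are set to zero with a warning.  Negative solutions are truncated at 0.
    """
    df = obs.for_trait(trait)
    y = df["value"].to_numpy(float)
    n = len(y)
    acc, acc_levels, loc, loc_levels, yr, yr_levels = _trait_design(df)
    L, Y = len(loc_levels), len(yr_levels)
    cell = pd.Series(df["accession"].astype(str) + "|" + df["environment"].astype(str))
    reps = cell.value_counts()
    R = int(round(reps.median()))

    ones = sp.csr_matrix(np.ones((n, 1)))
    Z_L = _one_hot(loc, L)
    Z_Y = _one_hot(yr, Y)
    Z_LY = _interaction(loc, L, yr, Y)
    Z_G = _one_hot(acc, len(acc_levels))
    Z_GL = _interaction(acc, len(acc_levels), loc, L)
    Z_GY = _interaction(acc, len(acc_levels), yr, Y)

    X0 = sp.hstack([ones, Z_L, Z_Y, Z_LY], format="csr")
    X1 = sp.hstack([X0, Z_G], format="csr")
    X2 = sp.hstack([X1, Z_GL], format="csr")
    X3 = sp.hstack([X2, Z_GY], format="csr")

    P = [_Projector(X) for X in (X0, X1, X2, X3)]
    fit = [p.fit_ss(y) for p in P]
    yty = float(y @ y)

    # rows: sequential SS for G, GL, GY, and residual SS
    ss = np.array([fit[1] - fit[0], fit[2] - fit[1], fit[3] - fit[2], yty - fit[3]])
    df_seq = np.array(
        [P[1].rank - P[0].rank, P[2].rank - P[1].rank, P[3].rank - P[2].rank,
         n - P[3].rank],
        dtype=float,
    )
    # E[SS_t] = s2E * df_t + sum_c s2c * (tr(Zc' P_t Zc) - tr(Zc' P_{t-1} Zc))
    Zs = {"g": Z_G, "gl": Z_GL, "gy": Z_GY}
    tr_full = {k: float(Z.multiply(Z).sum()) for k, Z in Zs.items()}
    A = np.zeros((4, 4))  # unknowns [s2g, s2gl, s2gy, s2e]
    for row, (hi, lo) in enumerate([(1, 0), (2, 1), (3, 2)]):
        for col, key in enumerate(("g", "gl", "gy")):
            A[row, col] = P[hi].trace_zpz(Zs[key]) - P[lo].trace_zpz(Zs[key])
        A[row, 3] = df_seq[row]
    A[3, 3] = df_seq[3]  # residual row: random-term columns cancel exactly

    estimable = np.ones(4, dtype=bool)
    names = ("sigma2_g", "sigma2_gl", "sigma2_gy", "sigma2_e")
    for i in range(4):
        if A[i, i] < 1e-8:
            estimable[i] = False
            warnings.warn(
                f"{names[i]} is not estimable from this design; set to 0",
                stacklevel=2,
            )
    sol = np.zeros(4)
    idx = np.flatnonzero(estimable)
    if len(idx):
        sol[idx] = np.linalg.lstsq(A[np.ix_(idx, idx)], ss[idx], rcond=None)[0]
    sol = np.maximum(sol, 0.0)
    return VarianceComponents(
        sigma2_g=float(sol[0]),
        sigma2_gl=float(sol[1]),
        sigma2_gy=float(sol[2]),
        sigma2_e=float(sol[3]),
        n_locations=L,
        n_years=Y,
        n_replicates=max(R, 1),
    )


# ---------------------------------------------------------------------------
# BLUEs
# ---------------------------------------------------------------------------


def fit_blue(
    obs: PhenotypeTable,
    trait: str,
    vc: VarianceComponents | None = None,
) -> pd.Series:
    """Best linear unbiased estimates of per-accession genotypic values.

    Genotype is fixed; environment (location-by-year cell) main effects are
    sum-to-zero coded so genotype coefficients are directly interpretable as
    ``mu + G_i``; GxL and GxY interactions are random with variance ratios
    taken from Henderson III estimates.  With a single environment the
    per-accession mean is returned with a warning.
    """
    df = obs.for_trait(trait)
    envs = df["environment"].unique()
    if len(envs) < 2:
        warnings.warn(
            "single environment: BLUE falls back to per-accession means",
            stacklevel=2,
        )
        return df.groupby("accession")["value"].mean().rename(trait)

    if vc is None:
        vc = estimate_variance_components(obs, trait)

    y = df["value"].to_numpy(float)
    acc, acc_levels, loc, loc_levels, yr, yr_levels = _trait_design(df)
    env, env_levels = pd.factorize(df["environment"], sort=True)
    n_g, n_env = len(acc_levels), len(env_levels)

    X_g = _one_hot(acc, n_g)
    # sum-to-zero environment contrast: last level = -(sum of others)
    E = np.zeros((n_env, n_env - 1))
    E[: n_env - 1] = np.eye(n_env - 1)
    E[n_env - 1] = -1.0
    X_env = sp.csr_matrix(_one_hot(env, n_env) @ E)
    X = sp.hstack([X_g, X_env], format="csr")

    blocks = [X]
    penalties = [np.zeros(X.shape[1])]
    if vc.sigma2_e > 1e-12:
        if vc.sigma2_gl > 1e-12:
            Z = _interaction(acc, n_g, loc, len(loc_levels))
            blocks.append(Z)
            penalties.append(np.full(Z.shape[1], vc.sigma2_e / vc.sigma2_gl))
        if vc.sigma2_gy > 1e-12:
            Z = _interaction(acc, n_g, yr, len(yr_levels))
            blocks.append(Z)
            penalties.append(np.full(Z.shape[1], vc.sigma2_e / vc.sigma2_gy))
    A = sp.hstack(blocks, format="csr")
    lam = np.concatenate(penalties)
    lhs = (A.T @ A + sp.diags(lam)).tocsc()
    rhs = A.T @ y
    try:
        coef = spsolve(lhs, rhs)
    except RuntimeError:  # singular normal equations
        coef = sp.linalg.lsqr(lhs, rhs)[0]
    if np.isnan(coef[:n_g]).any():
        coef = sp.linalg.lsqr(lhs, rhs)[0]
    return pd.Series(coef[:n_g], index=list(acc_levels), name=trait)


# ---------------------------------------------------------------------------
# correlations and group tests
# ---------------------------------------------------------------------------


def phenotypic_correlation(blues: dict[str, pd.Series]):
    """Pairwise-complete Pearson correlation matrix across traits.

    Returns (r, p) DataFrames.  Constant traits produce NaN entries and a
    warning.
    """
    traits = list(blues)
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j in range(i + 1, len(traits)):
            b = traits[j]
            joined = pd.concat([blues[a], blues[b]], axis=1, join="inner").dropna()
            if len(joined) < 3:
                raise ValueError(f"fewer than 3 shared accessions for {a} vs {b}")
            x, yv = joined.iloc[:, 0], joined.iloc[:, 1]
            if x.std() == 0 or yv.std() == 0:
                warnings.warn(f"constant trait in pair ({a}, {b}); r undefined",
                              stacklevel=2)
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(x, yv)
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


@dataclass
class GeneticCorrelation:
    r_g: float
    se: float
    v_g1: float
    v_g2: float
    cov_g: float
    flag: str = ""


def _he_slopes(z1, z2, k_off, iu):
    x = k_off
    xm = x - x.mean()
    denom = float(xm @ xm)
    p11 = z1[iu[0]] * z1[iu[1]]
    p22 = z2[iu[0]] * z2[iu[1]]
    p12 = 0.5 * (z1[iu[0]] * z2[iu[1]] + z2[iu[0]] * z1[iu[1]])
    v1 = float(xm @ (p11 - p11.mean())) / denom
    v2 = float(xm @ (p22 - p22.mean())) / denom
    c = float(xm @ (p12 - p12.mean())) / denom
    return v1, v2, c


def genetic_correlation(
    blues1: pd.Series,
    blues2: pd.Series,
    grm: np.ndarray,
    samples: list[str],
    n_blocks: int = 20,
) -> GeneticCorrelation:
    """Haseman-Elston genetic correlation with a block-jackknife SE.

    Cross-products of standardized trait pairs are regressed on off-diagonal
    GRM entries; ``r_g = cov_g / sqrt(v_g1 * v_g2)``.  This is a deterministic
    method-of-moments alternative to bivariate REML.  If either genetic
    variance estimate is <= 0, ``r_g`` is NaN with an explanatory flag;
    ``|r_g| > 1`` is clipped with a flag, never silently.
    """
    idx = pd.Index(samples)
    common = idx.intersection(blues1.dropna().index).intersection(
        blues2.dropna().index
    )
    pos = np.array([idx.get_loc(s) for s in common])
    K = grm[np.ix_(pos, pos)]
    z1 = blues1.loc[common].to_numpy(float)
    z2 = blues2.loc[common].to_numpy(float)
    z1 = (z1 - z1.mean()) / z1.std()
    z2 = (z2 - z2.mean()) / z2.std()
    n = len(common)
    iu = np.triu_indices(n, k=1)
    k_off = K[iu]

    v1, v2, c = _he_slopes(z1, z2, k_off, iu)
    if v1 <= 0 or v2 <= 0:
        return GeneticCorrelation(np.nan, np.nan, v1, v2, c,
                                  flag="nonpositive genetic variance")
    r = c / np.sqrt(v1 * v2)

    # delete-a-block jackknife over accessions
    n_blocks = min(n_blocks, n)
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    reps = []
    for b in range(n_blocks):
        keep = np.ones(n, dtype=bool)
        keep[bounds[b]:bounds[b + 1]] = False
        kk = np.flatnonzero(keep)
        Ksub = K[np.ix_(kk, kk)]
        iu_s = np.triu_indices(len(kk), k=1)
        v1b, v2b, cb = _he_slopes(z1[kk], z2[kk], Ksub[iu_s], iu_s)
        if v1b > 0 and v2b > 0:
            reps.append(cb / np.sqrt(v1b * v2b))
    if len(reps) >= 2:
        reps = np.array(reps)
        m = len(reps)
        se = float(np.sqrt((m - 1) / m * np.sum((reps - reps.mean()) ** 2)))
    else:
        se = np.nan
    flag = ""
    if abs(r) > 1:
        flag = f"clipped from {r:.4f}"
        r = float(np.clip(r, -1.0, 1.0))
    return GeneticCorrelation(float(r), se, v1, v2, c, flag)


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    difference: float
    t: float
    df: float
    p: float
    n_a: int
    n_b: int


def group_compare(values: pd.Series, grouping: pd.Series,
                  group_a: str, group_b: str) -> GroupComparison:
    """Welch two-sided t-test between two sample groups."""
    joined = pd.concat([values.rename("v"), grouping.rename("g")], axis=1).dropna()
    a = joined.loc[joined["g"] == group_a, "v"].to_numpy(float)
    b = joined.loc[joined["g"] == group_b, "v"].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
    )
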