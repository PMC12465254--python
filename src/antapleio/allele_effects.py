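"""Favorable-allele bookkeeping and pleiotropy classification.

Favorable alleles are defined trait-wise: for dormancy traits (GP3D, GP7D)
the favorable allele DECREASES germination percentage (stronger dormancy);
for size traits (TKW, KL, KW) it INCREASES the trait.  On top of that the
module provides:

- favorable-allele frequency (FAF) shifts between landraces and cultivars,
- per-accession favorable-allele accumulation counts (carriage = favorable
  dosage >= 1, a presence/absence rule suited to near-inbred material),
- binned trend fits (count or release year vs. phenotype),
- the independent / antagonistic / synergistic per-SNP classification from
  homozygote-contrast Welch t-tests on BLUE phenotypes, anchored on the
  TKW-increasing allele (antagonistic: that allele also raises GP;
  synergistic: it lowers GP),
- phenotypic variance explained (PVE) of a SNP set by joint OLS after
  greedy LD pruning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from antapleio.io_core import DORMANCY_TRAITS, SIZE_TRAITS, GenotypeMatrix

logger = logging.getLogger(__name__)

CLASSES = ("independent", "antagonistic", "synergistic")


# ---------------------------------------------------------------------------
# favorable-allele assignment and FAF
# ---------------------------------------------------------------------------


def assign_favorable_alleles(
    assoc_by_trait: dict[str, pd.DataFrame],
    threshold_log10p: float = 5.0,
) -> pd.DataFrame:
    """Favorable-allele table for all significant (MTA) SNPs per trait.

    For a dormancy trait the favorable allele is ALT if beta < 0 else REF;
    for a size trait ALT if beta > 0 else REF.  Variants with beta exactly 0
    are skipped with a warning.  The ``variant`` column carries the row index
    of the variant in the association table (aligned to the genotype matrix).
    """
    frames = []
    for trait, assoc in assoc_by_trait.items():
        if trait in DORMANCY_TRAITS:
            fav_alt = lambda b: b < 0  # noqa: E731  (dormancy: GP-reducing)
        elif trait in SIZE_TRAITS:
            fav_alt = lambda b: b > 0  # noqa: E731
        else:
            raise ValueError(f"unknown trait {trait!r}")
        sig = assoc[assoc["neg_log10_p"] > threshold_log10p]
        zero = sig["beta"] == 0
        if zero.any():
            warnings.warn(
                f"{trait}: skipped {int(zero.sum())} significant SNPs with beta == 0",
                stacklevel=2,
            )
            sig = sig[~zero]
        out = sig[["chrom", "pos", "ref", "alt", "beta", "p"]].copy()
        out.insert(0, "variant", sig.index)
        out.insert(0, "trait", trait)
        out["favorable"] = np.where(fav_alt(sig["beta"].to_numpy()), "alt", "ref")
        frames.append(out)
    cols = ["trait", "variant", "chrom", "pos", "ref", "alt", "beta", "p", "favorable"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


def _group_alt_freq(G: GenotypeMatrix, idx: np.ndarray, variants: np.ndarray):
    dos = G.dosage[np.ix_(idx, variants)]
    n_al = 2.0 * np.sum(~np.isnan(dos), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.nansum(dos, axis=0) / n_al


def compute_faf_shift(
    G: GenotypeMatrix,
    fav: pd.DataFrame,
    group_a: str = "landrace",
    group_b: str = "cultivar",
) -> pd.DataFrame:
    """Per-SNP favorable-allele frequency in two groups plus shift direction.

    Direction is 'up' / 'down' / 'unchanged' by the sign of FAF_B - FAF_A
    (conventionally cultivar minus landrace).
    """
    ia, ib = G.group_indices(group_a), G.group_indices(group_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both groups must be non-empty")
    variants = fav["variant"].to_numpy()
    alt_a = _group_alt_freq(G, ia, variants)
    alt_b = _group_alt_freq(G, ib, variants)
    is_alt = (fav["favorable"] == "alt").to_numpy()
    faf_a = np.where(is_alt, alt_a, 1.0 - alt_a)
    faf_b = np.where(is_alt, alt_b, 1.0 - alt_b)
    out = fav.copy()
    out["faf_a"] = faf_a
    out["faf_b"] = faf_b
    delta = faf_b - faf_a
    out["direction"] = np.select(
        [delta > 0, delta < 0], ["up", "down"], default="unchanged"
    )
    return out


def faf_summary(shift: pd.DataFrame) -> pd.DataFrame:
    """Percentage of SNPs with increased / decreased / unchanged FAF per trait."""
    rows = []
    for trait, grp in shift.groupby("trait", sort=True):
        n = len(grp)
        counts = grp["direction"].value_counts()
        rows.append(
            {
                "trait": trait,
                "n_snps": n,
                "pct_up": 100.0 * counts.get("up", 0) / n,
                "pct_down": 100.0 * counts.get("down", 0) / n,
                "pct_unchanged": 100.0 * counts.get("unchanged", 0) / n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-accession accumulation
# ---------------------------------------------------------------------------


def count_favorable_alleles(G: GenotypeMatrix, fav: pd.DataFrame) -> pd.DataFrame:
    """Per-accession favorable-allele counts for dormancy and size loci.

    An accession carries a locus's favorable allele if its favorable-allele
    dosage is >= 1; missing genotypes contribute 0.  A variant listed for
    several traits of the same group is counted once per group.
    """
    if fav.empty:
        raise ValueError("favorable-allele table is empty")
    counts = pd.DataFrame(
        0, index=pd.Index(G.samples, name="accession"), columns=["dormancy", "size"]
    )
    for group_name, traits in (("dormancy", DORMANCY_TRAITS), ("size", SIZE_TRAITS)):
        sub = fav[fav["trait"].isin(traits)].drop_duplicates("variant")
        if sub.empty:
            continue
        dos = G.dosage[:, sub["variant"].to_numpy()]
        is_alt = (sub["favorable"] == "alt").to_numpy()
        fav_dos = np.where(is_alt[None, :], dos, 2.0 - dos)
        carried = np.where(np.isnan(fav_dos), 0.0, (fav_dos >= 1).astype(float))
        counts[group_name] = carried.sum(axis=1).astype(int)
    counts["total"] = counts["dormancy"] + counts["size"]
    return counts


def count_histogram(counts: pd.Series, edges=(20, 60, 100, 140)) -> pd.Series:
    """Accession counts per total-favorable-allele bin (e.g. 20-60, 60-100...)."""
    labels = [f"{lo}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]
    binned = pd.cut(counts, bins=list(edges), labels=labels, include_lowest=True)
    return binned.value_counts().reindex(labels).fillna(0).astype(int)


# ---------------------------------------------------------------------------
# trend fits
# ---------------------------------------------------------------------------


@dataclass
class TrendFit:
    slope: float
    intercept: float
    r2: float
    bin_mid: np.ndarray
    bin_mean: np.ndarray
    bin_n: np.ndarray


def trend_fit(x, y, n_bins: int = 10, min_per_bin: int = 5) -> TrendFit:
    """Binned-mean trend: regress bin mean y on bin midpoint x.

    Equal-width bins over x; bins with fewer than ``min_per_bin`` members are
    merged rightward (the last bin merges leftward).  Requires >= 3 bins
    after merging.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) == 0 or x.min() == x.max():
        raise ValueError("x has no spread; trend undefined")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    which = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    # merge sparse bins rightward
    members: list[list[int]] = [[] for _ in range(n_bins)]
    spans: list[list[float]] = [[edges[i], edges[i + 1]] for i in range(n_bins)]
    for i, b in enumerate(which):
        members[b].append(i)
    merged_members, merged_spans = [], []
    carry: list[int] = []
    carry_lo: float | None = None
    for b in range(n_bins):
        cur = carry + members[b]
        lo = carry_lo if carry_lo is not None else spans[b][0]
        if len(cur) < min_per_bin and b < n_bins - 1:
            carry, carry_lo = cur, lo
            continue
        merged_members.append(cur)
        merged_spans.append([lo, spans[b][1]])
        carry, carry_lo = [], None
    if carry:  # leftover sparse tail merges leftward
        if merged_members:
            merged_members[-1].extend(carry)
            merged_spans[-1][1] = spans[-1][1]
        else:
            merged_members.append(carry)
            merged_spans.append([carry_lo, spans[-1][1]])
    keep = [i for i, m in enumerate(merged_members) if len(m) > 0]
    mids = np.array([(merged_spans[i][0] + merged_spans[i][1]) / 2 for i in keep])
    means = np.array([y[merged_members[i]].mean() for i in keep])
    ns = np.array([len(merged_members[i]) for i in keep])
    if len(mids) < 3:
        raise ValueError("fewer than 3 non-empty bins after merging")
    slope, intercept = np.polyfit(mids, means, 1)
    pred = slope * mids + intercept
    sst = float(np.sum((means - means.mean()) ** 2))
    r2 = 1.0 - float(np.sum((means - pred) ** 2)) / sst if sst > 0 else 1.0
    return TrendFit(float(slope), float(intercept), float(r2), mids, means, ns)


# ---------------------------------------------------------------------------
# pleiotropy classification
# ---------------------------------------------------------------------------


def _variant_effect(dos, blue, min_hom: int):
    """Per-trait effect direction and P for one variant.

    Primary test: Welch t between the two homozygote groups (dosage 0 vs 2).
    If either homozygote group has n < min_hom, falls back to the t-test of
    the dosage-regression slope (flagged).
    Returns (direction of ALT allele, P, fallback_used).
    """
    ok = np.isfinite(dos) & np.isfinite(blue)
    d, b = dos[ok], blue[ok]
    g0, g2 = b[d == 0], b[d == 2]
    if len(g0) >= min_hom and len(g2) >= min_hom:
        if np.var(g0) == 0 and np.var(g2) == 0:
            diff = g2.mean() - g0.mean()
            return np.sign(diff), (0.0 if diff != 0 else 1.0), False
        t = stats.ttest_ind(g2, g0, equal_var=False)
        return np.sign(g2.mean() - g0.mean()), float(t.pvalue), False
    # dosage-regression fallback
    if len(d) < 3 or np.var(d) == 0:
        return 0.0, 1.0, True
    res = stats.linregress(d, b)
    return np.sign(res.slope), float(res.pvalue), True


def classify_pleiotropy(
    G: GenotypeMatrix,
    blue_gp: pd.Series,
    blue_tkw: pd.Series,
    mta_gp,
    mta_tkw,
    alpha: float = 0.05,
    sample_idx: np.ndarray | None = None,
    min_hom: int = 5,
) -> pd.DataFrame:
    """Classify SNPs in the union of two MTA sets as independent /
    antagonistic / synergistic.

    A trait is "affected" if the SNP is in that trait's MTA set OR its
    homozygote-contrast Welch P is below ``alpha``.  SNPs affecting both
    traits are oriented on the TKW-increasing allele: if that allele's GP is
    higher the SNP is antagonistic (trade-off), if lower, synergistic.
    """
    mta_gp = set(int(i) for i in mta_gp)
    mta_tkw = set(int(i) for i in mta_tkw)
    union = sorted(mta_gp | mta_tkw)
    if not union:
        raise ValueError("empty MTA union")
    if sample_idx is None:
        sample_idx = np.arange(G.n_samples)
    sample_idx = np.asarray(sample_idx)
    samples = [G.samples[i] for i in sample_idx]
    bgp = blue_gp.reindex(samples).to_numpy(float)
    btkw = blue_tkw.reindex(samples).to_numpy(float)

    rows = []
    for v in union:
        dos = G.dosage[sample_idx, v]
        gp_dir, gp_p, gp_fb = _variant_effect(dos, bgp, min_hom)
        tkw_dir, tkw_p, tkw_fb = _variant_effect(dos, btkw, min_hom)
        affected_gp = (v in mta_gp) or (gp_p < alpha)
        affected_tkw = (v in mta_tkw) or (tkw_p < alpha)
        if affected_gp and affected_tkw and gp_dir != 0 and tkw_dir != 0:
            cls = "antagonistic" if gp_dir == tkw_dir else "synergistic"
        else:
            cls = "independent"
        rows.append(
            {
                "variant": v,
                "in_mta_gp": v in mta_gp,
                "in_mta_tkw": v in mta_tkw,
                "gp_direction": gp_dir,
                "gp_p": gp_p,
                "tkw_direction": tkw_dir,
                "tkw_p": tkw_p,
                "fallback": gp_fb or tkw_fb,
                "snp_class": cls,
            }
        )
    return pd.DataFrame(rows)


def class_percentages(classification: pd.DataFrame) -> pd.Series:
    """Percentage of SNPs per class; sums to 100 over classified SNPs."""
    n = len(classification)
    counts = classification["snp_class"].value_counts()
    return pd.Series(
        {c: 100.0 * counts.get(c, 0) / n for c in CLASSES}, name="percent"
    )


def classification_summary(
    G: GenotypeMatrix,
    blue_gp: pd.Series,
    blue_tkw: pd.Series,
    mta_gp,
    mta_tkw,
    alpha: float = 0.05,
    panels: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Class percentages per sample panel (all / landrace / cultivar).

    Percentages are over the union of both MTA sets; the intersection size is
    reported alongside as an alternative denominator.
    """
    if panels is None:
        panels = {
            "all": np.arange(G.n_samples),
            "landrace": G.group_indices("landrace"),
            "cultivar": G.group_indices("cultivar"),
        }
    n_union = len(set(int(i) for i in mta_gp) | set(int(i) for i in mta_tkw))
    n_inter = len(set(int(i) for i in mta_gp) & set(int(i) for i in mta_tkw))
    rows = []
    for panel, idx in panels.items():
        cl = classify_pleiotropy(
            G, blue_gp, blue_tkw, mta_gp, mta_tkw, alpha=alpha, sample_idx=idx
        )
        pct = class_percentages(cl)
        for c in CLASSES:
            rows.append(
                {
                    "panel": panel,
                    "snp_class": c,
                    "percent": pct[c],
                    "n_union": n_union,
                    "n_intersection": n_inter,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phenotypic variance explained
# ---------------------------------------------------------------------------


@dataclass
class PveResult:
    pve: float
    n_snps_input: int
    n_snps_fitted: int
    n_samples: int


def _greedy_prune(X: np.ndarray, order: np.ndarray, prune_r2: float) -> list[int]:
    kept: list[int] = []
    Z = X - X.mean(axis=0)
    sd = Z.std(axis=0)
    for j in order:
        if sd[j] == 0:
            continue
        ok = True
        for k in kept:
            r = (Z[:, j] @ Z[:, k]) / (len(Z) * sd[j] * sd[k])
            if r * r >= prune_r2:
                ok = False
                break
        if ok:
            kept.append(int(j))
    return kept


def pve_of_set(
    G: GenotypeMatrix,
    snp_idx,
    blue: pd.Series,
    p_values=None,
    prune_r2: float = 0.9,
) -> PveResult:
    """Joint-OLS phenotypic variance explained by a SNP set.

    The set is greedily LD-pruned at r2 >= ``prune_r2`` (keeping the
    lower-P member first); if more than n/2 SNPs remain, the lowest-P n/2
    are fitted.  PVE is the coefficient of determination of the joint
    ordinary-least-squares fit on mean-imputed dosages.
    """
    snp_idx = np.asarray(list(snp_idx), dtype=int)
    if len(snp_idx) == 0:
        raise ValueError("empty SNP set")
    mask = np.array(
        [s in blue.index and np.isfinite(blue.get(s, np.nan)) for s in G.samples]
    )
    if mask.sum() < 30:
        raise ValueError("phenotype present for fewer than 30 accessions")
    y = blue.reindex([s for s, m in zip(G.samples, mask) if m]).to_numpy(float)
    X = G.imputed_dosage()[np.ix_(np.flatnonzero(mask), snp_idx)]
    if p_values is not None:
        order = np.argsort(np.asarray(list(p_values), float), kind="stable")
    else:
        order = np.arange(len(snp_idx))
    kept = _greedy_prune(X, order, prune_r2)
    n = len(y)
    if len(kept) >= n // 2:
        kept = kept[: max(n // 2, 1)]
    Xk = X[:, kept]
    design = np.column_stack([np.ones(n), Xk])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn(
            "singular design after pruning; re-pruning at r2 >= 0.99",
            stacklevel=2,
        )
        kept2 = _greedy_prune(X, np.array(kept), 0.99)
        Xk = X[:, kept2]
        design = np.column_stack([np.ones(n), Xk])
        kept = kept2
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    pve = 1.0 - float(resid @ resid) / sst if sst > 0 else np.nan
    return PveResult(
        pve=pve,
        n_snps_input=len(snp_idx),
        n_snps_fitted=Xk.shape[1],
        n_samples=n,
    )
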