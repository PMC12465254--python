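"""Overlapping trait regions, tagSNP haplotypes and pyramiding analysis.

Dormancy- and size-associated regions that overlap by at least one bp are
named ``Qgd-gs.<chrom>.<index>``.  Haplotypes are built from tagSNP dosage
tuples collapsed to homozygote calls (unphased data cannot resolve
heterozygote haplotypes; het/missing accessions are unassigned, which suits
near-inbred material).  Haplotypes are labelled Hap 1, Hap 2, ... by
descending landrace frequency; haplotypes carried by fewer than ten
accessions are excluded from downstream tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from antapleio.io_core import GenotypeMatrix
from antapleio.gwas_mlm import AssociatedRegion

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# region overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapRegion:
    region_id: str
    chrom: str
    start: int
    end: int
    lead_dormancy: tuple[str, int]
    lead_size: tuple[str, int]


def overlap_trait_regions(
    regions_dormancy: list[AssociatedRegion],
    regions_size: list[AssociatedRegion],
) -> list[OverlapRegion]:
    """Pairs of dormancy/size regions with >= 1 bp intersection.

    The overlap interval, both parents' lead SNPs and a stable
    ``Qgd-gs.<chrom>.<index>`` ID are emitted.
    """
    out = []
    counter: dict[str, int] = {}
    for rd in regions_dormancy:
        for rs in regions_size:
            if rd.chrom != rs.chrom:
                continue
            lo = max(rd.start, rs.start)
            hi = min(rd.end, rs.end)
            if lo > hi:
                continue
            counter[rd.chrom] = counter.get(rd.chrom, 0) + 1
            out.append(
                OverlapRegion(
                    region_id=f"Qgd-gs.{rd.chrom}.{counter[rd.chrom]}",
                    chrom=rd.chrom,
                    start=lo,
                    end=hi,
                    lead_dormancy=(rd.lead_chrom, rd.lead_pos),
                    lead_size=(rs.lead_chrom, rs.lead_pos),
                )
            )
    return out


# ---------------------------------------------------------------------------
# tagSNPs and haplotype calling
# ---------------------------------------------------------------------------


def select_tag_snps(
    G: GenotypeMatrix,
    snp_idx,
    p_values,
    tag_r2: float = 0.8,
) -> list[int]:
    """Greedy tagging of significant SNPs in a region.

    Repeatedly keep the lowest-P untagged SNP and absorb every SNP with
    r2 >= ``tag_r2`` to it.  Deterministic given the input order (P ties are
    broken by input position).
    """
    snp_idx = np.asarray(list(snp_idx), dtype=int)
    if len(snp_idx) == 0:
        raise ValueError("empty SNP set for tagging")
    p = np.asarray(list(p_values), float)
    X = G.imputed_dosage()[:, snp_idx]
    Z = X - X.mean(axis=0)
    sd = Z.std(axis=0)
    remaining = list(np.argsort(p, kind="stable"))
    tags: list[int] = []
    while remaining:
        t = remaining.pop(0)
        tags.append(int(snp_idx[t]))
        if sd[t] == 0:
            continue
        keep = []
        for j in remaining:
            if sd[j] == 0:
                keep.append(j)
                continue
            r = (Z[:, t] @ Z[:, j]) / (len(Z) * sd[t] * sd[j])
            if r * r < tag_r2:
                keep.append(j)
        remaining = keep
    return tags


@dataclass
class HaplotypeAssignment:
    """Per-accession haplotype labels for one region."""

    region_id: str
    tag_snps: list[int]
    labels: pd.Series  # accession -> 'Hap 1', ..., or '' for unassigned
    counts: pd.Series  # label -> accession count (all haplotypes)
    retained: list[str] = field(default_factory=list)  # >= min_count haplotypes
    haplotype_alleles: dict[str, tuple] = field(default_factory=dict)


def call_haplotypes(
    G: GenotypeMatrix,
    tag_snps,
    min_count: int = 10,
    region_id: str = "",
) -> HaplotypeAssignment:
    """Haplotypes from homozygote tagSNP dosage tuples.

    Accessions heterozygous or missing at any tagSNP are unassigned.
    Haplotypes are ranked by landrace frequency (Hap 1 = most common in
    landraces; ties broken by overall count then allele tuple) and those
    carried by fewer than ``min_count`` accessions are excluded from
    downstream tests (but remain in the assignment, flagged by exclusion
    from ``retained``).
    """
    tag_snps = list(int(t) for t in tag_snps)
    if not tag_snps:
        raise ValueError("tagSNP list is empty")
    dos = G.dosage[:, tag_snps]
    hom = np.all((dos == 0.0) | (dos == 2.0), axis=1)
    if not hom.any():
        raise ValueError("all accessions heterozygous or missing at tagSNPs")
    tuples = [tuple(int(d) for d in row) for row in dos[hom]]
    assigned = pd.Series("", index=pd.Index(G.samples, name="accession"), dtype=object)
    hap_of = pd.Series(tuples, index=np.flatnonzero(hom))

    is_lr = (G.metadata["group"] == "landrace").to_numpy()
    uniq = sorted(set(tuples))
    lr_counts = {
        h: sum(1 for i, t in hap_of.items() if t == h and is_lr[i]) for h in uniq
    }
    all_counts = {h: sum(1 for t in tuples if t == h) for h in uniq}
    ranked = sorted(uniq, key=lambda h: (-lr_counts[h], -all_counts[h], h))
    label_of = {h: f"Hap {k + 1}" for k, h in enumerate(ranked)}
    for i, h in hap_of.items():
        assigned.iloc[i] = label_of[h]
    counts = pd.Series({label_of[h]: all_counts[h] for h in ranked})
    retained = [label_of[h] for h in ranked if all_counts[h] >= min_count]
    if len(retained) < len(ranked):
        logger.info(
            "%s: excluded %d haplotypes with < %d accessions",
            region_id or "region", len(ranked) - len(retained), min_count,
        )
    return HaplotypeAssignment(
        region_id=region_id,
        tag_snps=tag_snps,
        labels=assigned,
        counts=counts,
        retained=retained,
        haplotype_alleles={label_of[h]: h for h in ranked},
    )


# ---------------------------------------------------------------------------
# haplotype effect tests
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeEffect:
    region_id: str
    means: pd.DataFrame  # per haplotype: mean_gp, mean_tkw, n
    favorable_hap: str  # lowest-GP retained haplotype
    undesirable_hap: str
    tkw_p: float
    effect_label: str  # antagonistic / synergistic / none
    pairwise: pd.DataFrame


def haplotype_effect_test(
    assignment: HaplotypeAssignment,
    blue_gp: pd.Series,
    blue_tkw: pd.Series,
    alpha: float = 0.05,
) -> HaplotypeEffect:
    """Compare retained haplotypes on GP and TKW BLUEs.

    The haplotype with the lowest mean GP is "favorable-dormancy".  The
    region is synergistic if that haplotype also has significantly higher
    TKW than the highest-GP (undesirable) haplotype, antagonistic if
    significantly lower, none otherwise.
    """
    haps = assignment.retained
    if len(haps) < 2:
        warnings.warn("fewer than 2 retained haplotypes; effect label 'none'",
                      stacklevel=2)
        means = pd.DataFrame(columns=["mean_gp", "mean_tkw", "n"])
        return HaplotypeEffect(assignment.region_id, means, "", "", np.nan,
                               "none", pd.DataFrame())
    rows = {}
    values = {}
    for h in haps:
        acc = assignment.labels.index[assignment.labels == h]
        gp = blue_gp.reindex(acc).dropna()
        tkw = blue_tkw.reindex(acc).dropna()
        rows[h] = {"mean_gp": gp.mean(), "mean_tkw": tkw.mean(), "n": len(acc)}
        values[h] = (gp, tkw)
    means = pd.DataFrame(rows).T

    pair_rows = []
    for i, ha in enumerate(haps):
        for hb in haps[i + 1:]:
            for trait, k in (("gp", 0), ("tkw", 1)):
                va, vb = values[ha][k], values[hb][k]
                if len(va) >= 2 and len(vb) >= 2 and (va.var() + vb.var()) > 0:
                    p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
                elif len(va) >= 2 and len(vb) >= 2:
                    p = 1.0 if va.mean() == vb.mean() else 0.0
                else:
                    p = np.nan
                pair_rows.append({"hap_a": ha, "hap_b": hb, "trait": trait, "p": p})
    pairwise = pd.DataFrame(pair_rows)

    fav = means["mean_gp"].idxmin()
    und = means["mean_gp"].idxmax()
    va, vb = values[fav][1], values[und][1]
    if fav == und or len(va) < 2 or len(vb) < 2:
        tkw_p, label = np.nan, "none"
    else:
        if (va.var() + vb.var()) > 0:
            tkw_p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        else:
            tkw_p = 1.0 if va.mean() == vb.mean() else 0.0
        if tkw_p < alpha and va.mean() > vb.mean():
            label = "synergistic"  # strong dormancy AND bigger seed
        elif tkw_p < alpha and va.mean() < vb.mean():
            label = "antagonistic"  # strong dormancy at a seed-size cost
        else:
            label = "none"
    return HaplotypeEffect(assignment.region_id, means, fav, und, tkw_p, label,
                           pairwise)


# ---------------------------------------------------------------------------
# pyramiding
# ---------------------------------------------------------------------------


def pyramiding_analysis(
    assignments: list[HaplotypeAssignment],
    favorable_haps: list[str],
    blue_gp: pd.Series,
    blue_tkw: pd.Series,
) -> pd.DataFrame:
    """Phenotype means by number of favorable haplotypes stacked.

    Accessions are grouped by how many of the given regions' favorable
    haplotypes they carry (0..k).  Dormancy improvement of stack group g is
    ``(mean GP_0 - mean GP_g) / mean GP_0 * 100``; size improvement is
    ``(mean TKW_g - mean TKW_0) / mean TKW_0 * 100``.  Each group is
    Welch-tested against group 0.  Empty stack groups are omitted.
    """
    if len(assignments) < 2:
        raise ValueError("pyramiding needs >= 2 regions")
    if len(favorable_haps) != len(assignments):
        raise ValueError("one favorable haplotype per region required")
    samples = assignments[0].labels.index
    stack = pd.Series(0, index=samples)
    informative = pd.Series(True, index=samples)
    for asg, fav in zip(assignments, favorable_haps):
        lab = asg.labels.reindex(samples).fillna("")
        stack += (lab == fav).astype(int)
        informative &= lab != ""
    stack = stack[informative]

    rows = []
    base_gp = blue_gp.reindex(stack.index[stack == 0]).dropna()
    base_tkw = blue_tkw.reindex(stack.index[stack == 0]).dropna()
    if len(base_gp) == 0:
        raise ValueError("no accessions in the zero-favorable baseline group")
    for g in range(len(assignments) + 1):
        acc = stack.index[stack == g]
        if len(acc) == 0:
            logger.info("stack group %d empty; omitted", g)
            continue
        gp = blue_gp.reindex(acc).dropna()
        tkw = blue_tkw.reindex(acc).dropna()
        if g == 0 or len(gp) < 2 or len(base_gp) < 2:
            p_gp = np.nan
        else:
            p_gp = float(stats.ttest_ind(gp, base_gp, equal_var=False).pvalue)
        if g == 0 or len(tkw) < 2 or len(base_tkw) < 2:
            p_tkw = np.nan
        else:
            p_tkw = float(stats.ttest_ind(tkw, base_tkw, equal_var=False).pvalue)
        rows.append(
            {
                "n_favorable": g,
                "n_accessions": len(acc),
                "mean_gp": gp.mean(),
                "mean_tkw": tkw.mean(),
                "dormancy_improvement_pct":
                    100.0 * (base_gp.mean() - gp.mean()) / base_gp.mean(),
                "size_improvement_pct":
                    100.0 * (tkw.mean() - base_tkw.mean()) / base_tkw.mean(),
                "p_vs_zero_gp": p_gp,
                "p_vs_zero_tkw": p_tkw,
            }
        )
    return pd.DataFrame(rows)
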