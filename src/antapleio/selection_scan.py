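"""Windowed diversity / differentiation statistics and sweep-candidate calling.

Statistics are computed in sliding windows (default 200 kb with a 100 kb
step) from observed allele counts (no imputation):

- nucleotide diversity ``pi``: per-site ``(n/(n-1)) * 2p(1-p)`` summed over
  SNPs and divided by the window length in bp;
- Weir & Cockerham (1984) Fst, combined over SNPs as a ratio of sums
  (weighted estimator); negative window values are retained;
- the landrace/cultivar pi-ratio, with windows where the denominator
  population has zero diversity dropped (counted);
- sweep candidates: windows at or above the empirical top-``top_frac``
  quantile of each statistic, merged into regions, plus the union across
  statistics with per-statistic provenance (externally computed XP-CLR
  region files may be supplied through the same union interface).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from antapleio.io_core import GenotypeMatrix

logger = logging.getLogger(__name__)


def _windows(chrom_len: int, window_bp: int, step_bp: int) -> np.ndarray:
    starts = np.arange(1, max(chrom_len - window_bp + 2, 2), step_bp)
    if len(starts) == 0:
        starts = np.array([1])
    return starts


def _chrom_lengths(G: GenotypeMatrix, chrom_lengths: dict | None) -> dict[str, int]:
    if chrom_lengths is not None:
        return dict(chrom_lengths)
    return {
        str(c): int(g["pos"].max())
        for c, g in G.variants.groupby("chrom", sort=False)
    }


def _site_pi(dos: np.ndarray) -> np.ndarray:
    """Per-site diversity from a (samples x variants) dosage slice."""
    n_al = 2.0 * np.sum(~np.isnan(dos), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dos, axis=0) / n_al
        pi = np.where(n_al > 1, n_al / (n_al - 1.0) * 2.0 * p * (1.0 - p), 0.0)
    return np.where(n_al > 0, pi, 0.0)


def windowed_pi(
    G: GenotypeMatrix,
    sample_idx: np.ndarray,
    window_bp: int = 200_000,
    step_bp: int = 100_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity for one sample subset.

    Monomorphic and unobserved sites contribute zero; the denominator is the
    full window length in bp.
    """
    sample_idx = np.asarray(sample_idx)
    if len(sample_idx) < 2:
        raise ValueError("pi requires at least 2 samples")
    lengths = _chrom_lengths(G, chrom_lengths)
    site = _site_pi(G.dosage[sample_idx, :])
    rows = []
    for chrom, grp in G.variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        vals = site[grp.index.to_numpy()]
        for start in _windows(lengths[str(chrom)], window_bp, step_bp):
            lo, hi = np.searchsorted(pos, [start, start + window_bp])
            rows.append(
                {
                    "chrom": str(chrom),
                    "start": int(start),
                    "end": int(start + window_bp),
                    "value": float(vals[lo:hi].sum() / window_bp),
                    "n_snps": int(hi - lo),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "n_snps"])


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------


def wc_fst_components(
    G: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Weir & Cockerham (1984) variance components (a, a+b+c).

    Uses genotype-level information (observed heterozygosity) for two
    populations of diploids.  SNPs with fewer than two genotyped samples in
    either population get NaN components.
    """
    comps = []
    for idx in (idx_a, idx_b):
        dos = G.dosage[np.asarray(idx), :]
        n_i = np.sum(~np.isnan(dos), axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.nansum(dos, axis=0) / (2.0 * n_i)
            h_i = np.nansum(dos == 1.0, axis=0) / n_i
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    abc = np.where(valid, a + b + c, np.nan)
    return a, abc


def windowed_fst(
    G: GenotypeMatrix,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    window_bp: int = 200_000,
    step_bp: int = 100_000,
    chrom_lengths: dict | None = None,
) -> tuple[pd.DataFrame, float]:
    """Sliding-window Weir-Cockerham Fst plus the genome-wide weighted value.

    Window and genome-wide values are ratio-of-sums (sum of ``a`` components
    over sum of ``a+b+c``); windows without polymorphic SNPs are NaN.
    """
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("both subsets need n >= 2")
    lengths = _chrom_lengths(G, chrom_lengths)
    a, abc = wc_fst_components(G, idx_a, idx_b)
    usable = np.isfinite(abc) & (abc != 0.0)
    rows = []
    for chrom, grp in G.variants.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        for start in _windows(lengths[str(chrom)], window_bp, step_bp):
            lo, hi = np.searchsorted(pos, [start, start + window_bp])
            sub = cols[lo:hi]
            sub = sub[usable[sub]]
            if len(sub):
                value = float(a[sub].sum() / abc[sub].sum())
            else:
                value = np.nan
            rows.append(
                {
                    "chrom": str(chrom),
                    "start": int(start),
                    "end": int(start + window_bp),
                    "value": value,
                    "n_snps": int(len(sub)),
                }
            )
    genome_wide = float(np.nansum(a[usable]) / np.nansum(abc[usable]))
    return (
        pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "n_snps"]),
        genome_wide,
    )


def pi_ratio(pi_a: pd.DataFrame, pi_b: pd.DataFrame) -> pd.DataFrame:
    """Window-wise diversity ratio pi_A / pi_B (landrace over cultivar).

    Windows where ``pi_B`` is zero are dropped; the drop count is logged and
    attached as ``.attrs['n_dropped_zero_denominator']``.
    """
    merged = pi_a.merge(
        pi_b, on=["chrom", "start", "end"], suffixes=("_a", "_b")
    )
    keep = merged["value_b"] > 0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("pi_ratio: dropped %d windows with zero denominator pi", n_drop)
    out = merged.loc[keep, ["chrom", "start", "end"]].copy()
    out["value"] = merged.loc[keep, "value_a"] / merged.loc[keep, "value_b"]
    out["n_snps"] = merged.loc[keep, ["n_snps_a", "n_snps_b"]].max(axis=1)
    out = out.reset_index(drop=True)
    out.attrs["n_dropped_zero_denominator"] = n_drop
    return out


# ---------------------------------------------------------------------------
# sweep candidates
# ---------------------------------------------------------------------------


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    statistics: tuple[str, ...]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


def _merge_windows(df: pd.DataFrame, stat: str) -> list[SweepRegion]:
    regions = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None:
                cur = [row.start, row.end]
            elif row.start <= cur[1]:
                cur[1] = max(cur[1], row.end)
            else:
                regions.append(SweepRegion(str(chrom), cur[0], cur[1], (stat,)))
                cur = [row.start, row.end]
        if cur is not None:
            regions.append(SweepRegion(str(chrom), cur[0], cur[1], (stat,)))
    return regions


def sweep_candidates(
    stats_by_name: dict[str, pd.DataFrame],
    top_frac: float = 0.05,
) -> dict[str, list[SweepRegion]]:
    """Windows at/above the (1 - top_frac) empirical quantile, merged.

    Returns per-statistic candidate region lists plus their ``'union'`` with
    per-statistic provenance flags.  External region lists (e.g. XP-CLR
    output) can be folded into the union via :func:`union_regions`.
    """
    per_stat: dict[str, list[SweepRegion]] = {}
    for name, df in stats_by_name.items():
        vals = df["value"].dropna()
        if len(vals) < 20:
            raise ValueError(f"{name}: need >= 20 windows for quantile calling")
        thr = np.quantile(vals, 1.0 - top_frac)
        sel = df[df["value"] >= thr]
        per_stat[name] = _merge_windows(sel, name)
    per_stat["union"] = union_regions(
        [r for name in stats_by_name for r in per_stat[name]]
    )
    return per_stat


def union_regions(regions: list[SweepRegion]) -> list[SweepRegion]:
    """Merge overlapping regions from multiple statistics, keeping provenance."""
    out: list[SweepRegion] = []
    by_chrom: dict[str, list[SweepRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur = None
        for r in rs:
            if cur is None:
                cur = SweepRegion(chrom, r.start, r.end, tuple(r.statistics))
            elif r.start <= cur.end:
                cur = SweepRegion(
                    chrom,
                    cur.start,
                    max(cur.end, r.end),
                    tuple(sorted(set(cur.statistics) | set(r.statistics))),
                )
            else:
                out.append(cur)
                cur = SweepRegion(chrom, r.start, r.end, tuple(r.statistics))
        if cur is not None:
            out.append(cur)
    return out


def overlap_with_sweeps(regions, sweeps: list[SweepRegion]):
    """Flag GWAS regions overlapping >=1 bp of any sweep region.

    Returns (per-region boolean list, summary dict with count / total /
    fraction / percent).
    """
    flags = []
    for reg in regions:
        hit = any(s.overlaps(reg.chrom, reg.start, reg.end) for s in sweeps)
        flags.append(hit)
    total = len(flags)
    count = int(sum(flags))
    frac = count / total if total else np.nan
    summary = {
        "selected": count,
        "total": total,
        "fraction": frac,
        "percent": 100.0 * frac if total else np.nan,
    }
    return flags, summary
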