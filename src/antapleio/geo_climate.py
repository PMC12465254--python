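"""Climate joining, haplotype-climate tests and climate-population clustering.

Climate enters as a pre-extracted per-accession table with Bio1 (annual mean
temperature, degrees C) and Bio12 (annual precipitation, mm); raster
extraction is out of scope but any table with the same columns plugs in
(including alternative future-scenario tables).  Accessions are clustered
into K climate populations by k-means on the standardized (Bio1, Bio12)
plane, with labels renumbered by ascending mean Bio12 so Pop K is always the
wettest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from antapleio.haplotype_regions import HaplotypeAssignment

logger = logging.getLogger(__name__)


def attach_climate(metadata: pd.DataFrame, climate: pd.DataFrame) -> pd.DataFrame:
    """Join the climate table onto sample metadata by accession ID.

    Accessions without climate values are flagged ``excluded=True`` (they are
    dropped from climate tests only, not from the rest of the pipeline).
    """
    out = metadata.copy()
    out.index.name = "accession"
    cl = climate.set_index("accession")[["bio1", "bio12"]]
    out = out.join(cl, how="left")
    out["excluded"] = out["bio1"].isna() | out["bio12"].isna()
    if (~out["excluded"]).sum() == 0:
        raise ValueError("no accessions with climate data after the join")
    n_ex = int(out["excluded"].sum())
    if n_ex:
        logger.info("attach_climate: %d accessions without climate data flagged", n_ex)
    return out


@dataclass
class ClimateHaplotypeTest:
    variable: str
    mean_favorable: float
    mean_undesirable: float
    difference: float
    p: float
    n_favorable: int
    n_undesirable: int


def climate_haplotype_test(
    assignment: HaplotypeAssignment,
    climate: pd.DataFrame,
    variable: str,
    favorable_hap: str,
    undesirable_hap: str | None = None,
) -> ClimateHaplotypeTest:
    """Welch t-test of a climate variable between favorable- and
    undesirable-haplotype carriers.

    ``undesirable_hap=None`` pools all other retained haplotypes.
    """
    cl = climate
    if "excluded" in cl.columns:
        cl = cl[~cl["excluded"]]
    if "accession" in cl.columns:
        cl = cl.set_index("accession")
    lab = assignment.labels.reindex(cl.index).fillna("")
    fav_mask = lab == favorable_hap
    if undesirable_hap is None:
        und_mask = lab.isin([h for h in assignment.retained if h != favorable_hap])
    else:
        und_mask = lab == undesirable_hap
    a = cl.loc[fav_mask, variable].dropna().to_numpy(float)
    b = cl.loc[und_mask, variable].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both haplotype groups need n >= 2 with climate data")
    if a.var() + b.var() > 0:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        p = 1.0 if a.mean() == b.mean() else 0.0
    return ClimateHaplotypeTest(
        variable=variable,
        mean_favorable=float(a.mean()),
        mean_undesirable=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        p=p,
        n_favorable=len(a),
        n_undesirable=len(b),
    )


def cluster_climate_pops(
    climate: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_init: int = 100,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means climate populations on standardized (Bio1, Bio12).

    Returns per-accession Pop labels (1..K, ascending mean Bio12, so Pop K
    has the highest precipitation) and the cluster centers on the original
    scale.
    """
    if k < 2:
        raise ValueError("K must be >= 2")
    cl = climate
    if "excluded" in cl.columns:
        cl = cl[~cl["excluded"]]
    if "accession" in cl.columns:
        cl = cl.set_index("accession")
    X = cl[["bio1", "bio12"]].dropna()
    if len(X) < k:
        raise ValueError("fewer accessions with climate data than clusters")
    mu, sd = X.mean(), X.std().replace(0, 1.0)
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(Z.to_numpy())
    centers = pd.DataFrame(km.cluster_centers_, columns=["bio1", "bio12"]) * sd.values + mu.values
    order = centers["bio12"].argsort().to_numpy()  # ascending precipitation
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[raw], index=X.index, name="pop")
    centers = centers.iloc[order].reset_index(drop=True)
    centers.index = pd.Index(np.arange(1, k + 1), name="pop")
    return labels, centers


def hap_freq_by_group(
    assignment: HaplotypeAssignment,
    grouping: pd.Series,
    favorable_hap: str | None = None,
) -> pd.DataFrame:
    """Haplotype frequency table per group among assigned accessions.

    ``grouping`` may be climate Pop labels, breeding-period bins or the
    landrace/cultivar split.  Rows sum to 1 over retained haplotypes; the
    favorable-haplotype column is additionally exposed when requested.
    Empty groups are omitted.
    """
    lab = assignment.labels
    df = pd.DataFrame({"hap": lab, "group": grouping.reindex(lab.index)})
    df = df[(df["hap"].isin(assignment.retained)) & df["group"].notna()]
    if df.empty:
        raise ValueError("no assigned accessions with group labels")
    tab = pd.crosstab(df["group"], df["hap"], normalize="index")
    tab = tab.reindex(columns=assignment.retained, fill_value=0.0)
    if favorable_hap is not None:
        tab = tab.copy()
        tab["favorable_frequency"] = tab.get(favorable_hap, 0.0)
    return tab


def release_period_bins(
    release_year: pd.Series, edges=(1900, 1940, 1960, 1980, 2000, 2025)
) -> pd.Series:
    """Breeding-period bins from cultivar release years."""
    labels = [f"{lo}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]
    return pd.cut(release_year, bins=list(edges), labels=labels, include_lowest=True)
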