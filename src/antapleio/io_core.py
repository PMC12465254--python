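"""Data model, readers/writers and variant/sample filtering.

Conventions used throughout the package:

- Dosage counts copies of the ALT allele, so "allele frequency" always means
  ALT-allele frequency; favorable-allele logic resolves REF/ALT explicitly.
- Coordinates are 1-based inclusive (VCF convention); windows are half-open
  ``[start, start + size)`` in bp.
- Missing dosages are stored as NaN.  They are mean-imputed per variant only
  inside GRM / PCA / regression computations, never in allele-frequency or
  diversity computations, which use observed allele counts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DORMANCY_TRAITS = frozenset({"GP3D", "GP7D"})
SIZE_TRAITS = frozenset({"TKW", "KL", "KW"})
KNOWN_TRAITS = DORMANCY_TRAITS | SIZE_TRAITS

VALID_GROUPS = frozenset({"landrace", "cultivar", "other"})

_ENV_RE = re.compile(r"^([A-Za-z]+)[-_]?(\d{4})$")


def parse_environment(label: str) -> tuple[str, int]:
    """Split an environment label like ``ZX2021`` or ``BJ2023`` into
    (location, year)."""
    m = _ENV_RE.match(str(label))
    if m is None:
        raise ValueError(f"cannot parse environment label {label!r} as location+year")
    return m.group(1), int(m.group(2))


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosage matrix (samples x variants) with metadata.

    Parameters
    ----------
    samples
        Ordered accession IDs.
    variants
        DataFrame with columns ``chrom, pos, ref, alt`` (pos 1-based),
        positions strictly increasing within each chromosome.
    dosage
        Float array of shape (n_samples, n_variants); entries in {0, 1, 2}
        or NaN for missing calls.
    metadata
        Per-sample records indexed by accession ID with at least a ``group``
        column (landrace / cultivar / other); optional ``release_year``,
        ``latitude``, ``longitude``, ``seed_color``.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(f"invalid dosage value at sample {bad[0]}, variant {bad[1]}")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if len(self.metadata) == 0:
            self.metadata = pd.DataFrame(
                {"group": ["other"] * len(self.samples)}, index=self.samples
            )
        missing = set(self.samples) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]} ...")
        self.metadata = self.metadata.loc[self.samples]
        bad_groups = set(self.metadata["group"]) - VALID_GROUPS
        if bad_groups:
            raise ValueError(f"unknown sample groups: {bad_groups}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_freq(self) -> np.ndarray:
        """ALT-allele frequency per variant, over non-missing alleles."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def site_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    def group_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero((self.metadata["group"] == group).to_numpy())

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        samples = [self.samples[i] for i in idx]
        return GenotypeMatrix(
            samples=samples,
            variants=self.variants.copy(),
            dosage=self.dosage[idx, :].copy(),
            metadata=self.metadata.iloc[idx].copy(),
        )

    def subset_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
            metadata=self.metadata.copy(),
        )

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing calls replaced by the per-variant mean.

        Used only for GRM / PCA / regression-style computations.
        """
        X = self.dosage.copy()
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
        return X


@dataclass
class PhenotypeTable:
    """Long-format multi-environment phenotype observations.

    One row per (accession, trait, environment, replicate, value).  GP traits
    are percentages in [0, 100]; TKW is grams; KL/KW are millimetres.
    """

    data: pd.DataFrame

    REQUIRED = ("accession", "trait", "environment", "replicate", "value")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        d = self.data
        gp = d["trait"].isin(DORMANCY_TRAITS)
        vals = d.loc[gp, "value"]
        if len(vals) and ((vals < 0) | (vals > 100)).any():
            raise ValueError("GP values must lie in [0, 100]")
        size = d["trait"].isin(SIZE_TRAITS)
        if len(d.loc[size]) and (d.loc[size, "value"] <= 0).any():
            raise ValueError("size-trait values must be strictly positive")

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["environment"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise ValueError(f"trait {trait!r} absent from phenotype table")
        return sub.copy()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_NUC = frozenset("ACGT")


def read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"accession": str})
    if "accession" not in meta.columns:
        raise ValueError("metadata table must have an 'accession' column")
    meta = meta.set_index("accession")
    if "group" not in meta.columns:
        raise ValueError("metadata table must have a 'group' column")
    return meta


def read_genotypes(vcf_path, metadata_path) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF plus a sample-metadata TSV.

    Multi-allelic or non-SNP records are excluded (the exclusion count is
    logged).  Missing GT calls become NaN dosages.  Samples are returned in
    metadata order.
    """
    from cyvcf2 import VCF

    meta = read_metadata(metadata_path)
    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = list(vcf.samples)
    extra = set(vcf_samples) - set(meta.index)
    if extra:
        raise ValueError(
            f"samples present in VCF but absent from metadata: {sorted(extra)}"
        )

    rows = []
    dosages = []
    n_excluded = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_excluded += 1
            continue
        if rec.REF not in _NUC or rec.ALT[0] not in _NUC:
            n_excluded += 1
            continue
        # gts012: 0/1/2 = alt count, 3 = missing
        gt = rec.gt_types.astype(float)
        gt[gt == 3] = np.nan
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        dosages.append(gt)
    if not rows:
        raise ValueError(f"no biallelic SNP records found in {vcf_path}")
    if n_excluded:
        logger.info("excluded %d non-biallelic/non-SNP records", n_excluded)

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = np.vstack(dosages).T  # samples x variants, VCF sample order

    # reorder samples to metadata order; metadata may list extra accessions
    keep_meta = meta.loc[[s for s in meta.index if s in set(vcf_samples)]]
    order = [vcf_samples.index(s) for s in keep_meta.index]
    G = GenotypeMatrix(
        samples=list(keep_meta.index),
        variants=variants,
        dosage=dosage[order, :],
        metadata=keep_meta,
    )
    G.n_excluded_records = n_excluded  # type: ignore[attr-defined]
    return G


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT-only biallelic SNP records."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, grp in G.variants.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j, var in enumerate(G.variants.itertuples(index=False)):
            gts = "\t".join(
                "./." if np.isnan(d) else code[d] for d in G.dosage[:, j]
            )
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.chrom}_{var.pos}\t{var.ref}\t"
                f"{var.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_metadata(G: GenotypeMatrix, path) -> None:
    out = G.metadata.copy()
    out.index.name = "accession"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"accession": str, "trait": str, "environment": str}
    )
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_climate(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    need = {"accession", "bio1", "bio12"}
    if not need <= set(df.columns):
        raise ValueError(f"climate table must have columns {sorted(need)}")
    return df


def write_climate(climate: pd.DataFrame, path) -> None:
    climate.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_variants(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    site_missing_max: float = 0.2,
    sample_missing_max: float = 0.1,
) -> GenotypeMatrix:
    """Remove low-MAF and high-missingness variants, then high-missingness
    samples.

    A variant is dropped if its minor allele frequency (over non-missing
    alleles) is <= ``maf_min`` or its per-site missing rate is
    >= ``site_missing_max``.  A sample is dropped if its missing rate over
    the retained variants is >= ``sample_missing_max``.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must lie in [0, 0.5]")
    for name, v in (("site_missing_max", site_missing_max),
                    ("sample_missing_max", sample_missing_max)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")

    # alternate variant- and sample-level passes to a fixed point so that
    # re-filtering the output is a no-op (sample removal shifts per-site MAF)
    out = G
    while True:
        keep_var = (out.maf() > maf_min) & (out.site_missing_rate() < site_missing_max)
        if not keep_var.any():
            raise ValueError(
                "all variants removed by filtering; review maf_min / "
                "missing-rate thresholds"
            )
        if not keep_var.all():
            out = out.subset_variants(keep_var)
        keep_smp = out.sample_missing_rate() < sample_missing_max
        if not keep_smp.all():
            logger.info("removing %d samples with high missingness",
                        (~keep_smp).sum())
            out = out.subset_samples(keep_smp)
        if keep_var.all() and keep_smp.all():
            break
    logger.info(
        "filter_variants: %d/%d variants, %d/%d samples retained",
        out.n_variants, G.n_variants, out.n_samples, G.n_samples,
    )
    return out
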