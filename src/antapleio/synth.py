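"""Synthetic structured-population generator.

Emulates the statistical structure of a landrace / cultivar / other diversity
panel so that every downstream stage is testable without real data:

- genotypes follow a Balding–Nichols model: ancestral allele frequencies are
  uniform on [0.05, 0.95]; each subpopulation draws its frequency from a Beta
  distribution with differentiation parameter ``F`` (the expected Weir &
  Cockerham Fst between subpopulations);
- planted QTLs carry configurable effects on the dormancy trait (germination
  percentage, GP) and the size trait (thousand-kernel weight, TKW) with
  antagonistic (same-sign), synergistic (opposite-sign) or independent
  architecture;
- breeding selection is emulated by shifting the favorable-size-allele
  frequency of every size-affecting QTL in the cultivar subpopulation;
- cultivar release years are rank-matched to the per-accession favorable
  size-allele count, so later releases carry more size alleles;
- phenotypes follow a genotype + location + year + GxL + GxY + residual model
  with two replicates per environment; GP values are clipped to [0, 100];
- local linkage is emulated by founder-block copying: non-QTL variants in a
  block copy a latent founder haplotype with a per-variant flip probability,
  which yields nonzero local r-squared without a recombination map;
- the climate table draws (Bio1, Bio12) from three cluster centers, optionally
  stratified on carriage of a chosen QTL's favorable allele.

The generator deliberately omits hexaploid subgenome homoeology, realistic
wheat LD maps and demographic history.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from antapleio import io_core
from antapleio.io_core import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

QTL_CLASSES = ("antagonistic", "synergistic", "independent-dormancy", "independent-size")

#: cross-trait effect scaling: a QTL's GP effect carries over to GP7D, its
#: TKW effect to kernel length / width, mimicking correlated trait batteries.
TRAIT_EFFECT_SCALE = {
    "GP3D": ("gp", 1.0),
    "GP7D": ("gp", 0.75),
    "TKW": ("tkw", 1.0),
    "KL": ("tkw", 0.03),
    "KW": ("tkw", 0.015),
}


@dataclass(frozen=True)
class QTL:
    """A planted causal variant with per-allele (per ALT copy) effects.

    ``beta_gp`` is in GP percentage points, ``beta_tkw`` in grams.  Sign
    conventions (for the ALT allele):

    - antagonistic: same sign on both traits (high TKW with high GP, the
      breeding trade-off);
    - synergistic: opposite signs (high TKW with low GP, both desirable);
    - independent-dormancy / independent-size: single-trait effect.
    """

    index: int
    qtl_class: str
    beta_gp: float
    beta_tkw: float

    def __post_init__(self) -> None:
        if self.qtl_class not in QTL_CLASSES:
            raise ValueError(f"unknown QTL class {self.qtl_class!r}")
        sg, st = np.sign(self.beta_gp), np.sign(self.beta_tkw)
        if self.qtl_class == "antagonistic" and (sg == 0 or st == 0 or sg != st):
            raise ValueError("antagonistic QTL requires equal nonzero effect signs")
        if self.qtl_class == "synergistic" and (sg == 0 or st == 0 or sg == st):
            raise ValueError("synergistic QTL requires opposite nonzero effect signs")
        if self.qtl_class == "independent-dormancy" and (sg == 0 or st != 0):
            raise ValueError("independent-dormancy QTL must affect GP only")
        if self.qtl_class == "independent-size" and (st == 0 or sg != 0):
            raise ValueError("independent-size QTL must affect TKW only")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic panel.

    Defaults mirror a 545-accession diversity panel: 265 landraces, 215
    cultivars and 65 other accessions, phenotyped in four location-by-year
    environments with two replicates.
    """

    n_landrace: int = 265
    n_cultivar: int = 215
    n_other: int = 65
    n_variants: int = 2000
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"1A": 20_000_000, "2A": 20_000_000, "3A": 20_000_000}
    )
    divergence_f: float = 0.07
    qtls: list[QTL] = field(default_factory=list)
    selection_shift: float = 0.2
    #: hitchhiking emulation: neutral variants within this distance of a
    #: size-affecting QTL have their cultivar frequency pushed toward the
    #: nearer boundary by selection_shift (diversity loss in the swept
    #: window); 0 disables it and keeps pure Balding-Nichols frequencies.
    sweep_flank_bp: int = 0
    environments: tuple[str, ...] = ("ZX2021", "ZX2022", "ZX2023", "BJ2023")
    n_replicates: int = 2
    trait_means: dict[str, float] = field(
        default_factory=lambda: {"GP3D": 55.0, "GP7D": 75.0, "TKW": 42.0, "KL": 6.2, "KW": 3.0}
    )
    env_offsets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "ZX2021": {"GP3D": 3.0, "GP7D": 2.0, "TKW": 1.0, "KL": 0.05, "KW": 0.02},
            "ZX2022": {"GP3D": -2.0, "GP7D": -1.0, "TKW": -0.5, "KL": -0.03, "KW": -0.01},
            "ZX2023": {"GP3D": 0.0, "GP7D": 0.0, "TKW": 0.0, "KL": 0.0, "KW": 0.0},
            "BJ2023": {"GP3D": 1.0, "GP7D": 1.0, "TKW": 0.8, "KL": 0.04, "KW": 0.015},
        }
    )
    var_gl: dict[str, float] = field(
        default_factory=lambda: {"GP3D": 2.0, "GP7D": 2.0, "TKW": 1.0, "KL": 0.01, "KW": 0.0025}
    )
    var_gy: dict[str, float] = field(
        default_factory=lambda: {"GP3D": 2.0, "GP7D": 2.0, "TKW": 1.0, "KL": 0.01, "KW": 0.0025}
    )
    var_e: dict[str, float] = field(
        default_factory=lambda: {"GP3D": 4.0, "GP7D": 4.0, "TKW": 2.25, "KL": 0.04, "KW": 0.01}
    )
    year_range: tuple[int, int] = (1900, 2020)
    block_size: int = 1
    flip_prob: float = 0.05
    climate_centers: tuple[tuple[float, float], ...] = (
        (8.0, 420.0),
        (12.0, 650.0),
        (16.5, 900.0),
    )
    climate_sds: tuple[float, float] = (1.5, 60.0)
    climate_assoc_qtl: int | None = None
    climate_assoc_strength: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.divergence_f < 1.0):
            raise ValueError("divergence_f must lie in (0, 1)")
        idx = [q.index for q in self.qtls]
        if len(set(idx)) != len(idx):
            raise ValueError("QTL indices must be unique")
        if idx and (min(idx) < 0 or max(idx) >= self.n_variants):
            raise ValueError("QTL index out of range")
        for d in (self.var_gl, self.var_gy, self.var_e):
            if any(v < 0 for v in d.values()):
                raise ValueError("variance components must be >= 0")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_landrace + self.n_cultivar + self.n_other

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.trait_means)


def default_qtl_plan(
    n_variants: int,
    n_antagonistic: int = 30,
    n_synergistic: int = 10,
    n_independent: int = 60,
    rng: np.random.Generator | None = None,
    gp_effect_range: tuple[float, float] = (2.0, 5.0),
    tkw_effect_range: tuple[float, float] = (0.6, 1.5),
    major_frac: float = 0.25,
    gp_major_range: tuple[float, float] = (7.0, 12.0),
    tkw_major_range: tuple[float, float] = (2.5, 4.0),
) -> list[QTL]:
    """Draw a QTL plan with the configured class mix.

    Independent QTLs are split evenly between dormancy-only and size-only.
    The effect-size distribution is L-shaped, as in real trait architectures:
    a fraction ``major_frac`` of QTLs are major loci (uniform on the
    ``*_major_range`` ranges, in the Tamyb10/TaMFT league) over a polygenic
    background of minor loci (the base ranges).  Signs are random for
    independent/antagonistic QTLs; synergistic QTLs are oriented so one
    allele raises TKW and lowers GP.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n_total = n_antagonistic + n_synergistic + n_independent
    if n_total > n_variants:
        raise ValueError("more QTLs requested than variants")
    positions = rng.choice(n_variants, size=n_total, replace=False)
    positions.sort()
    classes = (
        ["antagonistic"] * n_antagonistic
        + ["synergistic"] * n_synergistic
        + ["independent-dormancy"] * (n_independent // 2)
        + ["independent-size"] * (n_independent - n_independent // 2)
    )
    rng.shuffle(classes)
    qtls = []
    for idx, cls in zip(positions, classes):
        if rng.random() < major_frac:
            bg = rng.uniform(*gp_major_range)
            bt = rng.uniform(*tkw_major_range)
        else:
            bg = rng.uniform(*gp_effect_range)
            bt = rng.uniform(*tkw_effect_range)
        if cls == "antagonistic":
            s = rng.choice([-1.0, 1.0])
            q = QTL(int(idx), cls, s * bg, s * bt)
        elif cls == "synergistic":
            s = rng.choice([-1.0, 1.0])
            q = QTL(int(idx), cls, -s * bg, s * bt)
        elif cls == "independent-dormancy":
            q = QTL(int(idx), cls, rng.choice([-1.0, 1.0]) * bg, 0.0)
        else:
            q = QTL(int(idx), cls, 0.0, rng.choice([-1.0, 1.0]) * bt)
        qtls.append(q)
    return qtls


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    climate: pd.DataFrame
    config: SimulationConfig
    qtl_truth: pd.DataFrame
    genetic_values: dict[str, np.ndarray]


# ---------------------------------------------------------------------------


def _variant_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms, lengths = zip(*cfg.chromosome_lengths.items())
    lengths = np.array(lengths, float)
    counts = np.floor(cfg.n_variants * lengths / lengths.sum()).astype(int)
    counts[0] += cfg.n_variants - counts.sum()
    rows = []
    for chrom, L, k in zip(chroms, lengths, counts):
        pos = np.unique(rng.integers(1, int(L), size=3 * k))
        while len(pos) < k:
            pos = np.unique(np.concatenate([pos, rng.integers(1, int(L), size=2 * k)]))
        pos = np.sort(rng.choice(pos, size=k, replace=False))
        for p in pos:
            rows.append((chrom, int(p)))
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    nucs = np.array(list("ACGT"))
    ref = nucs[rng.integers(0, 4, size=len(df))]
    alt_shift = rng.integers(1, 4, size=len(df))
    alt = nucs[(np.searchsorted(nucs, ref) + alt_shift) % 4]
    df["ref"] = ref
    df["alt"] = alt
    return df


def _favorable_alt_is(q: QTL) -> dict[str, bool]:
    """Whether ALT is the favorable allele, per trait group.

    Size favorable = TKW-increasing; dormancy favorable = GP-decreasing.
    """
    out = {}
    if q.beta_tkw != 0:
        out["size"] = q.beta_tkw > 0
    if q.beta_gp != 0:
        out["dormancy"] = q.beta_gp < 0
    return out


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate genotypes, multi-environment phenotypes and climate data."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    m = cfg.n_variants
    F = cfg.divergence_f

    variants = _variant_table(cfg, rng)
    samples = (
        [f"LR{i:04d}" for i in range(cfg.n_landrace)]
        + [f"CV{i:04d}" for i in range(cfg.n_cultivar)]
        + [f"OT{i:04d}" for i in range(cfg.n_other)]
    )
    groups = (
        ["landrace"] * cfg.n_landrace
        + ["cultivar"] * cfg.n_cultivar
        + ["other"] * cfg.n_other
    )
    group_slices = {
        "landrace": slice(0, cfg.n_landrace),
        "cultivar": slice(cfg.n_landrace, cfg.n_landrace + cfg.n_cultivar),
        "other": slice(cfg.n_landrace + cfg.n_cultivar, n),
    }

    # --- allele frequencies (Balding-Nichols) ---
    p_anc = rng.uniform(0.05, 0.95, size=m)
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    freqs = {g: rng.beta(a, b) for g in ("landrace", "cultivar", "other")}

    qtl_idx = np.array([q.index for q in cfg.qtls], dtype=int)
    # breeding selection: shift favorable-size-allele frequency in cultivars.
    # Cultivars descend from landraces, so at selected loci the cultivar
    # frequency starts from the landrace draw (selection dominates drift);
    # neutral loci keep their independent Balding-Nichols draw.
    for q in cfg.qtls:
        fav = _favorable_alt_is(q)
        if "size" in fav and cfg.selection_shift != 0.0:
            shift = cfg.selection_shift if fav["size"] else -cfg.selection_shift
            freqs["cultivar"][q.index] = np.clip(
                freqs["landrace"][q.index] + shift, 0.01, 0.99
            )
            if cfg.sweep_flank_bp > 0:
                # hitchhiking: linked neutral variants drift toward fixation
                chrom = variants["chrom"].iat[q.index]
                pos = variants["pos"].iat[q.index]
                near = (
                    (variants["chrom"] == chrom)
                    & (variants["pos"] - pos).abs().le(cfg.sweep_flank_bp)
                ).to_numpy()
                near[qtl_idx] = False
                p_cv = freqs["cultivar"][near]
                toward = np.where(p_cv >= 0.5, 1.0, -1.0)
                freqs["cultivar"][near] = np.clip(
                    p_cv + toward * cfg.selection_shift, 0.01, 0.99
                )

    # --- genotypes ---
    dosage = np.empty((n, m), dtype=float)
    is_qtl = np.zeros(m, dtype=bool)
    if len(qtl_idx):
        is_qtl[qtl_idx] = True
    for g, sl in group_slices.items():
        ng = sl.stop - sl.start
        if ng == 0:
            continue
        p = freqs[g]
        if cfg.block_size <= 1:
            dosage[sl] = rng.binomial(2, p[None, :], size=(ng, m))
        else:
            dos = np.empty((ng, m))
            j = 0
            while j < m:
                block = [j]
                while (
                    len(block) < cfg.block_size
                    and block[-1] + 1 < m
                    and not is_qtl[block[-1] + 1]
                    and variants["chrom"].iat[block[-1] + 1] == variants["chrom"].iat[j]
                ):
                    block.append(block[-1] + 1)
                if is_qtl[j] or len(block) == 1:
                    dos[:, j] = rng.binomial(2, p[j], size=ng)
                    j += 1
                    continue
                pb = p[j]
                h = rng.random((ng, 2)) < pb  # latent founder haplotypes
                for v in block:
                    flips = rng.random((ng, 2)) < cfg.flip_prob
                    dos[:, v] = (h ^ flips).sum(axis=1)
                j = block[-1] + 1
            dosage[sl] = dos

    # --- genetic values ---
    genetic = {t: np.zeros(n) for t in cfg.traits}
    for q in cfg.qtls:
        z = dosage[:, q.index] - 2.0 * p_anc[q.index]
        for trait, (which, scale) in TRAIT_EFFECT_SCALE.items():
            if trait not in genetic:
                continue
            beta = q.beta_gp if which == "gp" else q.beta_tkw
            genetic[trait] += scale * beta * z

    # --- release years: rank-matched to favorable size-allele count ---
    size_qtls = [q for q in cfg.qtls if q.beta_tkw != 0]
    fav_size_count = np.zeros(n)
    for q in size_qtls:
        d = dosage[:, q.index]
        fav_d = d if q.beta_tkw > 0 else 2.0 - d
        fav_size_count += fav_d >= 1
    release_year = np.full(n, np.nan)
    cv = group_slices["cultivar"]
    ncv = cv.stop - cv.start
    if ncv:
        jitter = rng.uniform(0, 0.5, size=ncv)  # RNG tie-breaking
        order = np.argsort(fav_size_count[cv] + jitter, kind="stable")
        years = np.round(np.linspace(*cfg.year_range, num=ncv))
        yr = np.empty(ncv)
        yr[order] = years  # more favorable size alleles -> later year
        release_year[cv] = yr

    metadata = pd.DataFrame(
        {
            "group": groups,
            "release_year": release_year,
            "latitude": rng.uniform(25, 55, size=n).round(4),
            "longitude": rng.uniform(-10, 120, size=n).round(4),
            "seed_color": rng.choice(["red", "white"], size=n),
        },
        index=pd.Index(samples, name="accession"),
    )
    G = GenotypeMatrix(samples=samples, variants=variants, dosage=dosage, metadata=metadata)

    # --- phenotypes ---
    locs = sorted({io_core.parse_environment(e)[0] for e in cfg.environments})
    years_u = sorted({io_core.parse_environment(e)[1] for e in cfg.environments})
    rows = []
    clipped = {t: 0 for t in cfg.traits}
    total = {t: 0 for t in cfg.traits}
    for trait in cfg.traits:
        gl = rng.normal(0, np.sqrt(cfg.var_gl.get(trait, 0.0)), size=(n, len(locs)))
        gy = rng.normal(0, np.sqrt(cfg.var_gy.get(trait, 0.0)), size=(n, len(years_u)))
        sd_e = np.sqrt(cfg.var_e.get(trait, 0.0))
        for env in cfg.environments:
            loc, year = io_core.parse_environment(env)
            li, yi = locs.index(loc), years_u.index(year)
            base = (
                cfg.trait_means[trait]
                + cfg.env_offsets.get(env, {}).get(trait, 0.0)
                + genetic[trait]
                + gl[:, li]
                + gy[:, yi]
            )
            for rep in range(1, cfg.n_replicates + 1):
                vals = base + rng.normal(0, sd_e, size=n)
                if trait in io_core.DORMANCY_TRAITS:
                    clipped[trait] += int(((vals < 0) | (vals > 100)).sum())
                    vals = np.clip(vals, 0.0, 100.0)
                else:
                    vals = np.maximum(vals, 0.01)
                total[trait] += n
                rows.append(
                    pd.DataFrame(
                        {
                            "accession": samples,
                            "trait": trait,
                            "environment": env,
                            "replicate": rep,
                            "value": vals,
                        }
                    )
                )
    pheno = PhenotypeTable(pd.concat(rows, ignore_index=True))
    for t in cfg.traits:
        if t in io_core.DORMANCY_TRAITS and total[t] and clipped[t] / total[t] > 0.5:
            warnings.warn(
                f"{t}: {clipped[t] / total[t]:.0%} of values hit the [0, 100] clip "
                "boundary; clipping distorts effect-size linearity",
                stacklevel=2,
            )

    # --- climate ---
    K = len(cfg.climate_centers)
    centers = np.array(cfg.climate_centers, float)
    order_b12 = np.argsort(centers[:, 1])
    cluster = rng.integers(0, K, size=n)
    if cfg.climate_assoc_qtl is not None:
        q = next(q for q in cfg.qtls if q.index == cfg.climate_assoc_qtl)
        fav = _favorable_alt_is(q)
        alt_is_fav = fav.get("size", fav.get("dormancy", True))
        d = dosage[:, q.index]
        fav_d = d if alt_is_fav else 2.0 - d
        carrier = fav_d >= 1
        hi = order_b12[-1]  # wettest cluster
        take = carrier & (rng.random(n) < cfg.climate_assoc_strength)
        cluster[take] = hi
    bio1 = centers[cluster, 0] + rng.normal(0, cfg.climate_sds[0], size=n)
    bio12 = np.maximum(centers[cluster, 1] + rng.normal(0, cfg.climate_sds[1], size=n), 0.0)
    climate = pd.DataFrame(
        {"accession": samples, "bio1": bio1, "bio12": bio12, "true_cluster": cluster}
    )

    truth_rows = []
    for q in cfg.qtls:
        fav = _favorable_alt_is(q)
        var = variants.iloc[q.index]
        truth_rows.append(
            {
                "index": q.index,
                "chrom": var["chrom"],
                "pos": var["pos"],
                "qtl_class": q.qtl_class,
                "beta_gp": q.beta_gp,
                "beta_tkw": q.beta_tkw,
                "fav_size_allele": (
                    ("alt" if fav["size"] else "ref") if "size" in fav else ""
                ),
                "fav_dormancy_allele": (
                    ("alt" if fav["dormancy"] else "ref") if "dormancy" in fav else ""
                ),
                "p_anc": p_anc[q.index],
                "p_landrace": freqs["landrace"][q.index],
                "p_cultivar": freqs["cultivar"][q.index],
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "index", "chrom", "pos", "qtl_class", "beta_gp", "beta_tkw",
            "fav_size_allele", "fav_dormancy_allele", "p_anc", "p_landrace",
            "p_cultivar",
        ],
    )
    return SimulatedDataset(G, pheno, climate, cfg, truth, genetic)


# ---------------------------------------------------------------------------


def write_dataset(ds: SimulatedDataset, directory, overwrite: bool = False) -> dict[str, Path]:
    """Write VCF + metadata/phenotype/climate TSVs + a manifest JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "genotypes.vcf",
        "metadata": directory / "samples.tsv",
        "phenotypes": directory / "phenotypes.tsv",
        "climate": directory / "climate.tsv",
        "manifest": directory / "manifest.json",
    }
    for p in paths.values():
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace")
    io_core.write_vcf(ds.genotypes, paths["vcf"])
    io_core.write_metadata(ds.genotypes, paths["metadata"])
    io_core.write_phenotypes(ds.phenotypes, paths["phenotypes"])
    io_core.write_climate(ds.climate, paths["climate"])
    cfg_dict = dataclasses.asdict(ds.config)
    cfg_dict["qtls"] = [dataclasses.asdict(q) for q in ds.config.qtls]
    manifest = {"seed": ds.config.seed, "config": cfg_dict}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    logger.info("wrote synthetic dataset to %s", directory)
    return paths
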