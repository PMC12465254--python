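# Methods

## Scope and data model

The package analyses a diploid, near-inbred diversity panel genotyped at
biallelic SNPs (VCF in, dosage = ALT-allele count, NaN for missing) with a
sample table assigning each accession to one of `landrace`, `cultivar`,
`other`, plus optional release year, coordinates and seed color. Phenotypes
are long-format multi-environment observations of five traits: germination
percentage after 3/7 days (GP3D, GP7D, %; low = strong dormancy) and
thousand-kernel weight / kernel length / kernel width (TKW g, KL mm, KW mm).
Coordinates are 1-based; windows are half-open `[start, start+size)`.
Missing dosages are mean-imputed per variant only inside GRM / PCA /
regression computations; allele-frequency, π and F_ST computations use
observed allele counts.

Variant filtering defaults to MAF > 0.05, site missingness < 0.20, sample
missingness < 0.10, and iterates variant- and sample-level passes to a fixed
point so filtering is idempotent.

## Multi-environment models

**Variance components.** Environments are location×year cells parsed from
labels like `ZX2021`. Components (σ²G, σ²GL, σ²GY, σ²E) are estimated by
Henderson's Method III: sequential fitting of
`[1, L, Y, LY] → +G → +GL → +GY`, with exact expected sums of squares
obtained from projector traces, solved as a linear system and truncated at
zero. The estimator is deterministic and exact in expectation for arbitrary
unbalanced layouts (e.g. one location observed in a single year). A
component whose stratum is absent (single location, year or replicate) is
set to 0 with a warning. Genotype×location×year interaction is not modelled
separately; it folds into σ²E. REML would be the main alternative; the
moment estimator was chosen for determinism and desk-scale speed, and the
two coincide in expectation for the balanced designs the generator emits.

**Heritability.** `H² = σ²G / (σ²G + σ²GL/L + σ²GY/Y + σ²E/(Y·R·L))`,
evaluated exactly; σ²G = 0 returns 0 with a warning. Scale-invariant by
construction. L, Y are counts of distinct locations/years; R is the median
replicate count per accession×environment cell.

**BLUEs.** Genotype enters as fixed full-rank dummies; environment main
effects as sum-to-zero fixed contrasts; G×L and G×Y as random effects with
ridge penalties λ = σ²E/σ²component from the Henderson-III fit, solved by
sparse mixed-model equations. Environment main effects are *fixed* because
with ~2 locations and ~3 years their variances are not meaningfully
estimable, and sum-coding gives the exact property that on balanced
noise-free data BLUE_i equals the accession mean. BLUEs are
location-equivariant (adding c to all observations adds c to every BLUE).
A single-environment table falls back to per-accession means with a warning.

**Genetic correlation.** Haseman–Elston regression: cross-products of
standardized trait pairs regressed on off-diagonal GRM entries; r_g =
ĉov_g/√(v̂_g1·v̂_g2), standard error by delete-a-block jackknife over
accessions (20 blocks). Non-positive variance estimates flag the result as
undefined; |r_g| > 1 is clipped with an explicit flag. This is a
deterministic method-of-moments alternative to bivariate REML, adequate for
synthetic validation; its sampling error is larger than REML's at equal n.

**Group comparisons** use Welch's t-test throughout (unequal group sizes and
variances between landraces and cultivars).

## Mixed-model association scan

VanRaden GRM `K = ZZᵀ / (2Σp(1−p))` with Z the dosage deviation from 2p.
PCA operates on centered, √(2pq)-standardized dosages with a deterministic
sign convention (largest-magnitude loading positive). The scan follows
EMMAX: δ = σ²e/σ²g is estimated once under the covariate-only null by
profile REML on the eigendecomposed GRM (61-point log₁₀ grid on
[1e−5, 1e5], refined by bounded minimization), then each variant is tested
by GLS with fixed variance components; Wald P from a t distribution with
n − #PCs − 2 df. Eigenvalues below 1e−8 are clipped with a warning. One PC
covariate by default. With an identity kinship the scan reduces exactly to
OLS (a regression test asserts agreement to 1e−6), and on permuted
phenotypes the P < 0.05 fraction is calibrated (asserted within
[0.03, 0.07] over 20 replicates of 2000 variants).

Significant variants (−log₁₀P > 5, the fixed threshold) are clumped:
consecutive significant SNPs ≤ 1 Mb apart (configurable) join a cluster;
clusters with **more than five** members become associated regions; the lead
SNP is the minimum-P member with position as tie-break. LD decay reports
binned mean pairwise r² up to 1 Mb; the half-decay distance is the midpoint
of the first bin at or below half the maximum bin mean, defined as the first
populated bin when the curve is already flat (no decay left to observe).

## Selection scans

π per site is `(n/(n−1))·2p(1−p)` over observed alleles, summed per window
and divided by the *full window length* in bp (the convention of the common
windowed-π tools; a documented bias where genotyped sites are sparse).
F_ST is Weir & Cockerham (1984) with genotype-level heterozygosity, combined
as a ratio of sums within windows and genome-wide; negative window values
are retained. The π-ratio is π_landrace/π_cultivar; windows with zero
cultivar diversity are dropped with a logged count. Sweep candidates are
windows at/above the empirical (1 − 0.05) quantile per statistic, merged
into regions; the union across statistics carries per-statistic provenance
and accepts externally computed region lists (e.g. XP-CLR output, which is
not reimplemented here). A GWAS region is "selected" if it overlaps a sweep
region by ≥ 1 bp.

## Favorable alleles and pleiotropy classes

Favorable = GP-decreasing allele (dormancy) or trait-increasing allele
(size), taken from the scan's β sign (β > 0 ⇔ ALT raises the trait), for
SNPs above the significance threshold. FAF shifts compare favorable-allele
frequencies between groups (direction = sign of cultivar − landrace).
Per-accession accumulation uses a presence/absence carriage rule (favorable
dosage ≥ 1; missing counts 0) suited to near-inbred material. Trend fits
bin x into equal-width bins (≥ 5 members, sparse bins merged rightward) and
regress bin-mean y on bin midpoints.

Classification of the union of the two traits' MTA sets: per trait, the two
homozygote groups (dosage 0 vs 2) are compared by Welch's t-test on the
BLUE; a trait is "affected" if the SNP is in that trait's MTA set or P <
0.05 (configurable). One affected trait → independent. Both → orient on the
TKW-increasing allele: GP higher → antagonistic, GP lower → synergistic.
SNPs with a homozygote class under 5 accessions fall back to a
dosage-regression slope test and are flagged. Class percentages are reported
over the union (the intersection size is reported as an alternative
denominator). Note the per-SNP t-test is a marginal test: under strong
group-level selection, genome-wide allele-frequency differentiation induces
dosage–phenotype correlations at SNPs with no causal second-trait effect,
inflating the antagonistic class; this is a property of the method itself,
so class-recovery validation runs on panels without the selection shift.

PVE of a SNP set: greedy LD pruning at r² ≥ 0.9 keeping lower-P members, a
cap of n/2 lowest-P variants, then joint OLS on mean-imputed dosages; PVE is
the R². A singular design triggers re-pruning at r² ≥ 0.99 with a warning.

## Haplotypes, pyramiding, climate

Overlapping dormancy×size regions (≥ 1 bp) are named `Qgd-gs.<chrom>.<n>`.
tagSNPs come from greedy tagging of the region's significant SNPs (keep
lowest-P, absorb r² ≥ 0.8). Haplotypes are homozygote tagSNP dosage tuples —
unphased data cannot resolve heterozygote haplotypes, so het/missing
accessions are unassigned; labels are Hap 1, Hap 2, … by descending landrace
frequency, and haplotypes with fewer than ten accessions are excluded from
tests. The lowest-GP retained haplotype is "favorable-dormancy"; a region is
synergistic/antagonistic if that haplotype's TKW is significantly
higher/lower than the highest-GP haplotype's. Pyramiding groups accessions
by the number of favorable haplotypes carried; improvements are
`(GP₀−GP_g)/GP₀·100` and `(TKW_g−TKW₀)/TKW₀·100` against the
zero-favorable baseline, with Welch tests versus that group.

Climate enters as a pre-extracted per-accession (Bio1 °C, Bio12 mm) table;
raster extraction is out of scope but any table with those columns plugs in.
Accessions cluster into K = 3 populations by k-means on z-scored (Bio1,
Bio12) with 100 restarts and seed control; labels are renumbered by
ascending mean Bio12 so Pop K is always the wettest. Haplotype–climate
associations are Welch t-tests between favorable- and
undesirable-haplotype carriers.

## The synthetic generator

`synth.simulate_dataset` emulates a landrace→cultivar panel:

- **Genotypes**: ancestral frequencies ~ U(0.05, 0.95); per-subpopulation
  frequencies ~ Balding–Nichols Beta with differentiation F (default 0.07,
  a typical landrace/cultivar divergence); dosages Binomial(2, p). F is the
  expected Weir–Cockerham F_ST, which the tests verify (±0.015 over 50
  replicates). Optional founder-block linkage: variants in a block copy a
  latent founder haplotype with per-variant flip probability, giving local
  r² without a recombination map (off by default).
- **QTLs**: per-allele effects on GP (%/copy) and TKW (g/copy), with GP7D,
  KL, KW receiving scaled copies (0.75, 0.03, 0.015) to emulate correlated
  trait batteries. Class conventions: antagonistic = same sign on both
  traits, synergistic = opposite (TKW up, GP down), independent = one trait.
  `default_qtl_plan` draws an L-shaped effect distribution: 25% major loci
  (|β_GP| ∈ [7, 12] %, |β_TKW| ∈ [2.5, 4] g) over a minor-polygene
  background (|β_GP| ∈ [2, 5], |β_TKW| ∈ [0.6, 1.5]), mirroring real
  dormancy/size architectures where a few major genes sit on a polygenic
  background. With the default 100-QTL plan this yields a GP3D genetic SD
  around 25% and TKW around 7–9 g, matching the spread reported for real
  diversity panels (GP3D BLUEs spanning roughly 6–95%, TKW 20–62 g).
- **Breeding selection**: at size-affecting QTLs the cultivar frequency is
  the landrace frequency plus `selection_shift` (default 0.2) toward the
  TKW-increasing allele, clipped to [0.01, 0.99] — cultivars descend from
  landraces, so at selected loci selection dominates drift; neutral loci
  keep independent Balding–Nichols draws. Optional `sweep_flank_bp` pushes
  linked neutral variants toward fixation in cultivars to emulate
  hitchhiking diversity loss (off by default). Cultivar release years are
  rank-matched to the per-accession favorable size-allele count (RNG
  tie-breaks), spanning 1900–2020.
- **Phenotypes**: trait mean + environment offset + Σ β·(dosage − 2p_anc) +
  G×L + G×Y + residual, two replicates in each of ZX2021/ZX2022/ZX2023/
  BJ2023 (deliberately reproducing the one-location-one-year unbalance).
  Default variance components: σ²GL = σ²GY = 2, σ²E = 4 (GP, %²);
  1, 1, 2.25 (TKW, g²). GP is clipped to [0, 100] after noise (a warning
  fires if > 50% of values clip); clipping compresses extreme genotypic
  values and biases extreme-effect recovery, which the trend/classification
  tests tolerate by construction.
- **Climate**: (Bio1, Bio12) from three cluster centers (8 °C/420 mm,
  12 °C/650 mm, 16.5 °C/900 mm; SD 1.5 °C / 60 mm); optionally, carriers of
  a chosen QTL's favorable allele are drawn from the wettest cluster with
  probability 0.9 to plant a haplotype–climate association.

What the generator does **not** emulate: hexaploid subgenome homoeology,
realistic wheat LD maps and recombination, demographic history beyond a
single divergence parameter, genotype-by-environment structure beyond
additive G×L/G×Y draws, genotyping error, and ascertainment bias. Passing
tests therefore demonstrate correctness of the estimators and recovery under
the stated generative model, not robustness to every feature of real panel
data.

## Validation problem sizes

The simulation-based checks run at desk scale, chosen to keep the full suite
within a few minutes while leaving the assertions statistically meaningful:
F_ST calibration at 2000 SNPs × (200+200) accessions × 50 replicates;
mixed-model null calibration at 2000 variants × 200 accessions × 20
replicates; class-recovery and FAF panels at 5000 variants × 500 accessions
× 3 replicates (30 antagonistic / 10 synergistic / 60 independent QTLs);
PVE checks at n = 500 × 20 replicates; variance-component recovery at 300
accessions × 8 observations × 20 replicates. `scripts/acceptance.py` uses
the same conditions with sub-seeds derived from `--seed`.

## Numerical choices and edge cases

- Quantile thresholds for sweep calling use linear-interpolation empirical
  quantiles with a ≥ rule (equal-valued windows are all selected).
- Region/lead ties break toward smaller position; haplotype label ties break
  by overall count then allele tuple, making every labelling deterministic.
- All pipeline TSVs are written with `%.6g` floats; `antapleio run` is
  byte-reproducible given (config, seed).
- Degenerate inputs error early with actionable messages: all variants
  filtered, all-monomorphic GRM, empty MTA union, single-haplotype regions
  (warned, labelled `none`), constant-x trend fits.

## Known limitations

- Henderson III can attribute variance poorly when the location×year grid is
  extremely sparse; components are then near-unidentifiable and are reported
  truncated at zero rather than regularized.
- The EMMAX single-δ approximation understates uncertainty for variants with
  very strong effects (the usual trade-off against exact per-variant REML).
- The homozygote t-test classification inherits the confounding-by-structure
  discussed above; interpreting class frequencies on strongly selected
  panels requires that caveat.
- Genetic correlation by Haseman–Elston has no closed-form small-sample
  correction; the block jackknife understates the SE for very small panels.
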