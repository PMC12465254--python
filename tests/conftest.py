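import numpy as np
import pandas as pd
import pytest

from antapleio.io_core import GenotypeMatrix, PhenotypeTable
from antapleio import synth


def make_genotypes(dosage, groups=None, chrom="1A", spacing=1000, start=1000):
    """GenotypeMatrix from a raw dosage array with evenly spaced variants."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    samples = [f"S{i:03d}" for i in range(n)]
    if groups is None:
        groups = ["landrace"] * (n // 2) + ["cultivar"] * (n - n // 2)
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": start + spacing * np.arange(m),
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    meta = pd.DataFrame({"group": groups}, index=samples)
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage,
                         metadata=meta)


def balanced_phenotypes(genetic, trait="GP3D", envs=("ZX2021", "ZX2022"),
                        n_reps=2, mean=50.0, env_offsets=None, noise=None,
                        rng=None):
    """Balanced PhenotypeTable: value = mean + g_i + env_offset (+ noise)."""
    genetic = np.asarray(genetic, float)
    samples = [f"S{i:03d}" for i in range(len(genetic))]
    env_offsets = env_offsets or {e: 0.0 for e in envs}
    rows = []
    for env in envs:
        for rep in range(1, n_reps + 1):
            vals = mean + genetic + env_offsets[env]
            if noise is not None:
                vals = vals + rng.normal(0, noise, size=len(genetic))
            rows.append(pd.DataFrame({
                "accession": samples, "trait": trait, "environment": env,
                "replicate": rep, "value": vals,
            }))
    return PhenotypeTable(pd.concat(rows, ignore_index=True))


@pytest.fixture(scope="session")
def small_sim():
    """Modest two-subpopulation panel with planted QTLs of every class."""
    rng = np.random.default_rng(11)
    cfg = synth.SimulationConfig(
        n_landrace=100,
        n_cultivar=100,
        n_other=20,
        n_variants=600,
        qtls=synth.default_qtl_plan(600, 6, 3, 8, rng),
        seed=11,
    )
    return synth.simulate_dataset(cfg)
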