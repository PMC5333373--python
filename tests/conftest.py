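from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from splicemap import SimConfig
from splicemap.simulate import simulate_dataset
from splicemap.types import ASEventTable, CovariateTable, GenotypeMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale planted study used across module tests."""
    return SimConfig(
        n_samples=150,
        n_snps=400,
        n_events=50,
        chrom_length=4_000_000,
        n_causal=8,
        maf_range=(0.1, 0.5),
        frac_causal_in_gwas_loci=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


def toy_genotypes(dosage_rows: dict[str, list[float]], positions: list[int] | None = None,
                  chrom: str = "chr1") -> GenotypeMatrix:
    """Hand-built genotype panel from explicit dosage vectors."""
    snp_ids = list(dosage_rows)
    n = len(next(iter(dosage_rows.values())))
    samples = [f"S{i:03d}" for i in range(1, n + 1)]
    if positions is None:
        positions = list(range(1000, 1000 + 1000 * len(snp_ids), 1000))
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    dosage = pd.DataFrame(
        np.asarray([dosage_rows[s] for s in snp_ids], dtype=float),
        index=snps.index,
        columns=samples,
    )
    geno = GenotypeMatrix(snps, dosage)
    geno.recompute_maf()
    return geno


def toy_events(rows: list[tuple], samples: list[str], psi: np.ndarray,
               quality_ok: np.ndarray | None = None) -> ASEventTable:
    """Hand-built event table; rows are (event_id, chrom, start, end)."""
    events = pd.DataFrame(
        [
            {"gene": f"G_{eid}", "as_type": "AltEX", "chrom": chrom, "span_start": s, "span_end": e}
            for eid, chrom, s, e in rows
        ],
        index=pd.Index([r[0] for r in rows], name="event_id"),
    )
    psi = np.asarray(psi, dtype=float)
    if quality_ok is None:
        quality_ok = ~np.isnan(psi)
    return ASEventTable(
        events,
        pd.DataFrame(psi, index=events.index, columns=samples),
        pd.DataFrame(np.asarray(quality_ok, dtype=bool), index=events.index, columns=samples),
    )


def toy_covariates(samples: list[str], rng: np.random.Generator | None = None) -> CovariateTable:
    rng = rng or np.random.default_rng(0)
    return CovariateTable(
        pd.DataFrame(
            {"age_death": rng.normal(70, 10, len(samples))},
            index=pd.Index(samples, name="sample_id"),
        )
    )
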