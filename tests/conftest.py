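import numpy as np
import pandas as pd
import pytest

from qtlcurator.containers import DosageMatrix
from qtlcurator.simulate import simulate_genotypes


def make_dosage_matrix(
    dosage: np.ndarray,
    chromosome: str = "chr1",
    sex: list[str] | None = None,
    positions: list[int] | None = None,
    r2: list[float] | None = None,
) -> DosageMatrix:
    """Hand-built DosageMatrix for small explicit test cases."""
    dosage = np.asarray(dosage, dtype=float)
    n, v = dosage.shape
    positions = positions or [1_000_000 + 1000 * j for j in range(v)]
    variants = pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": positions,
            "ref": "A",
            "alt": "G",
            "r2": r2 if r2 is not None else np.nan,
        }
    )
    from qtlcurator.containers import classify_region

    variants["region"] = [
        classify_region(chromosome, int(p)) for p in positions
    ]
    variants["variant"] = (
        variants["chromosome"].astype(str)
        + "_" + variants["position"].astype(str)
        + "_A_G"
    )
    variants = variants[
        ["variant", "chromosome", "position", "ref", "alt", "region", "r2"]
    ]
    return DosageMatrix(
        samples=[f"S{i}" for i in range(n)],
        sex=sex or ["unknown"] * n,
        variants=variants,
        dosage=dosage,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genotypes():
    return simulate_genotypes(80, 12, maf=0.3, seed=11)


@pytest.fixture
def sumstats_frame(small_genotypes, rng):
    """A valid summary-statistics frame over the small genotype panel."""
    from qtlcurator.cis import nominal_scan

    y = rng.standard_normal(80)
    return nominal_scan(
        y, small_genotypes, trait_id="traitA", group_id="geneA"
    ).drop(columns=["note"])
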