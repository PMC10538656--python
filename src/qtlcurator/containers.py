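"""In-memory containers shared across the pipeline.

All genomic intervals held by these containers are 0-based half-open;
1-based conventions (VCF positions, GFF3 features) are converted at the I/O
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# GRCh38 pseudoautosomal regions, 1-based inclusive bounds as published.
PAR1_GRCH38 = (10_001, 2_781_479)
PAR2_GRCH38 = (155_701_383, 156_030_895)

AUTOSOME = "autosome"
X_PAR = "X_PAR"
X_NONPAR = "X_nonPAR"

_X_NAMES = {"X", "chrX", "23", "chr23"}


def classify_region(
    chromosome: str,
    position: int,
    par1: tuple[int, int] = PAR1_GRCH38,
    par2: tuple[int, int] = PAR2_GRCH38,
) -> str:
    """Tag a variant as autosome / X_PAR / X_nonPAR from its 1-based position."""
    if chromosome not in _X_NAMES:
        return AUTOSOME
    if par1[0] <= position <= par1[1] or par2[0] <= position <= par2[1]:
        return X_PAR
    return X_NONPAR


VARIANT_COLUMNS = ["variant", "chromosome", "position", "ref", "alt", "region", "r2"]


@dataclass
class DosageMatrix:
    """Samples x variants genotype dosages in [0, 2].

    Parameters
    ----------
    samples : list of str
    sex : list of str
        Per-sample label in {"female", "male", "unknown"}, aligned to samples.
    variants : pandas.DataFrame
        One row per variant with columns ``variant`` (canonical id),
        ``chromosome``, ``position`` (1-based), ``ref``, ``alt``, ``region``
        (autosome / X_PAR / X_nonPAR) and ``r2`` (imputation quality, NaN when
        unavailable).
    dosage : ndarray, shape (n_samples, n_variants)
        Alt-allele dosages; NaN marks a missing genotype.
    """

    samples: list[str]
    sex: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(self.sex) != len(self.samples):
            raise ValueError("sex labels must align with samples")
        obs = self.dosage[np.isfinite(self.dosage)]
        if obs.size and (obs.min() < -1e-9 or obs.max() > 2 + 1e-9):
            raise ValueError("observed dosages must lie in [0, 2]")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variants table lacks columns {missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missingness(self) -> np.ndarray:
        """Fraction of missing genotypes per variant."""
        return np.mean(~np.isfinite(self.dosage), axis=0)

    def sample_missingness(self) -> np.ndarray:
        """Fraction of missing genotypes per sample."""
        return np.mean(~np.isfinite(self.dosage), axis=1)

    def maf(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Folded minor-allele frequency from observed dosages (mean/2)."""
        d = self.dosage if sample_mask is None else self.dosage[sample_mask]
        with np.errstate(invalid="ignore"):
            af = np.nanmean(d, axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def female_mask(self) -> np.ndarray:
        return np.array([s == "female" for s in self.sex])

    def male_mask(self) -> np.ndarray:
        return np.array([s == "male" for s in self.sex])

    def subset_variants(self, keep: np.ndarray) -> "DosageMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return replace(
            self,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
        )

    def subset_samples(self, keep: np.ndarray) -> "DosageMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return replace(
            self,
            samples=[self.samples[i] for i in idx],
            sex=[self.sex[i] for i in idx],
            dosage=self.dosage[idx, :],
        )


TRAIT_COLUMNS = ["trait_id", "group_id", "chromosome", "start", "end", "method"]

STAGES = ("raw", "tpm", "usage", "standardised")
METHODS = ("ge", "exon", "tx", "txrevise", "leafcutter")


@dataclass
class TraitMatrix:
    """Samples x molecular traits with trait metadata and a pipeline stage tag.

    ``traits`` carries one row per trait: ``trait_id``, ``group_id`` (gene or
    splice-junction cluster), genomic span (0-based half-open ``start``/``end``
    on ``chromosome``) and quantification ``method`` (ge / exon / tx /
    txrevise / leafcutter).  ``stage`` records how far along the normalisation
    pipeline the values are: raw, tpm, usage or standardised.
    """

    samples: list[str]
    traits: pd.DataFrame
    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.traits)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.traits)} traits"
            )
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        missing = [c for c in TRAIT_COLUMNS if c not in self.traits.columns]
        if missing:
            raise ValueError(f"traits table lacks columns {missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def groups(self) -> dict[str, np.ndarray]:
        """Map group_id -> integer indices of its traits (in table order)."""
        out: dict[str, np.ndarray] = {}
        for gid, sub in self.traits.groupby("group_id", sort=False):
            out[str(gid)] = sub.index.to_numpy()
        return out

    def subset_traits(self, keep: np.ndarray) -> "TraitMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return replace(
            self,
            traits=self.traits.iloc[idx].reset_index(drop=True),
            values=self.values[:, idx],
        )


@dataclass
class TranscriptModel:
    """One transcript: ordered exon list in 0-based half-open coordinates."""

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon [{s}, {e}) in {self.transcript_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)
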