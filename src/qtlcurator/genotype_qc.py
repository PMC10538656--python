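"""Variant- and sample-level genotype quality control.

Implements the standard pre-imputation filters (Hardy-Weinberg exact test,
missingness, minor allele frequency), the post-imputation filters (MAF and
imputation R2) and the X-chromosome conventions: QC statistics on X variants
are computed in females only, and male dosages in the non-pseudoautosomal
region are doubled onto the 0-2 diploid scale.

Defaults follow common QTL-catalogue practice: variants are excluded at
HWE p < 1e-6, missingness > 0.05 or MAF < 0.01; samples at missingness > 5%;
post-imputation, variants need MAF >= 0.01 and R2 >= 0.4.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from qtlcurator.containers import DosageMatrix, X_NONPAR, X_PAR


class QcError(ValueError):
    pass


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditional on the observed allele counts, the heterozygote count under
    HWE follows the distribution

        P(n_Aa = h) ∝ N! / (n_AA! h! n_aa!) * 2^h,

    over all heterozygote counts ``h`` with the same parity as the minor
    allele count.  The p-value is the summed probability of all heterozygote
    counts no more probable than the observed one (the SNP-HWE formulation).
    Probabilities are built by the stable ratio recurrence

        P(h+2) / P(h) = h (h-1) / ((hom1+1)(hom2+1) * 4) ... inverted,

    then normalised, so no factorial overflows occur.

    Returns a p-value in (0, 1].
    """
    for name, v in (("n_AA", n_AA), ("n_Aa", n_Aa), ("n_aa", n_aa)):
        if v < 0 or int(v) != v:
            raise QcError(f"{name} must be a non-negative integer, got {v}")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise QcError("all genotype counts are zero; HWE test undefined")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    # possible het counts share the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    if hets.size == 0:
        return 1.0
    probs = np.empty(hets.size)
    probs[0] = 1.0
    for i in range(1, hets.size):
        h = hets[i]
        hom_r = (n_minor - h) // 2  # minor-homozygote count at h
        hom_c = n - h - hom_r
        # ratio P(h) / P(h-2): going up two hets splits one hom pair
        probs[i] = probs[i - 1] * 4.0 * (hom_r + 1) * (hom_c + 1) / (h * (h - 1))
        if probs[i] > 1e250:  # rescale to dodge overflow at large n
            probs[: i + 1] /= probs[i]
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    # 1e-12 relative slack keeps ties at the observed probability included
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _genotype_counts(dosage_col: np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype counts from a dosage column (nearest integer)."""
    obs = dosage_col[np.isfinite(dosage_col)]
    calls = np.rint(obs).astype(int)
    return int(np.sum(calls == 0)), int(np.sum(calls == 1)), int(np.sum(calls == 2))


def qc_filter_variants(
    matrix: DosageMatrix,
    hwe_p_max: float = 1e-6,
    miss_max: float = 0.05,
    maf_min: float = 0.01,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Variant-level QC: exclude at HWE p < hwe_p_max, missingness > miss_max
    or MAF < maf_min (strict inequalities on all three).

    On X-chromosome variants (PAR and non-PAR) all three statistics are
    computed on female samples only; the decision is then applied to all
    samples.  Returns a boolean keep-mask and a per-variant report with
    columns variant, maf, missingness, hwe_p, decision, reason.
    """
    is_x = matrix.variants["region"].isin([X_PAR, X_NONPAR]).to_numpy()
    females = matrix.female_mask()
    if is_x.any() and not females.any():
        warnings.warn(
            "X-chromosome variants present but no female samples; "
            "X variants are unevaluable and excluded",
            stacklevel=2,
        )

    n_v = matrix.n_variants
    maf = np.full(n_v, np.nan)
    miss = np.full(n_v, np.nan)
    hwe_p = np.full(n_v, np.nan)

    auto_mask = ~is_x
    maf[auto_mask] = matrix.maf()[auto_mask]
    miss[auto_mask] = matrix.missingness()[auto_mask]
    if is_x.any() and females.any():
        fsub = matrix.dosage[females]
        with np.errstate(invalid="ignore"):
            af = np.nanmean(fsub, axis=0) / 2.0
        maf[is_x] = np.minimum(af, 1 - af)[is_x]
        miss[is_x] = np.mean(~np.isfinite(fsub), axis=0)[is_x]

    for j in range(n_v):
        if is_x[j]:
            if not females.any():
                continue
            col = matrix.dosage[females, j]
        else:
            col = matrix.dosage[:, j]
        counts = _genotype_counts(col)
        if sum(counts) > 0:
            hwe_p[j] = hwe_exact_test(*counts)

    keep = np.ones(n_v, dtype=bool)
    reasons = []
    for j in range(n_v):
        why = []
        if is_x[j] and not females.any():
            why.append("unevaluable_no_females")
        else:
            if hwe_p[j] < hwe_p_max:
                why.append("hwe")
            if miss[j] > miss_max:
                why.append("missingness")
            if maf[j] < maf_min:
                why.append("maf")
        keep[j] = not why
        reasons.append(",".join(why))
    report = pd.DataFrame(
        {
            "variant": matrix.variants["variant"],
            "maf": maf,
            "missingness": miss,
            "hwe_p": hwe_p,
            "decision": np.where(keep, "keep", "exclude"),
            "reason": reasons,
        }
    )
    return keep, report


def qc_filter_samples(matrix: DosageMatrix, miss_max: float = 0.05) -> np.ndarray:
    """Keep samples whose genotype missingness is <= miss_max (strict 'more
    than 5% missing' exclusion)."""
    return matrix.sample_missingness() <= miss_max


def harmonise_x_dosage(
    matrix: DosageMatrix, mask_male_hets: bool = False
) -> DosageMatrix:
    """Double male dosages in the X non-PAR region onto the diploid scale.

    Males are haploid outside the pseudoautosomal regions, so imputation
    emits dosages in [0, 1] there; doubling puts them on the same 0-2 scale
    as female genotypes.  Results are clipped to [0, 2]; female samples and
    PAR variants are untouched.  A dosage above 1 pre-doubling triggers a
    warning (haploid expectation violated).  With ``mask_male_hets=True``,
    male non-PAR genotypes at exactly 1.0 — impossible heterozygous hard
    calls on a haploid chromosome — are set missing instead of doubled;
    off by default because a fractional imputed dosage of 1.0 is a
    legitimate value that the doubling rule maps to 2.0.
    """
    males = matrix.male_mask()
    nonpar = (matrix.variants["region"] == X_NONPAR).to_numpy()
    if not males.any() or not nonpar.any():
        return matrix
    dosage = matrix.dosage.copy()
    block = dosage[np.ix_(males, nonpar)]
    if mask_male_hets:
        het = np.isfinite(block) & (np.abs(block - 1.0) < 1e-9)
        if het.any():
            block[het] = np.nan
    if np.nanmax(np.where(np.isfinite(block), block, -np.inf)) > 1 + 1e-9:
        warnings.warn(
            "male non-PAR dosage > 1 before doubling; haploid expectation violated",
            stacklevel=2,
        )
    dosage[np.ix_(males, nonpar)] = np.clip(block * 2.0, 0.0, 2.0)
    return replace(matrix, dosage=dosage)


def post_imputation_filter(
    matrix: DosageMatrix, maf_min: float = 0.01, r2_min: float = 0.4
) -> tuple[np.ndarray, pd.DataFrame]:
    """Post-imputation variant filter: keep iff MAF >= maf_min and R2 >= r2_min.

    A variant with no R2 value is excluded with reason ``missing_r2``.
    """
    maf = matrix.maf()
    r2 = matrix.variants["r2"].to_numpy(dtype=float)
    keep = np.ones(matrix.n_variants, dtype=bool)
    reasons = []
    for j in range(matrix.n_variants):
        why = []
        if maf[j] < maf_min:
            why.append("maf")
        if not np.isfinite(r2[j]):
            why.append("missing_r2")
        elif r2[j] < r2_min:
            why.append("r2")
        keep[j] = not why
        reasons.append(",".join(why))
    report = pd.DataFrame(
        {
            "variant": matrix.variants["variant"],
            "maf": maf,
            "r2": r2,
            "decision": np.where(keep, "keep", "exclude"),
            "reason": reasons,
        }
    )
    return keep, report
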