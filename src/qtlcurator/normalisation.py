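"""Normalisation of molecular-trait matrices ahead of QTL scanning.

Five quantification methods are supported and follow two pipelines:

* count-based traits (gene expression ``ge``, exon expression ``exon``):
  counts -> GC-content correction -> TPM low-expression filter -> inverse
  normal transform;
* usage-based traits (transcript ``tx``, promoter/splicing events
  ``txrevise``, splice junctions ``leafcutter``): expression -> within-group
  usage ratios -> inverse normal transform.

The inverse normal transform maps each trait's ranks onto standard normal
quantiles, Phi^-1((rank - 0.5)/n) with average ranks at ties, so every trait
enters the scan with an identical marginal distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import stats

from qtlcurator.containers import TraitMatrix


class NormalisationError(ValueError):
    pass


def compute_tpm(counts: TraitMatrix, effective_lengths: np.ndarray) -> TraitMatrix:
    """Transcripts-per-million: length-normalise counts, rescale each sample
    to sum to 1e6.

    ``effective_lengths`` is one positive length (bp) per trait, aligned with
    the trait table.  A sample whose counts are all zero has no defined TPM
    and is an error.
    """
    lengths = np.asarray(effective_lengths, dtype=float)
    if lengths.shape != (counts.n_traits,):
        raise NormalisationError(
            f"expected {counts.n_traits} lengths, got {lengths.shape}"
        )
    if (lengths <= 0).any():
        raise NormalisationError("effective lengths must be positive")
    if (counts.values < 0).any():
        raise NormalisationError("counts must be non-negative")
    rate = counts.values / lengths
    totals = rate.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise NormalisationError(
            f"sample(s) with all-zero counts: {[counts.samples[i] for i in zero]}"
        )
    tpm = rate / totals[:, None] * 1e6
    return replace(counts, values=tpm, stage="tpm")


def low_expression_filter(
    tpm: TraitMatrix, threshold: float = 1.0, frac: float = 0.95
) -> np.ndarray:
    """Keep-mask over traits; a trait is dropped when at least ``frac`` of
    samples sit below ``threshold`` TPM.

    The boundary is inclusive: exactly 95% of samples below 1 TPM excludes
    the trait.
    """
    if tpm.stage != "tpm":
        raise NormalisationError(f"expected stage 'tpm', got {tpm.stage!r}")
    below = np.mean(tpm.values < threshold, axis=0)
    return below < frac


def usage_ratios(expr: TraitMatrix) -> TraitMatrix:
    """Within-group usage: each trait divided by the summed expression of its
    group (gene or junction cluster) in the same sample.

    A sample whose group total is zero gets missing usages for every trait of
    that group.  Singleton groups produce a degenerate usage identically 1
    and are flagged with a warning; they carry no usage information and are
    normally dropped upstream.
    """
    if (expr.values[np.isfinite(expr.values)] < 0).any():
        raise NormalisationError("expression must be non-negative")
    values = np.full_like(expr.values, np.nan, dtype=float)
    degenerate = []
    for gid, idx in expr.groups().items():
        block = expr.values[:, idx]
        if len(idx) == 1:
            degenerate.append(gid)
        totals = np.nansum(block, axis=1)
        ok = totals > 0
        values[np.ix_(ok, idx)] = block[ok] / totals[ok, None]
    if degenerate:
        warnings.warn(
            f"singleton group(s) with degenerate usage == 1: {degenerate[:5]}"
            + ("..." if len(degenerate) > 5 else ""),
            stacklevel=2,
        )
    return replace(expr, values=values, stage="usage")


def inverse_normal_transform(values: np.ndarray, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse normal transform of each column.

    Non-missing entries of a column are ranked (ties -> average rank) and
    mapped to Phi^-1((rank - offset) / n).  Missing values propagate.  A
    column with fewer than 2 non-missing values is left entirely missing;
    a fully tied column maps to all zeros (every value at the median rank)
    and must be excluded before scanning as it carries no information.
    """
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        mask = np.isfinite(col)
        obs = col[mask]
        if obs.size < 2:
            continue
        ranks = stats.rankdata(obs, method="average")
        out[mask, j] = stats.norm.ppf((ranks - offset) / obs.size)
    return out[:, 0] if squeeze else out


def standardise(matrix: TraitMatrix, offset: float = 0.5) -> TraitMatrix:
    """Apply the inverse normal transform per trait; final pipeline stage."""
    return replace(
        matrix,
        values=inverse_normal_transform(matrix.values, offset=offset),
        stage="standardised",
    )


def gc_correct(
    counts: TraitMatrix,
    gc_content: np.ndarray,
    effective_lengths: np.ndarray | None = None,
    lowess_frac: float = 0.5,
    min_traits: int = 20,
) -> TraitMatrix:
    """Remove per-sample systematic GC-content trends from log2 expression.

    For every sample, the deviation of log2(count + 0.5) (length-normalised
    when lengths are given) from the cohort-mean profile is smoothed against
    GC fraction (LOWESS); the fitted sample-level trend is subtracted and
    each trait re-centred on its original mean.  This removes the
    sample-specific GC amplification bias that differs between libraries.
    The GC trend shared by the whole cohort is deliberately left in place:
    the per-trait inverse normal transform applied downstream removes any
    trait-level shift, so only between-sample bias can distort association
    testing.  It is a simplified smooth-trend correction, not a full
    conditional quantile normalisation.

    With fewer than ``min_traits`` traits the trend cannot be estimated and
    the input is returned unchanged with a warning.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    gc = np.asarray(gc_content, dtype=float)
    if gc.shape != (counts.n_traits,):
        raise NormalisationError(f"expected {counts.n_traits} GC values")
    if ((gc <= 0) | (gc >= 1)).any():
        raise NormalisationError("GC content must be in (0, 1)")
    if counts.n_traits < min_traits:
        warnings.warn(
            f"only {counts.n_traits} traits; GC correction skipped", stacklevel=2
        )
        return counts
    y = np.log2(counts.values + 0.5)
    if effective_lengths is not None:
        y = y - np.log2(np.asarray(effective_lengths, dtype=float) / 1e3)
    trait_means = y.mean(axis=0)
    order = np.argsort(gc)

    def _trend(values: np.ndarray) -> np.ndarray:
        fit = lowess(values[order], gc[order], frac=lowess_frac,
                     return_sorted=False)
        out = np.empty_like(fit)
        out[order] = fit
        return out

    corrected = np.empty_like(y)
    for i in range(counts.n_samples):
        # per-sample deviation from the cohort profile carries the bias
        corrected[i] = y[i] - _trend(y[i] - trait_means)
    corrected += trait_means - corrected.mean(axis=0)
    return replace(counts, values=corrected, stage="raw")
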