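"""Cis-QTL association scanning.

A cis window of +/- 1 Mb is anchored at each gene's strand-aware start.
Nominal associations are ordinary least squares of the standardised trait on
alt-allele dosage plus covariates (typically the first six genotype and six
phenotype principal components); effect sizes, standard errors and two-sided
t-test p-values are reported per variant.  Group-level significance comes
from permutations that shuffle sample labels jointly across all traits of a
group (gene or splice-junction cluster), preserving trait-trait correlation,
with the add-one empirical p-value estimator.  Dataset-level discovery uses
Benjamini-Hochberg FDR across groups.

The OLS is computed through the Frisch-Waugh-Lovell decomposition: trait and
dosages are residualised on the covariates once, then each variant's slope is
a scalar projection — algebraically identical to the full multiple
regression, and fast enough to permute directly instead of relying on a
beta-distribution approximation of the permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from qtlcurator.containers import DosageMatrix, TranscriptModel

MIN_CIS_VARIANTS = 5


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class CisWindow:
    """Cis testing window (0-based half-open) anchored at the gene start."""

    group_id: str
    chromosome: str
    start: int
    end: int
    anchor: int

    def contains(self, position_1based: int) -> bool:
        return self.start <= position_1based - 1 < self.end


def define_cis_window(
    gene: TranscriptModel, size: int = 1_000_000, stranded: bool = True
) -> CisWindow:
    """+/- ``size`` bp window around the strand-aware transcription start.

    For a plus-strand gene the anchor is the leftmost base; for minus strand
    the rightmost.  The window is clamped at the chromosome origin.
    """
    if stranded and gene.strand == "-":
        anchor = gene.end - 1
    else:
        anchor = gene.start
    return CisWindow(
        group_id=gene.gene_id,
        chromosome=gene.chromosome,
        start=max(anchor - size, 0),
        end=anchor + size,
        anchor=anchor,
    )


def compute_pcs(matrix: np.ndarray, k: int = 6, scale: bool = True) -> np.ndarray:
    """First ``k`` principal-component scores of a samples x features matrix.

    Columns are centred and, by default, scaled to unit variance
    (zero-variance columns dropped); ``scale=False`` gives covariance-based
    scores, which are invariant to orthogonal rotation of the features.  The
    sign of each component is fixed so that its largest-magnitude loading is
    positive, making the scores deterministic.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = X[:, keep] - X[:, keep].mean(axis=0)
    if scale:
        X = X / sd[keep]
    if k >= min(n, X.shape[1]):
        raise ScanError(
            f"k={k} must be below min(n_samples, n_features)={min(n, X.shape[1])}"
        )
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            scores[:, j] *= -1
    return scores


def _with_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    C = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ScanError("covariate matrix (with intercept) is rank deficient")
    return C


def residualise(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Project columns of ``values`` off the covariate column space."""
    q, _ = np.linalg.qr(covariates)
    values = np.asarray(values, dtype=float)
    return values - q @ (q.T @ values)


def _ols_stats(
    ry: np.ndarray, rg: np.ndarray, df: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column slope, SE and p of residualised trait on residualised dosage."""
    gss = np.einsum("ij,ij->j", rg, rg)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (rg.T @ ry) / gss
        rss = ry @ ry - beta**2 * gss
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / df / gss)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    # residualised constant columns leave only rounding noise in gss
    bad = gss <= 1e-10 * rg.shape[0]
    beta[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    return beta, se, p


def nominal_scan(
    trait: np.ndarray,
    dosages: DosageMatrix,
    covariates: np.ndarray | None = None,
    trait_id: str = "trait",
    group_id: str = "group",
    min_variants: int = MIN_CIS_VARIANTS,
) -> pd.DataFrame:
    """Per-variant OLS of one standardised trait on dosage + covariates.

    Returns a summary-statistics frame (one row per variant) with beta, se,
    two-sided p, MAF and allele counts.  Traits with fewer than
    ``min_variants`` variants in their window or zero variance are rejected
    up front — they cannot be scanned meaningfully.  Samples with a missing
    dosage are dropped pairwise per variant; a monomorphic dosage column
    yields a row with missing beta/se and a ``zero_variance_dosage`` note.
    """
    y = np.asarray(trait, dtype=float)
    if dosages.n_variants < min_variants:
        raise ScanError(
            f"trait {trait_id}: only {dosages.n_variants} variants in cis window "
            f"(minimum {min_variants})"
        )
    y_obs = y[np.isfinite(y)]
    if y_obs.size < 3 or np.ptp(y_obs) == 0:
        raise ScanError(f"trait {trait_id} has zero variance")
    n = dosages.n_samples
    if y.shape != (n,):
        raise ScanError("trait vector does not match sample count")

    G = dosages.dosage
    C = _with_intercept(covariates, n)
    base_ok = np.isfinite(y)

    maf = dosages.maf()
    with np.errstate(invalid="ignore"):
        ac = np.rint(np.nansum(G, axis=0)).astype(int)
    an = 2 * np.sum(np.isfinite(G), axis=0)

    beta = np.full(dosages.n_variants, np.nan)
    se = np.full(dosages.n_variants, np.nan)
    pval = np.full(dosages.n_variants, np.nan)
    notes = np.array([""] * dosages.n_variants, dtype=object)

    full_cols = np.flatnonzero(np.all(np.isfinite(G[base_ok]), axis=0))
    if full_cols.size:
        mask = base_ok
        df = int(mask.sum()) - C.shape[1] - 1
        ry = residualise(y[mask], C[mask])
        rg = residualise(G[np.ix_(mask, full_cols)], C[mask])
        b, s, p = _ols_stats(ry, rg, df)
        beta[full_cols], se[full_cols], pval[full_cols] = b, s, p
    for j in np.setdiff1d(np.arange(dosages.n_variants), full_cols):
        mask = base_ok & np.isfinite(G[:, j])
        df = int(mask.sum()) - C.shape[1] - 1
        if df < 1:
            notes[j] = "insufficient_samples"
            continue
        ry = residualise(y[mask], C[mask])
        rg = residualise(G[mask, j : j + 1], C[mask])
        b, s, p = _ols_stats(ry, rg, df)
        beta[j], se[j], pval[j] = b[0], s[0], p[0]
    notes[~np.isfinite(beta) & (notes == "")] = "zero_variance_dosage"

    out = dosages.variants[["variant", "chromosome", "position", "ref", "alt"]].copy()
    out.insert(0, "molecular_trait_id", trait_id)
    out.insert(1, "molecular_trait_object_id", group_id)
    out["maf"] = maf
    out["beta"] = beta
    out["se"] = se
    out["pvalue"] = pval
    out["ac"] = ac
    out["an"] = an
    out["note"] = notes
    return out


@dataclass
class GroupScanResult:
    """Result of a grouped permutation scan for one gene / cluster."""

    group_id: str
    sumstats: pd.DataFrame
    lead_trait: str
    lead_variant: str
    lead_p: float
    empirical_p: float
    n_perm: int


def group_permutation(
    traits: np.ndarray,
    trait_ids: list[str],
    dosages: DosageMatrix,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    group_id: str = "group",
) -> GroupScanResult:
    """Group-level empirical p-value from direct permutations.

    The observed statistic is the minimum nominal p over every (trait,
    variant) pair of the group.  Each permutation applies one shared shuffle
    of sample labels to all traits of the group (keeping the traits' mutual
    correlation intact) and the scan is repeated; the empirical p is
    ``(1 + #{perm min-p <= observed}) / (1 + n_perm)``.

    Traits and dosages are residualised on the covariates once up front and
    the permutation acts on trait residuals — with residualised columns the
    per-pair t statistic is a monotone function of the correlation
    coefficient, so each permutation only needs one matrix product.  Missing
    dosages are mean-imputed for the permutation pass only.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100; empirical p is coarse", stacklevel=2)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    Y = np.atleast_2d(np.asarray(traits, dtype=float))
    if Y.shape[0] != dosages.n_samples:
        Y = Y.T
    n, t = Y.shape
    if not np.isfinite(Y).all():
        raise ScanError(
            f"group {group_id}: traits contain missing values; drop or impute "
            "before the permutation pass"
        )
    C = _with_intercept(covariates, n)
    df = n - C.shape[1] - 1

    G = dosages.dosage.copy()
    col_mean = np.nanmean(G, axis=0)
    miss = ~np.isfinite(G)
    if miss.any():
        G[miss] = np.take(col_mean, np.nonzero(miss)[1])

    Yr = residualise(Y, C)
    Gr = residualise(G, C)
    keep = np.einsum("ij,ij->j", Gr, Gr) > 1e-12
    Gr = Gr[:, keep]
    variant_ids = dosages.variants["variant"].to_numpy()[keep]
    if Gr.shape[1] == 0:
        raise ScanError(f"group {group_id}: all dosage columns are constant")
    Gn = Gr / np.linalg.norm(Gr, axis=0)
    Yn = Yr / np.linalg.norm(Yr, axis=0)

    r_obs = Yn.T @ Gn  # t x v correlations
    best = np.unravel_index(np.argmax(np.abs(r_obs)), r_obs.shape)
    r_max_obs = np.abs(r_obs[best])

    count = 0
    chunk = max(1, min(n_perm, 512 * 200 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        r = np.einsum("pnt,nv->ptv", Yn[perms], Gn)
        count += int(np.sum(np.abs(r).max(axis=(1, 2)) >= r_max_obs - 1e-15))
        done += m
    empirical_p = (1 + count) / (1 + n_perm)

    rows = []
    for k, tid in enumerate(trait_ids):
        ss = nominal_scan(
            Y[:, k],
            dosages,
            covariates=covariates,
            trait_id=tid,
            group_id=group_id,
        )
        rows.append(ss)
    sumstats = pd.concat(rows, ignore_index=True)
    lead_p = _r_to_p(r_max_obs, df)
    return GroupScanResult(
        group_id=group_id,
        sumstats=sumstats,
        lead_trait=trait_ids[best[0]],
        lead_variant=str(variant_ids[best[1]]),
        lead_p=lead_p,
        empirical_p=empirical_p,
        n_perm=n_perm,
    )


def _r_to_p(r: float, df: int) -> float:
    r = min(abs(r), 1.0 - 1e-15)
    tstat = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(tstat, df))


def dataset_fdr(
    empirical_p: pd.Series | dict[str, float], level: float = 0.01
) -> pd.DataFrame:
    """Benjamini-Hochberg across groups; returns the per-group decision table.

    Groups passing are the dataset's discoveries ("eGenes" for gene-level
    traits).
    """
    s = pd.Series(empirical_p, dtype=float)
    reject, q, _, _ = multipletests(s.to_numpy(), alpha=level, method="fdr_bh")
    return pd.DataFrame(
        {"group_id": s.index, "empirical_p": s.to_numpy(), "qvalue": q,
         "significant": reject}
    ).reset_index(drop=True)


def exon_effect_profile(
    lead_dosage: np.ndarray,
    exon_values: np.ndarray,
    exon_ids: list[str],
    covariates: np.ndarray | None = None,
    fdr_level: float = 0.01,
) -> pd.DataFrame:
    """Effect of the lead variant on each exon-level trait of a gene.

    Per exon: OLS beta with 95% CI (beta +/- 1.96 se) and a significance
    flag from Benjamini-Hochberg at ``fdr_level`` across the gene's exons —
    the panel drawn under a stratified coverage track.  Zero-variance exons
    are reported with missing estimates and excluded from the FDR.
    """
    g = np.asarray(lead_dosage, dtype=float)
    E = np.atleast_2d(np.asarray(exon_values, dtype=float))
    if E.shape[0] != g.size:
        E = E.T
    n = g.size
    C = _with_intercept(covariates, n)
    df = n - C.shape[1] - 1
    ok = np.isfinite(g)
    rg = residualise(g[ok, None], C[ok])
    sd = E[ok].std(axis=0, ddof=1)
    testable = np.isfinite(sd) & (sd > 0)

    beta = np.full(E.shape[1], np.nan)
    se = np.full(E.shape[1], np.nan)
    pval = np.full(E.shape[1], np.nan)
    if testable.any():
        rE = residualise(E[np.ix_(ok, np.flatnonzero(testable))], C[ok])
        gss = float(rg[:, 0] @ rg[:, 0])
        b = (rE.T @ rg[:, 0]) / gss
        rss = np.maximum(np.einsum("ij,ij->j", rE, rE) - b**2 * gss, 0.0)
        s = np.sqrt(rss / df / gss)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 2.0 * stats.t.sf(np.abs(b / s), df)
        beta[testable], se[testable], pval[testable] = b, s, p
    flags = np.zeros(E.shape[1], dtype=bool)
    if testable.any():
        flags[testable] = multipletests(
            pval[testable], alpha=fdr_level, method="fdr_bh"
        )[0]
    return pd.DataFrame(
        {
            "exon_id": exon_ids,
            "beta": beta,
            "se": se,
            "ci_low": beta - 1.96 * se,
            "ci_high": beta + 1.96 * se,
            "pvalue": pval,
            "significant": flags,
            "note": np.where(testable, "", "zero_variance"),
        }
    )
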