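"""Seeded generators with planted ground truth.

Everything the pipeline consumes can be simulated here: Hardy-Weinberg
genotypes with optional block LD, molecular-trait groups with a planted
causal variant, a two-transcript gene whose exon usage responds to genotype
(the classic splicing-QTL motif: two transcripts sharing all exons except a
long/short version of one internal exon), per-sample binned read coverage,
and single-effect fine-mapping outputs built from Wakefield approximate
Bayes factors.  Each generator is deterministic given its seed, and outputs
are written in exactly the dialects the I/O layer reads back.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qtlcurator.containers import (
    DosageMatrix,
    TraitMatrix,
    TranscriptModel,
    classify_region,
)
from qtlcurator.io_formats import (
    BedGraphTrack,
    write_bedgraph,
    write_credible_sets,
    write_gff3,
    write_lbf,
    write_sumstats,
    write_vcf,
)

# Wakefield prior variance on the standardised effect: sd 0.15
WAKEFIELD_W = 0.15**2


@dataclass
class FixtureTruth:
    """Planted ground truth for one simulated signal."""

    causal_variant: str
    effect: float
    affected_traits: list[str]
    qtl_type: str  # "eQTL" or "sQTL"
    seed: int

    def as_dict(self) -> dict:
        return {
            "causal_variant": self.causal_variant,
            "effect": self.effect,
            "affected_traits": ";".join(self.affected_traits),
            "qtl_type": self.qtl_type,
            "seed": self.seed,
        }


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf: float | np.ndarray = 0.3,
    ld_block_size: int | None = None,
    ld_r: float = 0.9,
    chromosome: str = "chr1",
    start_position: int = 1_000_000,
    spacing: int = 1_000,
    sex: list[str] | None = None,
    seed: int = 0,
) -> DosageMatrix:
    """Hard-call genotypes drawn under Hardy-Weinberg equilibrium.

    With ``ld_block_size`` set, variants are partitioned into consecutive
    blocks; within a block every variant shares the block's allele frequency
    and each haplotype copies a per-block anchor allele with probability
    sqrt(ld_r), giving pairwise genotype correlation about ``ld_r``.
    """
    rng = np.random.default_rng(seed)
    maf = np.broadcast_to(np.asarray(maf, dtype=float), (n_variants,)).copy()
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("maf values must lie in (0, 0.5]")
    haps = np.empty((2, n_samples, n_variants), dtype=np.int8)
    if ld_block_size is None:
        for h in range(2):
            haps[h] = rng.random((n_samples, n_variants)) < maf
    else:
        c = np.sqrt(ld_r)
        for b_start in range(0, n_variants, ld_block_size):
            b_end = min(b_start + ld_block_size, n_variants)
            p = maf[b_start]
            maf[b_start:b_end] = p  # constant frequency within a block
            for h in range(2):
                anchor = rng.random(n_samples) < p
                for j in range(b_start, b_end):
                    fresh = rng.random(n_samples) < p
                    copy = rng.random(n_samples) < c
                    haps[h, :, j] = np.where(copy, anchor, fresh)
    dosage = haps.sum(axis=0).astype(float)
    positions = start_position + spacing * np.arange(n_variants)
    alleles = rng.choice(["A", "C", "G", "T"], size=(n_variants, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    variants = pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": positions,
            "ref": alleles[:, 0],
            "alt": alleles[:, 1],
            "r2": np.nan,
        }
    )
    variants["region"] = [
        classify_region(chromosome, int(p)) for p in positions
    ]
    variants["variant"] = (
        variants["chromosome"].astype(str)
        + "_" + variants["position"].astype(str)
        + "_" + variants["ref"] + "_" + variants["alt"]
    )
    variants = variants[
        ["variant", "chromosome", "position", "ref", "alt", "region", "r2"]
    ]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    sex = sex if sex is not None else ["unknown"] * n_samples
    return DosageMatrix(samples=samples, sex=sex, variants=variants, dosage=dosage)


def simulate_trait_group(
    dosages: DosageMatrix,
    causal_index: int,
    n_traits: int = 10,
    lead_effect: float = 1.0,
    decoy_effect: float = 0.5,
    noise_corr: float = 0.5,
    group_id: str = "geneA",
    method: str = "exon",
    seed: int = 0,
) -> tuple[TraitMatrix, FixtureTruth]:
    """A group of correlated traits with one planted signal.

    Trait 0 carries the full effect (``lead_effect`` in residual-sd units of
    the standardised dosage); the remaining traits carry the attenuated
    ``decoy_effect`` — mimicking exon-level traits that partially overlap a
    spliced event — plus noise correlated across traits at ``noise_corr``.
    """
    rng = np.random.default_rng(seed)
    n = dosages.n_samples
    g = dosages.dosage[:, causal_index]
    gz = (g - g.mean()) / g.std(ddof=0)
    shared = rng.standard_normal(n)
    effects = np.full(n_traits, decoy_effect)
    effects[0] = lead_effect
    own = rng.standard_normal((n, n_traits))
    noise = np.sqrt(noise_corr) * shared[:, None] + np.sqrt(1 - noise_corr) * own
    values = gz[:, None] * effects[None, :] + noise
    span = (
        int(dosages.variants["position"].iloc[causal_index]) - 5_000,
        int(dosages.variants["position"].iloc[causal_index]) + 5_000,
    )
    traits = pd.DataFrame(
        {
            "trait_id": [f"{group_id}.t{k}" for k in range(n_traits)],
            "group_id": group_id,
            "chromosome": dosages.variants["chromosome"].iloc[causal_index],
            "start": span[0],
            "end": span[1],
            "method": method,
        }
    )
    truth = FixtureTruth(
        causal_variant=str(dosages.variants["variant"].iloc[causal_index]),
        effect=lead_effect,
        affected_traits=[f"{group_id}.t0"],
        qtl_type="sQTL" if method in ("tx", "txrevise", "leafcutter", "exon") else "eQTL",
        seed=seed,
    )
    tm = TraitMatrix(
        samples=list(dosages.samples), traits=traits, values=values, stage="raw"
    )
    return tm, truth


# ---------------------------------------------------------------------------
# Two-transcript splicing-QTL gene
# ---------------------------------------------------------------------------


@dataclass
class SimulatedGene:
    """Bundle for one simulated splicing-QTL gene."""

    models: list[TranscriptModel]
    usage: TraitMatrix  # tx usage for the two transcripts
    exon_counts: TraitMatrix
    gene_counts: TraitMatrix
    coverage: np.ndarray  # samples x span (per-base, real scale)
    coverage_span: tuple[int, int]  # 0-based half-open genomic span
    depths: np.ndarray
    truth: FixtureTruth
    exon_spans: dict[str, tuple[int, int]] = field(default_factory=dict)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_gene(
    dosages: DosageMatrix,
    causal_index: int,
    effect: float = 2.0,
    base: float = 0.0,
    depth: float = 50.0,
    gene_start: int | None = None,
    gene_id: str = "geneA",
    flank: int = 100,
    seed: int = 0,
) -> SimulatedGene:
    """A two-transcript gene whose transcript usage responds to genotype.

    Both transcripts share four exons except that transcript 2 carries a
    short version of exon 3.  Per sample, usage of transcript 2 is
    logistic(base + effect * dosage) with ``effect`` in logit units; exon
    and gene read counts are Poisson around the mixture expectation, and
    per-base coverage is the depth-scaled expected read density of the
    transcript mixture (Poisson per 5-bp bin).  Total gene output does not
    depend on genotype — a pure splicing QTL, no expression QTL.
    """
    rng = np.random.default_rng(seed)
    n = dosages.n_samples
    chrom = str(dosages.variants["chromosome"].iloc[causal_index])
    if gene_start is None:
        gene_start = int(dosages.variants["position"].iloc[causal_index]) - 2_000

    e = gene_start
    exons_long = [
        (e, e + 200),
        (e + 500, e + 650),
        (e + 1_000, e + 1_300),  # long exon 3
        (e + 1_800, e + 2_000),
    ]
    exons_short = [
        (e, e + 200),
        (e + 500, e + 650),
        (e + 1_000, e + 1_150),  # short exon 3
        (e + 1_800, e + 2_000),
    ]
    tx1 = TranscriptModel(f"{gene_id}.tx1", gene_id, chrom, "+", exons_long)
    tx2 = TranscriptModel(f"{gene_id}.tx2", gene_id, chrom, "+", exons_short)

    g = dosages.dosage[:, causal_index]
    usage2 = _logistic(base + effect * g)
    usage = np.column_stack([1.0 - usage2, usage2])

    depths = depth * rng.uniform(0.5, 2.0, size=n)  # library-depth spread

    # per-base expected density of each transcript over the gene span
    span = (gene_start - flank, exons_long[-1][1] + flank)
    width = span[1] - span[0]
    dens = np.zeros((2, width))
    for t, model in enumerate((tx1, tx2)):
        for s, ee in model.exons:
            dens[t, s - span[0] : ee - span[0]] = 1.0
    mix = usage @ dens  # samples x width expected relative density
    lam = mix * (depths / depth)[:, None] * (depth / 10.0)
    n_bins = -(-width // 5)
    pad = n_bins * 5 - width
    lam_p = np.pad(lam, ((0, 0), (0, pad)))
    binned = rng.poisson(lam_p.reshape(n, n_bins, 5).sum(axis=2)) / 5.0
    coverage = np.repeat(binned, 5, axis=1)[:, :width]

    # exon-level counts: reads assigned to each (merged) exon variant part
    exon_parts = {
        f"{gene_id}.e1": exons_long[0],
        f"{gene_id}.e2": exons_long[1],
        f"{gene_id}.e3_common": (exons_long[2][0], exons_short[2][1]),
        f"{gene_id}.e3_ext": (exons_short[2][1], exons_long[2][1]),
        f"{gene_id}.e4": exons_long[3],
    }
    part_ids = list(exon_parts)
    exp = np.zeros((n, len(part_ids)))
    for j, pid in enumerate(part_ids):
        s, ee = exon_parts[pid]
        exp[:, j] = mix[:, s - span[0] : ee - span[0]].sum(axis=1)
    exon_vals = rng.poisson(exp * (depths / depth)[:, None] / 10.0).astype(float)
    gene_vals = rng.poisson(
        np.full(n, 40.0) * depths / depth
    ).astype(float)[:, None]

    def _tm(ids, vals, method):
        spans = (
            [exon_parts[i] for i in ids]
            if method == "exon"
            else [(span[0], span[1])] * len(ids)
        )
        traits = pd.DataFrame(
            {
                "trait_id": ids,
                "group_id": gene_id,
                "chromosome": chrom,
                "start": [s for s, _ in spans],
                "end": [ee for _, ee in spans],
                "method": method,
            }
        )
        return TraitMatrix(
            samples=list(dosages.samples), traits=traits, values=vals, stage="raw"
        )

    usage_tm = _tm([tx1.transcript_id, tx2.transcript_id], usage, "tx")
    usage_tm.stage = "usage"
    exon_tm = _tm(part_ids, exon_vals, "exon")
    gene_tm = _tm([gene_id], gene_vals, "ge")

    truth = FixtureTruth(
        causal_variant=str(dosages.variants["variant"].iloc[causal_index]),
        effect=effect,
        affected_traits=[tx2.transcript_id],
        qtl_type="sQTL",
        seed=seed,
    )
    return SimulatedGene(
        models=[tx1, tx2],
        usage=usage_tm,
        exon_counts=exon_tm,
        gene_counts=gene_tm,
        coverage=coverage,
        coverage_span=span,
        depths=depths,
        truth=truth,
        exon_spans=exon_parts,
    )


# ---------------------------------------------------------------------------
# Single-effect fine-mapping outputs (Wakefield approximate Bayes factors)
# ---------------------------------------------------------------------------


def wakefield_lbf(
    beta: np.ndarray, se: np.ndarray, W: float = WAKEFIELD_W
) -> np.ndarray:
    """Natural-log approximate Bayes factor of association per variant.

    ln ABF = 0.5 ln(se^2 / (se^2 + W)) + 0.5 z^2 W / (se^2 + W) with z =
    beta/se and W the prior effect variance (default 0.15^2 on the
    standardised scale).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    z = beta / se
    v = se**2
    return 0.5 * np.log(v / (v + W)) + 0.5 * z**2 * W / (v + W)


def simulate_finemap_outputs(
    sumstats: pd.DataFrame,
    coverage_of: float = 0.95,
    W: float = WAKEFIELD_W,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-effect credible sets and LBF vectors from a nominal scan.

    For every molecular trait in ``sumstats`` one signal is constructed:
    per-variant Wakefield log Bayes factors, posterior inclusion
    probabilities as their softmax, and the credible set as the smallest
    variant set whose cumulative PIP reaches ``coverage_of``.  Emitted in the
    same long dialects the pipeline's readers consume.
    """
    cs_rows = []
    lbf_rows = []
    for trait, sub in sumstats.groupby("molecular_trait_id", sort=True):
        sub = sub[np.isfinite(sub["beta"]) & np.isfinite(sub["se"])]
        if sub.empty:
            continue
        lbf = wakefield_lbf(sub["beta"].to_numpy(), sub["se"].to_numpy(), W=W)
        z = sub["beta"].to_numpy() / sub["se"].to_numpy()
        m = lbf.max()
        pip = np.exp(lbf - m)
        pip /= pip.sum()
        if np.allclose(z, 0.0):
            warnings.warn(
                f"trait {trait}: degenerate all-zero z; credible set is the "
                "whole window",
                stacklevel=2,
            )
        order = np.argsort(-pip, kind="stable")
        cum = np.cumsum(pip[order])
        k = int(np.searchsorted(cum, coverage_of) + 1)
        members = order[:k]
        cs_id = f"{trait}_L1"
        base = sub.iloc[members][
            ["molecular_trait_object_id", "variant", "chromosome",
             "position", "ref", "alt"]
        ].copy()
        base.insert(0, "molecular_trait_id", trait)
        base.insert(2, "cs_id", cs_id)
        base["pip"] = pip[members]
        base["z"] = z[members]
        cs_rows.append(base)
        lb = sub[["variant", "chromosome", "position", "ref", "alt"]].copy()
        lb.insert(0, "molecular_trait_id", trait)
        lb.insert(1, "signal_index", 1)
        lb["lbf"] = lbf
        lbf_rows.append(lb)
    cs = (
        pd.concat(cs_rows, ignore_index=True)
        if cs_rows
        else pd.DataFrame()
    )
    lbfs = (
        pd.concat(lbf_rows, ignore_index=True)
        if lbf_rows
        else pd.DataFrame()
    )
    return cs, lbfs


# ---------------------------------------------------------------------------
# Full on-disk bundle
# ---------------------------------------------------------------------------


def write_trait_matrix(tm: TraitMatrix, path: str | os.PathLike) -> str:
    """Trait metadata columns followed by one column per sample."""
    df = tm.traits.copy()
    vals = pd.DataFrame(tm.values.T, columns=tm.samples)
    out = pd.concat([df.reset_index(drop=True), vals], axis=1)
    out.to_csv(path, sep="\t", index=False, compression="infer")
    return os.fspath(path)


def read_trait_matrix(path: str | os.PathLike, stage: str = "raw") -> TraitMatrix:
    df = pd.read_csv(path, sep="\t", compression="infer")
    meta_cols = ["trait_id", "group_id", "chromosome", "start", "end", "method"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"trait matrix lacks metadata columns {missing}")
    samples = [c for c in df.columns if c not in meta_cols]
    return TraitMatrix(
        samples=samples,
        traits=df[meta_cols].copy(),
        values=df[samples].to_numpy(dtype=float).T,
        stage=stage,
    )


def make_dataset(
    out_dir: str | os.PathLike,
    n_samples: int = 100,
    n_genes: int = 2,
    n_variants_per_gene: int = 30,
    effect: float = 2.0,
    depth: float = 50.0,
    seed: int = 0,
    force: bool = False,
) -> dict[str, str]:
    """Write a complete fixture bundle: VCF, GFF3, per-sample bedGraphs,
    trait matrices and the planted-truth table.  Deterministic per seed."""
    out = os.fspath(out_dir)
    if os.path.exists(out) and os.listdir(out) and not force:
        raise FileExistsError(f"{out} exists and is non-empty; pass force=True")
    os.makedirs(out, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, str] = {}
    all_models: list[TranscriptModel] = []
    truth_rows = []
    usage_tms, exon_tms, gene_tms = [], [], []
    matrices = []
    for gidx in range(n_genes):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        dos = simulate_genotypes(
            n_samples,
            n_variants_per_gene,
            maf=rng.uniform(0.1, 0.5),
            chromosome="chr1",
            start_position=1_000_000 + gidx * 1_000_000,
            seed=sub_seed,
        )
        causal = int(rng.integers(5, n_variants_per_gene - 5))
        gene = simulate_gene(
            dos,
            causal,
            effect=effect,
            depth=depth,
            gene_id=f"gene{gidx}",
            seed=sub_seed + 1,
        )
        matrices.append(dos)
        all_models.extend(gene.models)
        truth_rows.append(gene.truth.as_dict())
        usage_tms.append(gene.usage)
        exon_tms.append(gene.exon_counts)
        gene_tms.append(gene.gene_counts)
        if gidx == 0:
            # one bedGraph per sample for the first gene's span
            cov_dir = os.path.join(out, "coverage")
            os.makedirs(cov_dir, exist_ok=True)
            s0, _ = gene.coverage_span
            for i, sample in enumerate(dos.samples):
                binned = gene.coverage[i][::5]
                n_bins = binned.size
                iv = pd.DataFrame(
                    {
                        "chromosome": "chr1",
                        "start": s0 + 5 * np.arange(n_bins),
                        "end": s0 + 5 * (np.arange(n_bins) + 1),
                        "value": binned,
                    }
                )
                p = os.path.join(cov_dir, f"{sample}.bedgraph")
                write_bedgraph(BedGraphTrack(iv, bin_width=5), p)
            paths["coverage_dir"] = cov_dir

    merged = _concat_dosages(matrices)
    paths["vcf"] = write_vcf(merged, os.path.join(out, "genotypes.vcf"))
    paths["gff3"] = write_gff3(all_models, os.path.join(out, "annotation.gff3"))
    for name, tms in (("usage_tx", usage_tms), ("counts_exon", exon_tms),
                      ("counts_gene", gene_tms)):
        tm = _concat_traits(tms)
        paths[name] = write_trait_matrix(tm, os.path.join(out, f"{name}.tsv"))
    truth = pd.DataFrame(truth_rows)
    paths["truth"] = os.path.join(out, "truth.tsv")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def _concat_dosages(matrices: list[DosageMatrix]) -> DosageMatrix:
    base = matrices[0]
    variants = pd.concat(
        [m.variants for m in matrices], ignore_index=True
    )
    dosage = np.hstack([m.dosage for m in matrices])
    return DosageMatrix(
        samples=base.samples, sex=base.sex, variants=variants, dosage=dosage
    )


def _concat_traits(tms: list[TraitMatrix]) -> TraitMatrix:
    base = tms[0]
    traits = pd.concat([t.traits for t in tms], ignore_index=True)
    values = np.hstack([t.values for t in tms])
    return TraitMatrix(
        samples=base.samples, traits=traits, values=values, stage=base.stage
    )


__all__ = [
    "FixtureTruth",
    "SimulatedGene",
    "simulate_genotypes",
    "simulate_trait_group",
    "simulate_gene",
    "wakefield_lbf",
    "simulate_finemap_outputs",
    "make_dataset",
    "write_trait_matrix",
    "read_trait_matrix",
    "write_sumstats",
    "write_credible_sets",
    "write_lbf",
]
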