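"""Readers and writers for every external format the pipeline touches.

Tabular dialects (tab-separated, header row, gzip accepted by extension):

* summary statistics — one variant-trait association per row with the fixed
  column set ``molecular_trait_id, molecular_trait_object_id, variant,
  chromosome, position, ref, alt, maf, beta, se, pvalue, ac, an``; extra
  columns are preserved opaquely;
* credible sets — one credible-set member per row
  (``... cs_id, variant, ..., pip, z``);
* log Bayes factors — long format, one (signal, variant) per row with a
  ``signal_index`` column rather than one wide column per signal, so the
  number of signals per trait is not baked into the schema.

Genotypes come from VCF (``DS`` dosage field, ``GT`` hard-call fallback),
transcript annotation from GFF3, and read coverage from binned bedGraph.
External conventions (1-based closed GFF3, 0-based half-open bedGraph,
1-based VCF positions) are converted to internal 0-based half-open intervals
here and nowhere else; VCF/variant-id positions stay 1-based because they are
part of the canonical ``chr_pos_ref_alt`` identifier.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from qtlcurator.containers import DosageMatrix, TranscriptModel, classify_region
from qtlcurator.variants import VariantIdError, VariantKey


class FormatError(ValueError):
    """A file violates its format contract (missing column, bad header...)."""


class RecordError(ValueError):
    """A single record is unparseable; carries the 1-based data line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


SUMSTAT_COLUMNS = [
    "molecular_trait_id",
    "molecular_trait_object_id",
    "variant",
    "chromosome",
    "position",
    "ref",
    "alt",
    "maf",
    "beta",
    "se",
    "pvalue",
    "ac",
    "an",
]

CS_COLUMNS = [
    "molecular_trait_id",
    "molecular_trait_object_id",
    "cs_id",
    "variant",
    "chromosome",
    "position",
    "ref",
    "alt",
    "pip",
    "z",
]

LBF_COLUMNS = [
    "molecular_trait_id",
    "signal_index",
    "variant",
    "chromosome",
    "position",
    "ref",
    "alt",
    "lbf",
]

_INT_COLS = {"position", "ac", "an", "signal_index"}
_FLOAT_COLS = {"maf", "beta", "se", "pvalue", "pip", "z", "lbf"}


def _read_table(path: str | os.PathLike, mandatory: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise FormatError(
            f"{os.fspath(path)}: missing mandatory column(s) {', '.join(missing)}"
        )
    for col in df.columns:
        if col in _INT_COLS:
            df[col] = df[col].astype(np.int64)
        elif col in _FLOAT_COLS:
            df[col] = df[col].astype(float)
    _validate_variant_column(df)
    return df


def _validate_variant_column(df: pd.DataFrame) -> None:
    if "variant" not in df.columns:
        return
    for i, vid in enumerate(df["variant"]):
        try:
            key = VariantKey.from_id(vid)
        except VariantIdError as exc:
            raise RecordError(str(exc), line=i + 1) from exc
        if "position" in df.columns and key.position != df["position"].iloc[i]:
            raise RecordError(
                f"variant id {vid} disagrees with position column "
                f"{df['position'].iloc[i]}",
                line=i + 1,
            )


def _write_table(df: pd.DataFrame, path: str | os.PathLike, columns: list[str]) -> str:
    extra = [c for c in df.columns if c not in columns]
    out = df[columns + extra].copy()
    if {"chromosome", "position"} <= set(out.columns):
        out = out.sort_values(
            ["chromosome", "position"], kind="stable"
        ).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, compression="infer")
    return os.fspath(path)


def read_sumstats(path: str | os.PathLike) -> pd.DataFrame:
    """Read a summary-statistics table; extra columns preserved."""
    return _read_table(path, SUMSTAT_COLUMNS)


def write_sumstats(df: pd.DataFrame, path: str | os.PathLike) -> str:
    """Write summary statistics sorted by (chromosome, position)."""
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cannot write sumstats, missing {missing}")
    return _write_table(df, path, SUMSTAT_COLUMNS)


def read_credible_sets(path: str | os.PathLike) -> pd.DataFrame:
    return _read_table(path, CS_COLUMNS)


def write_credible_sets(df: pd.DataFrame, path: str | os.PathLike) -> str:
    missing = [c for c in CS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cannot write credible sets, missing {missing}")
    return _write_table(df, path, CS_COLUMNS)


def read_lbf(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_table(path, LBF_COLUMNS)
    if not np.isfinite(df["lbf"]).all():
        raise FormatError(f"{os.fspath(path)}: non-finite lbf values")
    return df


def write_lbf(df: pd.DataFrame, path: str | os.PathLike) -> str:
    missing = [c for c in LBF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cannot write LBF table, missing {missing}")
    return _write_table(df, path, LBF_COLUMNS)


# ---------------------------------------------------------------------------
# VCF dosages
# ---------------------------------------------------------------------------


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive, VCF convention)."""
    try:
        chrom, span = region.rsplit(":", 1)
        start_s, end_s = span.split("-")
        start, end = int(start_s.replace(",", "")), int(end_s.replace(",", ""))
    except ValueError as exc:
        raise FormatError(f"cannot parse region {region!r}") from exc
    if start < 1 or end < start:
        raise FormatError(f"invalid region bounds in {region!r}")
    return chrom, start, end


def read_dosages(
    vcf_path: str | os.PathLike,
    region: str | None = None,
    sex: dict[str, str] | None = None,
) -> DosageMatrix:
    """Load genotype dosages from a VCF into a :class:`DosageMatrix`.

    Per sample and variant the ``DS`` field is used when present; otherwise
    the ``GT`` hard call is converted to an alt-allele count.  A missing
    genotype becomes NaN, never 0.  ``region`` restricts to a 1-based
    inclusive ``chrom:start-end`` span.  ``sex`` maps sample id to
    female/male; unlisted samples are tagged unknown.
    """
    span = parse_region(region) if region else None
    rows: list[np.ndarray] = []
    meta: list[dict] = []
    with pysam.VariantFile(os.fspath(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        has_r2 = "R2" in vcf.header.info
        for rec in vcf:
            if span is not None:
                chrom, start, end = span
                if rec.chrom != chrom or not (start <= rec.pos <= end):
                    continue
            if rec.alts is None or len(rec.alts) != 1:
                continue  # only biallelic records carry a single dosage
            dos = np.full(len(samples), np.nan)
            for i, s in enumerate(samples):
                call = rec.samples[s]
                ds = call.get("DS")
                if ds is not None:
                    if isinstance(ds, (tuple, list)):
                        ds = ds[0]
                    if ds is not None:
                        dos[i] = float(ds)
                        continue
                gt = call.get("GT")
                if gt is not None and not all(a is None for a in gt):
                    dos[i] = float(sum(1 for a in gt if a == 1))
            r2 = rec.info.get("R2", None) if has_r2 else None
            if isinstance(r2, (tuple, list)):
                r2 = r2[0]
            meta.append(
                {
                    "variant": f"{rec.chrom}_{rec.pos}_{rec.ref}_{rec.alts[0]}",
                    "chromosome": rec.chrom,
                    "position": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "region": classify_region(rec.chrom, rec.pos),
                    "r2": np.nan if r2 is None else float(r2),
                }
            )
            rows.append(dos)
    variants = pd.DataFrame(
        meta,
        columns=["variant", "chromosome", "position", "ref", "alt", "region", "r2"],
    )
    dosage = (
        np.array(rows).T if rows else np.empty((len(samples), 0))
    )
    sex = sex or {}
    labels = [sex.get(s, "unknown") for s in samples]
    return DosageMatrix(samples=samples, sex=labels, variants=variants, dosage=dosage)


def write_vcf(matrix: DosageMatrix, path: str | os.PathLike) -> str:
    """Write a DosageMatrix as an uncompressed VCF with DS and GT fields.

    GT is the rounded hard call (haploid-impossible rounding is not checked
    here); DS carries the dosage verbatim.  Readable back with pysam.
    """
    chroms = list(dict.fromkeys(matrix.variants["chromosome"]))
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation R2">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    order = matrix.variants.sort_values(["chromosome", "position"], kind="stable").index
    gts = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j in order:
        row = matrix.variants.iloc[j]
        r2 = row["r2"]
        info = "." if not np.isfinite(r2) else f"R2={r2:g}"
        fields = [
            str(row["chromosome"]),
            str(int(row["position"])),
            row["variant"],
            row["ref"],
            row["alt"],
            ".",
            "PASS",
            info,
            "GT:DS",
        ]
        for i in range(matrix.n_samples):
            d = matrix.dosage[i, j]
            if not np.isfinite(d):
                fields.append("./.:.")
            else:
                fields.append(f"{gts[int(round(np.clip(d, 0, 2)))]}:{d:g}")
        lines.append("\t".join(fields))
    text = "\n".join(lines) + "\n"
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write(text)
    return os.fspath(path)


# ---------------------------------------------------------------------------
# GFF3 transcript models
# ---------------------------------------------------------------------------


def read_gff3(path: str | os.PathLike) -> list[TranscriptModel]:
    """Parse gene/transcript/exon features into transcript models.

    Follows GENCODE conventions: transcripts (``transcript`` or ``mRNA``)
    carry a ``Parent`` gene attribute and exons a ``Parent`` transcript
    attribute.  Coordinates are converted from 1-based closed to 0-based
    half-open.  An exon without a Parent is a format error.
    """
    import gffutils

    db = gffutils.create_db(
        os.fspath(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    tx_parent: dict[str, tuple[str, str, str]] = {}
    for ftype in ("transcript", "mRNA"):
        for tx in db.features_of_type(ftype):
            parents = tx.attributes.get("Parent", [])
            gene_id = parents[0] if parents else tx.id
            tx_parent[tx.id] = (gene_id, tx.seqid, tx.strand)
    exons: dict[str, list[tuple[int, int]]] = {t: [] for t in tx_parent}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents:
            raise FormatError(f"exon {exon.id} has no Parent attribute")
        for parent in parents:
            if parent not in exons:
                raise FormatError(
                    f"exon {exon.id} names unknown Parent transcript {parent}"
                )
            exons[parent].append((exon.start - 1, exon.end))
    models = []
    for tx_id, (gene_id, chrom, strand) in tx_parent.items():
        if not exons[tx_id]:
            continue
        models.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=gene_id,
                chromosome=chrom,
                strand=strand,
                exons=exons[tx_id],
            )
        )
    return models


def write_gff3(models: list[TranscriptModel], path: str | os.PathLike) -> str:
    """Write transcript models as a minimal GENCODE-style GFF3."""
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    genes: dict[str, list[TranscriptModel]] = {}
    for m in models:
        genes.setdefault(m.gene_id, []).append(m)
    for gene_id, txs in genes.items():
        chrom = txs[0].chromosome
        strand = txs[0].strand
        g_start = min(t.start for t in txs)
        g_end = max(t.end for t in txs)
        buf.write(
            f"{chrom}\tqtlcurator\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
            f"ID={gene_id}\n"
        )
        for t in txs:
            buf.write(
                f"{chrom}\tqtlcurator\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{strand}\t.\tID={t.transcript_id};Parent={gene_id}\n"
            )
            for k, (s, e) in enumerate(t.exons, start=1):
                buf.write(
                    f"{chrom}\tqtlcurator\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={t.transcript_id}.exon{k};Parent={t.transcript_id}\n"
                )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
    return os.fspath(path)


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------


@dataclass
class BedGraphTrack:
    """Binned coverage from a bedGraph file (0-based half-open intervals)."""

    intervals: pd.DataFrame  # columns chromosome, start, end, value
    bin_width: int = 5

    def query(self, chromosome: str, start: int, end: int) -> np.ndarray:
        """Per-bin mean coverage over [start, end) at the track's bin width.

        The returned vector has ``ceil(span / bin_width)`` entries; bases not
        covered by any interval count as 0.
        """
        if end <= start:
            raise ValueError(f"empty query span [{start}, {end})")
        span = end - start
        per_base = np.zeros(span)
        sub = self.intervals[self.intervals["chromosome"] == chromosome]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            lo, hi = max(s, start), min(e, end)
            if hi > lo:
                per_base[lo - start : hi - start] = v
        n_bins = -(-span // self.bin_width)
        pad = n_bins * self.bin_width - span
        if pad:
            per_base = np.concatenate([per_base, np.full(pad, np.nan)])
        with np.errstate(invalid="ignore"):
            return np.nanmean(per_base.reshape(n_bins, self.bin_width), axis=1)


def read_bedgraph(path: str | os.PathLike, bin_width: int = 5) -> BedGraphTrack:
    """Read a bedGraph file; overlapping intervals are a format error."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        names=["chromosome", "start", "end", "value"],
        dtype={"chromosome": str, "start": np.int64, "end": np.int64, "value": float},
        compression="infer",
    )
    if (df["end"] <= df["start"]).any():
        raise FormatError(f"{os.fspath(path)}: interval with end <= start")
    df = df.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    same = df["chromosome"].eq(df["chromosome"].shift())
    if (same & (df["start"] < df["end"].shift())).any():
        raise FormatError(f"{os.fspath(path)}: overlapping intervals")
    return BedGraphTrack(intervals=df, bin_width=bin_width)


def write_bedgraph(track: BedGraphTrack, path: str | os.PathLike) -> str:
    track.intervals.to_csv(
        path, sep="\t", header=False, index=False, compression="infer"
    )
    return os.fspath(path)
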