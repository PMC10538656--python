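"""Genotype-stratified QTL coverage plots.

The display coordinate system keeps exons at natural scale and compresses
every intron to a fixed width (default 50 nt), so splicing differences in
exonic read coverage are visible regardless of intron size.  Samples are
grouped by the hard-called genotype class (0/1/2 copies of the alt allele)
of a chosen variant, each sample's coverage is divided by its own mean over
the plotted span (cancelling library-depth differences exactly), and the
per-class mean track is drawn.  Below the coverage panel sits the per-exon
effect-size panel (beta with 95% CI of the same variant on each exon-level
trait, significant exons highlighted) and the annotation panel with the
reference transcript and any event annotations — all three share the
rescaled axis.

Every number that ends up in the figure is also emitted as a tidy table so
the plot can be tested without image diffing.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qtlcurator.containers import TranscriptModel

DEFAULT_INTRON_WIDTH = 50


class CoverageError(ValueError):
    pass


def union_exons(models: list[TranscriptModel]) -> list[tuple[int, int]]:
    """Union-merge the exons of all displayed transcripts (0-based half-open)."""
    intervals = sorted(e for m in models for e in m.exons)
    if not intervals:
        raise CoverageError("no exons to merge")
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class _Segment:
    real_start: int
    real_end: int
    target_start: float
    target_end: float

    @property
    def scale(self) -> float:
        return (self.target_end - self.target_start) / (self.real_end - self.real_start)


@dataclass
class CoordinateMap:
    """Piecewise-linear map from genomic to display coordinates.

    Exon (and flank) segments are length-preserving; every intron maps onto
    exactly ``intron_width`` display units.  The map is strictly increasing
    and invertible on exonic and flanking bases.
    """

    exons: list[tuple[int, int]]
    intron_width: int = DEFAULT_INTRON_WIDTH
    flank: int = 0
    segments: list[_Segment] = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise CoverageError("empty exon list")
        exons = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise CoverageError("exons must be non-overlapping after union-merge")
        segs: list[_Segment] = []
        t = 0.0
        if self.flank:
            r0 = exons[0][0] - self.flank
            segs.append(_Segment(r0, exons[0][0], t, t + self.flank))
            t += self.flank
        for i, (s, e) in enumerate(exons):
            segs.append(_Segment(s, e, t, t + (e - s)))
            t += e - s
            if i + 1 < len(exons):
                nxt = exons[i + 1][0]
                if nxt > e:
                    segs.append(_Segment(e, nxt, t, t + self.intron_width))
                    t += self.intron_width
        if self.flank:
            last = exons[-1][1]
            segs.append(_Segment(last, last + self.flank, t, t + self.flank))
            t += self.flank
        self.segments = segs
        self._real_starts = [s.real_start for s in segs]
        self._target_starts = [s.target_start for s in segs]

    @property
    def real_start(self) -> int:
        return self.segments[0].real_start

    @property
    def real_end(self) -> int:
        return self.segments[-1].real_end

    @property
    def target_length(self) -> float:
        return self.segments[-1].target_end

    def map_position(self, position: float) -> float:
        """Genomic -> display coordinate (clamps outside the mapped span)."""
        if position <= self.real_start:
            return 0.0
        if position >= self.real_end:
            return self.target_length
        i = bisect_right(self._real_starts, position) - 1
        seg = self.segments[i]
        return seg.target_start + (position - seg.real_start) * seg.scale

    def invert(self, target: float) -> float:
        """Display -> genomic coordinate; exact on exonic/flank bases."""
        if target < 0 or target > self.target_length:
            raise CoverageError(f"target {target} outside [0, {self.target_length}]")
        if target == self.target_length:
            return float(self.real_end)
        i = bisect_right(self._target_starts, target) - 1
        seg = self.segments[i]
        return seg.real_start + (target - seg.target_start) / seg.scale

    def project(self, per_base: np.ndarray) -> np.ndarray:
        """Resample per-base coverage aligned to ``real_start`` onto the
        display axis (one value per display unit)."""
        per_base = np.asarray(per_base, dtype=float)
        span = self.real_end - self.real_start
        if per_base.shape[-1] != span:
            raise CoverageError(
                f"per-base vector length {per_base.shape[-1]} != mapped span {span}"
            )
        n_t = int(round(self.target_length))
        idx = np.empty(n_t, dtype=int)
        for t in range(n_t):
            real = self.invert(t + 0.5)
            idx[t] = min(int(real) - self.real_start, span - 1)
        return per_base[..., idx]


@dataclass
class StratifiedCoverage:
    """Per-genotype-class mean coverage on the display scale."""

    variant: str
    class_counts: dict[int, int]
    class_means: dict[int, np.ndarray]
    n_dropped: int
    scale_method: str = "per_sample_mean"

    @property
    def classes(self) -> list[int]:
        return sorted(self.class_means)


def stratify_coverage(
    vectors: np.ndarray,
    dosages: np.ndarray,
    variant: str = "variant",
    rounding_tol: float = 0.25,
    scale: str = "per_sample_mean",
) -> StratifiedCoverage:
    """Average per-sample coverage tracks within genotype classes.

    ``vectors`` is samples x positions (any shared scale/binning); ``dosages``
    is the per-sample dosage of the stratifying variant.  A sample joins
    class round(dosage) when |dosage - round(dosage)| <= rounding_tol,
    otherwise it is dropped and counted.  With ``per_sample_mean`` scaling
    each track is divided by its own mean before averaging, so per-sample
    depth factors cancel exactly; ``none`` averages raw tracks.
    """
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    d = np.asarray(dosages, dtype=float)
    if V.shape[0] != d.size:
        raise CoverageError(
            f"{V.shape[0]} coverage tracks vs {d.size} dosages"
        )
    if scale not in ("per_sample_mean", "none"):
        raise CoverageError(f"unknown scale method {scale!r}")
    hard = np.rint(d)
    usable = np.isfinite(d) & (np.abs(d - hard) <= rounding_tol)
    if scale == "per_sample_mean":
        means = V.mean(axis=1)
        usable &= means > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            V = V / np.where(means > 0, means, np.nan)[:, None]
    n_dropped = int((~usable).sum())
    if not usable.any():
        raise CoverageError("all samples dropped from stratification")
    counts: dict[int, int] = {}
    tracks: dict[int, np.ndarray] = {}
    for cls in (0, 1, 2):
        mask = usable & (hard == cls)
        if mask.any():
            counts[cls] = int(mask.sum())
            tracks[cls] = V[mask].mean(axis=0)
    return StratifiedCoverage(
        variant=variant,
        class_counts=counts,
        class_means=tracks,
        n_dropped=n_dropped,
        scale_method=scale,
    )


def _bin(values: np.ndarray, width: int) -> np.ndarray:
    n = values.size
    n_bins = -(-n // width)
    pad = n_bins * width - n
    if pad:
        values = np.concatenate([values, np.full(pad, np.nan)])
    with np.errstate(invalid="ignore"):
        return np.nanmean(values.reshape(n_bins, width), axis=1)


def render_qtl_plot(
    strat: StratifiedCoverage | None,
    exon_effects: pd.DataFrame | None,
    models: list[TranscriptModel],
    cmap: CoordinateMap,
    out_path: str | None = None,
    bin_width: int = 5,
    exon_spans: dict[str, tuple[int, int]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Compose the three-panel coverage figure and emit its tables.

    Panels (top to bottom): genotype-stratified coverage, per-exon effect
    sizes with 95% CIs (significant exons in dark blue), transcript
    annotation boxes.  All panels share the display axis of ``cmap``.  Any
    missing input leaves its panel as a placeholder; the others still render.
    ``exon_spans`` maps exon_id -> genomic (start, end) so panel B aligns
    under panel A.  Returns the tables actually plotted: ``coverage``,
    ``exon_effects``, ``tracks``.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    tables: dict[str, pd.DataFrame] = {}
    xlim = (0.0, cmap.target_length)
    fig, axes = plt.subplots(
        3, 1, figsize=(10, 7), sharex=True,
        gridspec_kw={"height_ratios": [2.2, 1.4, 1.0]},
    )
    class_colours = {0: "#1f77b4", 1: "#9467bd", 2: "#d62728"}

    ax = axes[0]
    if strat is not None:
        rows = []
        for cls in strat.classes:
            binned = _bin(strat.class_means[cls], bin_width)
            x = np.arange(binned.size) * bin_width + bin_width / 2
            ax.plot(
                x, binned, color=class_colours.get(cls, "black"),
                label=f"{cls} ({strat.class_counts[cls]})",
            )
            for bs, v in zip(np.arange(binned.size) * bin_width, binned):
                rows.append(
                    {"genotype_class": cls, "target_bin_start": float(bs),
                     "coverage": float(v)}
                )
        ax.legend(title=strat.variant, fontsize=7, loc="upper right")
        ax.set_ylabel("normalised coverage")
        tables["coverage"] = pd.DataFrame(rows)
    else:
        ax.text(0.5, 0.5, "coverage unavailable", transform=ax.transAxes,
                ha="center")
        tables["coverage"] = pd.DataFrame(
            columns=["genotype_class", "target_bin_start", "coverage"]
        )

    ax = axes[1]
    if exon_effects is not None and len(exon_effects):
        eff = exon_effects.copy()
        if exon_spans:
            centres = [
                cmap.map_position((exon_spans[e][0] + exon_spans[e][1]) / 2)
                if e in exon_spans else np.nan
                for e in eff["exon_id"]
            ]
        else:
            centres = np.linspace(xlim[0], xlim[1], len(eff) + 2)[1:-1]
        eff["target_centre"] = centres
        sig = eff["significant"].fillna(False).astype(bool)
        for flag, colour in ((False, "#b0c4de"), (True, "#00308f")):
            sub = eff[sig == flag]
            ax.errorbar(
                sub["target_centre"], sub["beta"],
                yerr=1.96 * sub["se"], fmt="o", color=colour, markersize=4,
                capsize=2,
            )
        ax.axhline(0.0, lw=0.5, color="grey")
        ax.set_ylabel("exon effect")
        tables["exon_effects"] = eff
    else:
        ax.text(0.5, 0.5, "no exon effects", transform=ax.transAxes, ha="center")
        tables["exon_effects"] = pd.DataFrame()

    ax = axes[2]
    rows = []
    for i, m in enumerate(models):
        y = len(models) - i
        starts = [cmap.map_position(s) for s, _ in m.exons]
        ends = [cmap.map_position(e) for _, e in m.exons]
        ax.hlines(y, min(starts), max(ends), lw=0.8, color="grey")
        for (s, e), ts, te in zip(m.exons, starts, ends):
            ax.add_patch(
                plt.Rectangle((ts, y - 0.3), te - ts, 0.6, color="#444444")
            )
            rows.append(
                {"transcript_id": m.transcript_id, "exon_start": s,
                 "exon_end": e, "target_start": ts, "target_end": te}
            )
        ax.text(xlim[0], y + 0.35, m.transcript_id, fontsize=6)
    ax.set_ylim(0, len(models) + 1)
    ax.set_yticks([])
    ax.set_xlabel("display coordinate (introns fixed width)")
    tables["tracks"] = pd.DataFrame(rows)

    for ax in axes:
        ax.set_xlim(*xlim)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return tables
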