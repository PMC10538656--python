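"""Signal-level colocalisation from per-signal log Bayes factors.

Given two fine-mapped signals — each a vector of natural-log Bayes factors
(LBFs) of "this variant is the causal one for this signal" over the variants
of a region — the posterior probabilities of the five classical hypotheses
are computed:

* H0 no association in either study,
* H1 / H2 association only in study 1 / study 2,
* H3 two distinct causal variants,
* H4 one shared causal variant.

With ``a_k``, ``b_k`` the LBFs over the K shared variants and prior
per-variant probabilities p1, p2 (single-study causality) and p12 (shared
causality), the unnormalised log weights are

    lH0 = 0
    lH1 = ln p1 + logsumexp(a)
    lH2 = ln p2 + logsumexp(b)
    lH3 = ln p1 + ln p2 + ln( sum_{k != j} e^{a_k + b_j} )
    lH4 = ln p12 + logsumexp(a + b)

and the posteriors are their softmax.  The H3 cross term is evaluated in log
space as lndiff(S1 + S2, S12); with a single shared variant (or when the
difference underflows) H3 has no support and PP3 = 0.  This is the
signal-pair computation used on SuSiE-style LBF exports, applied to every
pair of independent signals between a QTL dataset and a GWAS (up to 10
signals per locus), with pairs exceeding PP4 > 0.9 flagged as colocalised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import islice

import numpy as np
import pandas as pd
from scipy.special import logsumexp

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 5e-6

MAX_SIGNALS_PER_LOCUS = 10


class ColocError(ValueError):
    pass


@dataclass(frozen=True)
class ColocResult:
    signal1: tuple[str, int]
    signal2: tuple[str, int]
    n_shared_variants: int
    pp: tuple[float, float, float, float, float]  # PP0..PP4
    priors: tuple[float, float, float]

    @property
    def pp4(self) -> float:
        return self.pp[4]

    def as_dict(self) -> dict:
        d = {
            "trait1": self.signal1[0],
            "signal1": self.signal1[1],
            "trait2": self.signal2[0],
            "signal2": self.signal2[1],
            "n_shared_variants": self.n_shared_variants,
        }
        d.update({f"pp{i}": self.pp[i] for i in range(5)})
        return d


def lndiff(x: float, y: float) -> float:
    """log(e^x - e^y) computed stably; -inf when y >= x."""
    if y >= x:
        return -np.inf
    return x + np.log1p(-np.exp(y - x))


def pairwise_coloc(
    lbf_a: pd.DataFrame | np.ndarray,
    lbf_b: pd.DataFrame | np.ndarray,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    signal_a: tuple[str, int] = ("trait1", 1),
    signal_b: tuple[str, int] = ("trait2", 1),
) -> ColocResult:
    """Colocalise two signals from their LBF vectors.

    Frame inputs must carry ``variant`` and ``lbf`` columns and are
    intersected on the canonical variant id; array inputs are assumed
    pre-aligned.  All arithmetic is in log space; posteriors sum to 1.
    """
    if isinstance(lbf_a, pd.DataFrame) or isinstance(lbf_b, pd.DataFrame):
        a_s = pd.Series(
            lbf_a["lbf"].to_numpy(), index=lbf_a["variant"].to_numpy()
        )
        b_s = pd.Series(
            lbf_b["lbf"].to_numpy(), index=lbf_b["variant"].to_numpy()
        )
        shared = a_s.index.intersection(b_s.index)
        if shared.empty:
            raise ColocError(
                f"no shared variants between {signal_a} and {signal_b}"
            )
        a = a_s.loc[shared].to_numpy(dtype=float)
        b = b_s.loc[shared].to_numpy(dtype=float)
    else:
        a = np.asarray(lbf_a, dtype=float)
        b = np.asarray(lbf_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1 or a.size == 0:
            raise ColocError("pre-aligned LBF vectors must share a 1-D shape")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ColocError("non-finite log Bayes factor in input")

    s1 = logsumexp(a)
    s2 = logsumexp(b)
    s12 = logsumexp(a + b)
    k = a.size
    lw = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            (np.log(p1) + np.log(p2) + lndiff(s1 + s2, s12)) if k > 1 else -np.inf,
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(lw - logsumexp(lw))
    pp /= pp.sum()
    return ColocResult(
        signal1=signal_a,
        signal2=signal_b,
        n_shared_variants=k,
        pp=tuple(float(x) for x in pp),
        priors=(p1, p2, p12),
    )


def _signals_of(lbf: pd.DataFrame) -> dict[tuple[str, int], pd.DataFrame]:
    out: dict[tuple[str, int], pd.DataFrame] = {}
    for (trait, idx), sub in lbf.groupby(
        ["molecular_trait_id", "signal_index"], sort=True
    ):
        out[(str(trait), int(idx))] = sub
    return out


def coloc_scan(
    qtl_lbf: pd.DataFrame,
    gwas_lbf: pd.DataFrame,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    threshold: float = 0.9,
    max_signals: int = MAX_SIGNALS_PER_LOCUS,
) -> pd.DataFrame:
    """All cross-pairs of QTL and GWAS signals sharing variants.

    Long-format LBF tables are split into per-(trait, signal_index) vectors;
    at most ``max_signals`` signals per trait/locus are used (extra signals
    are dropped with a warning).  Every pair with a non-empty variant
    intersection is evaluated; pairs with PP4 strictly above ``threshold``
    are flagged colocalised.  The full table is returned either way.
    """
    qtl = _truncate(_signals_of(qtl_lbf), max_signals, "QTL")
    gwas = _truncate(_signals_of(gwas_lbf), max_signals, "GWAS")
    rows = []
    for sig_q, sub_q in qtl.items():
        for sig_g, sub_g in gwas.items():
            try:
                res = pairwise_coloc(
                    sub_q, sub_g, p1=p1, p2=p2, p12=p12,
                    signal_a=sig_q, signal_b=sig_g,
                )
            except ColocError:
                continue  # disjoint variant sets: pair not evaluable
            row = res.as_dict()
            row["colocalised"] = res.pp4 > threshold
            rows.append(row)
    return pd.DataFrame(rows)


def _truncate(
    signals: dict[tuple[str, int], pd.DataFrame], max_signals: int, label: str
) -> dict[tuple[str, int], pd.DataFrame]:
    by_trait: dict[str, list[tuple[str, int]]] = {}
    for key in signals:
        by_trait.setdefault(key[0], []).append(key)
    kept: dict[tuple[str, int], pd.DataFrame] = {}
    for trait, keys in by_trait.items():
        keys = sorted(keys, key=lambda k: k[1])
        if len(keys) > max_signals:
            warnings.warn(
                f"{label} trait {trait}: {len(keys)} signals supplied, "
                f"using first {max_signals}",
                stacklevel=2,
            )
        for key in islice(keys, max_signals):
            kept[key] = signals[key]
    return kept
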