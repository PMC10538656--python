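"""Canonical variant identifiers.

A variant is identified by the string ``chr_pos_ref_alt`` (e.g.
``chr11_14855172_G_A``) with a 1-based position.  The underscore-joined id is
the join key used across every table in the pipeline: summary statistics,
credible sets, log-Bayes-factor vectors and dosage matrices.
"""

from __future__ import annotations

from dataclasses import dataclass


class VariantIdError(ValueError):
    """Raised when a variant id string cannot be parsed."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """One biallelic variant.

    Attributes
    ----------
    chromosome : str
        Chromosome name as spelled in the source file (``chr11``, ``X`` ...).
    position : int
        1-based base-pair position of the first reference base.
    ref, alt : str
        Reference and alternate alleles; must differ.
    """

    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantIdError(f"position must be >= 1, got {self.position}")
        if not self.ref or not self.alt:
            raise VariantIdError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise VariantIdError(f"ref == alt ({self.ref}) is not a variant")

    @property
    def id(self) -> str:
        """Canonical ``chr_pos_ref_alt`` string."""
        return f"{self.chromosome}_{self.position}_{self.ref}_{self.alt}"

    @classmethod
    def from_id(cls, variant_id: str) -> "VariantKey":
        """Parse a canonical id.

        Chromosome names may themselves contain underscores (alt contigs);
        the final three fields are position, ref and alt.
        """
        parts = variant_id.strip().split("_")
        if len(parts) < 4:
            raise VariantIdError(f"cannot parse variant id {variant_id!r}")
        chrom = "_".join(parts[:-3])
        pos_s, ref, alt = parts[-3:]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise VariantIdError(
                f"non-integer position in variant id {variant_id!r}"
            ) from exc
        return cls(chromosome=chrom, position=pos, ref=ref, alt=alt)

    def __str__(self) -> str:
        return self.id


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(allele: str) -> str:
    return allele.upper().translate(_COMPLEMENT)[::-1]


def is_swapped_complement(a: VariantKey, b: VariantKey) -> bool:
    """True when ``b`` is ``a`` with alleles swapped and strand-flipped.

    Used when intersecting variant sets from two studies typed on opposite
    strands; position and chromosome must already agree.
    """
    return (
        a.chromosome == b.chromosome
        and a.position == b.position
        and a.ref == reverse_complement(b.alt)
        and a.alt == reverse_complement(b.ref)
    )
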