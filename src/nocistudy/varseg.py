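"""Candidate-variant filtering and pedigree segregation testing.

Models the exome-candidate triage used in consanguineous recessive
pedigrees: hard-filter candidates on population frequency, deleterious-
ness (CADD) and a recessive-compatible zygosity, then test whether each
variant's genotypes across the affected relatives are consistent with
the proposed inheritance mode.  The alternate allele is inferred per
record as the allele observed homozygous (or hemizygous on the male X)
in the index patient -- candidate tables of this kind carry genotype
strings, not reference/alternate annotations.

The bundled fixture ``data/cip_candidate_variants.tsv`` holds the nine
autism/intellectual-disability candidate variants of a two-patient CIP
family screen, in which no candidate is shared by both affected cousins
(all nine are excluded by segregation).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .iolib import ValidationError, VariantRecord, read_variant_table

__all__ = [
    "SegregationCall",
    "filter_candidates",
    "segregation_filter",
    "load_cip_candidates",
]

RETAINED = "retained"
NOT_SHARED = "not_shared"
ZYGOSITY_MISMATCH = "zygosity_mismatch"
MODE_INCOMPATIBLE = "mode_incompatible"

_X_LINKED = {"XLR", "XLD"}


@dataclass(frozen=True)
class SegregationCall:
    """Verdict for one candidate variant."""

    gene: str
    retained: bool
    reason: str

    def __post_init__(self) -> None:
        if self.retained != (self.reason == RETAINED):
            raise ValidationError("retained iff reason == 'retained'")


def load_cip_candidates() -> list[VariantRecord]:
    """The bundled nine-candidate CIP-family variant table."""
    ref = resources.files("nocistudy.data") / "cip_candidate_variants.tsv"
    with resources.as_file(ref) as path:
        return read_variant_table(path)


def filter_candidates(
    variants: Sequence[VariantRecord],
    max_freq: float = 0.001,
    min_cadd: float = 20.0,
) -> list[VariantRecord]:
    """Hard filters preceding segregation testing.

    Keeps records that are rare (population frequency <= ``max_freq``;
    an absent frequency passes), predicted deleterious (CADD >=
    ``min_cadd``; absent passes) and whose claimed zygosity is
    compatible with a recessive pattern (homozygous or hemizygous).
    """
    kept = []
    for v in variants:
        if v.population_freq is not None and v.population_freq > max_freq:
            continue
        if v.cadd is not None and v.cadd < min_cadd:
            continue
        if v.zygosity_claimed.lower() not in ("homozygous", "hemizygous"):
            continue
        kept.append(v)
    return kept


def _parse_genotype(gene: str, ind: str, text: str) -> tuple[str, ...]:
    alleles = tuple(a.strip() for a in text.strip().split("/"))
    if len(alleles) not in (1, 2) or not all(alleles):
        raise ValidationError(
            f"variant {gene!r}: unparsable genotype {text!r} for {ind!r}"
        )
    return alleles


def _infer_alt(gene: str, index_gt: tuple[str, ...]) -> str | None:
    """Alternate allele: the allele homozygous (or hemizygous) in the index."""
    if len(set(index_gt)) != 1:
        return None
    return index_gt[0]


def segregation_filter(
    variants: Sequence[VariantRecord],
    affected: Sequence[str] = ("P1", "P2"),
) -> list[SegregationCall]:
    """Test each candidate for segregation with disease in the affecteds.

    A record is retained only when every affected individual carries the
    alternate allele in the state the inheritance mode requires:
    homozygous alternate for autosomal recessive (and for mode NA, which
    is treated as AR), hemizygous alternate for X-linked modes in male
    affecteds.  The alternate allele is inferred from the index patient
    (the first entry of ``affected``).

    Reasons for exclusion: ``not_shared`` when an affected lacks the
    required alternate state, ``zygosity_mismatch`` when the index
    genotype itself is not homozygous (no alternate can be inferred),
    ``mode_incompatible`` when an X-linked record carries a two-allele
    genotype for a male affected.
    """
    if not affected:
        raise ValidationError("need at least one affected individual")
    index = affected[0]
    calls = []
    for v in variants:
        missing = [ind for ind in affected if ind not in v.genotypes]
        if missing:
            raise ValidationError(
                f"variant {v.gene!r}: no genotype for {missing}"
            )
        mode = (v.inheritance or "NA").upper()
        x_linked = mode in _X_LINKED
        genotypes = {
            ind: _parse_genotype(v.gene, ind, v.genotypes[ind])
            for ind in affected
        }
        if x_linked and any(len(gt) != 1 for gt in genotypes.values()):
            calls.append(SegregationCall(v.gene, False, MODE_INCOMPATIBLE))
            continue
        alt = _infer_alt(v.gene, genotypes[index])
        if alt is None:
            calls.append(SegregationCall(v.gene, False, ZYGOSITY_MISMATCH))
            continue
        required = (alt,) if x_linked else (alt, alt)
        shared = all(
            tuple(sorted(genotypes[ind])) == tuple(sorted(required))
            for ind in affected
        )
        if shared:
            calls.append(SegregationCall(v.gene, True, RETAINED))
        else:
            calls.append(SegregationCall(v.gene, False, NOT_SHARED))
    return calls
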