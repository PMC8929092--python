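"""Rare-variant prioritization inside significant shared regions.

Stage two: functional classification of annotated variants, the rarity
filter (synonymous/benign excluded; both population MAFs < 0.001 or
unknown), carrier counting over family pools, and the between-family
gene-overlap (upset) summary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .model import (
    CarrierState,
    FunctionClass,
    HHMapError,
    Pedigree,
    VariantRecord,
)

__all__ = [
    "FunctionClass",
    "PrioritizedVariant",
    "classify_function",
    "passes_rare_filter",
    "prioritize",
    "count_carriers",
    "gene_overlap",
    "family_gene_sets",
]

logger = logging.getLogger(__name__)

MAF_THRESHOLD = 0.001


@dataclass
class PrioritizedVariant:
    """Variant retained by the filter, with its region and carrier counts."""

    record: VariantRecord
    family_id: str
    region_chrom: str
    region_start: int
    region_end: int
    affected_carriers: tuple[int, int]  # (k, n)
    unaffected_carriers: Optional[tuple[int, int]]  # None: no unaffected data
    cross_build: bool = False


def classify_function(annotation_string: str) -> FunctionClass:
    """Map an ANNOVAR-style (or free-text) functional label to a class.

    Case-insensitive keyword matching; unknown labels map to ``OTHER`` with
    a logged warning. An empty string is an error.
    """
    if not isinstance(annotation_string, str) or not annotation_string.strip():
        raise HHMapError("empty function annotation")
    s = annotation_string.strip().lower().replace("′", "'").replace("’", "'")
    compact = s.replace("-", "").replace("_", "").replace(" ", "")
    if "frameshift" in compact:
        return FunctionClass.FRAMESHIFT_INDEL
    if "stopgain" in compact or "stoploss" in compact or "stop gain" in s or "stop loss" in s:
        return FunctionClass.STOPGAIN_LOSS
    # "slicing" tolerated: appears as a typo for splicing in annotations
    if "splic" in compact or "slicing" in compact:
        return FunctionClass.SPLICING
    if "nonsynonymous" in compact:
        return FunctionClass.NONSYNONYMOUS
    if "synonymous" in compact:
        return FunctionClass.SYNONYMOUS
    if "ncrna" in compact or "noncoding" in compact:
        return FunctionClass.NONCODING_RNA
    if "utr5" in compact or "5'utr" in compact:
        return FunctionClass.UTR5
    if "utr3" in compact or "3'utr" in compact:
        return FunctionClass.UTR3
    if "upstream" in compact:
        return FunctionClass.UPSTREAM
    if "intronic" in compact or "intron" in compact or "promoter" in compact:
        return FunctionClass.INTRONIC_PROMOTER
    logger.warning("unrecognized function annotation %r mapped to OTHER", annotation_string)
    return FunctionClass.OTHER


def passes_rare_filter(
    record: VariantRecord, maf_threshold: float = MAF_THRESHOLD
) -> bool:
    """Rarity filter for candidate variants.

    Synonymous variants and variants labelled exactly "benign"
    (case-insensitive) are always rejected. Otherwise both population MAFs
    must individually be unknown (``None``) or below ``maf_threshold``.
    """
    if record.function_class is FunctionClass.SYNONYMOUS:
        return False
    label = (record.pathogenicity_label or "").strip().lower()
    if label == "benign":
        return False
    for maf in (record.maf_1000g, record.maf_gnomad):
        if maf is not None and maf >= maf_threshold:
            return False
    return True


def count_carriers(
    record: VariantRecord, sample_ids: Sequence[str]
) -> tuple[int, int]:
    """``(k, n)``: carriers among the samples with a non-missing state."""
    k = n = 0
    for sid in sample_ids:
        state = record.carriers[sid]
        if state is CarrierState.MISSING:
            continue
        n += 1
        if state is CarrierState.CARRIER:
            k += 1
    return k, n


def prioritize(
    records: Sequence[VariantRecord],
    representatives: Sequence,
    pedigree: Pedigree,
    family_id: str,
    maf_threshold: float = MAF_THRESHOLD,
    min_affected_fraction: Optional[float] = None,
) -> list[PrioritizedVariant]:
    """Filter variants to those inside the family's significant regions.

    ``representatives`` must already be significance-filtered; each needs
    ``chrom``, ``start_bp``, ``end_bp`` attributes (e.g.
    :class:`~hhmap.hh.RepresentativeRCHH`). A variant is kept when it
    overlaps any region, passes :func:`passes_rare_filter`, and (optionally)
    is carried by at least ``min_affected_fraction`` of the counted affected.
    Carrier counts run over the family members present in the variant table.
    """
    sequenced = [s for s in _table_samples(records)]
    fam_members = {i.individual_id: i for i in pedigree.members(family_id)}
    seq_affected = sorted(
        s
        for s in sequenced
        if s in fam_members and fam_members[s].affection.value == "affected"
    )
    seq_unaffected = sorted(
        s
        for s in sequenced
        if s in fam_members and fam_members[s].affection.value == "unaffected"
    )
    if records and not (seq_affected or seq_unaffected):
        raise HHMapError(f"family {family_id!r} has no sequenced member")
    regions = [(str(r.chrom), int(r.start_bp), int(r.end_bp)) for r in representatives]
    out: list[PrioritizedVariant] = []
    for rec in records:
        hit = None
        for chrom, start, end in regions:
            if rec.overlaps(chrom, start, end):
                hit = (chrom, start, end)
                break
        if hit is None:
            continue
        if not passes_rare_filter(rec, maf_threshold):
            continue
        cross_build = False
        for r in representatives:
            build = getattr(r, "genome_build", None)
            if build is not None and build != rec.genome_build:
                cross_build = True
        k_aff, n_aff = count_carriers(rec, seq_affected)
        if min_affected_fraction is not None:
            if n_aff == 0 or k_aff / n_aff < min_affected_fraction:
                continue
        unaff = count_carriers(rec, seq_unaffected) if seq_unaffected else None
        out.append(
            PrioritizedVariant(
                record=rec,
                family_id=family_id,
                region_chrom=hit[0],
                region_start=hit[1],
                region_end=hit[2],
                affected_carriers=(k_aff, n_aff),
                unaffected_carriers=unaff,
                cross_build=cross_build,
            )
        )
    out.sort(key=lambda pv: (pv.record.chrom, pv.record.start))
    return out


def _table_samples(records: Sequence[VariantRecord]) -> list[str]:
    seen: dict[str, None] = {}
    for rec in records:
        for sid in rec.carriers:
            seen.setdefault(sid, None)
    return list(seen)


def family_gene_sets(
    records_by_family: Mapping[str, Sequence[VariantRecord]],
    representatives_by_family: Mapping[str, Sequence],
) -> dict[str, set[str]]:
    """Genes with any variant inside each family's significant regions."""
    out: dict[str, set[str]] = {}
    for fam, records in records_by_family.items():
        regions = [
            (str(r.chrom), int(r.start_bp), int(r.end_bp))
            for r in representatives_by_family.get(fam, ())
        ]
        genes = {
            rec.gene
            for rec in records
            if rec.gene and any(rec.overlaps(*rg) for rg in regions)
        }
        if genes:
            out[fam] = genes
    return out


def gene_overlap(
    family_gene_sets: Mapping[str, set[str]],
) -> dict[frozenset, int]:
    """Exclusive (upset-style) intersection counts of family gene sets.

    Every gene contributes to exactly one subset: the full set of families
    whose gene set contains it. Empty subsets are omitted, so the counts
    partition the union of all genes.
    """
    if not family_gene_sets:
        raise HHMapError("need at least one family gene set")
    membership: dict[str, set[str]] = {}
    for fam, genes in family_gene_sets.items():
        for g in genes:
            membership.setdefault(g, set()).add(fam)
    counts: dict[frozenset, int] = {}
    for fams in membership.values():
        key = frozenset(fams)
        counts[key] = counts.get(key, 0) + 1
    return counts
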