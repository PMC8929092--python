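"""Readers and writers for PLINK PED/MAP, annotated variant CSV, and a
minimal VCF subset.

PED/MAP follow the classic PLINK text dialect: whitespace-delimited, allele
codes A/C/G/T (``0`` = missing allele), MAP columns chrom / id / cM / bp.
Heterozygous calls are unordered (``A G`` is the same call as ``G A``).
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    Affection,
    Call,
    CarrierState,
    FormatError,
    GenotypeMatrix,
    Individual,
    MarkerPanel,
    Pedigree,
    VariantRecord,
)
from .variants import classify_function

__all__ = [
    "read_ped_map",
    "write_ped_map",
    "read_variant_table",
    "variant_table_samples",
    "write_variant_table",
    "read_vcf_minimal",
]

_AFFECTION_CODES = {
    "2": Affection.AFFECTED,
    "1": Affection.UNAFFECTED,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
}


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise FormatError(
                    f"{map_path}: line {lineno}: expected 4 MAP columns, got {len(fields)}"
                )
            chrom, marker_id, cm, bp = fields
            rows.append((marker_id, chrom, int(bp), float(cm)))
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "bp", "cm"])


def read_ped_map(
    ped_path,
    map_path,
    panel: Optional[MarkerPanel] = None,
    genome_build: str = "unknown",
) -> tuple[MarkerPanel, GenotypeMatrix, Pedigree]:
    """Load a PLINK PED/MAP pair.

    When ``panel`` is given its allele labels decide HOM_REF vs HOM_ALT;
    otherwise labels are inferred per marker (lexicographically smaller
    observed allele first; unobserved second allele recorded as ``"0"``).
    Every sample present in the PED is marked genotyped in the pedigree.
    """
    markers = _read_map(map_path)
    n_markers = len(markers)
    if panel is not None and panel.n_markers != n_markers:
        raise FormatError(
            f"panel has {panel.n_markers} markers but MAP lists {n_markers}"
        )

    individuals: list[Individual] = []
    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_markers} "
                    f"fields for {n_markers} markers, got {len(fields)}"
                )
            fam, iid, father, mother, sex, pheno = fields[:6]
            if iid in sample_ids:
                raise FormatError(f"{ped_path}: line {lineno}: duplicate sample id {iid!r}")
            aff = _AFFECTION_CODES.get(pheno, Affection.UNKNOWN)
            individuals.append(
                Individual(
                    individual_id=iid,
                    family_id=fam,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=sex,
                    affection=aff,
                    genotyped=True,
                )
            )
            sample_ids.append(iid)
            allele_rows.append(np.array(fields[6:], dtype="<U8").reshape(n_markers, 2))

    alleles = (
        np.stack(allele_rows) if allele_rows else np.empty((0, n_markers, 2), dtype="<U8")
    )

    if panel is None:
        a1 = np.full(n_markers, "0", dtype="<U8")
        a2 = np.full(n_markers, "0", dtype="<U8")
        for j in range(n_markers):
            observed = sorted(set(alleles[:, j, :].ravel()) - {"0"})
            if len(observed) > 2:
                raise FormatError(
                    f"marker {markers['marker_id'][j]!r}: more than two alleles {observed}"
                )
            if observed:
                a1[j] = observed[0]
            if len(observed) == 2:
                a2[j] = observed[1]
        table = markers.assign(a1=a1, a2=a2)
        panel = MarkerPanel(table, genome_build=genome_build)
    else:
        a1 = panel.markers["a1"].to_numpy().astype("<U8")
        a2 = panel.markers["a2"].to_numpy().astype("<U8")

    calls = np.full((len(sample_ids), n_markers), Call.MISSING.value, dtype=np.int8)
    for i in range(len(sample_ids)):
        x, y = alleles[i, :, 0], alleles[i, :, 1]
        known = (x != "0") & (y != "0")
        for j in np.flatnonzero(known):
            pair = {x[j], y[j]}
            if not pair <= {a1[j], a2[j]}:
                raise FormatError(
                    f"sample {sample_ids[i]!r} marker "
                    f"{panel.marker_id[j]!r}: alleles {sorted(pair)} not in "
                    f"panel labels ({a1[j]}, {a2[j]})"
                )
            if x[j] != y[j]:
                calls[i, j] = Call.HET.value
            elif x[j] == a1[j]:
                calls[i, j] = Call.HOM_REF.value
            else:
                calls[i, j] = Call.HOM_ALT.value
    matrix = GenotypeMatrix(panel, sample_ids, calls)
    return panel, matrix, Pedigree(individuals)


def write_ped_map(
    panel: MarkerPanel,
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    out_prefix,
) -> tuple[Path, Path]:
    """Emit ``<out_prefix>.ped`` and ``<out_prefix>.map``.

    Deterministic column order; MISSING becomes ``0 0``. An empty cohort
    yields an empty PED with the MAP still listing every marker.
    """
    out_prefix = Path(out_prefix)
    map_path = out_prefix.with_suffix(".map")
    ped_path = out_prefix.with_suffix(".ped")
    m = panel.markers
    with open(map_path, "w") as fh:
        for row in m.itertuples(index=False):
            # repr: shortest exact round-trip for the cM coordinate
            fh.write(f"{row.chrom}\t{row.marker_id}\t{float(row.cm)!r}\t{row.bp}\n")

    a1 = m["a1"].to_numpy().astype("<U8")
    a2 = m["a2"].to_numpy().astype("<U8")
    aff_code = {
        Affection.AFFECTED: "2",
        Affection.UNAFFECTED: "1",
        Affection.UNKNOWN: "0",
    }
    with open(ped_path, "w") as fh:
        for sid in matrix.sample_ids:
            ind = pedigree.get(sid)
            calls = matrix.row(sid)
            fields = [
                ind.family_id,
                sid,
                ind.father_id or "0",
                ind.mother_id or "0",
                ind.sex,
                aff_code[ind.affection],
            ]
            for j, c in enumerate(calls):
                if c == Call.HOM_REF.value:
                    fields += [a1[j], a1[j]]
                elif c == Call.HET.value:
                    fields += [a1[j], a2[j]]
                elif c == Call.HOM_ALT.value:
                    fields += [a2[j], a2[j]]
                elif c == Call.MISSING.value:
                    fields += ["0", "0"]
                else:  # pragma: no cover - GenotypeMatrix validates states
                    raise FormatError(f"unknown call state {c}")
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


_VARIANT_COLUMNS = (
    "chrom",
    "start",
    "end",
    "ref",
    "alt",
    "function",
    "gene",
    "maf_1000g",
    "maf_gnomad",
    "pathogenicity",
)


def variant_table_samples(csv_path) -> list[str]:
    """Sample ids present as genotype columns in a variant CSV."""
    with open(csv_path, newline="") as fh:
        header = next(csv.reader(fh), [])
    return [c for c in header if c not in _VARIANT_COLUMNS]


def read_variant_table(
    csv_path,
    sample_ids: Sequence[str],
    genome_build: str = "unknown",
) -> list[VariantRecord]:
    """Load an annotated variant CSV (one genotype column per sample).

    Expected named columns: ``chrom, start, end, ref, alt, function, gene,
    maf_1000g, maf_gnomad, pathogenicity`` plus one column per entry of
    ``sample_ids`` holding ``carrier`` / ``non_carrier`` / ``missing`` (or
    ``1`` / ``0`` / ``.``). Empty or ``.`` MAF cells become unknown (None).
    """
    records: list[VariantRecord] = []
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing_cols = [c for c in _VARIANT_COLUMNS if c not in header]
        if missing_cols:
            raise FormatError(f"{csv_path}: missing columns {missing_cols}")
        for sid in sample_ids:
            if sid not in header:
                raise FormatError(f"{csv_path}: no genotype column for sample {sid!r}")
        for rownum, row in enumerate(reader, 2):
            try:
                fclass = classify_function(row["function"])
            except Exception as exc:
                raise FormatError(
                    f"{csv_path}: row {rownum}: bad function value "
                    f"{row['function']!r} ({exc})"
                ) from exc
            carriers = {
                sid: _parse_carrier(row[sid], csv_path, rownum, sid)
                for sid in sample_ids
            }
            patho = (row["pathogenicity"] or "").strip()
            records.append(
                VariantRecord(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    gene=row["gene"],
                    function_class=fclass,
                    function_label=row["function"],
                    maf_1000g=_parse_maf(row["maf_1000g"]),
                    maf_gnomad=_parse_maf(row["maf_gnomad"]),
                    pathogenicity_label=None if patho in ("", ".") else patho,
                    carriers=carriers,
                    genome_build=genome_build,
                )
            )
    return records


def _parse_maf(cell: Optional[str]) -> Optional[float]:
    if cell is None:
        return None
    cell = cell.strip()
    if cell in ("", "."):
        return None
    return float(cell)


_CARRIER_CODES = {
    "carrier": CarrierState.CARRIER,
    "1": CarrierState.CARRIER,
    "non_carrier": CarrierState.NON_CARRIER,
    "0": CarrierState.NON_CARRIER,
    "missing": CarrierState.MISSING,
    ".": CarrierState.MISSING,
    "": CarrierState.MISSING,
}


def _parse_carrier(cell, path, rownum, sid) -> CarrierState:
    try:
        return _CARRIER_CODES[(cell or "").strip().lower()]
    except KeyError:
        raise FormatError(
            f"{path}: row {rownum}: bad carrier value {cell!r} for sample {sid!r}"
        ) from None


def write_variant_table(
    records: Sequence[VariantRecord], sample_ids: Sequence[str], csv_path
) -> Path:
    """Write records to the CSV dialect accepted by :func:`read_variant_table`."""
    csv_path = Path(csv_path)
    carrier_code = {
        CarrierState.CARRIER: "carrier",
        CarrierState.NON_CARRIER: "non_carrier",
        CarrierState.MISSING: "missing",
    }
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_VARIANT_COLUMNS) + list(sample_ids))
        for rec in records:
            writer.writerow(
                [
                    rec.chrom,
                    rec.start,
                    rec.end,
                    rec.ref,
                    rec.alt,
                    rec.function_label or rec.function_class.value,
                    rec.gene,
                    "" if rec.maf_1000g is None else repr(rec.maf_1000g),
                    "" if rec.maf_gnomad is None else repr(rec.maf_gnomad),
                    rec.pathogenicity_label or "",
                ]
                + [carrier_code[rec.carriers[s]] for s in sample_ids]
            )
    return csv_path


def read_vcf_minimal(vcf_path, genome_build: str = "unknown") -> list[VariantRecord]:
    """Parse a small uncompressed VCF (4.2 subset; GT field only).

    Any genotype containing an alt allele maps to CARRIER, ``0/0`` to
    NON_CARRIER, ``./.`` to MISSING. Only the first alt allele of a
    multi-allelic site is used. Annotation-dependent fields (gene, function,
    MAFs) are left null/OTHER for downstream tools to fill.
    """
    from .model import FunctionClass

    records: list[VariantRecord] = []
    samples: list[str] = []
    with open(vcf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                samples = cols[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(f"{vcf_path}: line {lineno}: truncated VCF record")
            chrom, pos, _id, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise FormatError(f"{vcf_path}: line {lineno}: no GT in FORMAT")
            gt_idx = fmt.index("GT")
            alt0 = alt.split(",")[0]
            carriers: dict[str, CarrierState] = {}
            for sid, sample_field in zip(samples, fields[9:]):
                gt = sample_field.split(":")[gt_idx]
                alleles = gt.replace("|", "/").split("/")
                if all(a == "." for a in alleles):
                    carriers[sid] = CarrierState.MISSING
                elif any(a not in ("0", ".") for a in alleles):
                    carriers[sid] = CarrierState.CARRIER
                else:
                    carriers[sid] = CarrierState.NON_CARRIER
            end = pos + max(len(ref), 1) - 1
            records.append(
                VariantRecord(
                    chrom=chrom,
                    start=pos,
                    end=end,
                    ref=ref,
                    alt=alt0,
                    gene="",
                    function_class=FunctionClass.OTHER,
                    function_label="",
                    carriers=carriers,
                    genome_build=genome_build,
                )
            )
    return records
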