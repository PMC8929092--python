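"""Packaged machine-readable copies of the study's summary tables.

Three TSVs ship with the distribution: per-family cohort counts
(``table1``), the list of significant shared regions with sharing counts
and -log10(p) (``table2``), and the prioritized exome variants with carrier
counts (``table3``). Region coordinates in ``table2`` are hg18; the exome
table header states hg18 while the sequencing pipeline aligned to hg19, so
containment of a variant in its stated region is checked but never "fixed":
mismatching rows are returned as warnings.
"""
from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .model import FormatError

__all__ = ["TableFixtures", "load_fixtures", "parse_share", "parse_region"]

_CHECKSUMS = {
    "table1.tsv": "7bf1cb1f460b1dbdc5b9506834a36829ee610bc30e0e6be3c3de2f3dfc45ba76",
    "table2.tsv": "636fe5196e49afa353bfc432462a30504ccb236c5baa6ac0abe45937fc04bdd8",
    "table3.tsv": "84cd7f7f40e87ba9465151ef1c43cbb53547e799b3f52a68ec3ff1f7b7973920",
}

_SHARE_RE = re.compile(r"^\s*(\d+)\s+out\s+of\s+(\d+)\s*$")
_REGION_RE = re.compile(r"^\s*chr\s*([\w]+)\s*:\s*(\d+)\s*-\s*(\d+)\s*$")


def parse_share(cell: str) -> tuple[int, int] | None:
    """Parse ``"k out of n"`` to ``(k, n)``; ``"NA"`` to ``None``."""
    if cell.strip().upper() == "NA":
        return None
    m = _SHARE_RE.match(cell)
    if not m:
        raise FormatError(f"unparseable sharing cell {cell!r}")
    k, n = int(m.group(1)), int(m.group(2))
    if k > n:
        raise FormatError(f"sharing cell {cell!r} has k > n")
    return k, n


def parse_region(cell: str) -> tuple[str, int, int]:
    """Parse ``"chrC:start-end"`` (spaces tolerated)."""
    m = _REGION_RE.match(cell)
    if not m:
        raise FormatError(f"unparseable region {cell!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))


@dataclass
class TableFixtures:
    """The three packaged tables plus containment warnings for table 3."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    build_warnings: list[str] = field(default_factory=list)
    region_build: str = "hg18"
    variant_build: str = "hg19"  # per the sequencing pipeline's reference


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("hhmap.data").joinpath(name)
    data = ref.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FormatError(
            f"packaged fixture {name} is corrupted (sha256 {digest})"
        )
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def load_fixtures() -> TableFixtures:
    """Load and validate the packaged tables.

    Adds parsed integer columns for counts and sharing cells, and collects a
    warning for every exome variant whose printed coordinates fall outside
    its stated (differently-built) region instead of altering either.
    """
    t1 = _read("table1.tsv")
    for col in (
        "total_affected",
        "genotyped_affected",
        "total_unaffected",
        "genotyped_unaffected",
    ):
        t1[col] = t1[col].astype(int)

    t2 = _read("table2.tsv")
    t2["neg_log10_p"] = t2["neg_log10_p"].astype(float)
    shares = t2["patient_share"].map(parse_share)
    t2["patient_k"] = [s[0] for s in shares]
    t2["patient_n"] = [s[1] for s in shares]
    shares = t2["control_share"].map(parse_share)
    t2["control_k"] = [s[0] for s in shares]
    t2["control_n"] = [s[1] for s in shares]
    bp = t2["bp_range"].str.split("-", expand=True).astype(int)
    t2["start_bp"], t2["end_bp"] = bp[0], bp[1]

    t3 = _read("table3.tsv")
    t3["start"] = t3["start"].astype(int)
    t3["end"] = t3["end"].astype(int)
    aff = t3["affected"].map(parse_share)
    t3["affected_k"] = [s[0] for s in aff]
    t3["affected_n"] = [s[1] for s in aff]
    unaff = t3["unaffected"].map(parse_share)
    t3["unaffected_k"] = [s[0] if s else None for s in unaff]
    t3["unaffected_n"] = [s[1] if s else None for s in unaff]

    warnings: list[str] = []
    for row in t3.itertuples(index=False):
        chrom, start, end = parse_region(row.rchh_region)
        if str(row.chr) != chrom or not (start <= row.start and row.end <= end):
            warnings.append(
                f"{row.gene} {row.chr}:{row.start}-{row.end} lies outside its "
                f"stated region {row.rchh_region} (region build hg18, variant "
                f"coordinates hg19-derived); builds differ, not corrected"
            )
    return TableFixtures(table1=t1, table2=t2, table3=t3, build_warnings=warnings)
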