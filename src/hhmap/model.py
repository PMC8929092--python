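"""Core domain types: marker panels, genotype matrices, pedigrees, variants.

Coordinates are 1-based, fully-closed intervals throughout. Genome builds are
carried as opaque string tags; no liftover is performed anywhere.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Call",
    "Affection",
    "CarrierState",
    "FunctionClass",
    "MarkerPanel",
    "GenotypeMatrix",
    "Individual",
    "Pedigree",
    "VariantRecord",
    "HHMapError",
    "FormatError",
    "PedigreeError",
]


class HHMapError(Exception):
    """Base class for all package errors."""


class FormatError(HHMapError):
    """Malformed or inconsistent input data."""


class PedigreeError(HHMapError):
    """Structurally invalid pedigree."""


class Call(enum.IntEnum):
    """Biallelic genotype call state."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class CarrierState(enum.Enum):
    CARRIER = "carrier"
    NON_CARRIER = "non_carrier"
    MISSING = "missing"


class FunctionClass(enum.Enum):
    """Closed enumeration of variant functional categories."""

    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    FRAMESHIFT_INDEL = "frameshift_indel"
    SPLICING = "splicing"
    STOPGAIN_LOSS = "stopgain_loss"
    INTRONIC_PROMOTER = "intronic_promoter"
    UTR5 = "utr5"
    UTR3 = "utr3"
    NONCODING_RNA = "noncoding_rna"
    UPSTREAM = "upstream"
    OTHER = "other"


_PANEL_COLUMNS = ("marker_id", "chrom", "bp", "cm", "a1", "a2")


class MarkerPanel:
    """Ordered biallelic SNP panel with a genetic (cM) map.

    Parameters
    ----------
    markers
        DataFrame with columns ``marker_id, chrom, bp, cm, a1, a2``. Markers
        of one chromosome must form a contiguous block, with ``bp`` strictly
        increasing and ``cm`` non-decreasing within the block.
    genome_build
        Opaque build tag (e.g. ``"hg18"``); carried through, never acted on.
    """

    def __init__(self, markers: pd.DataFrame, genome_build: str = "unknown"):
        missing = [c for c in _PANEL_COLUMNS if c not in markers.columns]
        if missing:
            raise FormatError(f"marker table lacks columns: {missing}")
        markers = markers.reset_index(drop=True).copy()
        markers["marker_id"] = markers["marker_id"].astype(str)
        markers["chrom"] = markers["chrom"].astype(str)
        markers["bp"] = markers["bp"].astype(np.int64)
        markers["cm"] = markers["cm"].astype(float)
        if markers["marker_id"].duplicated().any():
            dup = markers.loc[markers["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise FormatError(f"duplicate marker id {dup!r}")
        self.markers = markers
        self.genome_build = genome_build
        # contiguous chromosome blocks, in order of first appearance
        self._slices: dict[str, slice] = {}
        chrom = markers["chrom"].to_numpy()
        if len(chrom):
            starts = np.flatnonzero(np.r_[True, chrom[1:] != chrom[:-1]])
            ends = np.r_[starts[1:], len(chrom)]
            for s, e in zip(starts, ends):
                name = chrom[s]
                if name in self._slices:
                    raise FormatError(f"chromosome {name!r} is not contiguous")
                self._slices[name] = slice(int(s), int(e))
            bp = markers["bp"].to_numpy()
            cm = markers["cm"].to_numpy()
            for name, sl in self._slices.items():
                if np.any(np.diff(bp[sl]) <= 0):
                    raise FormatError(f"bp not strictly increasing on chromosome {name}")
                if np.any(np.diff(cm[sl]) < 0):
                    raise FormatError(f"cM not non-decreasing on chromosome {name}")
        self._index: dict[str, int] = {
            m: i for i, m in enumerate(markers["marker_id"])
        }

    # -- accessors -------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def __len__(self) -> int:
        return self.n_markers

    @property
    def marker_id(self) -> np.ndarray:
        return self.markers["marker_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.markers["chrom"].to_numpy()

    @property
    def bp(self) -> np.ndarray:
        return self.markers["bp"].to_numpy()

    @property
    def cm(self) -> np.ndarray:
        return self.markers["cm"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        return list(self._slices)

    def chrom_slice(self, chromosome: str) -> slice:
        try:
            return self._slices[str(chromosome)]
        except KeyError:
            raise KeyError(f"unknown chromosome {chromosome!r}") from None

    def marker_index(self, marker_id: str) -> int:
        return self._index[marker_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerPanel):
            return NotImplemented
        return (
            self.genome_build == other.genome_build
            and self.markers.equals(other.markers)
        )


class GenotypeMatrix:
    """Genotype calls for a sample cohort over a :class:`MarkerPanel`.

    Calls are stored as an ``int8`` array of shape ``(n_samples, n_markers)``
    with values from :class:`Call`.
    """

    def __init__(
        self,
        panel: MarkerPanel,
        sample_ids: Sequence[str],
        calls: np.ndarray,
    ):
        sample_ids = [str(s) for s in sample_ids]
        if len(set(sample_ids)) != len(sample_ids):
            seen: set[str] = set()
            dup = next(s for s in sample_ids if s in seen or seen.add(s))
            raise FormatError(f"duplicate sample id {dup!r}")
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(sample_ids), panel.n_markers):
            raise FormatError(
                f"call matrix shape {calls.shape} does not match "
                f"{len(sample_ids)} samples x {panel.n_markers} markers"
            )
        valid = np.isin(calls, [c.value for c in Call])
        if not valid.all():
            bad = calls[~valid][0]
            raise FormatError(f"invalid call state {bad}")
        self.panel = panel
        self.sample_ids = sample_ids
        self.calls = calls
        self._row = {s: i for i, s in enumerate(sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.calls[self._row[sample_id]]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._row


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "1" male, "2" female, "0" unknown
    affection: Affection
    genotyped: bool = True


class Pedigree:
    """Family structures with affection status.

    Validates that parent references resolve (or are null) and that the
    parent graph is acyclic; founders have both parents null.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.individual_id in self._members:
                raise PedigreeError(f"duplicate individual id {ind.individual_id!r}")
            self._members[ind.individual_id] = ind
        for ind in self._members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self._members:
                    raise PedigreeError(
                        f"{ind.individual_id}: parent {pid!r} not in pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done
        for start in self._members:
            if start in state:
                continue
            stack = [(start, iter(self._parents_of(start)))]
            state[start] = 0
            while stack:
                node, parents = stack[-1]
                advanced = False
                for p in parents:
                    if state.get(p) == 0:
                        raise PedigreeError(f"pedigree cycle through {p!r}")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(self._parents_of(p))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    def _parents_of(self, individual_id: str) -> list[str]:
        ind = self._members[individual_id]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None]

    # -- accessors -------------------------------------------------------
    def __iter__(self):
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def get(self, individual_id: str) -> Individual:
        return self._members[individual_id]

    @property
    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self._members.values():
            seen.setdefault(ind.family_id, None)
        return list(seen)

    def members(self, family_id: str) -> list[Individual]:
        return [i for i in self._members.values() if i.family_id == family_id]

    def founders(self) -> list[Individual]:
        return [
            i
            for i in self._members.values()
            if i.father_id is None and i.mother_id is None
        ]

    def genotyped_affected(self, family_id: str) -> list[str]:
        """Patient pool: genotyped, affected members of the family."""
        return sorted(
            i.individual_id
            for i in self.members(family_id)
            if i.genotyped and i.affection is Affection.AFFECTED
        )

    def genotyped_unaffected(self, family_id: str) -> list[str]:
        """Control pool: genotyped, unaffected members of the family."""
        return sorted(
            i.individual_id
            for i in self.members(family_id)
            if i.genotyped and i.affection is Affection.UNAFFECTED
        )


@dataclass
class VariantRecord:
    """Annotated exome variant with per-sample carrier states.

    ``start``/``end`` are 1-based inclusive. ``alt`` is ``"-"`` for a pure
    deletion and ``ref`` is ``"-"`` for a pure insertion. MAF fields are
    ``None`` when the frequency is unreported ("unknown").
    """

    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    gene: str
    function_class: FunctionClass
    function_label: str = ""
    maf_1000g: Optional[float] = None
    maf_gnomad: Optional[float] = None
    pathogenicity_label: Optional[str] = None
    carriers: Mapping[str, CarrierState] = field(default_factory=dict)
    genome_build: str = "unknown"

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom)
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start > self.end:
            raise FormatError(
                f"variant {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if not isinstance(self.function_class, FunctionClass):
            raise FormatError(
                f"function_class must be a FunctionClass, got {self.function_class!r}"
            )
        for name in ("maf_1000g", "maf_gnomad"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= float(v) <= 1.0):
                raise FormatError(f"{name}={v} outside [0, 1]")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Any-base overlap of closed intervals on the same chromosome."""
        return str(chrom) == self.chrom and self.start <= end and start <= self.end
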