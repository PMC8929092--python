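"""Synthetic multiplex-family cohort generator.

Gene-dropping over a three-generation pedigree with recombination as a
Poisson crossover process on the cM map (Haldane, no interference), an
implanted founder segment forced to co-segregate with affection, per-call
genotyping error and missingness, plus an annotated variant table carrying
one causal rare variant inside the implanted segment. Fully reproducible
from the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    Affection,
    Call,
    CarrierState,
    GenotypeMatrix,
    HHMapError,
    Individual,
    MarkerPanel,
    Pedigree,
    VariantRecord,
)
from .variants import classify_function

__all__ = [
    "ChromosomeSpec",
    "ImplantSpec",
    "VariantTableSpec",
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_cohort",
    "mendelian_check",
    "simulate_variant_table",
]

_MAX_CONDITION_ATTEMPTS = 10_000


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length_cm: float
    n_markers: int


@dataclass(frozen=True)
class ImplantSpec:
    """Founder segment forced into the designated affected individuals."""

    chrom: str = "1"
    start_cm: float = 45.0
    end_cm: float = 55.0
    carrier_ids: Optional[tuple[str, ...]] = None  # None: all affected
    # the co-inherited ancestral segment extends beyond the implant proper
    # by this much on each side (clipped to the chromosome map)
    condition_buffer_cm: float = 5.0


@dataclass(frozen=True)
class VariantTableSpec:
    n_noise_variants: int = 30
    pass_fraction: float = 0.3  # noise records built to survive the filter
    causal_function: str = "splicing"
    carrier_rate: float = 0.3  # per-sample carrier probability for noise


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chromosomes: tuple[ChromosomeSpec, ...] = (
        ChromosomeSpec("1", 100.0, 1000),
        ChromosomeSpec("2", 100.0, 1000),
    )
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_children: int = 19  # children of the focal founder couple
    sibship_size: int = 1  # grandchildren per child couple
    n_affected: int = 6
    n_controls_genotyped: int = 20
    implant: ImplantSpec = field(default_factory=ImplantSpec)
    epsilon: float = 0.001
    missing_rate: float = 0.01
    variant_spec: VariantTableSpec = field(default_factory=VariantTableSpec)
    family_id: str = "SIM1"
    genome_build: str = "simbuild"

    def __post_init__(self) -> None:
        for name, rate in (("epsilon", self.epsilon), ("missing_rate", self.missing_rate)):
            if not (0.0 <= rate <= 1.0):
                raise HHMapError(f"{name}={rate} outside [0, 1]")
        chrom_names = [c.name for c in self.chromosomes]
        if self.implant.chrom not in chrom_names:
            raise HHMapError(f"implant chromosome {self.implant.chrom!r} not simulated")
        spec = next(c for c in self.chromosomes if c.name == self.implant.chrom)
        if not (0.0 <= self.implant.start_cm <= self.implant.end_cm <= spec.length_cm):
            raise HHMapError("implant interval outside its chromosome map")


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated cohort."""

    implant_chrom: str
    implant_start_idx: int
    implant_end_idx: int
    implant_start_bp: int
    implant_end_bp: int
    implant_start_cm: float
    implant_end_cm: float
    carrier_flags: dict[str, bool]  # carries >=1 copy of the tagged segment
    causal_variant_id: str = "causal"


def _build_panel(config: SimulationConfig) -> MarkerPanel:
    rows = []
    for spec in config.chromosomes:
        cm = np.linspace(0.0, spec.length_cm, spec.n_markers)
        # bp tracks the cM map; the +index keeps bp strictly increasing on
        # degenerate (0 cM) chromosomes
        bp = np.round(cm * 1e6).astype(np.int64) + np.arange(spec.n_markers) + 1
        for j in range(spec.n_markers):
            rows.append(
                (f"c{spec.name}m{j}", spec.name, int(bp[j]), float(cm[j]), "A", "B")
            )
    return MarkerPanel(
        pd.DataFrame(rows, columns=["marker_id", "chrom", "bp", "cm", "a1", "a2"]),
        genome_build=config.genome_build,
    )


def _build_pedigree(config: SimulationConfig) -> tuple[Pedigree, list[str], list[str]]:
    """Three-generation template: focal couple, married children, sibships.

    Returns the pedigree plus the designated affected ids and the ids of
    genotyped unaffected (controls).
    """
    fam = config.family_id
    inds: list[Individual] = []

    def add(iid, father, mother, sex):
        inds.append(
            Individual(iid, fam, father, mother, sex, Affection.UNAFFECTED, True)
        )

    add("F0", None, None, "1")  # tagged founder
    add("M0", None, None, "2")
    children, grandchildren = [], []
    for i in range(1, config.n_children + 1):
        csex = "1" if i % 2 == 1 else "2"
        add(f"C{i}", "F0", "M0", csex)
        add(f"S{i}", None, None, "2" if csex == "1" else "1")
        children.append(f"C{i}")
        father, mother = (f"C{i}", f"S{i}") if csex == "1" else (f"S{i}", f"C{i}")
        for j in range(1, config.sibship_size + 1):
            gid = f"G{i}_{j}"
            add(gid, father, mother, "1" if j % 2 == 1 else "2")
            grandchildren.append(gid)

    # affected spread round-robin across sibships (cousins, not sib pairs,
    # keeping background IBD sharing among patients low); controls come from
    # married-in spouses and the lineages without affected members first
    if config.n_affected > len(grandchildren):
        raise HHMapError("pedigree template too small for n_affected")
    by_rank = sorted(
        grandchildren, key=lambda g: (int(g.split("_")[1]), int(g[1:].split("_")[0]))
    )
    affected = by_rank[: config.n_affected]
    control_order = (
        [f"S{i}" for i in range(1, config.n_children + 1)]
        + ["M0"]
        + [g for g in reversed(grandchildren) if g not in affected]
        + list(reversed(children))
    )
    if config.n_controls_genotyped > len(control_order):
        raise HHMapError("pedigree template too small for n_controls_genotyped")
    controls = control_order[: config.n_controls_genotyped]

    # connecting relatives outside both pools get UNKNOWN affection, so the
    # pools survive a PED round-trip (PED cannot carry the genotyped flag)
    genotyped = set(affected) | set(controls)

    def affection_of(iid: str) -> Affection:
        if iid in affected:
            return Affection.AFFECTED
        if iid in set(controls):
            return Affection.UNAFFECTED
        return Affection.UNKNOWN

    final = [
        replace(
            ind,
            affection=affection_of(ind.individual_id),
            genotyped=ind.individual_id in genotyped,
        )
        for ind in inds
    ]
    return Pedigree(final), affected, controls


def _required_tag_edges(
    pedigree: Pedigree, carrier_ids: Sequence[str], founder: str = "F0"
) -> set[tuple[str, str]]:
    """Transmission edges (parent -> child) that must carry the tagged
    segment so every designated carrier inherits it from the founder."""
    descendants = {founder}
    changed = True
    while changed:
        changed = False
        for ind in pedigree:
            if ind.individual_id in descendants:
                continue
            if ind.father_id in descendants or ind.mother_id in descendants:
                descendants.add(ind.individual_id)
                changed = True
    edges: set[tuple[str, str]] = set()
    for cid in carrier_ids:
        node = cid
        while node != founder:
            ind = pedigree.get(node)
            parent = None
            for p in (ind.father_id, ind.mother_id):
                if p is not None and p in descendants:
                    parent = p
                    break
            if parent is None:
                raise HHMapError(
                    f"no genealogical path from tagged founder to {cid!r}"
                )
            edges.add((parent, node))
            node = parent
    return edges


def _gamete(
    rng: np.random.Generator,
    haps: tuple[np.ndarray, np.ndarray],
    anc: tuple[np.ndarray, np.ndarray],
    cm: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis: Poisson crossovers at rate 1/Morgan, random start phase."""
    length_morgan = (cm[-1] - cm[0]) / 100.0 if len(cm) > 1 else 0.0
    n_xo = rng.poisson(length_morgan)
    phase = int(rng.integers(2))
    if n_xo == 0:
        return haps[phase].copy(), anc[phase].copy()
    xpts = np.sort(rng.uniform(cm[0], cm[-1], size=n_xo))
    seg = (phase + np.searchsorted(xpts, cm, side="right")) % 2
    allele = np.where(seg == 0, haps[0], haps[1])
    ancestry = np.where(seg == 0, anc[0], anc[1])
    return allele, ancestry


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[MarkerPanel, GenotypeMatrix, Pedigree, SimulatedTruth]:
    """Generate one multiplex family cohort with an implanted segment.

    Founder haplotypes are drawn marker-wise from allele frequencies sampled
    uniformly on ``maf_range``; descendants receive recombinant gametes; the
    gamete along every founder-to-affected transmission is resampled until
    it carries the tagged founder haplotype across the whole implant
    interval. Error and missingness are applied afterwards.
    """
    rng = np.random.default_rng(config.seed)
    panel = _build_panel(config)
    pedigree, affected, _controls = _build_pedigree(config)
    carrier_ids = (
        list(config.implant.carrier_ids)
        if config.implant.carrier_ids is not None
        else affected
    )
    tag_edges = _required_tag_edges(pedigree, carrier_ids)

    implant_sl = panel.chrom_slice(config.implant.chrom)
    cm_all = panel.cm
    local_cm = cm_all[implant_sl]
    in_implant_local = (local_cm >= config.implant.start_cm) & (
        local_cm <= config.implant.end_cm
    )
    implant_local_idx = np.flatnonzero(in_implant_local)
    if implant_local_idx.size == 0:
        raise HHMapError("implant interval contains no marker")
    buf = config.implant.condition_buffer_cm
    cond_local_idx = np.flatnonzero(
        (local_cm >= config.implant.start_cm - buf)
        & (local_cm <= config.implant.end_cm + buf)
    )

    order = [ind.individual_id for ind in pedigree]
    founders = {ind.individual_id for ind in pedigree.founders()}
    freqs = {
        spec.name: rng.uniform(*config.maf_range, size=spec.n_markers)
        for spec in config.chromosomes
    }

    # per chromosome: haplotype and ancestry arrays per individual
    haps: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    ancs: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for spec in config.chromosomes:
        chrom = spec.name
        sl = panel.chrom_slice(chrom)
        cm = cm_all[sl]
        q = freqs[chrom]
        h: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        a: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        on_implant_chrom = chrom == config.implant.chrom
        for iid in order:
            ind = pedigree.get(iid)
            if iid in founders:
                pair = tuple(
                    (rng.random(spec.n_markers) < q).astype(np.uint8) for _ in range(2)
                )
                tag0 = on_implant_chrom and iid == "F0"
                apair = (
                    np.full(spec.n_markers, tag0, dtype=bool),
                    np.zeros(spec.n_markers, dtype=bool),
                )
                h[iid], a[iid] = pair, apair
                continue
            gametes = []
            for parent in (ind.father_id, ind.mother_id):
                conditioned = on_implant_chrom and (parent, iid) in tag_edges
                for attempt in range(_MAX_CONDITION_ATTEMPTS):
                    allele, ancestry = _gamete(rng, h[parent], a[parent], cm)
                    if not conditioned or ancestry[cond_local_idx].all():
                        break
                else:
                    raise HHMapError(
                        f"could not condition transmission {parent}->{iid} on the implant"
                    )
                gametes.append((allele, ancestry))
            h[iid] = (gametes[0][0], gametes[1][0])
            a[iid] = (gametes[0][1], gametes[1][1])
        haps[chrom], ancs[chrom] = h, a

    # genotypes
    calls = np.empty((len(order), panel.n_markers), dtype=np.int8)
    for i, iid in enumerate(order):
        for spec in config.chromosomes:
            sl = panel.chrom_slice(spec.name)
            h0, h1 = haps[spec.name][iid]
            calls[i, sl] = (h0 + h1).astype(np.int8)
    if config.epsilon > 0:
        err = rng.random(calls.shape) < config.epsilon
        shift = rng.integers(1, 3, size=calls.shape, dtype=np.int8)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = Call.MISSING.value

    matrix = GenotypeMatrix(panel, order, calls)

    implant_global = implant_local_idx + implant_sl.start
    s_idx, e_idx = int(implant_global[0]), int(implant_global[-1])
    carrier_flags = {}
    a_impl = ancs[config.implant.chrom]
    for iid in order:
        a0, a1 = a_impl[iid]
        carrier_flags[iid] = bool(
            a0[implant_local_idx].all() or a1[implant_local_idx].all()
        )
    truth = SimulatedTruth(
        implant_chrom=config.implant.chrom,
        implant_start_idx=s_idx,
        implant_end_idx=e_idx,
        implant_start_bp=int(panel.bp[s_idx]),
        implant_end_bp=int(panel.bp[e_idx]),
        implant_start_cm=float(cm_all[s_idx]),
        implant_end_cm=float(cm_all[e_idx]),
        carrier_flags=carrier_flags,
    )
    return panel, matrix, pedigree, truth


# child call compatibility lookup: axes are father, mother, child (call + 1)
def _mendel_table() -> np.ndarray:
    allele_sets = {
        Call.MISSING.value: (0, 1),
        Call.HOM_REF.value: (0,),
        Call.HET.value: (0, 1),
        Call.HOM_ALT.value: (1,),
    }
    table = np.zeros((4, 4, 4), dtype=bool)
    for f, fa in allele_sets.items():
        for m, ma in allele_sets.items():
            table[f + 1, m + 1, Call.MISSING.value + 1] = True
            for x in fa:
                for y in ma:
                    table[f + 1, m + 1, x + y + 1] = True
    return table


_MENDEL = _mendel_table()


def mendelian_check(
    matrix: GenotypeMatrix, pedigree: Pedigree
) -> list[tuple[str, int]]:
    """(individual, marker index) pairs incompatible with the parents.

    Missing calls (child or parent) are always compatible. Individuals
    whose parents are absent from the matrix are skipped.
    """
    violations: list[tuple[str, int]] = []
    for ind in pedigree:
        if ind.individual_id not in matrix:
            continue
        if ind.father_id is None or ind.mother_id is None:
            continue
        if ind.father_id not in matrix or ind.mother_id not in matrix:
            continue
        f = matrix.row(ind.father_id).astype(np.intp) + 1
        m = matrix.row(ind.mother_id).astype(np.intp) + 1
        c = matrix.row(ind.individual_id).astype(np.intp) + 1
        bad = np.flatnonzero(~_MENDEL[f, m, c])
        violations.extend((ind.individual_id, int(j)) for j in bad)
    return violations


def simulate_variant_table(
    config: SimulationConfig,
    truth: SimulatedTruth,
    pedigree: Pedigree,
) -> list[VariantRecord]:
    """Annotated variant table: one causal record plus stratified noise.

    The causal record sits inside the implant, has unknown MAFs, a
    filter-passing functional class, and is carried exactly by the tagged
    founder-haplotype carriers. Each noise record independently falls in the
    filter-passing stratum with probability ``pass_fraction``.
    """
    spec = config.variant_spec
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    samples = [i.individual_id for i in pedigree if i.genotyped]
    chrom_len = {c.name: c.length_cm for c in config.chromosomes}

    def carriers_random() -> dict[str, CarrierState]:
        draws = rng.random(len(samples)) < spec.carrier_rate
        return {
            s: CarrierState.CARRIER if d else CarrierState.NON_CARRIER
            for s, d in zip(samples, draws)
        }

    causal_bp = (truth.implant_start_bp + truth.implant_end_bp) // 2
    records = [
        VariantRecord(
            chrom=truth.implant_chrom,
            start=causal_bp,
            end=causal_bp,
            ref="A",
            alt="C",
            gene="SIMGENE_CAUSAL",
            function_class=classify_function(spec.causal_function),
            function_label=spec.causal_function,
            maf_1000g=None,
            maf_gnomad=None,
            pathogenicity_label=None,
            carriers={
                s: CarrierState.CARRIER
                if truth.carrier_flags.get(s, False)
                else CarrierState.NON_CARRIER
                for s in samples
            },
            genome_build=config.genome_build,
        )
    ]
    chrom_names = list(chrom_len)
    for _ in range(spec.n_noise_variants):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        bp = int(rng.integers(1, max(2, int(chrom_len[chrom] * 1e6))))
        passing = rng.random() < spec.pass_fraction
        label, maf1, maf2, patho = "nonsynonymous SNV", None, None, None
        if passing:
            if rng.random() < 0.5:
                maf1 = float(rng.uniform(0.0, 0.0009))
            if rng.random() < 0.5:
                maf2 = float(rng.uniform(0.0, 0.0009))
        else:
            mode = int(rng.integers(3))
            if mode == 0:
                label = "synonymous SNV"
            elif mode == 1:
                patho = "benign"
            else:
                maf1 = float(rng.uniform(0.001, 0.5))
        records.append(
            VariantRecord(
                chrom=chrom,
                start=bp,
                end=bp,
                ref="A",
                alt="G",
                gene=f"GENE_{chrom}_{bp // 2_000_000}",
                function_class=classify_function(label),
                function_label=label,
                maf_1000g=maf1,
                maf_gnomad=maf2,
                pathogenicity_label=patho,
                carriers=carriers_random(),
                genome_build=config.genome_build,
            )
        )
    return records
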