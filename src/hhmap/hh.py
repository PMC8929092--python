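"""Homozygosity-haplotype engine.

Stage one of the pipeline: reduce genotypes to homozygous-only haplotypes,
detect regions of conserved homozygosity between pairs of individuals
(bounded by discordant homozygous markers, dhSNPs), pick per-window
representative regions maximally shared within a family's patient pool,
attach a pooled two-proportion statistic against the control pool, and
quantify robustness to genotyping error by seeded Monte-Carlo simulation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .model import Call, GenotypeMatrix, HHMapError, Pedigree

__all__ = [
    "HomozygosityHaplotype",
    "PairwiseRCHH",
    "RepresentativeRCHH",
    "ReliabilityResult",
    "build_hh",
    "find_dhsnps",
    "pairwise_rchh",
    "shared_rchh_scan",
    "pool_comparison_test",
    "significant_rchhs",
    "genotyping_error_reliability",
    "rca_expected_length",
]

_HOM = (Call.HOM_REF.value, Call.HOM_ALT.value)


@dataclass
class HomozygosityHaplotype:
    """Genotypes of one individual reduced to homozygous markers only.

    ``indices[chrom]`` holds global marker indices (strictly increasing);
    ``alleles[chrom]`` the homozygous allele character at each of them.
    """

    individual_id: str
    indices: dict[str, np.ndarray]
    alleles: dict[str, np.ndarray]

    def n_markers(self, chromosome: Optional[str] = None) -> int:
        if chromosome is not None:
            return len(self.indices.get(chromosome, ()))
        return sum(len(v) for v in self.indices.values())


@dataclass
class PairwiseRCHH:
    """Maximal dhSNP-free interval shared by a pair, trimmed to compSNPs."""

    pair: tuple[str, str]
    chrom: str
    start_idx: int  # global marker indices, inclusive
    end_idx: int
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    n_compsnp: int

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class RepresentativeRCHH:
    """Per-window representative region with pool-sharing statistics."""

    family_id: str
    chrom: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    start_marker: str
    end_marker: str
    length_cm: float
    patient_sharers: tuple[str, ...]
    k1: int
    n1: int
    k2: int
    n2: int
    z: Optional[float] = None
    p_value: Optional[float] = None
    neg_log10_p: Optional[float] = None


@dataclass
class ReliabilityResult:
    """Monte-Carlo estimate of error-induced dhSNP creation in a region."""

    chrom: str
    start_idx: int
    end_idx: int
    epsilon: float
    n_reps: int
    probability: float
    reliable: bool
    seed: int


def build_hh(matrix: GenotypeMatrix, individual_id: str) -> HomozygosityHaplotype:
    """Reduce an individual's genotypes to the homozygous markers only.

    Heterozygous and missing calls are dropped; marker order is preserved.
    """
    calls = matrix.row(individual_id)  # KeyError for unknown ids
    panel = matrix.panel
    indices: dict[str, np.ndarray] = {}
    alleles: dict[str, np.ndarray] = {}
    a1 = panel.markers["a1"].to_numpy()
    a2 = panel.markers["a2"].to_numpy()
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        c = calls[sl]
        hom = (c == Call.HOM_REF.value) | (c == Call.HOM_ALT.value)
        idx = np.flatnonzero(hom) + sl.start
        indices[chrom] = idx
        alleles[chrom] = np.where(
            calls[idx] == Call.HOM_REF.value, a1[idx], a2[idx]
        ).astype("<U8")
    return HomozygosityHaplotype(individual_id, indices, alleles)


def _dh_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean mask of discordant homozygous calls (AA vs BB)."""
    return ((a == Call.HOM_REF.value) & (b == Call.HOM_ALT.value)) | (
        (a == Call.HOM_ALT.value) & (b == Call.HOM_REF.value)
    )


def _comp_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean mask of compSNPs: homozygous non-missing in both members."""
    hom_a = (a == Call.HOM_REF.value) | (a == Call.HOM_ALT.value)
    hom_b = (b == Call.HOM_REF.value) | (b == Call.HOM_ALT.value)
    return hom_a & hom_b


def find_dhsnps(
    matrix: GenotypeMatrix, id_a: str, id_b: str, chromosome: str
) -> np.ndarray:
    """Global indices of markers where the pair is discordantly homozygous.

    Symmetric in ``(id_a, id_b)``; missing or heterozygous calls never
    contribute.
    """
    sl = matrix.panel.chrom_slice(chromosome)
    a = matrix.row(id_a)[sl]
    b = matrix.row(id_b)[sl]
    return np.flatnonzero(_dh_mask(a, b)) + sl.start


def pairwise_rchh(
    matrix: GenotypeMatrix,
    id_a: str,
    id_b: str,
    cutoff_cm: float,
    chromosomes: Optional[Sequence[str]] = None,
) -> list[PairwiseRCHH]:
    """Regions of conserved homozygosity between two individuals.

    Per chromosome, the maximal intervals between consecutive dhSNPs (or the
    chromosome ends) are trimmed to their outermost compSNPs; intervals whose
    genetic length is at least ``cutoff_cm`` are returned, disjoint and in
    panel order.
    """
    if cutoff_cm <= 0:
        raise HHMapError(f"cutoff_cm must be positive, got {cutoff_cm}")
    panel = matrix.panel
    bp, cm, ids = panel.bp, panel.cm, panel.marker_id
    pair = (id_a, id_b)
    out: list[PairwiseRCHH] = []
    for chrom in chromosomes if chromosomes is not None else panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        a = matrix.row(id_a)[sl]
        b = matrix.row(id_b)[sl]
        dh = np.flatnonzero(_dh_mask(a, b))
        comp = _comp_mask(a, b)
        comp_idx = np.flatnonzero(comp)
        # segment boundaries: chromosome ends and dhSNP positions
        bounds = np.r_[-1, dh, len(a)]
        for lo, hi in zip(bounds[:-1] + 1, bounds[1:]):  # [lo, hi) dhSNP-free
            if hi <= lo:
                continue
            inside = comp_idx[(comp_idx >= lo) & (comp_idx < hi)]
            if inside.size == 0:
                continue
            s, e = int(inside[0]) + sl.start, int(inside[-1]) + sl.start
            if cm[e] - cm[s] < cutoff_cm:
                continue
            out.append(
                PairwiseRCHH(
                    pair=pair,
                    chrom=chrom,
                    start_idx=s,
                    end_idx=e,
                    start_bp=int(bp[s]),
                    end_bp=int(bp[e]),
                    start_cm=float(cm[s]),
                    end_cm=float(cm[e]),
                    n_compsnp=int(inside.size),
                )
            )
    return out


def pool_comparison_test(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, float, float]:
    """Pooled two-proportion z-test of patient vs control sharing.

    One-sided, upper tail (patients sharing more). With pooled proportion
    0 or 1 there is no evidence either way: returns ``(0, 0.5, -log10 0.5)``.
    """
    if n1 < 1 or n2 < 1:
        raise HHMapError(f"pool sizes must be >= 1, got n1={n1}, n2={n2}")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise HHMapError(f"counts out of range: {k1}/{n1}, {k2}/{n2}")
    p_hat = (k1 + k2) / (n1 + n2)
    if p_hat in (0.0, 1.0):
        return 0.0, 0.5, -math.log10(0.5)
    se = math.sqrt(p_hat * (1.0 - p_hat) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = float(norm.sf(z))
    return z, p, -math.log10(p)


def significant_rchhs(
    representatives: Sequence[RepresentativeRCHH], threshold_neg_log10: float
) -> list[RepresentativeRCHH]:
    """Keep representatives with ``neg_log10_p >= threshold``.

    No multiple-testing adjustment: this is a deliberately liberal
    first-stage screen. Rows without a p-value (empty control pool) drop.
    """
    if threshold_neg_log10 < 0:
        raise HHMapError("threshold must be >= 0")
    return [
        r
        for r in representatives
        if r.neg_log10_p is not None and r.neg_log10_p >= threshold_neg_log10
    ]


def _pair_dh_positions(
    matrix: GenotypeMatrix, cache: dict, a: str, b: str, chrom: str
) -> np.ndarray:
    key = (min(a, b), max(a, b), chrom)
    if key not in cache:
        cache[key] = find_dhsnps(matrix, key[0], key[1], chrom)
    return cache[key]


def _dh_count_in(positions: np.ndarray, start_idx: int, end_idx: int) -> int:
    lo = np.searchsorted(positions, start_idx, side="left")
    hi = np.searchsorted(positions, end_idx, side="right")
    return int(hi - lo)


def _interval_around(
    positions: np.ndarray, mid_idx: int, lo_bound: int, hi_bound: int
) -> Optional[tuple[int, int]]:
    """Maximal interval containing ``mid_idx`` with no position from
    ``positions`` inside, clipped to ``[lo_bound, hi_bound]``; None when a
    position sits exactly at ``mid_idx``."""
    pos = int(np.searchsorted(positions, mid_idx, side="left"))
    if pos < len(positions) and positions[pos] == mid_idx:
        return None
    lo = int(positions[pos - 1]) + 1 if pos > 0 else lo_bound
    hi = int(positions[pos]) - 1 if pos < len(positions) else hi_bound
    return max(lo, lo_bound), min(hi, hi_bound)


def shared_rchh_scan(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    family_id: str,
    cutoff_cm: float = 7.0,
    window_cm: float = 1.0,
) -> list[RepresentativeRCHH]:
    """Family-level scan for representative shared regions.

    Each chromosome is partitioned into ``window_cm`` windows. Per window,
    the patient pair whose dhSNP-free interval around the window midpoint is
    longest (and >= ``cutoff_cm``) seeds a greedy sharing set: candidate
    patients join one at a time, each addition shrinking the interval to the
    largest sub-interval around the midpoint free of dhSNPs for every member
    pair, as long as it stays >= ``cutoff_cm`` (additions maximizing the
    remaining length, ties by id). This generalizes the pairwise region
    definition to multiple subjects: with |S| = 2 the interval is exactly
    the pairwise region covering the window. The final interval is trimmed
    to the outermost markers homozygous in at least two members. Control
    sharers are counted on the same interval (zero dhSNPs against every
    patient sharer) and the pooled proportion test is attached. Adjacent
    windows with an identical representative collapse into one row.
    """
    patients = pedigree.genotyped_affected(family_id)
    controls = pedigree.genotyped_unaffected(family_id)
    if len(patients) < 2:
        raise HHMapError(
            f"family {family_id!r} has {len(patients)} genotyped affected; need >= 2"
        )
    for sid in patients + controls:
        if sid not in matrix:
            raise HHMapError(f"family {family_id!r}: sample {sid!r} not in matrix")
    panel = matrix.panel
    cm = panel.cm
    cache: dict = {}
    pairs = list(combinations(patients, 2))

    results: list[RepresentativeRCHH] = []
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        if sl.stop - sl.start < 2:
            continue
        cm_lo, cm_hi = float(cm[sl.start]), float(cm[sl.stop - 1])
        n_windows = max(1, math.ceil((cm_hi - cm_lo) / window_cm)) if cm_hi > cm_lo else 1
        pair_dh = {
            (a, b): _pair_dh_positions(matrix, cache, a, b, chrom) for a, b in pairs
        }
        # markers homozygous per patient, for compSNP trimming
        hom = {
            p: ((matrix.row(p)[sl] == Call.HOM_REF.value)
                | (matrix.row(p)[sl] == Call.HOM_ALT.value))
            for p in patients
        }
        chrom_reps: list[RepresentativeRCHH] = []
        for w in range(n_windows):
            w0 = cm_lo + w * window_cm
            w1 = min(cm_lo + (w + 1) * window_cm, cm_hi)
            mid_cm = (w0 + w1) / 2.0
            mid_idx = sl.start + int(
                np.searchsorted(cm[sl], mid_cm, side="left").clip(0, sl.stop - sl.start - 1)
            )
            # seed: pair with the longest clean interval around the midpoint
            seed = None
            for a, b in pairs:
                iv = _interval_around(pair_dh[(a, b)], mid_idx, sl.start, sl.stop - 1)
                if iv is None:
                    continue
                length = cm[iv[1]] - cm[iv[0]]
                if length < cutoff_cm:
                    continue
                if seed is None or length > seed[0]:
                    seed = (length, (a, b), iv)
            if seed is None:
                continue
            members = list(seed[1])
            lo, hi = seed[2]
            remaining = [p for p in patients if p not in members]
            while remaining:
                best = None
                for cand in remaining:
                    c_lo, c_hi = lo, hi
                    ok = True
                    for m in members:
                        key = (min(cand, m), max(cand, m))
                        iv = _interval_around(
                            pair_dh.get(key)
                            if key in pair_dh
                            else _pair_dh_positions(matrix, cache, *key, chrom),
                            mid_idx,
                            sl.start,
                            sl.stop - 1,
                        )
                        if iv is None:
                            ok = False
                            break
                        c_lo, c_hi = max(c_lo, iv[0]), min(c_hi, iv[1])
                    if not ok or c_hi < c_lo:
                        continue
                    length = cm[c_hi] - cm[c_lo]
                    if length < cutoff_cm:
                        continue
                    if best is None or length > best[0] or (
                        length == best[0] and cand < best[1]
                    ):
                        best = (length, cand, (c_lo, c_hi))
                if best is None:
                    break
                members.append(best[1])
                remaining.remove(best[1])
                lo, hi = best[2]
            # trim to outermost markers homozygous in >= 2 members
            hom_count = np.zeros(hi - lo + 1, dtype=np.int16)
            for p in members:
                hom_count += hom[p][lo - sl.start : hi - sl.start + 1]
            comp_pos = np.flatnonzero(hom_count >= 2)
            if comp_pos.size == 0:
                continue
            t_lo, t_hi = lo + int(comp_pos[0]), lo + int(comp_pos[-1])
            if cm[t_hi] - cm[t_lo] < cutoff_cm:
                continue
            sharers = tuple(sorted(members))
            prev = chrom_reps[-1] if chrom_reps else None
            if prev is not None and (prev.start_idx, prev.end_idx) == (t_lo, t_hi) and (
                prev.patient_sharers == sharers
            ):
                continue  # collapse identical representative of adjacent window
            k2 = 0
            for c in controls:
                if all(
                    _dh_count_in(
                        _pair_dh_positions(matrix, cache, c, p, chrom), t_lo, t_hi
                    )
                    == 0
                    for p in sharers
                ):
                    k2 += 1
            rep = RepresentativeRCHH(
                family_id=family_id,
                chrom=chrom,
                start_idx=t_lo,
                end_idx=t_hi,
                start_bp=int(panel.bp[t_lo]),
                end_bp=int(panel.bp[t_hi]),
                start_marker=str(panel.marker_id[t_lo]),
                end_marker=str(panel.marker_id[t_hi]),
                length_cm=float(cm[t_hi] - cm[t_lo]),
                patient_sharers=sharers,
                k1=len(sharers),
                n1=len(patients),
                k2=k2,
                n2=len(controls),
            )
            if controls:
                rep.z, rep.p_value, rep.neg_log10_p = pool_comparison_test(
                    rep.k1, rep.n1, rep.k2, rep.n2
                )
            chrom_reps.append(rep)
        results.extend(chrom_reps)
    results.sort(key=lambda r: (panel.chrom_slice(r.chrom).start, r.start_idx))
    return results


def genotyping_error_reliability(
    matrix: GenotypeMatrix,
    interval,
    pool_ids: Sequence[str],
    epsilon: float,
    n_reps: int = 100_000,
    seed: int = 0,
) -> ReliabilityResult:
    """Probability that genotyping error alone creates a dhSNP in a region.

    Per replicate, every non-missing call in the interval for the pooled
    individuals is independently replaced, with probability ``epsilon``, by
    one of the other two genotype states (uniformly). The estimate is the
    fraction of replicates in which at least one pool pair that previously
    had no dhSNP in the interval gains one. The result is reliable when the
    estimate is below 0.001.

    ``interval`` is ``(chrom, start_idx, end_idx)`` with global marker
    indices (inclusive), or any object with those attributes.
    """
    if not (0.0 <= epsilon <= 1.0):
        raise HHMapError(f"epsilon must be in [0, 1], got {epsilon}")
    if n_reps < 1:
        raise HHMapError("n_reps must be >= 1")
    if hasattr(interval, "start_idx"):
        chrom, s, e = interval.chrom, interval.start_idx, interval.end_idx
    else:
        chrom, s, e = interval
    if e < s:
        raise HHMapError("interval contains no marker")
    rows = np.stack([matrix.row(i)[s : e + 1] for i in pool_ids])
    n_pool, n_markers = rows.shape
    pairs = [
        (i, j)
        for i, j in combinations(range(n_pool), 2)
        if not _dh_mask(rows[i], rows[j]).any()
    ]
    if epsilon == 0.0 or not pairs:
        return ReliabilityResult(
            str(chrom), int(s), int(e), epsilon, n_reps, 0.0, True, seed
        )
    rng = np.random.default_rng(seed)
    not_missing = rows != Call.MISSING.value
    hits = 0
    chunk = max(1, int(4_000_000 // max(1, n_pool * n_markers)))
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        err = (rng.random((b, n_pool, n_markers)) < epsilon) & not_missing
        shift = rng.integers(1, 3, size=(b, n_pool, n_markers), dtype=np.int8)
        perturbed = np.where(err, (rows + shift) % 3, rows)
        event = np.zeros(b, dtype=bool)
        for i, j in pairs:
            event |= _dh_mask(perturbed[:, i, :], perturbed[:, j, :]).any(axis=1)
        hits += int(event.sum())
        done += b
    prob = hits / n_reps
    return ReliabilityResult(
        str(chrom), int(s), int(e), epsilon, n_reps, prob, prob < 0.001, seed
    )


def rca_expected_length(m: int, n: int) -> float:
    """Expected length (Morgans) of the ancestral region shared by two
    subjects ``m`` and ``n`` generations below their common ancestor.

    Piecewise: ``2**(-m+1)`` when ``n == 0``; ``3/4`` when ``m == n == 1``;
    ``2**(-m-n+2)`` otherwise. Requires ``m >= n >= 0`` and ``m >= 1``.
    """
    if not (isinstance(m, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise HHMapError("m and n must be integers")
    if n > m:
        raise HHMapError(f"requires m >= n, got m={m}, n={n}")
    if m < 1 or n < 0:
        raise HHMapError(f"requires m >= 1 and n >= 0, got m={m}, n={n}")
    if n == 0:
        return float(2.0 ** (-m + 1))
    if m == 1 and n == 1:
        return 0.75
    return float(2.0 ** (-m - n + 2))
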