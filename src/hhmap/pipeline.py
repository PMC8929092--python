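"""Two-stage pipeline orchestration and report generation.

Stage one scans each selected family for representative shared regions and
filters them by significance; each surviving region gets a Monte-Carlo
genotyping-error reliability estimate. Stage two prioritizes rare variants
inside the significant regions and summarizes between-family gene overlap.
Reports are deterministic TSVs; the run log carries timestamps, config,
seeds and versions.
"""
from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .fixtures import load_fixtures
from .hh import (
    RepresentativeRCHH,
    genotyping_error_reliability,
    shared_rchh_scan,
    significant_rchhs,
)
from .io import (
    read_ped_map,
    read_variant_table,
    variant_table_samples,
    write_ped_map,
    write_variant_table,
)
from .model import GenotypeMatrix, HHMapError, MarkerPanel, Pedigree
from .simulate import SimulationConfig, simulate_cohort, simulate_variant_table
from .variants import (
    PrioritizedVariant,
    family_gene_sets,
    gene_overlap,
    prioritize,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "fixture_report",
    "format_rep_row",
    "write_scan_report",
    "write_variant_report",
    "write_overlap_report",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults follow the study)."""

    out_dir: Path = Path("hhmap_out")
    ped_path: Optional[Path] = None
    map_path: Optional[Path] = None
    variants_csv: Optional[Path] = None
    simulation: Optional[SimulationConfig] = None
    families: Optional[list[str]] = None  # None: every eligible family
    cutoff_cm: float = 7.0
    window_cm: float = 1.0
    neg_log10_threshold: float = 1.2
    epsilon: float = 0.001
    reliability_reps: int = 100_000
    seed: int = 0
    min_affected_fraction: Optional[float] = None
    genome_build: str = "unknown"

    def __post_init__(self) -> None:
        if self.cutoff_cm <= 0 or self.window_cm <= 0:
            raise HHMapError("cutoff_cm and window_cm must be positive")
        if self.neg_log10_threshold < 0:
            raise HHMapError("neg_log10_threshold must be >= 0")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items()})
        if sim is not None:
            cfg.simulation = _sim_config_from_dict(sim)
        return cfg


def _sim_config_from_dict(raw: dict) -> SimulationConfig:
    from .simulate import ChromosomeSpec, ImplantSpec, VariantTableSpec

    kwargs = dict(raw)
    if "chromosomes" in kwargs:
        kwargs["chromosomes"] = tuple(
            ChromosomeSpec(str(c["name"]), float(c["length_cm"]), int(c["n_markers"]))
            for c in kwargs["chromosomes"]
        )
    if "implant" in kwargs:
        imp = dict(kwargs["implant"])
        if imp.get("carrier_ids") is not None:
            imp["carrier_ids"] = tuple(imp["carrier_ids"])
        kwargs["implant"] = ImplantSpec(**imp)
    if "variant_spec" in kwargs:
        kwargs["variant_spec"] = VariantTableSpec(**kwargs["variant_spec"])
    if "maf_range" in kwargs:
        kwargs["maf_range"] = tuple(kwargs["maf_range"])
    return SimulationConfig(**kwargs)


def _fmt_p(x: Optional[float]) -> str:
    return "NA" if x is None else f"{x:.4g}"


def format_rep_row(rep: RepresentativeRCHH) -> list[str]:
    control = f"{rep.k2} out of {rep.n2}" if rep.n2 > 0 else "NA"
    return [
        rep.family_id,
        f"{rep.k1} out of {rep.n1}",
        control,
        rep.chrom,
        f"{rep.start_bp}-{rep.end_bp}",
        f"{rep.start_marker}-{rep.end_marker}",
        _fmt_p(rep.neg_log10_p),
    ]


def write_scan_report(reps: Sequence[RepresentativeRCHH], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "family\tpatient_share\tcontrol_share\tchr\tbp_range\tsnp_range\tneg_log10_p\n"
        )
        for rep in reps:
            fh.write("\t".join(format_rep_row(rep)) + "\n")
    return path


def write_variant_report(variants: Sequence[PrioritizedVariant], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "family\trchh_region\tchr\tstart\tend\tref\talt\tfunction\tgene\t"
            "affected\tunaffected\n"
        )
        for pv in variants:
            rec = pv.record
            unaff = (
                f"{pv.unaffected_carriers[0]} out of {pv.unaffected_carriers[1]}"
                if pv.unaffected_carriers is not None
                else "NA"
            )
            fh.write(
                "\t".join(
                    [
                        pv.family_id,
                        f"chr{pv.region_chrom}:{pv.region_start}-{pv.region_end}",
                        rec.chrom,
                        str(rec.start),
                        str(rec.end),
                        rec.ref,
                        rec.alt,
                        rec.function_label or rec.function_class.value,
                        rec.gene,
                        f"{pv.affected_carriers[0]} out of {pv.affected_carriers[1]}",
                        unaff,
                    ]
                )
                + "\n"
            )
    return path


def write_overlap_report(counts: dict, path) -> Path:
    """Upset-style TSV: family subset -> exclusive gene count."""
    path = Path(path)
    rows = sorted(
        ((sorted(k), v) for k, v in counts.items()),
        key=lambda kv: (len(kv[0]), kv[0]),
    )
    with open(path, "w") as fh:
        fh.write("families\tn_genes\n")
        for fams, count in rows:
            fh.write(f"{','.join(fams)}\t{count}\n")
    return path


@dataclass
class PipelineResult:
    out_dir: Path
    representatives: dict[str, list[RepresentativeRCHH]]
    significant: dict[str, list[RepresentativeRCHH]]
    prioritized: dict[str, list[PrioritizedVariant]]
    overlap: Optional[dict]
    reports: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute scan -> significance filter -> reliability -> variant
    prioritization -> overlap summary, writing all reports and a run log."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        log_lines.append(f"{stamp}\t{msg}")

    log(f"hhmap {__version__} starting; seed={config.seed}")
    log(f"config: {json.dumps(_config_dict(config), default=str, sort_keys=True)}")

    stage = "input"
    try:
        if config.simulation is not None:
            panel, matrix, pedigree, truth = simulate_cohort(config.simulation)
            records = simulate_variant_table(config.simulation, truth, pedigree)
            write_ped_map(panel, matrix, pedigree, out / "cohort")
            samples = [i.individual_id for i in pedigree if i.genotyped]
            write_variant_table(records, samples, out / "variants.csv")
            with open(out / "truth.json", "w") as fh:
                json.dump(dataclasses.asdict(truth), fh, indent=1, sort_keys=True)
            log(
                "simulated cohort: "
                f"implant {truth.implant_chrom}:{truth.implant_start_bp}-{truth.implant_end_bp}"
            )
        elif config.ped_path and config.map_path:
            panel, matrix, pedigree = read_ped_map(
                config.ped_path, config.map_path, genome_build=config.genome_build
            )
            if config.variants_csv:
                # the CSV may cover only the sequenced subset of the cohort
                sequenced = set(variant_table_samples(config.variants_csv))
                samples = [
                    i.individual_id for i in pedigree if i.individual_id in sequenced
                ]
                records = read_variant_table(
                    config.variants_csv, samples, genome_build=config.genome_build
                )
            else:
                records = []
        else:
            raise HHMapError("need either simulation config or ped/map paths")

        if config.families is not None:
            families = list(config.families)
        else:
            families = [
                f
                for f in pedigree.family_ids
                if len(pedigree.genotyped_affected(f)) >= 2
            ]
        if not families:
            raise HHMapError("no families selected")

        reps_by_family: dict[str, list[RepresentativeRCHH]] = {}
        sig_by_family: dict[str, list[RepresentativeRCHH]] = {}
        all_reps: list[RepresentativeRCHH] = []
        all_sig: list[RepresentativeRCHH] = []
        for fam in families:
            stage = f"scan family {fam}"
            reps = shared_rchh_scan(
                matrix, pedigree, fam, config.cutoff_cm, config.window_cm
            )
            sig = significant_rchhs(reps, config.neg_log10_threshold)
            reps_by_family[fam] = reps
            sig_by_family[fam] = sig
            all_reps.extend(reps)
            all_sig.extend(sig)
            log(f"family {fam}: {len(reps)} representatives, {len(sig)} significant")

        reliability_rows = []
        for i, rep in enumerate(all_sig):
            stage = f"reliability {rep.family_id} {rep.chrom}:{rep.start_bp}-{rep.end_bp}"
            rel_seed = config.seed * 100_003 + i
            rel = genotyping_error_reliability(
                matrix,
                rep,
                list(rep.patient_sharers),
                config.epsilon,
                config.reliability_reps,
                seed=rel_seed,
            )
            reliability_rows.append((rep, rel))
            log(
                f"reliability {rep.family_id} {rep.chrom}:{rep.start_bp}-{rep.end_bp} "
                f"epsilon={rel.epsilon} seed={rel_seed} prob={rel.probability:.6g} "
                f"reliable={rel.reliable}"
            )

        prioritized: dict[str, list[PrioritizedVariant]] = {}
        overlap_counts = None
        if records:
            records_by_family = {}
            for fam in families:
                stage = f"variants family {fam}"
                fam_records = _family_records(records, pedigree, fam)
                records_by_family[fam] = fam_records
                if sig_by_family[fam] and fam_records:
                    prioritized[fam] = prioritize(
                        fam_records,
                        sig_by_family[fam],
                        pedigree,
                        fam,
                        min_affected_fraction=config.min_affected_fraction,
                    )
                else:
                    prioritized[fam] = []
            stage = "gene overlap"
            gene_sets = family_gene_sets(records_by_family, sig_by_family)
            if gene_sets:
                overlap_counts = gene_overlap(gene_sets)
    except HHMapError as exc:
        raise HHMapError(f"stage '{stage}': {exc}") from exc

    reports = {
        "scan": write_scan_report(all_reps, out / "scan_report.tsv"),
        "significant": write_scan_report(all_sig, out / "significant_regions.tsv"),
    }
    with open(out / "reliability.tsv", "w") as fh:
        fh.write("family\tchr\tstart_bp\tend_bp\tepsilon\tn_reps\tprobability\treliable\n")
        for rep, rel in reliability_rows:
            fh.write(
                f"{rep.family_id}\t{rep.chrom}\t{rep.start_bp}\t{rep.end_bp}\t"
                f"{rel.epsilon:g}\t{rel.n_reps}\t{rel.probability:.6g}\t{rel.reliable}\n"
            )
    reports["reliability"] = out / "reliability.tsv"
    flat = [pv for fam in sorted(prioritized) for pv in prioritized[fam]]
    reports["variants"] = write_variant_report(flat, out / "variant_report.tsv")
    if overlap_counts is not None:
        reports["overlap"] = write_overlap_report(overlap_counts, out / "gene_overlap.tsv")
    log("pipeline finished")
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    reports["log"] = out / "run.log"
    return PipelineResult(
        out_dir=out,
        representatives=reps_by_family,
        significant=sig_by_family,
        prioritized=prioritized,
        overlap=overlap_counts,
        reports=reports,
    )


def _family_records(records, pedigree: Pedigree, family_id: str):
    member_ids = {i.individual_id for i in pedigree.members(family_id)}
    out = []
    for rec in records:
        if any(s in member_ids for s in rec.carriers):
            out.append(rec)
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def fixture_report() -> dict:
    """Summary statistics of the packaged tables (the acceptance surface)."""
    fx = load_fixtures()
    t1, t2, t3 = fx.table1, fx.table2, fx.table3
    per_family_rows = t2.groupby("family", sort=False).size().to_dict()
    return {
        "n_families": int(len(t1)),
        "total_affected": int(t1["total_affected"].sum()),
        "total_unaffected": int(t1["total_unaffected"].sum()),
        "genotyped_affected": int(t1["genotyped_affected"].sum()),
        "genotyped_unaffected": int(t1["genotyped_unaffected"].sum()),
        "n_rchh_rows": int(len(t2)),
        "rchh_rows_per_family": {str(k): int(v) for k, v in per_family_rows.items()},
        "max_neg_log10_p": float(t2["neg_log10_p"].max()),
        "min_neg_log10_p": float(t2["neg_log10_p"].min()),
        "n_variants": int(len(t3)),
        "n_build_warnings": len(fx.build_warnings),
    }
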