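"""Pipeline orchestration: configuration, stage ordering, combined report.

Stages run in dependency order — partition feeds capture-recapture;
saturation, variants, SSR and the gene screens are independent. Every
number in the combined report is taken verbatim from the stage that
produced it; nothing is recomputed at report time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

from . import capture_recapture, library_partition, saturation, ssr_scan, variant_stats
from .io_formats import (
    read_assignments,
    read_fasta,
    read_hits_tabular,
    read_orf_table,
    read_vcf_minimal,
    write_vcf_minimal,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "assembly_summary",
    "percent_reduction",
    "setup_logging",
]

log = logging.getLogger("transcensus")


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("transcensus")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


@dataclass
class RunConfig:
    """Flat key=value configuration; defaults are the published settings."""

    # inputs
    contigs: str = ""
    assignments: str = ""
    cross_hits: str = ""
    ref_hits_a: str = ""
    ref_hits_b: str = ""
    contig_ref_hits: str = ""
    vcf: str = ""
    orfs: str = ""
    # stage toggles
    run_partition: bool = True
    run_capture: bool = True
    run_saturation: bool = True
    run_variants: bool = True
    run_ssr: bool = True
    # thresholds (defaults = published settings)
    direct_min_cov: float = 0.80
    direct_max_e: float = 1e-50
    indirect_max_e: float = 1e-06
    indirect_min_cov: float = 0.80
    screen_max_e: float = 1e-03
    screen_min_positives: int = 50
    mt_max_e: float = 1e-10
    repeat_min_units: int = 4
    repeat_proximity: int = 1
    ssr_thresholds: str = "2:6,3:4,4:4,5:4,6:4"
    rarefaction_sizes: int = 20
    rarefaction_replicates: int = 10
    # misc
    seed: int = 0
    log_level: str = "INFO"
    outdir: str = "transcensus_out"

    def parsed_ssr_thresholds(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for part in self.ssr_thresholds.split(","):
            k, v = part.split(":")
            out[int(k)] = int(v)
        return out

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("["):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not hasattr(defaults, key):
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in {"1", "true", "yes"}
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _validate(config: RunConfig) -> None:
    """Dry validation pass: every enabled stage must have its inputs."""
    missing: list[str] = []

    def need(path: str, what: str) -> None:
        if not path:
            missing.append(f"{what}: no path configured")
        elif not Path(path).exists():
            missing.append(f"{what}: {path} does not exist")

    if config.run_partition or config.run_capture:
        need(config.contigs, "contigs FASTA")
        need(config.assignments, "read assignments TSV")
    if config.run_saturation:
        need(config.assignments, "read assignments TSV")
        need(config.contig_ref_hits, "contig->reference map TSV")
    if config.run_variants:
        need(config.vcf, "variant VCF")
        need(config.contigs, "contigs FASTA")
        need(config.orfs, "ORF table TSV")
    if config.run_ssr:
        need(config.contigs, "contigs FASTA")
    if missing:
        raise FileNotFoundError(
            "missing inputs for enabled stages:\n  " + "\n  ".join(missing)
        )


def _read_ref_map(path: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cid, ref = line.split("\t")[:2]
            mapping[cid] = ref
    return mapping


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and aggregate their outputs into one report."""
    _validate(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_text(), "inputs": {}}
    for name in ("contigs", "assignments", "vcf", "orfs", "contig_ref_hits"):
        path = getattr(config, name)
        if path and Path(path).exists():
            report["inputs"][name] = _digest(path)
            log.info("input %s = %s (sha256/12 %s)", name, path, report["inputs"][name])

    contigs = read_fasta(config.contigs) if config.contigs else []
    assignments = (
        read_assignments(config.assignments) if config.assignments else []
    )

    partition = None
    if config.run_partition:
        # restrict to contigs that actually have assigned reads (the
        # classification errors out on orphans by design)
        assigned_ids = {a.contig_id for a in assignments if a.contig_id}
        part_contigs = [c for c in contigs if c.id in assigned_ids or c.read_ids]
        partition = library_partition.classify_by_origin(part_contigs, assignments)
        if config.cross_hits and Path(config.cross_hits).exists():
            hits = read_hits_tabular(config.cross_hits, "blast6+qlen")
            library_partition.direct_subtraction(
                partition, hits, part_contigs,
                min_cov=config.direct_min_cov, max_e=config.direct_max_e,
            )
        if (
            config.ref_hits_a and config.ref_hits_b
            and Path(config.ref_hits_a).exists() and Path(config.ref_hits_b).exists()
        ):
            ha = read_hits_tabular(config.ref_hits_a, "blast6+qlen")
            hb = read_hits_tabular(config.ref_hits_b, "blast6+qlen")
            library_partition.indirect_subtraction(
                partition, ha, hb, part_contigs,
                max_e=config.indirect_max_e, min_cov=config.indirect_min_cov,
            )
        report["partition"] = library_partition.partition_summary(partition)

    if config.run_capture:
        if partition is None:
            raise ValueError("capture stage needs the partition stage")
        n1 = len(partition.specific_a) + len(partition.common)
        n2 = len(partition.specific_b) + len(partition.common)
        m = len(partition.common)
        est = capture_recapture.estimate_abundance(n1, n2, m)
        report["capture"] = {
            "n1": n1, "n2": n2, "m": m,
            "n_hat": est.n_hat_rounded, "se": est.se,
            "ci": [est.ci_low, est.ci_high],
            "completeness": capture_recapture.completeness_fraction(
                est.observed, est
            ),
        }

    if config.run_saturation:
        ref_map = _read_ref_map(config.contig_ref_hits)
        design = saturation.RarefactionDesign(
            n_sizes=config.rarefaction_sizes,
            n_replicates=config.rarefaction_replicates,
            seed=config.seed,
        )
        points = saturation.rarefy_counts(assignments, ref_map, design)
        fit = saturation.fit_hyperbolic(points)
        observed = int(round(points[-1].mean))
        report["saturation"] = (
            saturation.saturation_report(fit, observed)
            if fit.converged
            else {"converged": False, "diagnostics": fit.diagnostics}
        )

    if config.run_variants:
        variants = read_vcf_minimal(config.vcf, contigs)
        orfs = read_orf_table(config.orfs)
        summary, removed = variant_stats.summarize_variants(
            variants, orfs, contigs,
            min_units=config.repeat_min_units,
            proximity=config.repeat_proximity,
        )
        write_vcf_minimal(outdir / "removed_repeat_adjacent.vcf", removed)
        report["variants"] = {
            "retained_snps": summary.retained_snps,
            "retained_indels": summary.retained_indels,
            "removed_repeat_adjacent": summary.removed_repeat_adjacent,
            "ts": summary.ts, "tv": summary.tv,
            "ka": summary.ka, "ks": summary.ks,
            "utr_snps": summary.utr_snps,
            "mean_snps_per_contig": summary.mean_snps_per_contig,
            "mean_indels_per_contig": summary.mean_indels_per_contig,
            "snp_density_bp": summary.snp_density,
            "indel_density_bp": summary.indel_density,
            "diversifying_contigs": summary.diversifying_contigs,
            "diversifying_fraction": summary.diversifying_fraction,
        }

    if config.run_ssr:
        loci = ssr_scan.scan_ssrs(contigs, config.parsed_ssr_thresholds())
        orfs = read_orf_table(config.orfs) if config.orfs else []
        annotated, ssr_summary = ssr_scan.ssr_orf_overlap(loci, orfs)
        ssr_summary["motif_table"] = ssr_scan.motif_frequency_table(annotated)
        report["ssr"] = ssr_summary

    report["assembly"] = assembly_summary(contigs)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def percent_reduction(previous_count: int, current_count: int) -> float:
    """Percent sequence reduction between two assemblies."""
    if previous_count <= 0:
        raise ValueError("previous_count must be positive")
    return 100 * (previous_count - current_count) / previous_count


def assembly_summary(contigs, previous_count: int | None = None) -> dict:
    """Counts, lengths, GC (N excluded), coverage; optional % reduction
    relative to a previous assembly's sequence count."""
    n = len(contigs)
    total_len = sum(len(c) for c in contigs)
    gc = sum(c.sequence.count("G") + c.sequence.count("C") for c in contigs)
    acgt = sum(len(c) - c.sequence.count("N") for c in contigs)
    out = {
        "sequences": n,
        "total_length": total_len,
        "mean_length": total_len / n if n else 0.0,
        "gc_percent": 100 * gc / acgt if acgt else 0.0,
        "mean_coverage": sum(c.mean_coverage for c in contigs) / n if n else 0.0,
    }
    if previous_count is not None:
        out["reduction_percent"] = percent_reduction(previous_count, n)
    return out
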