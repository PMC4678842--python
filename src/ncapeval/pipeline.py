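"""End-to-end workflow: simulate -> filter control -> demux -> map ->
coverage -> evaluate, with a manifest and per-stage read ledger.

The stage order follows the published analysis: internal-control reads
are filtered by mapping against the control reference *before* barcode
separation (the spike-in enters the protocol after the barcoding PCR,
so control reads carry no barcode and belong to no library).

A single global seed is expanded deterministically into per-stage
substreams, so re-running a config is bit-identical and stages can be
re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .covstat import WindowScheme, depth_from_alignments, window_coverage, write_bedgraph, write_window_tsv
from .demux import BarcodeSpec, demux_reads, filter_control
from .enrichstat import evaluate, summarize_experiments, write_report
from .mapper import SeedIndex, map_read, write_sam
from .refmodel import Genome, GenomicInterval, TargetSet, read_bed, read_fasta, tile_baits
from .simlib import (
    CaptureParams,
    ControlSpec,
    ErrorParams,
    SimConfig,
    build_library,
    capture,
    sequence_reads,
    shear,
    write_fastq,
    write_truth,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "run_workflow"]


@dataclass
class RunConfig:
    """Validated file-based configuration for a full run."""

    reference_fasta: Path
    targets_bed: Path
    outdir: Path
    seed: int = 0
    bait_len: int = 460
    bait_overlap_bp: int = 20
    control_fasta: Path | None = None
    exclude_bed: Path | None = None
    barcodes: dict[str, str] = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    capture: dict = field(default_factory=dict)
    window_size_bp: int = 200
    window_step_bp: int = 100
    mapper_k: int = 11
    raw_text: str = ""

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        doc = tomllib.loads(text)
        ref = doc.get("reference", {})
        cfg = cls(
            reference_fasta=Path(ref["fasta"]),
            targets_bed=Path(ref["targets_bed"]),
            outdir=Path(doc.get("outdir", "ncapeval_out")),
            seed=int(doc.get("seed", 0)),
            bait_len=int(doc.get("baits", {}).get("bait_len", 460)),
            bait_overlap_bp=int(doc.get("baits", {}).get("overlap_bp", 20)),
            control_fasta=Path(ref["control_fasta"]) if "control_fasta" in ref else None,
            exclude_bed=Path(ref["exclude_bed"]) if "exclude_bed" in ref else None,
            barcodes=dict(doc.get("barcodes", {})),
            sim=dict(doc.get("sim", {})),
            capture=dict(doc.get("capture", {})),
            window_size_bp=int(doc.get("windows", {}).get("size_bp", 200)),
            window_step_bp=int(doc.get("windows", {}).get("step_bp", 100)),
            mapper_k=int(doc.get("mapper", {}).get("k", 11)),
            raw_text=text,
        )
        for p in [cfg.reference_fasta, cfg.targets_bed, cfg.control_fasta, cfg.exclude_bed]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        return cfg

    def sim_config(self, seed: int) -> SimConfig:
        cap = CaptureParams(**self.capture)
        kwargs = dict(self.sim)
        control_fraction = float(kwargs.pop("control_fraction", 0.0))
        control_iv = None
        if control_fraction > 0:
            ci = kwargs.pop("control_interval")  # [ref, start, end]
            control_iv = ControlSpec(
                GenomicInterval(ci[0], int(ci[1]), int(ci[2])), control_fraction
            )
        for key in ("error_2d", "error_template"):
            if key in kwargs:
                kwargs[key] = ErrorParams(*kwargs[key])
        return SimConfig(capture=cap, control=control_iv, seed=seed, **kwargs)


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage substream seeds (kept below 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_workflow(
    genome: Genome,
    targets: TargetSet,
    sim_cfg: SimConfig,
    outdir: str | Path,
    bait_len: int = 460,
    bait_overlap_bp: int = 20,
    barcodes: dict[str, str] | None = None,
    control_genome: Genome | None = None,
    exclusions: list[GenomicInterval] | None = None,
    scheme: WindowScheme | None = None,
    mapper_k: int = 11,
) -> dict:
    """Run the full synthetic workflow; returns the manifest dict.

    Baits are tiled over every target locus at *bait_len*.  Outputs
    (FASTQ, truth TSV, per-library SAM, coverage bedGraph/TSV, per-
    library evaluation report, combined summary, manifest) are written
    under *outdir* in standard text formats.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = scheme or WindowScheme(200, 100)
    manifest: dict = {
        "version": __version__,
        "seed": sim_cfg.seed,
        "stages": {},
        "inputs": {
            "references": genome.lengths(),
            "targets": {n: str(iv) for n, iv in targets.loci},
            "bait_len": bait_len,
        },
    }
    seeds = _stage_seeds(sim_cfg.seed)

    # --- baits + simulation
    pools = [tile_baits(genome, iv, bait_len, bait_overlap_bp) for _, iv in targets.loci]
    from .refmodel import BaitPool

    baits = BaitPool([b for p in pools for b in p.baits], overlap_bp=bait_overlap_bp)
    rng = np.random.default_rng(seeds[0])
    frags = shear(genome, sim_cfg, rng)
    kept = capture(frags, baits, sim_cfg.capture, rng)
    lib = build_library(kept, sim_cfg, control_genome, rng, barcodes=barcodes or None)
    reads, truth = sequence_reads(lib, sim_cfg, rng)
    write_fastq(outdir / "reads.fastq", reads)
    write_truth(outdir / "truth.tsv", truth, seed=sim_cfg.seed)
    manifest["stages"]["simulate"] = {
        "fragments": len(frags),
        "captured": len(kept),
        "library": len(lib),
        "reads": len(reads),
    }

    # --- control filtering (before demux, matching the published order)
    if control_genome is not None:
        kept_reads, control_reads = filter_control(reads, control_genome)
    else:
        kept_reads, control_reads = list(reads), []
    manifest["stages"]["filter_control"] = {
        "input": len(reads),
        "kept": len(kept_reads),
        "control": len(control_reads),
    }

    # --- demultiplexing
    libraries: dict[str, list] = {}
    if barcodes:
        specs = [BarcodeSpec(bid, seq) for bid, seq in sorted(barcodes.items())]
        result = demux_reads(kept_reads, specs)
        for read in kept_reads:
            lib_id = result.assignments[read.read_id].barcode_id
            libraries.setdefault(lib_id, []).append(read)
        manifest["stages"]["demux"] = {k: len(v) for k, v in sorted(libraries.items())}
        libraries.pop("unclassified", None)
    else:
        libraries["library"] = kept_reads
        manifest["stages"]["demux"] = {"library": len(kept_reads)}

    # --- mapping, coverage, evaluation per library
    index = SeedIndex(genome, k=mapper_k)
    reports = []
    for lib_id, lib_reads in sorted(libraries.items()):
        alignments = []
        n_unmapped = 0
        for read in lib_reads:
            aln = map_read(read.read_id, read.sequence, index)
            if aln is None:
                n_unmapped += 1
            else:
                alignments.append(aln)
        write_sam(outdir / f"{lib_id}.sam", alignments, genome)
        track = depth_from_alignments(alignments, genome)
        windows = window_coverage(track, scheme)
        write_window_tsv(outdir / f"{lib_id}.windows.tsv", windows)
        write_bedgraph(outdir / f"{lib_id}.bedgraph", windows=windows)
        report = evaluate(alignments, track, targets, exclusions, name=lib_id)
        write_report(outdir / f"{lib_id}.report", report)
        reports.append(report)
        manifest["stages"][f"map:{lib_id}"] = {
            "reads": len(lib_reads),
            "mapped": len(alignments),
            "unmapped": n_unmapped,
        }

    if reports:
        summary = summarize_experiments(reports)
        manifest["summary"] = {k: round(v, 4) for k, v in summary.items()}
        with open(outdir / "summary.json", "w") as fh:
            json.dump(manifest["summary"], fh, indent=2)
            fh.write("\n")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def run_all(config: RunConfig) -> dict:
    """File-driven entry point: load inputs, echo the config, run."""
    genome = read_fasta(config.reference_fasta)
    targets = read_bed(config.targets_bed, genome)
    control_genome = read_fasta(config.control_fasta) if config.control_fasta else None
    exclusions = None
    if config.exclude_bed:
        exclusions = read_bed(config.exclude_bed).intervals()
    config.outdir.mkdir(parents=True, exist_ok=True)
    if config.raw_text:
        (config.outdir / "config.toml").write_text(config.raw_text)
    sim_cfg = config.sim_config(seed=config.seed)
    return run_workflow(
        genome,
        targets,
        sim_cfg,
        config.outdir,
        bait_len=config.bait_len,
        bait_overlap_bp=config.bait_overlap_bp,
        barcodes=config.barcodes or None,
        control_genome=control_genome,
        exclusions=exclusions,
        scheme=WindowScheme(config.window_size_bp, config.window_step_bp),
        mapper_k=config.mapper_k,
    )
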