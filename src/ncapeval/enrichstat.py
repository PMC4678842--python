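"""On/off-target evaluation statistics for capture enrichment.

Definitions (standard for hybrid-capture evaluation):

* **sensitivity** — percentage of target bases represented by at least
  one read;
* **specificity** — percentage of mapped reads whose alignment overlaps
  an intended target by >= 1 bp (the bedtools-coverage convention).

Alignments overlapping an exclusion interval (the spiked-in sequencing
control region) are removed before any counting.  A read overlapping
several loci counts once per locus but once overall (deduplicated by
read id).  Displayed percentages are rounded to one decimal, half away
from zero; internal values keep full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .covstat import DepthTrack
from .mapper import Alignment
from .refmodel import GenomicInterval, TargetSet

__all__ = [
    "Contingency2x2",
    "LocusResult",
    "EnrichmentReport",
    "round1",
    "count_on_target",
    "sensitivity",
    "specificity",
    "evaluate",
    "report_from_counts",
    "summarize_experiments",
    "fisher_exact",
    "flanking_extension",
    "write_report",
]


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (report formatting)."""
    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10, x)


@dataclass(frozen=True)
class Contingency2x2:
    """Rows = experiments, columns = (on-target, off-target) read counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def row_percentages(self) -> tuple[float, float]:
        """On-target percentage of each row (e.g. enriched vs whole-genome)."""
        return (
            100.0 * self.a / (self.a + self.b),
            100.0 * self.c / (self.c + self.d),
        )


@dataclass(frozen=True)
class LocusResult:
    locus: str
    reads_on_target: int
    target_length_bp: int
    bases_covered: int

    def __post_init__(self) -> None:
        if self.bases_covered > self.target_length_bp:
            raise ValueError(f"{self.locus}: covered bases exceed target length")

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.bases_covered / self.target_length_bp


@dataclass
class EnrichmentReport:
    per_locus: list[LocusResult]
    total_mapped_reads: int
    reads_on_any_target: int
    excluded_region_reads: int = 0
    name: str = "experiment"

    @property
    def specificity_pct(self) -> float:
        if self.total_mapped_reads == 0:
            return 0.0
        return 100.0 * self.reads_on_any_target / self.total_mapped_reads

    @property
    def total_reads_on_loci(self) -> int:
        return sum(l.reads_on_target for l in self.per_locus)

    @property
    def total_target_length(self) -> int:
        return sum(l.target_length_bp for l in self.per_locus)

    @property
    def total_bases_covered(self) -> int:
        return sum(l.bases_covered for l in self.per_locus)

    @property
    def experiment_sensitivity_pct(self) -> float:
        tl = self.total_target_length
        return 100.0 * self.total_bases_covered / tl if tl else 0.0


# ---------------------------------------------------------------------------
# counting

def count_on_target(
    alignments: list[Alignment],
    targets: TargetSet,
    exclusions: list[GenomicInterval] | None = None,
) -> tuple[dict[str, int], int, int, int]:
    """Classify alignments against target loci.

    Returns ``(per_locus_counts, on_any_target, off_target, excluded)``.
    Exclusion wins over everything: any alignment overlapping an
    exclusion interval by >= 1 bp is removed first.  Counts are by read
    id; ``on_any_target`` deduplicates reads spanning several loci.
    """
    if not targets.loci:
        raise ValueError("empty target set")
    exclusions = list(exclusions or []) + list(targets.exclusions)
    per_locus = {name: 0 for name, _ in targets.loci}
    on_ids: set[str] = set()
    off = excluded = 0
    for aln in alignments:
        iv = aln.ref_interval
        if any(iv.overlap(x) > 0 for x in exclusions):
            excluded += 1
            continue
        hit = False
        for name, t in targets.loci:
            if iv.overlap(t) > 0:
                per_locus[name] += 1
                hit = True
        if hit:
            on_ids.add(aln.read_id)
        else:
            off += 1
    return per_locus, len(on_ids), off, excluded


def sensitivity(track: DepthTrack, targets: TargetSet) -> tuple[dict[str, float], float, dict[str, int]]:
    """Per-locus and experiment sensitivity from a depth track.

    Returns ``(per_locus_pct, experiment_pct, bases_covered)``; the
    experiment value pools bases over loci (100 * sum covered / sum length).
    """
    per_pct: dict[str, float] = {}
    covered: dict[str, int] = {}
    for name, iv in targets.loci:
        arr = track.depth.get(iv.ref)
        if arr is None:
            covered[name] = 0
        else:
            covered[name] = int(np.count_nonzero(arr[iv.start : iv.end]))
        per_pct[name] = 100.0 * covered[name] / iv.length()
    total_len = targets.total_length()
    exp = 100.0 * sum(covered.values()) / total_len if total_len else 0.0
    return per_pct, exp, covered


def specificity(reads_on_any_target: int, total_mapped_reads: int) -> float:
    """Percentage of mapped reads (after exclusion removal) on target."""
    if total_mapped_reads == 0:
        return 0.0
    if reads_on_any_target > total_mapped_reads:
        raise ValueError("on-target reads exceed total mapped reads")
    return 100.0 * reads_on_any_target / total_mapped_reads


def evaluate(
    alignments: list[Alignment],
    track: DepthTrack,
    targets: TargetSet,
    exclusions: list[GenomicInterval] | None = None,
    name: str = "experiment",
) -> EnrichmentReport:
    """Full per-experiment evaluation from alignments + depth."""
    per_locus, on_any, _off, excluded = count_on_target(alignments, targets, exclusions)
    _, _, covered = sensitivity(track, targets)
    results = [
        LocusResult(n, per_locus[n], iv.length(), min(covered[n], iv.length()))
        for n, iv in targets.loci
    ]
    return EnrichmentReport(
        per_locus=results,
        total_mapped_reads=len(alignments) - excluded,
        reads_on_any_target=on_any,
        excluded_region_reads=excluded,
        name=name,
    )


def report_from_counts(
    loci: list[LocusResult],
    total_mapped_reads: int,
    reads_on_any_target: int | None = None,
    name: str = "experiment",
) -> EnrichmentReport:
    """Build a report directly from tabulated counts (e.g. a published
    evaluation table), without alignments.  When ``reads_on_any_target``
    is not given, the per-locus counts are summed (valid when no read
    spans two loci)."""
    if reads_on_any_target is None:
        reads_on_any_target = sum(l.reads_on_target for l in loci)
    return EnrichmentReport(loci, total_mapped_reads, reads_on_any_target, name=name)


# ---------------------------------------------------------------------------
# cross-experiment summaries

def summarize_experiments(reports: list[EnrichmentReport]) -> dict[str, float]:
    """Mean and pooled sensitivity/specificity across experiments.

    ``mean_*`` is the unweighted mean of per-experiment values;
    ``pooled_*`` re-computes the ratio from summed counts (read- or
    base-weighted).  Both are reported because they answer different
    questions and differ whenever experiments differ in size.
    """
    if not reports:
        raise ValueError("no reports")
    sens = [r.experiment_sensitivity_pct for r in reports]
    spec = [r.specificity_pct for r in reports]
    pooled_sens = 100.0 * sum(r.total_bases_covered for r in reports) / sum(
        r.total_target_length for r in reports
    )
    pooled_spec = 100.0 * sum(r.reads_on_any_target for r in reports) / sum(
        r.total_mapped_reads for r in reports
    )
    return {
        "mean_sensitivity_pct": float(np.mean(sens)),
        "mean_specificity_pct": float(np.mean(spec)),
        "pooled_sensitivity_pct": pooled_sens,
        "pooled_specificity_pct": pooled_spec,
    }


def fisher_exact(t: Contingency2x2) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    All tables with the observed margins whose hypergeometric
    probability does not exceed the observed table's (within relative
    tolerance ~1e-7) contribute; large counts are handled in log space
    by the backing implementation (scipy)."""
    arr = t.as_array()
    if arr.sum(axis=0).min() <= 0 or arr.sum(axis=1).min() <= 0:
        raise ValueError("all row and column margins must be positive")
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# flanking extension

def flanking_extension(
    alignments: list[Alignment],
    target: GenomicInterval,
    threshold_bp: int = 500,
) -> tuple[list[tuple[str, int, int]], dict[str, float]]:
    """Per-read flank lengths beyond the target boundary.

    For every alignment overlapping *target*, ``left = max(0,
    target.start - aln.start)`` and ``right = max(0, aln.end -
    target.end)``.  The summary reports the maximum and median single-
    side extension and the number of reads exceeding *threshold_bp* on
    either side — the captured-fragment geometry that makes enrichment
    useful for discovering unknown flanking sequence.
    """
    rows: list[tuple[str, int, int]] = []
    for aln in alignments:
        iv = aln.ref_interval
        if iv.overlap(target) <= 0:
            continue
        left = max(0, target.start - iv.start)
        right = max(0, iv.end - target.end)
        rows.append((aln.read_id, left, right))
    if rows:
        ext = [max(l, r) for _, l, r in rows]
        summary = {
            "n_reads": float(len(rows)),
            "max_extension_bp": float(max(ext)),
            "median_extension_bp": float(np.median(ext)),
            "n_exceeding_threshold": float(sum(e > threshold_bp for e in ext)),
            "threshold_bp": float(threshold_bp),
        }
    else:
        summary = {
            "n_reads": 0.0,
            "max_extension_bp": 0.0,
            "median_extension_bp": 0.0,
            "n_exceeding_threshold": 0.0,
            "threshold_bp": float(threshold_bp),
        }
    return rows, summary


# ---------------------------------------------------------------------------
# report output

def write_report(path_prefix: str | Path, report: EnrichmentReport) -> None:
    """TSV per-locus table plus JSON experiment summary."""
    prefix = Path(path_prefix)
    with open(prefix.parent / (prefix.name + ".tsv"), "w") as fh:
        fh.write("locus\treads_on_target\ttarget_length_bp\tbases_covered\tsensitivity_pct\n")
        for l in report.per_locus:
            fh.write(
                f"{l.locus}\t{l.reads_on_target}\t{l.target_length_bp}\t"
                f"{l.bases_covered}\t{round1(l.sensitivity_pct)}\n"
            )
        fh.write(
            f"total\t{report.total_reads_on_loci}\t{report.total_target_length}\t"
            f"{report.total_bases_covered}\t{round1(report.experiment_sensitivity_pct)}\n"
        )
    summary = {
        "name": report.name,
        "total_mapped_reads": report.total_mapped_reads,
        "reads_on_any_target": report.reads_on_any_target,
        "excluded_region_reads": report.excluded_region_reads,
        "sensitivity_pct": round1(report.experiment_sensitivity_pct),
        "specificity_pct": round1(report.specificity_pct),
    }
    with open(prefix.parent / (prefix.name + ".json"), "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
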