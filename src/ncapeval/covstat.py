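"""Per-base depth and overlapping-window coverage with normalisation.

Depth is accumulated over the reference-consuming span of each
alignment.  Windows are anchored at coordinate 0 and stepped by
``step_bp`` (the study system uses 200/100-bp windows on the phage
genome and 2000/1000-bp windows on the bacterial genomes); the trailing
partial window is kept.  Per-window coverage is the mean per-base depth
in the window; the normalised track divides it by the library's total
mapped reads, which makes tracks comparable across libraries and is
exactly invariant to duplicating every read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mapper import Alignment
from .refmodel import Genome, GenomicInterval

__all__ = [
    "DepthTrack",
    "WindowScheme",
    "WindowCoverage",
    "depth_from_alignments",
    "window_coverage",
    "write_bedgraph",
    "write_window_tsv",
    "read_window_tsv",
]


@dataclass
class DepthTrack:
    depth: dict[str, np.ndarray]  # per reference, int32 per-base depth
    total_mapped_reads: int

    def total_depth(self) -> int:
        return int(sum(arr.sum() for arr in self.depth.values()))


@dataclass(frozen=True)
class WindowScheme:
    size_bp: int
    step_bp: int

    def __post_init__(self) -> None:
        if not 0 < self.step_bp <= self.size_bp:
            raise ValueError("require 0 < step_bp <= size_bp")


@dataclass(frozen=True)
class WindowCoverage:
    interval: GenomicInterval
    mean_depth: float
    normalized: float


def depth_from_alignments(alignments: list[Alignment], genome: Genome) -> DepthTrack:
    """Accumulate per-base depth; each alignment adds 1 over its
    reference interval (clipped to reference bounds)."""
    tracks = {name: np.zeros(genome.length(name), dtype=np.int32) for name in genome.names}
    for aln in alignments:
        if aln.ref not in tracks:
            raise ValueError(f"alignment {aln.read_id} to unknown reference {aln.ref!r}")
        arr = tracks[aln.ref]
        lo = max(0, aln.ref_interval.start)
        hi = min(len(arr), aln.ref_interval.end)
        if hi > lo:
            arr[lo:hi] += 1
    return DepthTrack(tracks, total_mapped_reads=len(alignments))


def _window_starts(ref_len: int, scheme: WindowScheme) -> list[int]:
    """Full-window starts at 0, step, ... while start + size <= L, plus one
    trailing partial window at the next step when the end is uncovered."""
    starts = list(range(0, max(ref_len - scheme.size_bp, 0) + 1, scheme.step_bp))
    if not starts:
        return [0]
    last_end = starts[-1] + scheme.size_bp
    nxt = starts[-1] + scheme.step_bp
    if last_end < ref_len and nxt < ref_len:
        starts.append(nxt)
    return starts


def window_coverage(track: DepthTrack, scheme: WindowScheme) -> list[WindowCoverage]:
    """Overlapping-window mean and normalised coverage for every reference."""
    out: list[WindowCoverage] = []
    total = track.total_mapped_reads
    for name, arr in track.depth.items():
        L = len(arr)
        csum = np.concatenate(([0], np.cumsum(arr, dtype=np.int64)))
        for start in _window_starts(L, scheme):
            end = min(start + scheme.size_bp, L)
            mean = float(csum[end] - csum[start]) / (end - start)
            norm = mean / total if total > 0 else 0.0
            out.append(WindowCoverage(GenomicInterval(name, start, end), mean, norm))
    return out


def write_bedgraph(
    path: str | Path,
    windows: list[WindowCoverage] | None = None,
    track: DepthTrack | None = None,
    mode: str = "window",
    value: str = "normalized",
) -> None:
    """Emit bedGraph (0-based half-open).

    ``mode="window"`` writes one record per window (*value* selects the
    mean or normalised column); ``mode="perbase"`` writes the depth
    track with runs of equal depth merged.
    """
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="ncapeval coverage"\n')
        if mode == "window":
            if windows is None:
                raise ValueError("window mode needs windows")
            prev: dict[str, int] = {}
            for w in windows:
                if w.interval.start < prev.get(w.interval.ref, -1):
                    raise ValueError("windows not sorted by start")
                prev[w.interval.ref] = w.interval.start
                v = w.normalized if value == "normalized" else w.mean_depth
                fh.write(f"{w.interval.ref}\t{w.interval.start}\t{w.interval.end}\t{v:.6g}\n")
        elif mode == "perbase":
            if track is None:
                raise ValueError("perbase mode needs a depth track")
            for name, arr in track.depth.items():
                if len(arr) == 0:
                    continue
                change = np.nonzero(np.diff(arr))[0] + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    fh.write(f"{name}\t{s}\t{e}\t{int(arr[s])}\n")
        else:
            raise ValueError(f"unknown mode {mode!r}")


def write_window_tsv(path: str | Path, windows: list[WindowCoverage]) -> None:
    with open(path, "w") as fh:
        fh.write("ref\tstart\tend\tmean_depth\tnormalized\n")
        for w in windows:
            fh.write(
                f"{w.interval.ref}\t{w.interval.start}\t{w.interval.end}\t"
                f"{w.mean_depth:.6f}\t{w.normalized:.6f}\n"
            )


def read_window_tsv(path: str | Path) -> list[WindowCoverage]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("ref\t"):
            raise ValueError(f"{path}: not a window TSV")
        for line in fh:
            ref, s, e, mean, norm = line.rstrip("\n").split("\t")
            out.append(
                WindowCoverage(GenomicInterval(ref, int(s), int(e)), float(mean), float(norm))
            )
    return out
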