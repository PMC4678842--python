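"""Published reference data for the MinION PCR-bait enrichment study system.

Coordinates, per-locus read counts and covered-base counts come from the
published multiplexed hybrid-capture enrichment of phage Lambda and the
rRNA operons of *E. coli* O157:H7 (Sakai) and K-12/W3110 on the MinION
sequencer.  These printed tables are inputs: the evaluation layer can be
exercised against them without access to the raw reads.

Locus coordinates are literature style (``nt. s - e``; see
:func:`ncapeval.refmodel.interval_from_coords`), so length = e - s.
"""

from __future__ import annotations

from dataclasses import dataclass

from .refmodel import GenomicInterval, TargetSet, interval_from_coords

LAMBDA_REF = "NC_001416.1"
O157_REF = "NC_002695.1"
K12_REF = "NC_007779.1"

LAMBDA_LENGTH = 48_502

#: 1317-bp phage Lambda enrichment target
LAMBDA_TARGET = interval_from_coords(LAMBDA_REF, 41_053, 42_370)

#: 5258-bp rrnH operon of O157:H7 used for bait generation (16S/23S/5S
#: rRNA plus alaV/ileV/aspU tRNAs)
O157_BAIT_TARGET = interval_from_coords(O157_REF, 227_102, 232_360)

#: 3'-terminal region of the Lambda genome corresponding to the spiked-in
#: internal sequencing control (CS-DNA); excluded from comparative analysis
LAMBDA_CONTROL_REGION = interval_from_coords(LAMBDA_REF, 43_502, 48_502)

#: Library barcodes: the 5' portion of the barcoded amplification primers
#: (Bar01_PR2_F / Bar02_PR2_F) after removing the shared 22-nt 3' tail
#: that anneals to the ligated PCR adapter.
PCR_PRIMER_TAIL = "TTTCTGTTGGTGCTGATATTGC"
BARCODES = {
    "Bar01": "GGTGCTGAAGAAAGTTGTCGGTGTCTTTGTGTTAACCT",     # 38 nt
    "Bar02": "GGTGCTGTCGATTCCGTTTGTAGTCGTCTGTTTAACCTA",    # 39 nt
}


@dataclass(frozen=True)
class PublishedLocus:
    """One row of the published per-locus enrichment evaluation."""

    name: str
    start: int
    end: int
    reads_on_target: int
    target_length_bp: int
    bases_covered: int

    def interval(self, ref: str) -> GenomicInterval:
        return interval_from_coords(ref, self.start, self.end)


#: O157:H7 (Sakai) evaluation loci: total mapped reads 2522
O157_LOCI = [
    PublishedLocus("rrnH", 227_102, 232_204, 330, 5102, 5102),
    PublishedLocus("aspV", 240_481, 240_557, 4, 76, 76),
    PublishedLocus("alaX", 3_244_824, 3_244_899, 2, 75, 75),
    PublishedLocus("alaW", 3_244_939, 3_245_014, 3, 75, 75),
    PublishedLocus("rrnG", 3_446_266, 3_451_276, 322, 5010, 5010),
    PublishedLocus("rrnD", 4_158_428, 4_163_775, 341, 5347, 5347),
    PublishedLocus("rrnC", 4_735_252, 4_740_264, 321, 5012, 5012),
    PublishedLocus("rrnA", 4_831_654, 4_836_758, 328, 5104, 5104),
    PublishedLocus("rrnB", 4_975_927, 4_980_939, 322, 5012, 5012),
    PublishedLocus("rrnE", 5_016_953, 5_021_965, 318, 5012, 5012),
]
O157_TOTAL_MAPPED = 2522

#: K-12/W3110 evaluation loci: total mapped reads 265; the small
#: off-operon tRNA/5S loci (aspV, alaW, rrfF) were not captured.
K12_LOCI = [
    PublishedLocus("rrnH", 223_771, 228_875, 34, 5104, 5104),
    PublishedLocus("aspV", 236_931, 237_007, 0, 76, 0),
    PublishedLocus("alaW", 2_523_602, 2_523_677, 0, 75, 0),
    PublishedLocus("rrnG", 2_724_725, 2_729_813, 37, 5088, 5088),
    PublishedLocus("rrfF", 3_423_278, 3_423_397, 0, 119, 0),
    PublishedLocus("rrnD", 3_423_523, 3_428_534, 36, 5011, 5011),
    PublishedLocus("rrnB", 3_464_925, 3_470_022, 36, 5097, 5097),
    PublishedLocus("rrnA", 3_596_045, 3_601_150, 35, 5105, 5105),
    PublishedLocus("rrnC", 3_689_862, 3_694_873, 37, 5011, 5011),
    PublishedLocus("rrnE", 4_211_654, 4_216_749, 36, 5095, 5095),
]
K12_TOTAL_MAPPED = 265

#: Lambda single-target evaluation: 1179 on-target reads of 1232 mapped
LAMBDA_READS_ON_TARGET = 1179
LAMBDA_TOTAL_MAPPED = 1232

#: Lambda read counts, whole-genome vs target-enrichment run
#: (on-target, off-target), control region excluded.
LAMBDA_WGS_COUNTS = (247, 1092)          # total 1339
LAMBDA_ENRICHED_COUNTS = (1179, 53)      # total 1232


def published_targets(which: str) -> TargetSet:
    """TargetSet for ``"O157"`` or ``"K12"`` built from the published rows."""
    ref = {"O157": O157_REF, "K12": K12_REF}[which]
    loci = {"O157": O157_LOCI, "K12": K12_LOCI}[which]
    return TargetSet([(l.name, l.interval(ref)) for l in loci])
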