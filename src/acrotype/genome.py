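"""Minimal genome model: autosome arm coordinates and driver-gene loci.

Coordinates are approximate GRCh38 positions (1-based, Mb resolution for
arm boundaries). This is deliberately coarse: the copy-number scoring only
needs arm lengths and gene intervals, not an annotation-grade model.
"""

from __future__ import annotations

import pandas as pd

# (chrom, length_bp, centromere_bp) -- approximate GRCh38
_CHROMS = [
    ("1", 248_900_000, 123_400_000), ("2", 242_200_000, 93_900_000),
    ("3", 198_300_000, 90_900_000), ("4", 190_200_000, 50_000_000),
    ("5", 181_500_000, 48_800_000), ("6", 170_800_000, 59_800_000),
    ("7", 159_300_000, 60_100_000), ("8", 145_100_000, 45_200_000),
    ("9", 138_400_000, 43_000_000), ("10", 133_800_000, 39_800_000),
    ("11", 135_100_000, 53_400_000), ("12", 133_300_000, 35_500_000),
    ("13", 114_400_000, 17_700_000), ("14", 107_000_000, 17_200_000),
    ("15", 102_000_000, 19_000_000), ("16", 90_300_000, 36_800_000),
    ("17", 83_300_000, 25_100_000), ("18", 80_400_000, 18_500_000),
    ("19", 58_600_000, 26_200_000), ("20", 64_400_000, 28_100_000),
    ("21", 46_700_000, 12_000_000), ("22", 50_800_000, 15_000_000),
]

# gene -> (chrom, start, end), 1-based inclusive, approximate GRCh38
GENES = {
    "BRAF": ("7", 140_719_327, 140_924_929),
    "NRAS": ("1", 114_704_469, 114_716_894),
    "KIT": ("4", 54_657_918, 54_740_715),
    "NF1": ("17", 31_094_927, 31_377_677),
    "CDKN2A": ("9", 21_967_752, 21_995_301),
    "TP53": ("17", 7_668_402, 7_687_550),
    "TERT": ("5", 1_253_167, 1_295_047),
    "CCND1": ("11", 69_641_156, 69_654_474),
}

DRIVER_GENES = ("BRAF", "NRAS", "KIT", "NF1")


def arm_model() -> pd.DataFrame:
    """Autosome arm table: chrom, arm, start, end (1-based inclusive)."""
    rows = []
    for chrom, length, cen in _CHROMS:
        rows.append({"chrom": chrom, "arm": "p", "start": 1, "end": cen})
        rows.append({"chrom": chrom, "arm": "q", "start": cen + 1, "end": length})
    return pd.DataFrame(rows)


def gene_interval(gene: str):
    """(chrom, start, end) for a named gene."""
    if gene not in GENES:
        raise KeyError(f"unknown gene {gene!r}")
    return GENES[gene]
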