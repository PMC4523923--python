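"""Ribosome-footprint binning and translation-start-site calling.

Footprint read starts over a gene region are binned in fixed windows
(default 30 bp, the resolution of the published profile). Among a set of
candidate start codons, the supported translation start is the most upstream
candidate whose downstream footprint density exceeds the density of the
region between the annotated start and the candidate by at least
``ratio_min``-fold — a sharp density step at an internal ATG is the
signature of a mis-annotated start codon. If no candidate downstream of the
annotated start shows such a step, the annotated start is reported as
supported (offset 0).

Coordinates are 0-based half-open throughout; only read start positions
(footprint 5' ends) are used, on the gene's own strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 30
DEFAULT_RATIO_MIN = 5.0
#: floor on the upstream mean: one pseudoread per bin
UPSTREAM_FLOOR = 1.0


@dataclass
class FootprintTrack:
    gene_id: str
    gene_length: int
    window: int
    bin_counts: np.ndarray = field(repr=False)
    candidate_starts: list[int]
    annotated_start: int

    def __post_init__(self) -> None:
        expected = math.ceil(self.gene_length / self.window)
        if len(self.bin_counts) != expected:
            raise ValueError("bin_counts length must be ceil(gene_length / window)")
        if np.any(np.asarray(self.bin_counts) < 0):
            raise ValueError("bin counts must be non-negative")
        self.candidate_starts = sorted(self.candidate_starts)


@dataclass(frozen=True)
class StartCall:
    gene_id: str
    chosen_start: int
    offset: int
    ratio: float
    annotated_supported: bool


def bin_reads(
    reads: pd.DataFrame,
    gene_length: int,
    window: int = DEFAULT_WINDOW,
    gene_id: str | None = None,
    candidate_starts: list[int] | None = None,
    annotated_start: int = 0,
) -> FootprintTrack:
    """Bin BED read starts into fixed windows over [0, gene_length).

    Bin i counts reads with start in [i*window, (i+1)*window); the total
    read count is conserved. Reads outside the region raise, listing the
    offending positions.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    starts = reads["start"].to_numpy(dtype=int) if len(reads) else np.array([], dtype=int)
    bad = starts[(starts < 0) | (starts >= gene_length)]
    if bad.size:
        shown = ", ".join(map(str, sorted(bad)[:10]))
        raise ValueError(
            f"{bad.size} read start(s) outside [0, {gene_length}): {shown}"
        )
    n_bins = math.ceil(gene_length / window)
    counts = np.bincount(starts // window, minlength=n_bins).astype(int)
    if gene_id is None:
        gene_id = str(reads["chrom"].iloc[0]) if len(reads) else "gene"
    return FootprintTrack(
        gene_id=gene_id,
        gene_length=gene_length,
        window=window,
        bin_counts=counts,
        candidate_starts=list(candidate_starts or []),
        annotated_start=annotated_start,
    )


def _mean_density(counts: np.ndarray, lo_bin: int, hi_bin: int) -> float | None:
    """Mean reads per bin over bin indices [lo_bin, hi_bin); None if empty."""
    if hi_bin <= lo_bin:
        return None
    return float(counts[lo_bin:hi_bin].mean())


def call_start_codon(
    track: FootprintTrack, ratio_min: float = DEFAULT_RATIO_MIN
) -> StartCall:
    """Call the supported translation start among the track's candidates.

    For each candidate c strictly downstream of the annotated start (scanned
    upstream-first), compare the mean per-bin density from the bin containing
    c onwards against the mean density of the bins fully inside
    [annotated_start, c); the upstream mean is floored at one pseudoread per
    bin (and is the floor itself when no full bin fits in the gap). The first
    candidate whose ratio exceeds ``ratio_min`` wins; otherwise the annotated
    start is reported with offset 0.
    """
    if not track.candidate_starts:
        raise ValueError("track has no candidate starts")
    if int(np.asarray(track.bin_counts).sum()) == 0:
        raise ValueError("track has no reads")
    counts = np.asarray(track.bin_counts)
    w = track.window
    ann = track.annotated_start
    ann_bin = ann // w

    for c in track.candidate_starts:
        if c <= ann:
            continue
        c_bin = c // w
        down = _mean_density(counts, c_bin, len(counts))
        if down is None:
            continue
        first_full = math.ceil(ann / w)
        up = _mean_density(counts, first_full, c_bin)
        up = UPSTREAM_FLOOR if up is None else max(up, UPSTREAM_FLOOR)
        ratio = down / up
        if ratio > ratio_min:
            return StartCall(
                gene_id=track.gene_id,
                chosen_start=c,
                offset=c - ann,
                ratio=ratio,
                annotated_supported=False,
            )

    down = _mean_density(counts, ann_bin, len(counts)) or 0.0
    return StartCall(
        gene_id=track.gene_id,
        chosen_start=ann,
        offset=0,
        ratio=float("nan"),
        annotated_supported=True,
    )


def profile_table(track: FootprintTrack) -> pd.DataFrame:
    """Per-bin profile for plotting: gene, bin_start, bin_end, count."""
    starts = np.arange(len(track.bin_counts)) * track.window
    return pd.DataFrame(
        {
            "gene": track.gene_id,
            "bin_start": starts,
            "bin_end": np.minimum(starts + track.window, track.gene_length),
            "count": track.bin_counts,
        }
    )
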