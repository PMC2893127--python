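"""Control-free quality diagnostics.

Three diagnostics that need no technical control sample:

* sample-overlap statistics between a ChIP library and an input library
  (little overlap means the input cannot serve as a local control);
* background-noise estimation from the mitochondrial chromosome, which is
  physically separated from nuclear transcription factors, so its
  ChIP/input read ratio estimates how much residual input-like material the
  ChIP library carries;
* a false-positive surrogate from a chromosome known to be absent from the
  sample (e.g. Chr Y in a female cell line): any called region there is
  spurious, and the cumulative count of such regions along the ranked list
  compares calling strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SampleOverlap:
    """Unique-read overlap between a ChIP and an input library."""

    chip_only: int
    input_only: int
    in_both: int
    chip_only_pct: float
    input_only_pct: float
    in_both_pct: float


@dataclass(frozen=True)
class NoiseEstimate:
    """Experimental-background estimate from the mitochondrial chromosome."""

    chrm_chip_reads: int
    chrm_input_reads: int
    chip_input_ratio: float
    input_noise_reads: int
    expected_chip_background: int


def overlap_report(chip_only: int, input_only: int, in_both: int) -> SampleOverlap:
    """Percent shares of the union, reported to two decimals."""
    if min(chip_only, input_only, in_both) < 0:
        raise ValueError("counts must be non-negative")
    total = chip_only + input_only + in_both
    if total == 0:
        raise ValueError("at least one count must be positive")
    pct = lambda c: round(100.0 * c / total, 2)
    return SampleOverlap(
        chip_only, input_only, in_both, pct(chip_only), pct(input_only), pct(in_both)
    )


def chip_input_ratio(chip_reads: int, input_reads: int) -> float:
    """ChIP/input read ratio, rounded to 4 decimals."""
    if input_reads <= 0:
        raise ZeroDivisionError("input read count must be positive")
    return round(chip_reads / input_reads, 4)


def background_noise_report(
    chrm_chip: int, chrm_input: int, input_noise_reads: int
) -> NoiseEstimate:
    """Expected experimental-background reads in the ChIP library.

    The mitochondrial ChIP/input ratio (rounded to 4 decimals) scales the
    genomic input noise reads; the product is truncated to an integer.
    Rounding before multiplying is deliberate: the estimate inherits the
    precision of the reported ratio.
    """
    ratio = chip_input_ratio(chrm_chip, chrm_input)
    return NoiseEstimate(
        chrm_chip_reads=chrm_chip,
        chrm_input_reads=chrm_input,
        chip_input_ratio=ratio,
        input_noise_reads=input_noise_reads,
        expected_chip_background=math.floor(ratio * input_noise_reads),
    )


def absent_chromosome_rate(
    ranked: pd.DataFrame, surrogate: str, genome=None
) -> np.ndarray:
    """Cumulative count of called regions on the surrogate chromosome as a
    function of rank (monotone non-decreasing, length = number of regions).

    ``ranked`` must carry ``chrom`` and ``rank`` columns.  When a genome
    table is supplied the surrogate name is validated against it.
    """
    if "chrom" not in ranked or "rank" not in ranked:
        raise ValueError("ranked frame must have 'chrom' and 'rank' columns")
    if genome is not None and surrogate not in genome:
        raise KeyError(f"surrogate chromosome {surrogate!r} not in genome table")
    ordered = ranked.sort_values("rank")
    hits = (ordered["chrom"] == surrogate).to_numpy()
    return np.cumsum(hits)


def overlap_table(rows: dict[str, SampleOverlap]) -> pd.DataFrame:
    """TSV-ready frame mirroring a per-chromosome-group overlap summary."""
    return pd.DataFrame(
        [
            {
                "group": name,
                "chip_only": o.chip_only,
                "input_only": o.input_only,
                "in_both": o.in_both,
                "chip_only_pct": o.chip_only_pct,
                "input_only_pct": o.input_only_pct,
                "in_both_pct": o.in_both_pct,
            }
            for name, o in rows.items()
        ]
    )
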