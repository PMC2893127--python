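"""Sliding-window strand profiles over PBRs and peak localization.

Each PBR is extended by *d* bp on both sides (a fragment's 5' tag can lie up
to one maximum fragment length away from the binding site) and scanned base
pair by base pair with a window of width *d*.  ``F[s]`` counts forward tags
with 5' position in ``[s, s+d)`` and ``R[s]`` the reverse tags, for every
window start ``s`` in the extended region.  The combined peak ``max(F+R)``
yields the per-region count p-value under the fitted background; the
separate forward/reverse peaks locate the binding site: the site estimate is
the midpoint between the downstream edge of the forward-peak window and the
start of the reverse-peak window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .countmodel import PBR, GammaPoissonModel, PoissonModel
from .tagio import FORWARD, REVERSE, GenomeTable, Region, TagRecord


class DegenerateProfileError(ValueError):
    """Profile empty or all-zero; no peak can be located."""


class TagIndex:
    """Per-chromosome sorted 5'-position arrays, split by strand.

    Build once and reuse across PBRs; slicing a profile is then two binary
    searches plus a bincount.
    """

    def __init__(self, fwd: dict[str, np.ndarray], rev: dict[str, np.ndarray]):
        self._fwd = fwd
        self._rev = rev

    @classmethod
    def from_tags(cls, tags: Sequence[TagRecord]) -> "TagIndex":
        fwd: dict[str, list[int]] = {}
        rev: dict[str, list[int]] = {}
        for tag in tags:
            (fwd if tag.strand == FORWARD else rev).setdefault(tag.chrom, []).append(
                tag.pos
            )
        return cls(
            {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in fwd.items()},
            {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in rev.items()},
        )

    def positions(self, chrom: str, strand: str) -> np.ndarray:
        store = self._fwd if strand == FORWARD else self._rev
        return store.get(chrom, np.zeros(0, dtype=np.int64))


@dataclass
class StrandProfile:
    """Forward/reverse window counts over an extended PBR."""

    chrom: str
    scan_start: int
    d: int
    F: np.ndarray
    R: np.ndarray

    @property
    def degenerate(self) -> bool:
        return self.F.size == 0

    @property
    def window_starts(self) -> np.ndarray:
        return self.scan_start + np.arange(self.F.size)


@dataclass(frozen=True)
class PeakInfo:
    """Peak summary of one profile (absolute genomic coordinates)."""

    peak_pos: int
    peak_count: int
    f_peak_pos: int
    r_peak_pos: int
    site_estimate: int


def _window_counts(pos: np.ndarray, scan_start: int, scan_end: int, d: int) -> np.ndarray:
    lo = np.searchsorted(pos, scan_start, "left")
    hi = np.searchsorted(pos, scan_end, "left")
    length = scan_end - scan_start
    arr = np.bincount(pos[lo:hi] - scan_start, minlength=length)
    cs = np.concatenate([[0], np.cumsum(arr)])
    return cs[d:] - cs[:-d]


def window_profile(
    tags: Sequence[TagRecord] | TagIndex,
    pbr: PBR | Region,
    d: int,
    genome: GenomeTable,
) -> StrandProfile:
    """Strand-split sliding-window counts over the PBR extended by *d* bp on
    each side (clipped to the chromosome).  An extended region shorter than
    *d* yields an empty, degenerate profile."""
    if d <= 0:
        raise ValueError("window size d must be positive")
    region = pbr.region if isinstance(pbr, PBR) else pbr
    index = tags if isinstance(tags, TagIndex) else TagIndex.from_tags(tags)
    scan_start = max(0, region.start - d)
    scan_end = min(genome[region.chrom], region.end + d)
    if scan_end - scan_start < d:
        empty = np.zeros(0, dtype=np.int64)
        return StrandProfile(region.chrom, scan_start, d, empty, empty)
    F = _window_counts(index.positions(region.chrom, FORWARD), scan_start, scan_end, d)
    R = _window_counts(index.positions(region.chrom, REVERSE), scan_start, scan_end, d)
    return StrandProfile(region.chrom, scan_start, d, F, R)


def locate_peaks(profile: StrandProfile) -> PeakInfo:
    """Locate the combined and per-strand peaks (leftmost-wins ties) and the
    site estimate midway between the forward-peak window's downstream edge
    and the reverse-peak window's start."""
    if profile.degenerate:
        raise DegenerateProfileError("empty profile")
    total = profile.F + profile.R
    if total.max() == 0:
        raise DegenerateProfileError("all-zero profile")
    s0, d = profile.scan_start, profile.d
    peak_idx = int(np.argmax(total))
    f_idx = int(np.argmax(profile.F))
    r_idx = int(np.argmax(profile.R))
    site = math_floor_half(((s0 + f_idx + d) + (s0 + r_idx)) / 2.0)
    site = min(max(site, s0), s0 + total.size + d - 2)  # keep inside scan range
    return PeakInfo(
        peak_pos=s0 + peak_idx,
        peak_count=int(total[peak_idx]),
        f_peak_pos=s0 + f_idx,
        r_peak_pos=s0 + r_idx,
        site_estimate=site,
    )


def math_floor_half(x: float) -> int:
    """Round half away from zero (deterministic, unlike banker's rounding)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def peak_pvalue(
    model: GammaPoissonModel | PoissonModel, peak: PeakInfo | int
) -> float:
    """p_c = Pr(X >= peak count) under the (zero-truncated) background."""
    count = peak.peak_count if isinstance(peak, PeakInfo) else int(peak)
    if count < 1:
        raise ValueError("peak count must be >= 1")
    return float(model.sf(count - 1))


def profile_to_bedgraph(profile: StrandProfile, fwd_path, rev_path) -> None:
    """Export the two strand tracks as bedGraph (1-bp window-start steps)."""
    for path, values in ((fwd_path, profile.F), (rev_path, profile.R)):
        with open(path, "w") as fh:
            for i, v in enumerate(values):
                if v:
                    s = profile.scan_start + i
                    fh.write(f"{profile.chrom}\t{s}\t{s + 1}\t{v}\n")
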