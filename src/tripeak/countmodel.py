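"""Genome binning and the zero-truncated Gamma-Poisson background model.

The genome is divided into non-overlapping windows of the maximum fragment
size *d* and the per-window unique-tag counts are tabulated.  Because tag
density is over-dispersed (non-specific protein-DNA binding makes the local
rate itself random), the background count in a window is modelled as a
Gamma-Poisson mixture, i.e. a negative binomial

    P(X = x) = C(x + r - 1, x) p^r (1 - p)^x ,   x = 0, 1, 2, ...

with mean r(1-p)/p and variance r(1-p)/p^2.  Zero-count windows are excluded
from the fit (zeros largely reflect non-mappable sequence rather than the
count process), so both the Gamma-Poisson and the Poisson comparison model
are fitted zero-truncated, with support x >= 1 and mass divided by
1 - P(X = 0).

An empirical FDR attaches to each integer count threshold k:

    eFDR(k) = min(1, N_total * Pr(count > k) / N_observed(count > k))

where Pr is the fitted truncated tail and N_total counts *all* windows.  The
smallest k with eFDR(k) <= alpha becomes the selection threshold; maximal
runs of adjacent windows exceeding it are merged into potential binding
regions (PBRs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .tagio import GenomeTable, Region, TagRecord


class DegenerateHistogramError(ValueError):
    """Histogram too degenerate to fit (needs >=2 distinct nonzero counts)."""


class FittingError(RuntimeError):
    """Optimizer failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params: tuple[float, float]):
        super().__init__(message)
        self.last_params = last_params


class ThresholdError(ValueError):
    """No count threshold satisfies the requested eFDR level."""


@dataclass
class CountHistogram:
    """Tabulated window counts: count value -> number of windows.

    ``n_total`` is the total number of windows in the genome, including
    zero-count windows (which may or may not be tabulated explicitly).
    """

    counts: dict[int, int]
    n_total: int

    def __post_init__(self) -> None:
        if any(k < 0 or f < 0 for k, f in self.counts.items()):
            raise ValueError("counts and frequencies must be non-negative")
        if sum(self.counts.values()) > self.n_total:
            raise ValueError("frequencies exceed the total number of windows")

    @property
    def max_count(self) -> int:
        return max((k for k, f in self.counts.items() if f > 0), default=0)

    def nonzero_items(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, frequencies) for counts >= 1 with positive frequency."""
        pairs = sorted((k, f) for k, f in self.counts.items() if k >= 1 and f > 0)
        ks = np.array([k for k, _ in pairs], dtype=np.int64)
        fs = np.array([f for _, f in pairs], dtype=np.int64)
        return ks, fs

    def n_observed_gt(self, k: int) -> int:
        """Number of windows with count strictly greater than *k*."""
        return sum(f for kk, f in self.counts.items() if kk > k)


# ---------------------------------------------------------------------------
# background distributions


@dataclass
class GammaPoissonModel:
    """Fitted (optionally zero-truncated) Gamma-Poisson background."""

    r: float
    p: float
    zero_truncated: bool = True

    def __post_init__(self) -> None:
        if not (self.r > 0 and 0 < self.p < 1):
            raise ValueError("require r > 0 and 0 < p < 1")

    @property
    def mean(self) -> float:
        """Mean of the untruncated mixture, r(1-p)/p."""
        return self.r * (1 - self.p) / self.p

    @property
    def dispersion(self) -> float:
        """Variance of the untruncated mixture, r(1-p)/p^2."""
        return self.r * (1 - self.p) / self.p**2

    def _p0(self) -> float:
        return self.p**self.r

    def pmf(self, k) -> np.ndarray | float:
        k = np.asarray(k)
        base = stats.nbinom.pmf(k, self.r, self.p)
        if self.zero_truncated:
            base = np.where(k >= 1, base / (1.0 - self._p0()), 0.0)
        return base if base.ndim else float(base)

    def sf(self, k) -> np.ndarray | float:
        """Pr(X > k).  Under truncation Pr(X > 0) = 1."""
        k = np.asarray(k)
        tail = stats.nbinom.sf(k, self.r, self.p)
        if self.zero_truncated:
            tail = np.minimum(tail / (1.0 - self._p0()), 1.0)
        return tail if tail.ndim else float(tail)


@dataclass
class PoissonModel:
    """Fitted (optionally zero-truncated) Poisson comparison model."""

    lam: float
    zero_truncated: bool = True

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("rate must be positive")

    def pmf(self, k) -> np.ndarray | float:
        k = np.asarray(k)
        base = stats.poisson.pmf(k, self.lam)
        if self.zero_truncated:
            base = np.where(k >= 1, base / -math.expm1(-self.lam), 0.0)
        return base if base.ndim else float(base)

    def sf(self, k) -> np.ndarray | float:
        k = np.asarray(k)
        tail = stats.poisson.sf(k, self.lam)
        if self.zero_truncated:
            tail = np.minimum(tail / -math.expm1(-self.lam), 1.0)
        return tail if tail.ndim else float(tail)


@dataclass
class FitReport:
    loglik_gp: float
    loglik_poisson: float
    aic_gp: float
    aic_poisson: float
    n_windows_fit: int
    converged: bool
    message: str = ""

    @property
    def preferred(self) -> str:
        return "gamma-poisson" if self.aic_gp <= self.aic_poisson else "poisson"


# ---------------------------------------------------------------------------
# operations


def bin_counts(
    tags: Sequence[TagRecord], genome: GenomeTable, d: int
) -> tuple[dict[str, np.ndarray], CountHistogram]:
    """Count tags in non-overlapping *d*-bp windows genome-wide.

    Window ``i`` on a chromosome covers ``[i*d, (i+1)*d)``; each tag is
    assigned by its 5' position regardless of strand.  The final partial
    window of each chromosome is kept.  Returns per-chromosome count arrays
    and the genome-wide :class:`CountHistogram` (zero windows included).
    """
    if d <= 0:
        raise ValueError("window size d must be positive")
    per_chrom: dict[str, np.ndarray] = {
        name: np.zeros(-(-length // d), dtype=np.int64) for name, length in genome.items()
    }
    for tag in tags:
        try:
            bins = per_chrom[tag.chrom]
        except KeyError:
            raise KeyError(f"tag on chromosome {tag.chrom!r} absent from genome table")
        if tag.pos >= genome[tag.chrom]:
            raise ValueError(
                f"tag position {tag.pos} beyond {tag.chrom} length {genome[tag.chrom]}"
            )
        bins[tag.pos // d] += 1
    all_counts = (
        np.concatenate(list(per_chrom.values())) if per_chrom else np.zeros(0, np.int64)
    )
    freqs = np.bincount(all_counts)
    hist = CountHistogram(
        counts={int(k): int(f) for k, f in enumerate(freqs) if f > 0},
        n_total=int(all_counts.size),
    )
    return per_chrom, hist


def _trunc_nbinom_negll(x: np.ndarray, ks: np.ndarray, fs: np.ndarray) -> float:
    r = math.exp(x[0])
    p = 1.0 / (1.0 + math.exp(-x[1]))
    if not (1e-12 < p < 1 - 1e-12) or not (1e-12 < r < 1e12):
        return 1e300
    logpmf = (
        gammaln(ks + r)
        - gammaln(r)
        - gammaln(ks + 1)
        + r * math.log(p)
        + ks * math.log1p(-p)
    )
    log_norm = math.log1p(-(p**r)) if p**r < 1.0 - 1e-300 else -1e300
    return float(-(fs * (logpmf - log_norm)).sum())


def fit_background(
    hist: CountHistogram,
) -> tuple[GammaPoissonModel, PoissonModel, FitReport]:
    """Maximum-likelihood zero-truncated Gamma-Poisson and Poisson fits.

    The Gamma-Poisson likelihood is maximized by quasi-Newton iteration on
    the transformed parameters (log r, logit p), initialized from method of
    moments; the truncated-Poisson rate solves lambda/(1-e^-lambda) = mean.
    """
    ks, fs = hist.nonzero_items()
    if len(ks) < 2:
        raise DegenerateHistogramError(
            "need at least 2 distinct nonzero count values to fit"
        )
    n = int(fs.sum())
    m = float((ks * fs).sum() / n)
    v = float((fs * (ks - m) ** 2).sum() / max(n - 1, 1))
    # method-of-moments start (treating the truncated sample as untruncated)
    if v > m * 1.0001:
        p0 = min(max(m / v, 1e-3), 0.999)
    else:
        p0 = 0.9
    r0 = max(m * p0 / (1 - p0), 1e-2)
    x0 = np.array([math.log(r0), math.log(p0 / (1 - p0))])
    res = optimize.minimize(
        _trunc_nbinom_negll,
        x0,
        args=(ks, fs),
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
    )
    r_hat = math.exp(res.x[0])
    p_hat = 1.0 / (1.0 + math.exp(-res.x[1]))
    if not res.success and res.status != 2:  # status 2: precision-loss stop, accept
        raise FittingError(f"Gamma-Poisson MLE failed: {res.message}", (r_hat, p_hat))
    gp = GammaPoissonModel(r_hat, p_hat, zero_truncated=True)

    # truncated Poisson: solve the mean equation
    def mean_eq(lam: float) -> float:
        return lam / -math.expm1(-lam) - m

    lam = optimize.brentq(mean_eq, 1e-10, max(2.0 * m, 2.0)) if m > 1 + 1e-12 else 1e-8
    pois = PoissonModel(max(lam, 1e-10), zero_truncated=True)

    ll_gp = -_trunc_nbinom_negll(res.x, ks, fs)
    ll_pois = float((fs * np.log(np.maximum(pois.pmf(ks), 1e-300))).sum())
    report = FitReport(
        loglik_gp=ll_gp,
        loglik_poisson=ll_pois,
        aic_gp=2 * 2 - 2 * ll_gp,
        aic_poisson=2 * 1 - 2 * ll_pois,
        n_windows_fit=n,
        converged=bool(res.success or res.status == 2),
        message=str(res.message),
    )
    return gp, pois, report


def gp_tail(model: GammaPoissonModel | PoissonModel, k: int) -> float:
    """Pr(count > k) under the fitted background (truncated when the model
    is truncated)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return float(model.sf(k))


def efdr_table(model: GammaPoissonModel, hist: CountHistogram) -> pd.DataFrame:
    """Empirical-FDR table for all thresholds k = 0 .. max observed count.

    ``efdr = min(1, n_total * Pr(count > k) / n_observed(count > k))``;
    rows whose observed exceedance is zero carry NaN.
    """
    rows = []
    for k in range(hist.max_count + 1):
        n_obs = hist.n_observed_gt(k)
        expected = hist.n_total * gp_tail(model, k)
        efdr = min(1.0, expected / n_obs) if n_obs > 0 else math.nan
        rows.append((k, n_obs, expected, efdr))
    return pd.DataFrame(rows, columns=["k", "n_observed", "expected", "efdr"])


def select_threshold(table: pd.DataFrame, alpha: float) -> int:
    """Smallest k with eFDR(k) <= alpha.  Regions kept downstream are those
    with count strictly greater than the returned threshold."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    ok = table[(table["n_observed"] > 0) & (table["efdr"] <= alpha)]
    if ok.empty:
        raise ThresholdError(
            f"no count threshold achieves eFDR <= {alpha}; consider a larger alpha"
        )
    return int(ok["k"].iloc[0])


@dataclass(frozen=True)
class PBR:
    """Potential binding region: a maximal run of adjacent windows whose
    counts exceed the selected threshold, merged."""

    region: Region
    tag_count: int
    source_bins: int


def select_pbrs(
    per_bin: Mapping[str, np.ndarray], k_star: int, d: int, genome: GenomeTable
) -> list[PBR]:
    """Merge adjacent windows with count > k_star into PBRs, sorted by
    (chromosome order, start)."""
    pbrs: list[PBR] = []
    for chrom in genome:
        counts = per_bin.get(chrom)
        if counts is None or counts.size == 0:
            continue
        mask = counts > k_star
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        clen = genome[chrom]
        for i0, i1 in zip(starts, ends):
            pbrs.append(
                PBR(
                    region=Region(chrom, int(i0) * d, min(int(i1) * d, clen)),
                    tag_count=int(counts[i0:i1].sum()),
                    source_bins=int(i1 - i0),
                )
            )
    return pbrs


def counts_to_bedgraph(per_bin: Mapping[str, np.ndarray], d: int,
                       genome: GenomeTable, path) -> None:
    """Export per-window counts as bedGraph (nonzero windows only)."""
    with open(path, "w") as fh:
        for chrom in genome:
            counts = per_bin.get(chrom)
            if counts is None:
                continue
            clen = genome[chrom]
            for i in np.flatnonzero(counts):
                fh.write(f"{chrom}\t{i * d}\t{min((i + 1) * d, clen)}\t{counts[i]}\n")
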