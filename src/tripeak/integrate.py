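"""Evidence integration: high-quality region selection, score rescaling,
re-ranking, and the second step of the two-step empirical-FDR procedure.

Every PBR carries three evidence scores -- the peak-count p-value p_c, the
pattern dissimilarity d_p, and the motif p-value p_m.  Their natural scales
differ by many orders of magnitude (peak-count p-values can reach 1e-30
while motif p-values bottom out around 1e-5), so the log scores are aligned
before averaging: the sorted log-d_p and log-p_m vectors are regressed on
the sorted log-p_c vector (quantile-matching ordinary least squares) and the
fitted affine maps are applied per region.  The combined score is the mean
of log-p_c and the two rescaled values; regions are re-ranked ascending.

Because the initial count threshold was chosen at eFDR level alpha and
re-ranking is a permutation of the same region set, flagging the top
(1 - alpha) fraction of the re-ranked list preserves the overall FDR; the
significant-set size depends only on the number of PBRs and alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LOG_EPSILON = 1e-6  # d_p can be exactly 0; enters as ln(d_p + epsilon)

ROUNDING_RULES = ("half_away_from_zero", "floor")


@dataclass(frozen=True)
class RegionScores:
    """The per-region evidence triple and its combined score."""

    p_c: float
    d_p: float
    p_m: float | None
    combined: float


def _ordinal_ranks(primary: np.ndarray) -> np.ndarray:
    """Rank positions 1..N by *primary* ascending, ties broken by original
    (genomic) order; deterministic."""
    order = np.lexsort((np.arange(primary.size), primary))
    ranks = np.empty(primary.size, dtype=np.int64)
    ranks[order] = np.arange(1, primary.size + 1)
    return ranks


def select_high_quality(df: pd.DataFrame, n_high_quality: int) -> pd.DataFrame:
    """Regions with both low count p-values and well-matched shapes.

    PBRs are ranked separately by ``p_c`` and by ``d_p``; the two top-q
    lists are intersected with q grown until the intersection reaches
    *n_high_quality* (or all PBRs are exhausted), then truncated to
    *n_high_quality* by the sum of the two ranks (ties: p_c, then genomic
    order).  Expects ``df`` in genomic order with columns p_c and d_p.
    """
    n = len(df)
    if n < 10:
        warnings.warn(
            f"only {n} PBRs available; using all for motif discovery", stacklevel=2
        )
    rank_c = _ordinal_ranks(df["p_c"].to_numpy(dtype=float))
    rank_d = _ordinal_ranks(df["d_p"].to_numpy(dtype=float))
    q = min(n_high_quality, n)
    while True:
        inside = (rank_c <= q) & (rank_d <= q)
        if inside.sum() >= min(n_high_quality, n) or q >= n:
            break
        q += 1
    idx = np.flatnonzero(inside)
    order = np.lexsort(
        (idx, df["p_c"].to_numpy(dtype=float)[idx], (rank_c + rank_d)[idx])
    )
    chosen = idx[order][:n_high_quality]
    return df.iloc[np.sort(chosen)]


def _quantile_ols_rescale(target_sorted: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Affine map fitted by OLS of the sorted target on the sorted x,
    applied to x.  Degenerate (constant) x maps to the target mean."""
    xs = np.sort(x)
    var = xs.var()
    if var < 1e-24:
        return np.full_like(x, target_sorted.mean())
    beta = ((xs - xs.mean()) * (target_sorted - target_sorted.mean())).mean() / var
    alpha = target_sorted.mean() - beta * xs.mean()
    return alpha + beta * x


def integrate_and_rank(df: pd.DataFrame, epsilon: float = LOG_EPSILON) -> pd.DataFrame:
    """Combine the three evidence scores and re-rank the PBRs.

    Adds columns x_c, x_p_rescaled, x_m_rescaled (NaN when the motif stage
    was skipped), combined, and rank (1 = most significant), and returns the
    frame sorted by rank.  PBRs with no motif hit must already carry
    ``p_m = 1``; a wholly absent/failed motif stage (p_m column missing or
    all-NaN) falls back to averaging x_c and rescaled x_p only.
    """
    out = df.reset_index(drop=True).copy()
    n = len(out)
    p_c = out["p_c"].to_numpy(dtype=float)
    if n < 3:
        warnings.warn("fewer than 3 PBRs; ranking by p_c alone", stacklevel=2)
        out["x_c"] = np.log(p_c) if n else np.zeros(0)
        out["x_p_rescaled"] = np.nan
        out["x_m_rescaled"] = np.nan
        out["combined"] = out["x_c"]
        out["rank"] = _ordinal_ranks(p_c)
        return out.sort_values("rank").reset_index(drop=True)

    x_c = np.log(p_c)
    x_p = np.log(out["d_p"].to_numpy(dtype=float) + epsilon)
    xc_sorted = np.sort(x_c)
    x_p_re = _quantile_ols_rescale(xc_sorted, x_p)

    p_m = out["p_m"].to_numpy(dtype=float) if "p_m" in out else np.full(n, np.nan)
    have_motif = np.isfinite(p_m).all() and len(p_m) == n
    if have_motif:
        x_m_re = _quantile_ols_rescale(xc_sorted, np.log(p_m))
        combined = (x_c + x_p_re + x_m_re) / 3.0
    else:
        if np.isfinite(p_m).any():
            raise ValueError("p_m must be present for all PBRs or for none")
        warnings.warn(
            "motif evidence unavailable; combining count and pattern scores only",
            stacklevel=2,
        )
        x_m_re = np.full(n, np.nan)
        combined = (x_c + x_p_re) / 2.0

    out["x_c"] = x_c
    out["x_p_rescaled"] = x_p_re
    out["x_m_rescaled"] = x_m_re
    out["combined"] = combined
    order = np.lexsort((np.arange(n), p_c, combined))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(1, n + 1)
    out["rank"] = rank
    return out.sort_values("rank").reset_index(drop=True)


def count_only_ranking(df: pd.DataFrame) -> pd.DataFrame:
    """Baseline ranking by the count p-value alone (ties: genomic order)."""
    out = df.reset_index(drop=True).copy()
    out["rank"] = _ordinal_ranks(out["p_c"].to_numpy(dtype=float))
    return out.sort_values("rank").reset_index(drop=True)


def significant_count(
    n_pbr: int, alpha: float, rounding: str = "half_away_from_zero"
) -> int:
    """Size of the significant set: (1 - alpha) * N rounded per the rule."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if rounding not in ROUNDING_RULES:
        raise ValueError(f"rounding must be one of {ROUNDING_RULES}")
    x = (1.0 - alpha) * n_pbr
    if rounding == "half_away_from_zero":
        return int(np.floor(x + 0.5))
    return int(np.floor(x))


def select_significant(
    ranked: pd.DataFrame, alpha: float, rounding: str = "half_away_from_zero"
) -> pd.DataFrame:
    """Flag the top (1 - alpha) fraction of the re-ranked PBRs."""
    out = ranked.copy()
    n_sig = significant_count(len(out), alpha, rounding)
    out["significant"] = out["rank"] <= n_sig
    return out
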