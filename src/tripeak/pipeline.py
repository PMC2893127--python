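"""End-to-end orchestration of the six-stage peak-calling pipeline.

bin -> fit background -> eFDR threshold -> PBRs -> strand profiles & peak
p-values -> pattern dissimilarities -> high-quality selection -> motif
discovery -> motif scan -> evidence integration -> significant-set
selection.  All randomness derives from one configured seed; rerunning with
identical inputs and configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .countmodel import (
    PBR,
    FitReport,
    GammaPoissonModel,
    PoissonModel,
    bin_counts,
    efdr_table,
    fit_background,
    select_pbrs,
    select_threshold,
)
from .integrate import (
    RegionScores,
    count_only_ranking,
    integrate_and_rank,
    select_high_quality,
    select_significant,
)
from .motif import MotifResult, accept_motif, extract_site_sequences, scan_pvalue, zoops_em
from .patternmatch import (
    ReferencePattern,
    SimRefConfig,
    dissimilarity,
    load_or_build_reference,
    observed_pattern,
)
from .profilescan import (
    DegenerateProfileError,
    TagIndex,
    locate_peaks,
    peak_pvalue,
    window_profile,
)
from .tagio import (
    GenomeTable,
    Region,
    ScoredRegion,
    TagRecord,
    deduplicate_tags,
    read_tags,
    write_scored_regions,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Tunable parameters of one pipeline run."""

    d: int = 250                      # maximum fragment size (bp); bin & window width
    alpha: float = 0.5                # pre-specified empirical FDR level
    n_high_quality: int = 200         # regions fed to motif discovery (<= 500)
    motif_width: int = 9
    flank: int = 20                   # bp of sequence kept around each peak site
    em_starts: int = 5
    min_motif_fraction: float = 0.25
    rounding: str = "half_away_from_zero"
    motif_enabled: bool = True
    ref_n_fragments: int = 3_000_000  # reference-pattern simulation size
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_high_quality > 500:
            raise ValueError("n_high_quality must not exceed 500")
        if self.d <= 0:
            raise ValueError("d must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    table: pd.DataFrame           # one row per PBR, ranked, with all scores
    gp_model: GammaPoissonModel
    poisson_model: PoissonModel
    fit_report: FitReport
    efdr: pd.DataFrame
    k_star: int
    reference: ReferencePattern
    motif: MotifResult | None
    motif_accepted: bool
    manifest: dict


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(msg: str) -> None:
    print(f"[tripeak] {msg}", file=sys.stderr)


def score_regions(
    tags: Sequence[TagRecord],
    genome: GenomeTable,
    config: PipelineConfig,
    cache_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, PipelineResult]:
    """Stages 1-3: count model, PBRs, profiles, patterns.

    Returns the per-PBR score frame (genomic order, columns chrom, start,
    end, tag_count, peak_pos, site_estimate, peak_count, p_c, d_p) plus a
    partially filled :class:`PipelineResult` (motif fields empty).
    """
    t0 = time.monotonic()
    tags, n_dup = deduplicate_tags(list(tags))
    per_bin, hist = bin_counts(tags, genome, config.d)
    try:
        gp, pois, report = fit_background(hist)
    except Exception as exc:
        raise StageError(f"background-fit stage failed: {exc}") from exc
    table = efdr_table(gp, hist)
    k_star = select_threshold(table, config.alpha)
    pbrs = select_pbrs(per_bin, k_star, config.d, genome)
    _log(
        f"binned {len(tags)} tags ({n_dup} duplicates removed); "
        f"k*={k_star}, {len(pbrs)} PBRs [{time.monotonic() - t0:.1f}s]"
    )

    ref = load_or_build_reference(
        SimRefConfig(
            n_fragments=config.ref_n_fragments, d=config.d, seed=config.seed
        ),
        cache_dir,
    )
    index = TagIndex.from_tags(tags)
    rows = []
    for pbr in pbrs:
        profile = window_profile(index, pbr, config.d, genome)
        try:
            peak = locate_peaks(profile)
            p_c = peak_pvalue(gp, peak)
            d_p = dissimilarity(observed_pattern(profile), ref)
            rows.append(
                (
                    pbr.region.chrom, pbr.region.start, pbr.region.end,
                    pbr.tag_count, peak.peak_pos, peak.site_estimate,
                    peak.peak_count, p_c, d_p,
                )
            )
        except DegenerateProfileError:
            rows.append(
                (
                    pbr.region.chrom, pbr.region.start, pbr.region.end,
                    pbr.tag_count, pbr.region.start, pbr.region.start,
                    0, 1.0, ref.max_dissimilarity,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "tag_count", "peak_pos",
            "site_estimate", "peak_count", "p_c", "d_p",
        ],
    )
    partial = PipelineResult(
        table=df,
        gp_model=gp,
        poisson_model=pois,
        fit_report=report,
        efdr=table,
        k_star=k_star,
        reference=ref,
        motif=None,
        motif_accepted=False,
        manifest={"n_tags": len(tags), "n_duplicates_removed": n_dup,
                  "n_windows": hist.n_total, "k_star": k_star,
                  "n_pbrs": len(pbrs)},
    )
    return df, partial


def attach_motif_scores(
    df: pd.DataFrame,
    fasta_path: str | Path,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, MotifResult | None, bool]:
    """Stages 4-5: discover the motif on high-quality regions, scan all PBRs.

    Returns the frame with a ``p_m`` column (all-1.0 fallback when no motif
    reaches the acceptance fraction), the EM result, and the accepted flag.
    """
    from pyfaidx import Fasta

    if df.empty:
        out = df.copy()
        out["p_m"] = np.zeros(0)
        return out, None, False
    hq = select_high_quality(df, min(config.n_high_quality, 500))
    sites = [
        (f"{r.chrom}:{r.start}-{r.end}", r.chrom, int(r.site_estimate))
        for r in hq.itertuples()
    ]
    seqs = extract_site_sequences(fasta_path, sites, flank=config.flank)
    usable = [s for s in seqs if len(s.sequence) >= config.motif_width]
    if not usable:
        raise StageError("motif stage failed: no usable site sequences")
    result = zoops_em(
        usable,
        w=config.motif_width,
        n_starts=config.em_starts,
        seed=config.seed,
    )
    accepted = accept_motif(result, config.min_motif_fraction)
    out = df.copy()
    if not accepted:
        _log(
            f"motif rejected (contained in {result.fraction_containing:.1%} "
            f"< {config.min_motif_fraction:.0%} of sequences); p_m fallback = 1"
        )
        out["p_m"] = 1.0
        return out, result, False
    fasta = Fasta(str(fasta_path))
    p_m = []
    for r in df.itertuples():
        seq = str(fasta[r.chrom][r.start : r.end])
        if len(seq) < config.motif_width:
            p_m.append(1.0)
        else:
            p_m.append(scan_pvalue(result.pssm, seq).p_value)
    out["p_m"] = p_m
    return out, result, accepted


def run_pipeline(
    tags_path: str | Path,
    genome_path: str | Path,
    config: PipelineConfig,
    fasta_path: str | Path | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline from files; optionally write all artifacts."""
    genome = GenomeTable.from_file(genome_path)
    tags = read_tags(tags_path, genome)
    if config.motif_enabled and fasta_path is None:
        raise StageError(
            "motif stage enabled but no genome FASTA given "
            "(pass one or disable the motif stage)"
        )
    df, result = score_regions(tags, genome, config, cache_dir=outdir)
    motif_result, accepted = None, False
    if config.motif_enabled:
        try:
            df, motif_result, accepted = attach_motif_scores(df, fasta_path, config)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"motif stage failed: {exc}") from exc
    ranked = integrate_and_rank(df)
    ranked = select_significant(ranked, config.alpha, config.rounding)
    result.table = ranked
    result.motif = motif_result
    result.motif_accepted = accepted

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {
            "tags": {"path": str(tags_path), "sha256": _checksum(tags_path)},
            "genome": {"path": str(genome_path), "sha256": _checksum(genome_path)},
            **(
                {"fasta": {"path": str(fasta_path), "sha256": _checksum(fasta_path)}}
                if fasta_path
                else {}
            ),
        },
        **result.manifest,
        "n_high_quality": (
            min(config.n_high_quality, len(df)) if config.motif_enabled else 0
        ),
        "motif_accepted": accepted,
        "motif_fraction": (
            motif_result.fraction_containing if motif_result else None
        ),
        "motif_consensus": (
            motif_result.pssm.consensus if motif_result and accepted else None
        ),
        "n_significant": int(ranked["significant"].sum()),
        "complete": True,
    }
    result.manifest = manifest

    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ranked = result.table
    rows = [
        ScoredRegion(
            region=Region(r.chrom, int(r.start), int(r.end)),
            rank=int(r.rank),
            combined=float(r.combined),
            p_c=float(r.p_c),
            d_p=float(r.d_p),
            p_m=float(r.p_m) if "p_m" in ranked.columns else None,
        )
        for r in ranked.itertuples()
    ]
    write_scored_regions(rows, outdir / "regions.bed")
    audit = ranked.copy()
    audit.to_csv(outdir / "audit.tsv", sep="\t", index=False, float_format="%.8g")
    result.efdr.to_csv(outdir / "efdr.tsv", sep="\t", index=False, float_format="%.8g")
    result.reference.to_tsv(outdir / "reference_pattern.tsv")
    if result.motif is not None and result.motif_accepted:
        (outdir / "motif.txt").write_text(
            result.motif.pssm.to_meme_text(
                nsites=int(result.motif.posteriors.sum()) or 1
            )
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def decoy_comparison(
    ranked: pd.DataFrame, decoy_chrom: str, top_n: int | None = None
) -> dict:
    """False-positive surrogate comparison of the full three-evidence
    ranking against the count-only baseline (same regions, same top-N)."""
    from .diagnostics import absent_chromosome_rate

    baseline = count_only_ranking(ranked)
    n = int(ranked["significant"].sum()) if top_n is None else top_n
    full_curve = absent_chromosome_rate(ranked, decoy_chrom)
    base_curve = absent_chromosome_rate(baseline, decoy_chrom)
    return {
        "top_n": n,
        "decoy_in_top_combined": int(full_curve[n - 1]) if n else 0,
        "decoy_in_top_count_only": int(base_curve[n - 1]) if n else 0,
        "combined_curve": full_curve,
        "count_only_curve": base_curve,
        # cumulative-curve comparison along the whole ranked list: the
        # three-evidence ranking should accumulate decoy (false-positive
        # surrogate) regions no faster at any rank, and strictly slower
        # somewhere, than the count-only baseline
        "curve_dominates": bool(
            np.all(full_curve <= base_curve) and np.any(full_curve < base_curve)
        ),
        "curve_auc_combined": int(full_curve.sum()),
        "curve_auc_count_only": int(base_curve.sum()),
    }
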