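"""Fully labelled synthetic ChIP-Seq datasets for desk-scale testing.

The generator emulates the four mechanisms that can enrich tags in a region:

1. *true binding sites* -- fragments spanning a planted site are pulled down
   with a high probability (scaled by a per-site occupancy strength);
2. *focal amplification* -- copy-number-gain intervals multiply the
   retention probability of every overlapping fragment, producing high but
   strand-symmetric coverage;
3. *nonspecific binding* -- an optional Gamma-distributed rate multiplier
   per background segment over-disperses the background, which is exactly
   what makes the Gamma-Poisson background model appropriate;
4. *random noise* -- the uniform background retention floor.

A decoy chromosome receives only background-probability fragments (no sites,
no amplifications) and serves as an internal false-positive surrogate.  The
genome sequence is i.i.d. uniform A/C/G/T with a (possibly mutated) motif
consensus written at every planted site; every retained fragment emits one
5'-end tag from a uniformly chosen end.  Everything is reproducible from the
seed, and outputs are plain text (FASTA, BED6, TSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .tagio import FORWARD, REVERSE, GenomeTable, TagRecord, write_tags

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FocalAmplification:
    """A copy-number-gain interval multiplying fragment retention."""

    chrom: str
    start: int
    end: int
    fold: float


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    pos: int
    strength: float
    strand: str
    motif_instance: str


@dataclass(frozen=True)
class DatasetConfig:
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 250_000),
        ("chr2", 250_000),
        ("chr3", 250_000),
        ("chrDecoy", 250_000),
    )
    n_sites: int = 10
    motif_consensus: str = "TTCCGGGAA"
    mutation_rate: float = 0.1
    p_site: float = 1.5e-2
    p_background: float = 5e-4
    site_strength_range: tuple[float, float] = (0.6, 1.0)
    background_gamma_shape: float | None = 5.0
    background_segment: int = 250
    # nonspecific-binding hotspots: a small fraction of background segments
    # with multiplicatively elevated retention (decoy included -- they are
    # background, not binding); they put spurious high-count regions into
    # the candidate list exactly as nonspecific binding does in real data
    hotspot_fraction: float = 0.01
    hotspot_fold_range: tuple[float, float] = (3.0, 10.0)
    fragment_length: tuple[int, int] = (150, 250)
    n_fragments: int = 20_000_000
    confounders: tuple[FocalAmplification, ...] = (
        FocalAmplification("chr1", 103_050, 104_050, 8.0),
        FocalAmplification("chr2", 50_950, 51_950, 8.0),
    )
    decoy_chrom: str | None = "chrDecoy"
    seed: int = 1

    def validate(self) -> None:
        names = [n for n, _ in self.genome]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate chromosome names")
        lengths = dict(self.genome)
        if self.decoy_chrom is not None and self.decoy_chrom not in lengths:
            raise ConfigError("decoy chromosome not in genome")
        for c in self.confounders:
            if c.chrom not in lengths:
                raise ConfigError(f"confounder on unknown chromosome {c.chrom!r}")
            if not (0 <= c.start < c.end <= lengths[c.chrom]):
                raise ConfigError("confounder interval outside chromosome")
            if c.chrom == self.decoy_chrom:
                raise ConfigError("decoy chromosome must stay background-only")
            if c.fold <= 0:
                raise ConfigError("amplification fold must be positive")
        if not (0 < self.p_background <= self.p_site < 1):
            raise ConfigError("require 0 < p_background <= p_site < 1")
        lo, hi = self.fragment_length
        if not (0 < lo <= hi <= min(l for _, l in self.genome)):
            raise ConfigError("fragment length range must fit every chromosome")
        if not (0 <= self.mutation_rate < 1):
            raise ConfigError("mutation rate must be in [0, 1)")
        if self.n_sites < 0 or self.n_fragments <= 0:
            raise ConfigError("n_sites and n_fragments must be non-negative/positive")


def default_config(seed: int = 1) -> DatasetConfig:
    """The canonical desk-scale fixture: 3 x 250 kb chromosomes plus a
    250 kb decoy, 10 sites of graded occupancy, 2 focal amplifications.

    Chromosome lengths keep signal windows below 1% of all windows -- the
    background-dominance regime the count model assumes and real
    whole-genome data exhibits.  Pull-down probabilities are ten times the
    reference-simulation values with their 20:1 enrichment ratio preserved,
    so that realistic per-site and per-window tag yields are reached with a
    tractable fragment count.
    """
    return DatasetConfig(seed=seed)


def pattern_benchmark_config(seed: int = 1) -> DatasetConfig:
    """A labelled benchmark with 50 binding sites and 50 amplification
    intervals on disjoint chromosomes, for pattern-discrimination studies.

    Pull-down probabilities are scaled up tenfold (site:background ratio
    preserved) so the per-region tag yield matches the default fixture at a
    tractable fragment count; the background is homogeneous so every amp
    region is purely the copy-number mechanism.
    """
    site_chroms = tuple((f"chrS{i}", 30_000) for i in range(1, 5))
    amp_chroms = tuple((f"chrA{i}", 30_000) for i in range(1, 5))
    amps = []
    for ci, (name, length) in enumerate(amp_chroms):
        k = 13 if ci < 2 else 12
        for j in range(k):
            start = 1000 + j * (length - 2000) // k
            amps.append(FocalAmplification(name, start, start + 800, 8.0))
    return DatasetConfig(
        genome=site_chroms + amp_chroms,
        n_sites=50,
        site_strength_range=(1.0, 1.0),
        background_gamma_shape=None,
        p_site=1e-2,
        p_background=5e-4,
        n_fragments=5_000_000,
        confounders=tuple(amps[:50]),
        decoy_chrom=None,
        seed=seed,
    )


def _allowed_segments(
    length: int, confounders: Sequence[FocalAmplification], chrom: str,
    margin: int, buffer: int,
) -> list[tuple[int, int]]:
    """Sub-intervals of [margin, length - margin) clear of confounders."""
    blocked = sorted(
        (max(0, c.start - buffer), min(length, c.end + buffer))
        for c in confounders
        if c.chrom == chrom
    )
    segments = []
    cursor = margin
    for b0, b1 in blocked:
        if b0 > cursor:
            segments.append((cursor, min(b0, length - margin)))
        cursor = max(cursor, b1)
    if cursor < length - margin:
        segments.append((cursor, length - margin))
    return [(a, b) for a, b in segments if b > a]


def _place_sites(config: DatasetConfig, rng: np.random.Generator) -> list[PlantedSite]:
    non_decoy = [
        (n, l) for n, l in config.genome if n != config.decoy_chrom
    ]
    if not non_decoy and config.n_sites > 0:
        raise ConfigError("no non-decoy chromosome to place sites on")
    # distribute sites over chromosomes proportionally (round-robin remainder)
    per_chrom = {n: config.n_sites // len(non_decoy) for n, _ in non_decoy}
    for i in range(config.n_sites % len(non_decoy)):
        per_chrom[non_decoy[i][0]] += 1
    lo_s, hi_s = config.site_strength_range
    strengths = (
        np.linspace(lo_s, hi_s, config.n_sites) if config.n_sites > 1
        else np.array([hi_s])
    )
    w = len(config.motif_consensus)
    sites: list[PlantedSite] = []
    k = 0
    for name, length in non_decoy:
        m = per_chrom[name]
        if m == 0:
            continue
        segments = _allowed_segments(length, config.confounders, name,
                                     margin=400, buffer=400)
        total = sum(b - a for a, b in segments)
        if total < m * (w + 20):
            raise ConfigError(f"not enough room for {m} sites on {name}")
        for j in range(m):
            # position at evenly spaced arc-length fractions of allowed room
            offset = int(total * (j + 1) / (m + 1))
            for a, b in segments:
                if offset < b - a:
                    pos = a + offset
                    break
                offset -= b - a
            instance = _mutate(config.motif_consensus, config.mutation_rate, rng)
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            sites.append(PlantedSite(name, pos, float(strengths[k]), strand, instance))
            k += 1
    return sites


def _mutate(consensus: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for b in consensus:
        if rng.random() < rate:
            choices = [c for c in "ACGT" if c != b]
            out.append(choices[int(rng.integers(3))])
        else:
            out.append(b)
    return "".join(out)


@dataclass
class Dataset:
    config: DatasetConfig
    genome: GenomeTable
    sequences: dict[str, str]
    tags: list[TagRecord]
    sites: list[PlantedSite]
    confounders: tuple[FocalAmplification, ...]
    n_fragments_retained: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Materialize FASTA, BED6 tags, genome table, and truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "tags": outdir / "tags.bed",
            "genome": outdir / "genome.tsv",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for name in self.genome:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        write_tags(self.tags, paths["tags"], self.genome)
        self.genome.to_file(paths["genome"])
        with open(paths["truth"], "w") as fh:
            fh.write("#type\tchrom\tstart\tend\tdetail\n")
            for s in self.sites:
                fh.write(
                    f"site\t{s.chrom}\t{s.pos}\t{s.pos + len(s.motif_instance)}\t"
                    f"strength={s.strength:.4f};strand={s.strand};"
                    f"instance={s.motif_instance}\n"
                )
            for c in self.confounders:
                fh.write(
                    f"amplification\t{c.chrom}\t{c.start}\t{c.end}\tfold={c.fold}\n"
                )
        return paths


def generate_dataset(config: DatasetConfig) -> Dataset:
    """Generate genome sequence, tags, and truth labels from *config*."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = GenomeTable(config.genome)
    names = genome.names
    lengths = np.array([genome[n] for n in names], dtype=np.int64)

    # genome sequence with planted (possibly mutated) motif instances
    sites = _place_sites(config, rng) if config.n_sites else []
    sequences: dict[str, str] = {}
    for name in names:
        arr = _BASES[rng.integers(0, 4, size=genome[name])]
        sequences[name] = "".join(arr)
    for s in sites:
        instance = (
            s.motif_instance
            if s.strand == FORWARD
            else s.motif_instance.translate(_COMP)[::-1]
        )
        seq = sequences[s.chrom]
        sequences[s.chrom] = (
            seq[: s.pos] + instance + seq[s.pos + len(instance) :]
        )

    # per-segment nonspecific-binding rate multipliers
    seg = config.background_segment
    multipliers = {}
    for n_name in names:
        size = -(-genome[n_name] // seg)
        if config.background_gamma_shape is not None:
            a = config.background_gamma_shape
            m = rng.gamma(a, 1.0 / a, size=size)
        else:
            m = np.ones(size)
        if config.hotspot_fraction > 0:
            hot = rng.random(size) < config.hotspot_fraction
            lo_f, hi_f = config.hotspot_fold_range
            m = np.where(hot, m * rng.uniform(lo_f, hi_f, size=size), m)
        multipliers[n_name] = m

    # fragments
    n = config.n_fragments
    lo, hi = config.fragment_length
    chrom_idx = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    L = rng.integers(lo, hi + 1, size=n)
    start = (rng.random(n) * (lengths[chrom_idx] - L + 1)).astype(np.int64)
    u_keep = rng.random(n)
    u_end = rng.random(n)

    site_pos: dict[str, np.ndarray] = {}
    site_strength: dict[str, np.ndarray] = {}
    for name in names:
        cs = [s for s in sites if s.chrom == name]
        cs.sort(key=lambda s: s.pos)
        site_pos[name] = np.array([s.pos for s in cs], dtype=np.int64)
        site_strength[name] = np.array([s.strength for s in cs])

    tags: list[TagRecord] = []
    n_retained = 0
    for ci, name in enumerate(names):
        mask = chrom_idx == ci
        if not mask.any():
            continue
        s_c, L_c = start[mask], L[mask]
        p = config.p_background * multipliers[name][s_c // seg]
        sp = site_pos[name]
        if sp.size:
            # fragment spans a site iff some planted position lies in [s, s+L)
            lo_i = np.searchsorted(sp, s_c, "left")
            hi_i = np.searchsorted(sp, s_c + L_c, "left")
            spans = hi_i > lo_i
            p = np.where(
                spans,
                config.p_site * site_strength[name][np.minimum(lo_i, sp.size - 1)],
                p,
            )
        for c in config.confounders:
            if c.chrom != name:
                continue
            overlap = (s_c < c.end) & (s_c + L_c > c.start)
            p = np.where(overlap, p * c.fold, p)
        keep = u_keep[mask] < p
        n_retained += int(keep.sum())
        fwd = u_end[mask][keep] < 0.5
        ks, kL = s_c[keep], L_c[keep]
        for pos in ks[fwd]:
            tags.append(TagRecord(name, int(pos), FORWARD))
        for pos, l in zip(ks[~fwd], kL[~fwd]):
            tags.append(TagRecord(name, int(pos + l - 1), REVERSE))

    tags.sort(key=lambda t: (names.index(t.chrom), t.pos, t.strand))
    return Dataset(
        config=config,
        genome=genome,
        sequences=sequences,
        tags=tags,
        sites=sites,
        confounders=config.confounders,
        n_fragments_retained=n_retained,
    )
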