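"""Synthetic genomes, tag libraries, TSS tables and peak sets.

The generator emulates the statistical structure the analyses assume:
21-23 nt tags placed as a homogeneous Poisson background over a
multi-chromosome genome, optional spiked windows where the tag intensity
is multiplied, a TSS table whose promoters carry ChIP-seq-style peaks
with a configurable probability, and an optional coupling between peak
status and tag rate (coupling = 1 means independence — the null regime).
A fraction of tags carries multimap weight 0.5.

Everything is a pure function of :class:`ScenarioConfig`, including the
seed, so a scenario regenerates byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
import yaml

from .genomic_io import (
    GenomeLayout,
    GenomicInterval,
    TagAlignment,
    TagLibrary,
    TssRecord,
    format_region,
    parse_region,
    write_bed,
    write_chrom_sizes,
    write_tss_table,
)

__all__ = [
    "DEFAULT_CHROMOSOMES",
    "DEFAULT_QUERY_LENGTH",
    "ScenarioConfig",
    "Scenario",
    "generate_genome",
    "generate_tags",
    "generate_tss_and_peaks",
    "simulate_scenario",
    "default_config",
]

# 20 Mb over four chromosomes: the desk-scale stand-in for a fly genome.
DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chr2L", 6_000_000),
    ("chr2R", 5_500_000),
    ("chr3L", 4_500_000),
    ("chr3R", 4_000_000),
)

# the Bithorax-Complex-sized query window
DEFAULT_QUERY_LENGTH = 340_000


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic scenario.

    background_rate is the Poisson intensity in tags per bp
    (5e-4 over 20 Mb gives ~1e4 tags, a desk-scale library).
    spikes are (interval, multiplier f >= 1) pairs: inside a spike the
    intensity is f * background_rate. coupling multiplies the intensity
    inside peak-bearing promoter windows (1.0 = independence).
    """

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = DEFAULT_CHROMOSOMES
    background_rate: float = 5e-4
    tag_length_range: tuple[int, int] = (21, 23)
    spikes: tuple[tuple[GenomicInterval, float], ...] = ()
    n_tss: int = 1000
    peak_prob: float = 0.5
    coupling: float = 1.0
    multimap_frac: float = 0.1
    flank: int = 50

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        if self.background_rate < 0 or not np.isfinite(self.background_rate):
            raise ValueError(f"background_rate must be finite and >= 0")
        lo, hi = self.tag_length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad tag_length_range {self.tag_length_range}")
        if not (0.0 <= self.peak_prob <= 1.0):
            raise ValueError(f"peak_prob must be in [0, 1], got {self.peak_prob}")
        if self.coupling < 0:
            raise ValueError(f"coupling must be >= 0, got {self.coupling}")
        if not (0.0 <= self.multimap_frac <= 1.0):
            raise ValueError(f"multimap_frac must be in [0, 1]")
        if self.n_tss < 1:
            raise ValueError(f"n_tss must be >= 1, got {self.n_tss}")
        layout = GenomeLayout.from_pairs(self.chromosomes)  # raises on dupes/0-length
        for iv, mult in self.spikes:
            layout.validate_interval(iv)
            if mult < 1:
                raise ValueError(f"spike multiplier must be >= 1, got {mult}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "chromosomes" in raw:
            raw["chromosomes"] = tuple(
                (str(n), int(l)) for n, l in raw["chromosomes"]
            )
        if "spikes" in raw:
            raw["spikes"] = tuple(
                (parse_region(s["region"]), float(s["multiplier"]))
                for s in raw["spikes"]
            )
        if "tag_length_range" in raw:
            raw["tag_length_range"] = tuple(raw["tag_length_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "chromosomes": [[n, l] for n, l in self.chromosomes],
            "background_rate": self.background_rate,
            "tag_length_range": list(self.tag_length_range),
            "spikes": [
                {"region": format_region(iv), "multiplier": mult}
                for iv, mult in self.spikes
            ],
            "n_tss": self.n_tss,
            "peak_prob": self.peak_prob,
            "coupling": self.coupling,
            "multimap_frac": self.multimap_frac,
            "flank": self.flank,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_config(seed: int = 0, **overrides) -> ScenarioConfig:
    """The default desk-scale scenario with field overrides."""
    return ScenarioConfig(seed=seed, **overrides)


def generate_genome(config: ScenarioConfig) -> GenomeLayout:
    """Layout exactly as configured (validation happens in the config)."""
    return GenomeLayout.from_pairs(config.chromosomes)


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per generation stage
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream])


def _place_tags(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    clen: int,
    len_range: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """n tags with start uniform in [lo, hi) and length uniform in len_range,
    clipped so tags never leave the chromosome."""
    lengths = rng.integers(len_range[0], len_range[1] + 1, size=n)
    starts = rng.integers(lo, hi, size=n)
    starts = np.minimum(starts, clen - lengths)
    starts = np.maximum(starts, 0)
    return starts, lengths


def generate_tags(
    config: ScenarioConfig,
    layout: GenomeLayout,
    extra_elevated: tuple[tuple[GenomicInterval, float], ...] = (),
) -> TagLibrary:
    """Poisson background plus superposed extra tags in elevated regions.

    Inside an elevated region (a configured spike, or a peak-bearing
    promoter window passed by the scenario driver) with multiplier f the
    intensity is exactly f * background_rate: the extra count is
    Poisson((f - 1) * rate * region_length) on top of the background that
    already covers the region. Elevated regions are assumed (effectively)
    disjoint.
    """
    rng = _rng(config, 1)
    lam = config.background_rate
    len_range = config.tag_length_range
    elevated = tuple(config.spikes) + tuple(extra_elevated)
    tags: list[TagAlignment] = []
    all_starts: list[np.ndarray] = []
    parts: list[tuple[str, np.ndarray, np.ndarray]] = []
    for chrom, clen in layout.chromosomes:
        n_bg = rng.poisson(lam * clen)
        starts, lengths = _place_tags(rng, n_bg, 0, clen, clen, len_range)
        parts.append((chrom, starts, lengths))
        for iv, mult in elevated:
            if iv.chrom != chrom or mult == 1.0:
                continue
            n_extra = rng.poisson((mult - 1.0) * lam * iv.length)
            s, l = _place_tags(rng, n_extra, iv.start, iv.end, clen, len_range)
            parts.append((chrom, s, l))
    n_total = sum(len(s) for _, s, _ in parts)
    weights = np.where(rng.random(n_total) < config.multimap_frac, 0.5, 1.0)
    k = 0
    for chrom, starts, lengths in parts:
        for s, l in zip(starts, lengths):
            tags.append(
                TagAlignment(
                    GenomicInterval(chrom, int(s), int(s + l)), float(weights[k])
                )
            )
            k += 1
    return TagLibrary(tags)


def _sample_distinct(rng: np.random.Generator, total: int, n: int) -> np.ndarray:
    """n distinct integers uniform over [0, total) without materializing
    a permutation of the full range."""
    if n > total:
        raise ValueError(f"cannot draw {n} distinct positions from {total}")
    if total <= 4 * n:
        return rng.permutation(total)[:n]
    chosen: set[int] = set()
    out: list[int] = []
    while len(out) < n:
        draw = rng.integers(0, total, size=2 * (n - len(out)))
        for v in draw:
            v = int(v)
            if v not in chosen:
                chosen.add(v)
                out.append(v)
                if len(out) == n:
                    break
    return np.array(out, dtype=np.int64)


def generate_tss_and_peaks(
    config: ScenarioConfig, layout: GenomeLayout
) -> tuple[list[TssRecord], list[GenomicInterval], pd.DataFrame]:
    """TSS positions uniform without replacement; peaks on a coin flip.

    TSS are placed so their full +/-flank windows fit inside the
    chromosome. Each promoter carries a peak (the promoter window itself)
    with probability peak_prob; the truth table records every promoter's
    class and its tag-rate multiplier (coupling if bound, else 1).
    """
    rng = _rng(config, 2)
    flank = config.flank
    spans = [(chrom, clen, max(0, clen - 2 * flank)) for chrom, clen in layout.chromosomes]
    total = sum(s for _, _, s in spans)
    if config.n_tss > total:
        raise ValueError(
            f"n_tss={config.n_tss} exceeds the {total} placeable TSS positions"
        )
    offsets = np.sort(_sample_distinct(rng, total, config.n_tss))
    strands = np.where(rng.random(config.n_tss) < 0.5, "+", "-")
    bound = rng.random(config.n_tss) < config.peak_prob
    tss: list[TssRecord] = []
    peaks: list[GenomicInterval] = []
    truth_rows = []
    cum = 0
    digits = len(str(config.n_tss))
    i = 0
    for chrom, clen, span in spans:
        in_chrom = offsets[(offsets >= cum) & (offsets < cum + span)] - cum
        for off in in_chrom:
            position0 = flank + int(off)
            gene_id = f"g{i + 1:0{digits}d}"
            rec = TssRecord(chrom, position0 + 1, str(strands[i]), gene_id)
            tss.append(rec)
            window = GenomicInterval(chrom, position0 - flank, position0 + flank + 1)
            if bound[i]:
                peaks.append(window)
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "position": rec.position,
                    "strand": rec.strand,
                    "window_start": window.start,
                    "window_end": window.end,
                    "pcg_bound": bool(bound[i]),
                    "rate_multiplier": config.coupling if bound[i] else 1.0,
                }
            )
            i += 1
        cum += span
    return tss, peaks, pd.DataFrame(truth_rows)


@dataclass
class Scenario:
    """One fully generated scenario, ready for the analyses or for disk."""

    config: ScenarioConfig
    layout: GenomeLayout
    library: TagLibrary
    tss: list[TssRecord]
    peaks: list[GenomicInterval]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.layout, outdir / "chrom.sizes")
        write_bed(self.library, outdir / "tags.bed")
        write_tss_table(self.tss, outdir / "tss.tsv")
        write_bed(self.peaks, outdir / "peaks.bed")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth.to_dict(orient="records"), fh, indent=1)
        self.config.to_yaml(outdir / "scenario.yaml")


def simulate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate genome, TSS/peaks, then tags (so peak-coupling can raise
    the tag rate inside bound promoter windows)."""
    layout = generate_genome(config)
    tss, peaks, truth = generate_tss_and_peaks(config, layout)
    elevated: tuple[tuple[GenomicInterval, float], ...] = ()
    if config.coupling != 1.0:
        elevated = tuple(
            (GenomicInterval(r.chrom, int(r.window_start), int(r.window_end)), config.coupling)
            for r in truth.itertuples()
            if r.pcg_bound
        )
    library = generate_tags(config, layout, extra_elevated=elevated)
    return Scenario(config, layout, library, tss, peaks, truth)
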