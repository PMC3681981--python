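"""Randomized-window enrichment test with exclusion-aware placement.

The question: is a query region (e.g. the ~340 kb Bithorax Complex)
enriched for weighted small-RNA tags relative to same-sized windows
placed uniformly at random across the genome? The null is built by
enumerating *every* valid start position for a window of the query's
length — excluding, by default, the query region itself — and sampling
starts uniformly over that exact space (with replacement across trials).
This reproduces the intended semantics of shuffleBed-style
randomization without rejection sampling: unbiased and never hanging,
whatever the exclusion geometry.

The empirical upper-tail p-value uses the add-one permutation estimator
(r + 1) / (n + 1), with ties counted as "at least as extreme". The
source study reports only visual consistency with the null histogram;
the p-value here is an addition and is labelled as such in output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomic_io import GenomeLayout, GenomicInterval
from .srna_quant import TagCountIndex
from .genomic_io import TagLibrary

__all__ = [
    "PlacementSpace",
    "EnrichmentResult",
    "build_placement_space",
    "sample_placement",
    "sample_placements",
    "empirical_p",
    "run_region_null",
    "random_window",
]


@dataclass(frozen=True)
class PlacementSpace:
    """Exact enumeration of valid window starts, stored as maximal gaps.

    Each gap is (chrom, lo, hi): every integer start s in [lo, hi) puts a
    window [s, s + window_length) inside the chromosome and clear of all
    exclusions. total_starts is the number of valid starts genome-wide.
    """

    window_length: int
    gaps: tuple[tuple[str, int, int], ...]
    total_starts: int

    def starts_on(self, chrom: str) -> int:
        return sum(hi - lo for c, lo, hi in self.gaps if c == chrom)

    def iter_starts(self):
        """Iterate every (chrom, start); intended for small toy spaces."""
        for chrom, lo, hi in self.gaps:
            for s in range(lo, hi):
                yield chrom, s


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def build_placement_space(
    layout: GenomeLayout,
    window_length: int,
    exclusions: tuple[GenomicInterval, ...] | list[GenomicInterval] = (),
) -> PlacementSpace:
    """Enumerate all starts s such that [s, s+L) fits the chromosome and
    overlaps no exclusion.

    A window starting at s overlaps exclusion [a, b) iff s < b and
    s + L > a, i.e. s in [a - L + 1, b - 1]; those starts are removed.
    Chromosomes shorter than the window contribute nothing.
    """
    if window_length < 1:
        raise ValueError(f"window_length must be >= 1, got {window_length}")
    gaps: list[tuple[str, int, int]] = []
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ex in exclusions:
        excl_by_chrom.setdefault(ex.chrom, []).append((ex.start, ex.end))
    for chrom, clen in layout.chromosomes:
        max_start = clen - window_length  # inclusive
        if max_start < 0:
            continue
        forbidden = []
        for a, b in excl_by_chrom.get(chrom, []):
            lo = max(0, a - window_length + 1)
            hi = min(b, max_start + 1)  # half-open on starts
            if lo < hi:
                forbidden.append((lo, hi))
        cursor = 0
        for lo, hi in _merge(forbidden):
            if cursor < lo:
                gaps.append((chrom, cursor, lo))
            cursor = max(cursor, hi)
        if cursor <= max_start:
            gaps.append((chrom, cursor, max_start + 1))
    total = sum(hi - lo for _, lo, hi in gaps)
    if total == 0:
        raise ValueError(
            f"no valid placement for a {window_length} bp window under the "
            f"given exclusions"
        )
    return PlacementSpace(window_length, tuple(gaps), total)


def sample_placements(
    space: PlacementSpace, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n starts uniform over the valid-start space (with replacement).

    Returns (chrom_index, start) arrays; chrom_index indexes space.gaps'
    chromosome of each draw. Uniformity over the flattened start space
    makes each chromosome's probability proportional to its valid-start
    count, as required.
    """
    sizes = np.array([hi - lo for _, lo, hi in space.gaps], dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    flat = rng.integers(0, space.total_starts, size=n)
    gap_idx = np.searchsorted(offsets, flat, side="right") - 1
    lo = np.array([g[1] for g in space.gaps], dtype=np.int64)
    starts = lo[gap_idx] + (flat - offsets[gap_idx])
    return gap_idx, starts


def sample_placement(
    space: PlacementSpace, rng: np.random.Generator
) -> GenomicInterval:
    """Draw one window uniform over all valid starts genome-wide."""
    gap_idx, starts = sample_placements(space, rng, 1)
    chrom = space.gaps[int(gap_idx[0])][0]
    s = int(starts[0])
    return GenomicInterval(chrom, s, s + space.window_length)


def empirical_p(observed: float, null_counts, tail: str = "upper") -> float:
    """Add-one empirical p: (#{null >= observed} + 1) / (n + 1).

    Ties count toward the numerator, so the estimate is never
    anti-conservative and lies in (0, 1].
    """
    if tail != "upper":
        raise ValueError(f"only the upper tail is defined, got {tail!r}")
    null_counts = np.asarray(null_counts, dtype=np.float64)
    if null_counts.size == 0:
        raise ValueError("null_counts must be non-empty")
    r = int(np.count_nonzero(null_counts >= observed))
    return (r + 1) / (null_counts.size + 1)


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed count vs the randomized-window null distribution."""

    query: GenomicInterval
    observed: float
    null_counts: np.ndarray
    n_trials: int
    empirical_p_upper: float
    seed: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray

    def to_dict(self) -> dict:
        from .genomic_io import format_region

        return {
            "query": format_region(self.query),
            "window_length": self.query.length,
            "observed": self.observed,
            "n_trials": self.n_trials,
            "empirical_p_upper": self.empirical_p_upper,
            "empirical_p_note": (
                "add-one upper-tail permutation estimate (r+1)/(n+1); "
                "an addition of this implementation, not a reported value"
            ),
            "seed": self.seed,
            "null_mean": float(self.null_counts.mean()),
            "null_sd": float(self.null_counts.std(ddof=1)) if self.n_trials > 1 else 0.0,
            "histogram": {
                "bin_edges": self.bin_edges.tolist(),
                "bin_counts": self.bin_counts.tolist(),
            },
            "null_counts": self.null_counts.tolist(),
        }


def _default_histogram(values: np.ndarray, observed: float):
    """Integer-width bins spanning the null and the observed value."""
    lo = int(np.floor(min(values.min(), observed)))
    hi = int(np.ceil(max(values.max(), observed))) + 1
    edges = np.arange(lo, hi + 1, dtype=np.float64)
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts


def run_region_null(
    library: TagLibrary,
    layout: GenomeLayout,
    query: GenomicInterval,
    n_trials: int = 10_000,
    exclusions: tuple[GenomicInterval, ...] | None = None,
    seed: int = 0,
    overlap_rule: str = "any_overlap",
    bin_edges: np.ndarray | None = None,
    index: TagCountIndex | None = None,
) -> EnrichmentResult:
    """Run the full randomized-window enrichment test.

    The window length equals the query length; exclusions default to the
    query itself. A single seeded generator drives all trials in order,
    so identical (inputs, seed) give a bit-identical result.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    layout.validate_interval(query)
    if exclusions is None:
        exclusions = (query,)
    space = build_placement_space(layout, query.length, exclusions)
    idx = index if index is not None else TagCountIndex(library)
    observed = idx.count(query, overlap_rule)
    rng = np.random.default_rng(seed)
    gap_idx, starts = sample_placements(space, rng, n_trials)
    null_counts = np.empty(n_trials, dtype=np.float64)
    gap_chroms = [g[0] for g in space.gaps]
    for gi in np.unique(gap_idx):
        mask = gap_idx == gi
        s = starts[mask]
        null_counts[mask] = idx.count_many(
            gap_chroms[int(gi)], s, s + space.window_length, overlap_rule
        )
    p = empirical_p(observed, null_counts)
    if bin_edges is None:
        edges, counts = _default_histogram(null_counts, observed)
    else:
        edges = np.asarray(bin_edges, dtype=np.float64)
        counts, edges = np.histogram(null_counts, bins=edges)
    return EnrichmentResult(
        query=query,
        observed=observed,
        null_counts=null_counts,
        n_trials=n_trials,
        empirical_p_upper=p,
        seed=seed,
        bin_edges=edges,
        bin_counts=counts,
    )


def random_window(
    layout: GenomeLayout, length: int, rng: np.random.Generator
) -> GenomicInterval:
    """A window of ``length`` placed uniformly over all valid starts."""
    space = build_placement_space(layout, length)
    return sample_placement(space, rng)
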