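import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from srnascan import GenomeLayout, GenomicInterval, TagAlignment, TagLibrary

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def toy_layout() -> GenomeLayout:
    return GenomeLayout.from_pairs([("chr1", 10_000), ("chr2", 5_000)])


def make_library(specs, library_total=None) -> TagLibrary:
    """specs: iterable of (chrom, start, end, weight)."""
    tags = [
        TagAlignment(GenomicInterval(c, s, e), w) for c, s, e, w in specs
    ]
    return TagLibrary(tags, library_total=library_total)


def random_library(rng: np.random.Generator, layout: GenomeLayout, n: int,
                   dyadic_weights=(1.0, 0.5, 0.25)) -> TagLibrary:
    """Random tags with dyadic weights so weighted sums are exact floats."""
    chroms = layout.chromosomes
    tags = []
    for _ in range(n):
        chrom, clen = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, 30))
        start = int(rng.integers(0, max(1, clen - length)))
        w = float(rng.choice(dyadic_weights))
        tags.append(TagAlignment(GenomicInterval(chrom, start, start + length), w))
    return TagLibrary(tags)


def brute_count(library: TagLibrary, region: GenomicInterval, rule: str) -> float:
    """All-pairs overlap-check oracle for weighted counting."""
    total = 0.0
    for tag in library.tags:
        iv = tag.interval
        if iv.chrom != region.chrom:
            continue
        if rule == "any_overlap":
            hit = iv.start < region.end and region.start < iv.end
        else:  # contained
            hit = region.start <= iv.start and iv.end <= region.end
        if hit:
            total += tag.weight
    return total


def brute_placement_starts(layout: GenomeLayout, window_length: int, exclusions):
    """Enumerate every valid (chrom, start) by direct checking."""
    valid = []
    for chrom, clen in layout.chromosomes:
        for s in range(0, clen - window_length + 1):
            w_start, w_end = s, s + window_length
            ok = all(
                not (ex.chrom == chrom and w_start < ex.end and ex.start < w_end)
                for ex in exclusions
            )
            if ok:
                valid.append((chrom, s))
    return valid


def brute_ks_D(x, y) -> float:
    """Exhaustive empirical-CDF evaluation at every pooled data point."""
    x, y = list(x), list(y)
    best = 0.0
    for t in sorted(set(x) | set(y)):
        fx = sum(v <= t for v in x) / len(x)
        fy = sum(v <= t for v in y) / len(y)
        best = max(best, abs(fx - fy))
    return best
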