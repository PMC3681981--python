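"""Promoter-class comparison of small-RNA load.

Promoters are symmetric windows around distinct RefSeq-style TSS
positions (default +/-50 nt, 101 bp total), classified as bound or
unbound by >= 1 bp overlap with a ChIP-seq peak set (e.g. PRC1/PcG
occupancy). Per-promoter weighted tag counts, normalized to tags per
ten million (tptm), are compared between the two classes with a
two-sample Kolmogorov-Smirnov test.

The K-S statistic is computed from the two empirical CDFs directly; the
p-value uses the asymptotic Kolmogorov distribution at effective sample
size n_x * n_y / (n_x + n_y). Zero-count promoters are retained in both
classes — discarding them would bias the comparison toward expressed
promoters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .genomic_io import GenomeLayout, GenomicInterval, TagLibrary, TssRecord
from .srna_quant import TagCountIndex, normalize_tpm

__all__ = [
    "PromoterWindow",
    "PromoterComparison",
    "define_promoters",
    "classify_by_peaks",
    "ks_two_sample",
    "compare_promoter_classes",
]


@dataclass(frozen=True)
class PromoterWindow:
    """A TSS-centred window; ``pcg_bound`` is assigned by classification."""

    interval: GenomicInterval
    gene_ids: tuple[str, ...]
    pcg_bound: bool | None = None

    @property
    def gene_id(self) -> str:
        return ",".join(self.gene_ids)


def define_promoters(
    tss: list[TssRecord],
    layout: GenomeLayout,
    flank: int = 50,
) -> list[PromoterWindow]:
    """One window [tss0 - flank, tss0 + flank + 1) per distinct (chrom, position).

    tss0 is the 0-based TSS coordinate; windows are clipped at chromosome
    edges, strand does not change the window (the flank is symmetric),
    and TSS records sharing a position collapse to one window with their
    gene ids concatenated.
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    by_pos: dict[tuple[str, int], list[str]] = {}
    for rec in tss:
        if rec.chrom not in layout:
            raise ValueError(f"unknown chromosome {rec.chrom!r}")
        clen = layout.length_of(rec.chrom)
        if rec.position > clen:
            raise ValueError(
                f"TSS {rec.gene_id} at {rec.chrom}:{rec.position} beyond "
                f"chromosome length {clen}"
            )
        by_pos.setdefault((rec.chrom, rec.position), []).append(rec.gene_id)
    chrom_order = {name: i for i, name in enumerate(layout.names)}
    windows: list[PromoterWindow] = []
    for (chrom, position) in sorted(by_pos, key=lambda k: (chrom_order[k[0]], k[1])):
        tss0 = position - 1
        clen = layout.length_of(chrom)
        start = max(0, tss0 - flank)
        end = min(clen, tss0 + flank + 1)
        gene_ids = tuple(sorted(set(by_pos[(chrom, position)])))
        windows.append(PromoterWindow(GenomicInterval(chrom, start, end), gene_ids))
    return windows


def classify_by_peaks(
    promoters: list[PromoterWindow],
    peaks: list[GenomicInterval],
) -> list[PromoterWindow]:
    """Set pcg_bound = True iff a window overlaps >= 1 peak by >= 1 bp.

    Peaks are merged per chromosome first, so the result is independent
    of peak input order and of overlapping/duplicated peaks.
    """
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for a, b in ivs:
            if ends and a <= ends[-1]:
                ends[-1] = max(ends[-1], b)
            else:
                starts.append(a)
                ends.append(b)
        merged[chrom] = (np.array(starts), np.array(ends))
    out = []
    for w in promoters:
        bound = False
        if w.interval.chrom in merged:
            starts, ends = merged[w.interval.chrom]
            # merged peaks are disjoint: the only candidate is the last
            # peak starting before the window's end
            i = int(np.searchsorted(starts, w.interval.end, side="left")) - 1
            bound = bool(i >= 0 and ends[i] > w.interval.start)
        out.append(replace(w, pcg_bound=bound))
    return out


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D = sup_t |F_x(t) - F_y(t)| over the empirical CDFs; p comes from the
    asymptotic Kolmogorov distribution evaluated at sqrt(n_x n_y /
    (n_x + n_y)) * D and is clamped to (0, 1]. Ties are handled exactly
    through right-continuous CDF evaluation at the pooled data points.
    """
    x = np.sort(np.asarray(x, dtype=np.float64))
    y = np.sort(np.asarray(y, dtype=np.float64))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / x.size
    cdf_y = np.searchsorted(y, grid, side="right") / y.size
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = np.sqrt(x.size * y.size / (x.size + y.size))
    p = float(kolmogorov(en * d))
    return d, min(max(p, np.finfo(float).tiny), 1.0)


@dataclass
class PromoterComparison:
    """Per-promoter tag loads split by peak class with the K-S comparison."""

    table: pd.DataFrame  # window, gene_ids, pcg_bound, raw, tptm
    bound_counts: np.ndarray
    unbound_counts: np.ndarray
    ks_D: float
    ks_p: float

    def summary(self) -> dict:
        return {
            "n_bound": int(self.bound_counts.size),
            "n_unbound": int(self.unbound_counts.size),
            "mean_tptm_bound": float(self.bound_counts.mean()),
            "mean_tptm_unbound": float(self.unbound_counts.mean()),
            "ks_D": self.ks_D,
            "ks_p": self.ks_p,
        }


def compare_promoter_classes(
    library: TagLibrary,
    promoters: list[PromoterWindow],
    overlap_rule: str = "any_overlap",
    index: TagCountIndex | None = None,
) -> PromoterComparison:
    """Count tags per promoter (tptm) and compare classes by K-S.

    Requires classified promoters (pcg_bound set) with both classes
    non-empty. Zero-count promoters are retained.
    """
    if any(w.pcg_bound is None for w in promoters):
        raise ValueError("promoters must be classified first (pcg_bound unset)")
    idx = index if index is not None else TagCountIndex(library)
    total = library.library_total
    rows = []
    for w in promoters:
        raw = idx.count(w.interval, overlap_rule)
        rows.append(
            {
                "chrom": w.interval.chrom,
                "start": w.interval.start,
                "end": w.interval.end,
                "gene_ids": w.gene_id,
                "pcg_bound": bool(w.pcg_bound),
                "raw": raw,
                "tptm": normalize_tpm(raw, total, 1e7),
            }
        )
    table = pd.DataFrame(rows)
    bound = table.loc[table["pcg_bound"], "tptm"].to_numpy()
    unbound = table.loc[~table["pcg_bound"], "tptm"].to_numpy()
    for name, vec in (("bound", bound), ("unbound", unbound)):
        if vec.size == 0:
            raise ValueError(f"promoter class {name!r} is empty")
    d, p = ks_two_sample(bound, unbound)
    return PromoterComparison(
        table=table,
        bound_counts=bound,
        unbound_counts=unbound,
        ks_D=d,
        ks_p=p,
    )
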