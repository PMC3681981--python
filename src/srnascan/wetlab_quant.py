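"""Bench-assay quantification formulas: qPCR, ChIP %input, MALDI isoform
fractions, and 3C contact normalization.

Each operation is an explicit arithmetic contract on Ct values, peak
areas, or crosslinking frequencies; no curve fitting or efficiency
correction is attempted (amplification efficiency is assumed to be 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IsoformSpectrum",
    "qpcr_relative_expression",
    "expression_fraction_of_reference",
    "chip_percent_input",
    "isoform_fractions",
    "normalize_contacts",
]


@dataclass(frozen=True)
class IsoformSpectrum:
    """Integrated MALDI peak areas for the isoforms of one peptide."""

    peptide: str
    areas: tuple[tuple[str, float], ...]  # (isoform label, area)

    def __post_init__(self) -> None:
        for label, area in self.areas:
            if area < 0:
                raise ValueError(f"negative area for isoform {label!r}: {area}")
        if not any(area > 0 for _, area in self.areas):
            raise ValueError(f"all areas zero for peptide {self.peptide!r}")


def qpcr_relative_expression(
    ct_ref: float, ct_ref_control: float, ct_sample: float, ct_sample_control: float
) -> float:
    """Relative expression A = 2^((Ct(ref)-Ct(ref-control)) - (Ct(sample)-Ct(sample-control))).

    Implemented literally as the source formula is printed; whether
    "ref"/"sample" denote genes or conditions is the caller's reading
    (both are consistent with the arithmetic — swapping the two Ct pairs
    inverts A).
    """
    for name, ct in (
        ("ct_ref", ct_ref),
        ("ct_ref_control", ct_ref_control),
        ("ct_sample", ct_sample),
        ("ct_sample_control", ct_sample_control),
    ):
        if not math.isfinite(ct):
            raise ValueError(f"{name} must be finite, got {ct}")
    return 2.0 ** ((ct_ref - ct_ref_control) - (ct_sample - ct_sample_control))


def expression_fraction_of_reference(ct_target: float, ct_reference: float) -> float:
    """Expression of a target as a fraction of a reference transcript: 2^(Ct_ref - Ct_target)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_reference - ct_target)


def chip_percent_input(
    ct_ip: float,
    ct_input: float,
    input_fraction: float = 1.0,
    ct_noab: float | None = None,
    floor_at_zero: bool = False,
) -> float:
    """ChIP signal as percent of input via 2^-dCt, background-corrected.

    ``input_fraction`` is the fraction of chromatin used as the input
    aliquot; the input Ct is dilution-adjusted by log2(1/input_fraction)
    before the delta. If a no-antibody Ct is given, its percent-input is
    subtracted in percent space (the background correction); the result
    may then be negative unless ``floor_at_zero``.
    """
    if not (0.0 < input_fraction <= 1.0):
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    if not (math.isfinite(ct_ip) and math.isfinite(ct_input)):
        raise ValueError("Ct values must be finite")
    ct_input_adj = ct_input - math.log2(1.0 / input_fraction)
    percent = 100.0 * 2.0 ** (ct_input_adj - ct_ip)
    if ct_noab is not None:
        percent -= chip_percent_input(ct_noab, ct_input, input_fraction)
    if floor_at_zero:
        percent = max(percent, 0.0)
    return percent


def isoform_fractions(spectrum: IsoformSpectrum) -> list[tuple[str, float]]:
    """Fraction of the total cluster area contributed by each isoform.

    The summed area over all isoforms of the peptide is taken as 100%;
    fractions sum to 1 within 1e-9.
    """
    areas = np.array([a for _, a in spectrum.areas], dtype=np.float64)
    total = areas.sum()
    fractions = areas / total
    return [(label, float(f)) for (label, _), f in zip(spectrum.areas, fractions)]


def _welch(control: np.ndarray, treatment: np.ndarray) -> tuple[float, float]:
    # degenerate zero-variance cases fall outside scipy's t machinery
    if control.std(ddof=1) == 0.0 and treatment.std(ddof=1) == 0.0:
        if control.mean() == treatment.mean():
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = stats.ttest_ind(treatment, control, equal_var=False)
    return float(t), float(p)


def normalize_contacts(table: pd.DataFrame, alpha: float = 0.05):
    """Normalize 3C crosslinking frequencies on the control and test pairs.

    ``table`` columns: pair, condition ({control, treatment}), replicate,
    frequency. Every frequency of a fragment pair is divided by that
    pair's control mean (so the normalized control mean is 1). Pairs with
    >= 2 replicates per condition get a two-tailed Welch t-test on the
    normalized values; the significance flag is p < alpha.

    Returns (normalized table, per-pair summary DataFrame).
    """
    required = {"pair", "condition", "replicate", "frequency"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = set(table["condition"]) - {"control", "treatment"}
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    if (table["frequency"] < 0).any():
        raise ValueError("frequencies must be nonnegative")
    norm = table.copy()
    norm["normalized"] = np.nan
    summaries = []
    for pair, grp in table.groupby("pair", sort=False):
        ctrl = grp.loc[grp["condition"] == "control", "frequency"].to_numpy(float)
        treat = grp.loc[grp["condition"] == "treatment", "frequency"].to_numpy(float)
        if ctrl.size == 0:
            raise ValueError(f"pair {pair!r} has no control replicate")
        ctrl_mean = ctrl.mean()
        if ctrl_mean <= 0:
            raise ValueError(f"pair {pair!r} has control mean {ctrl_mean}")
        norm.loc[grp.index, "normalized"] = grp["frequency"] / ctrl_mean
        if ctrl.size >= 2 and treat.size >= 2:
            t, p = _welch(ctrl / ctrl_mean, treat / ctrl_mean)
        else:
            t, p = math.nan, math.nan
        summaries.append(
            {
                "pair": pair,
                "n_control": int(ctrl.size),
                "n_treatment": int(treat.size),
                "control_mean": float(ctrl_mean),
                "normalized_treatment_mean": float(treat.mean() / ctrl_mean)
                if treat.size
                else math.nan,
                "t_statistic": t,
                "p_value": p,
                "significant": bool(p < alpha) if not math.isnan(p) else False,
            }
        )
    return norm, pd.DataFrame(summaries)
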