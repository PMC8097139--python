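"""Partial-derivative sensitivities of stomatal density.

From SD = 10^6 / (SS * c) with c = c(SI, a) = 1 + a*(100/SI - 1):

    dSD/dSS = -10^6 / (SS^2 * c)                 (< 0: dilution)
    dSD/dSI = 10^6 * 100*a / (SI^2 * SS * c^2)   (> 0: more stomata per cell)

A first-order decomposition attributes a density change to its geometric
(size) and non-geometric (index) parts:

    dSD ~ dSD/dSS * dSS + dSD/dSI * dSI

and the *constraint ratio* compares the magnitudes of the two channels:

    R_gc/nge = |dSD/dSS| / (dSD/dSI) = SI^2 * c / (100 * a * SS)

R_gc/nge > 1 means a unit change in stomatal size moves density more than
a unit change in stomatal index does; it is treated as a dimensionless
index although the two unit changes are 1 um^2 and 1 SI percentage point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import DEFAULT_A, UM2_PER_MM2, denom_factor, predict_si
from .traitio import TraitTable, complete_table

__all__ = [
    "SensitivityResult",
    "SensitivitySummary",
    "DeltaDecomposition",
    "d_sd_d_ss",
    "d_sd_d_si",
    "constraint_ratio",
    "delta_sd",
    "table_sensitivities",
]

logger = logging.getLogger(__name__)


def d_sd_d_ss(ss, si, a=DEFAULT_A):
    """Sensitivity of density to stomatal size, per mm^2 per um^2 (negative)."""
    ss = np.asarray(ss, dtype=float)
    if np.any(ss <= 0):
        raise ValueError("ss must be positive")
    out = -UM2_PER_MM2 / (ss**2 * denom_factor(si, a))
    return out.item() if np.ndim(out) == 0 else out


def d_sd_d_si(ss, si, a=DEFAULT_A):
    """Sensitivity of density to stomatal index, per mm^2 per SI point (positive)."""
    ss = np.asarray(ss, dtype=float)
    si_arr = np.asarray(si, dtype=float)
    if np.any(ss <= 0):
        raise ValueError("ss must be positive")
    c = denom_factor(si, a)
    out = UM2_PER_MM2 * (100.0 * a / si_arr**2) / (ss * np.asarray(c) ** 2)
    return out.item() if np.ndim(out) == 0 else out


def constraint_ratio(ss, si, a=DEFAULT_A):
    """R_gc/nge = |dSD/dSS| / (dSD/dSI) = SI^2 * c(SI,a) / (100 * a * SS)."""
    out = np.abs(d_sd_d_ss(ss, si, a)) / d_sd_d_si(ss, si, a)
    return out.item() if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class DeltaDecomposition:
    """First-order split of a density change into its two channels."""

    delta_ss: float  # um^2
    delta_si: float  # SI percentage points
    contribution_gc: float  # (dSD/dSS) * delta_ss, per mm^2
    contribution_nge: float  # (dSD/dSI) * delta_si, per mm^2
    delta_sd_linear: float  # their sum (linearization of the exact change)


def delta_sd(ss, si, a, delta_ss, delta_si) -> DeltaDecomposition:
    """Linearized density change at base point (ss, si) for given trait shifts."""
    gc = d_sd_d_ss(ss, si, a) * delta_ss
    nge = d_sd_d_si(ss, si, a) * delta_si
    return DeltaDecomposition(
        delta_ss=float(delta_ss),
        delta_si=float(delta_si),
        contribution_gc=float(gc),
        contribution_nge=float(nge),
        delta_sd_linear=float(gc + nge),
    )


@dataclass(frozen=True)
class SensitivityResult:
    """Per-species sensitivities and constraint ratio."""

    species: str
    ss_used: float
    si_used: float
    si_source: str  # 'observed' | 'predicted'
    d_sd_d_ss: float
    d_sd_d_si: float
    r_gc_nge: float


@dataclass(frozen=True)
class SensitivitySummary:
    """Distributional summary of R_gc/nge over a trait table."""

    mean_ratio: float  # arithmetic mean, raw scale
    median_ratio: float
    mean_log10_ratio: float  # mean of lg(R_gc/nge)
    fraction_below_1: float  # fraction in [0, 1] of records with ratio < 1
    n: int
    n_excluded: int  # infeasible (sd*ss >= 10^6) or incomplete records


def table_sensitivities(
    table: TraitTable,
    a: float = DEFAULT_A,
    si_mode: str = "predicted",
    params=None,
) -> tuple[list[SensitivityResult], SensitivitySummary]:
    """Per-record sensitivities and the R_gc/nge summary for a trait table.

    Parameters
    ----------
    table
        Trait table; records missing ss have it derived from sl first.
    a
        Epidermal/stomatal area ratio used throughout.
    si_mode
        'observed' uses each record's si; 'predicted' computes si from
        sd and ss via the model inverse (records violating the
        sd*ss < 10^6 packing bound are excluded with a logged count).
    """
    if si_mode not in ("observed", "predicted"):
        raise ValueError("si_mode must be 'observed' or 'predicted'")
    table = complete_table(table, params)
    results: list[SensitivityResult] = []
    n_excluded = 0
    for rec in table.records:
        if rec.ss is None:
            n_excluded += 1
            continue
        if si_mode == "observed":
            if rec.si is None:
                n_excluded += 1
                continue
            si_used = rec.si
        else:
            if rec.sd is None:
                n_excluded += 1
                continue
            if rec.sd * rec.ss >= UM2_PER_MM2:
                n_excluded += 1
                continue
            si_used = predict_si(rec.sd, rec.ss, a)
        results.append(
            SensitivityResult(
                species=rec.species,
                ss_used=rec.ss,
                si_used=float(si_used),
                si_source=si_mode,
                d_sd_d_ss=d_sd_d_ss(rec.ss, si_used, a),
                d_sd_d_si=d_sd_d_si(rec.ss, si_used, a),
                r_gc_nge=constraint_ratio(rec.ss, si_used, a),
            )
        )
    if not results:
        raise ValueError("no eligible records for sensitivity analysis")
    if n_excluded:
        logger.warning(
            "sensitivity analysis excluded %d record(s) "
            "(missing traits or infeasible sd*ss)",
            n_excluded,
        )
    ratios = np.array([r.r_gc_nge for r in results])
    summary = SensitivitySummary(
        mean_ratio=float(np.mean(ratios)),
        median_ratio=float(np.median(ratios)),
        mean_log10_ratio=float(np.mean(np.log10(ratios))),
        fraction_below_1=float(np.mean(ratios < 1.0)),
        n=len(results),
        n_excluded=n_excluded,
    )
    return results, summary
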