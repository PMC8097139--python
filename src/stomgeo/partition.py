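"""Variance partitioning of log stomatal density.

Splits the (adjusted) R^2 of lg SD into a geometric component carried by
lg(SL^-2), a non-geometric component carried by lg SI, and their overlap:

    R_ov^2   = R_gc^2 + R_nge^2 - R_o^2
    pure gc  = R_gc^2 - R_ov^2
    pure nge = R_nge^2 - R_ov^2

where R_o^2 is from the two-predictor model and R_gc^2, R_nge^2 from the
single-predictor models.  By construction pure_gc + pure_nge + overlap
equals the full-model R^2.  The geometric predictor is lg(SL^-2), i.e.
-2 * lg SL, because density scales intrinsically with inverse squared
stomatal length; adjusted R^2 is the default since the single- and
two-predictor models differ in parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .traitio import TraitTable

__all__ = ["PartitionResult", "variation_partition"]


@dataclass(frozen=True)
class PartitionResult:
    """Additive decomposition of explained variance in lg SD."""

    r2_full: float  # both predictors (R_o^2)
    r2_gc: float  # lg(SL^-2) alone
    r2_nge: float  # lg SI alone
    r2_overlap: float  # shared component
    pure_gc: float
    pure_nge: float
    n: int
    adjusted: bool
    has_negative_component: bool  # adjusted R^2 can go (slightly) negative

    @property
    def gc_to_nge(self) -> float:
        """Ratio of pure geometric to pure non-geometric variance."""
        return self.pure_gc / self.pure_nge


def _r2(y, X, adjusted: bool) -> float:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return float(model.rsquared_adj if adjusted else model.rsquared)


def variation_partition(table: TraitTable, adjusted: bool = True) -> PartitionResult:
    """Partition lg SD variance between lg(SL^-2) and lg SI.

    Only records with sd, sl and an *observed* stomatal index enter.
    Negative adjusted-R^2 components are reported as computed (flagged),
    never clamped.

    Raises
    ------
    ValueError
        Fewer than 4 usable records, a constant predictor, or exactly
        collinear predictors.
    """
    df = table.to_dataframe()
    observed_si = np.array(
        [r.derived_flags.get("si", "observed") == "observed" for r in table.records]
    )
    mask = (
        df["sd_per_mm2"].notna().to_numpy()
        & df["sl_um"].notna().to_numpy()
        & df["si_pct"].notna().to_numpy()
        & observed_si
    )
    sub = df.loc[mask]
    n = len(sub)
    if n < 4:
        raise ValueError(f"need >= 4 records with sd, sl and observed si, found {n}")

    lg_sd = np.log10(sub["sd_per_mm2"].to_numpy(dtype=float))
    x_gc = -2.0 * np.log10(sub["sl_um"].to_numpy(dtype=float))  # lg(SL^-2)
    x_nge = np.log10(sub["si_pct"].to_numpy(dtype=float))

    if np.std(x_gc) == 0.0 or np.std(x_nge) == 0.0:
        raise ValueError("degenerate data: a predictor is constant")
    r_pred = np.corrcoef(x_gc, x_nge)[0, 1]
    if abs(r_pred) >= 1.0 - 1e-12:
        raise ValueError("degenerate data: predictors are exactly collinear")

    r2_full = _r2(lg_sd, np.column_stack([x_gc, x_nge]), adjusted)
    r2_gc = _r2(lg_sd, x_gc, adjusted)
    r2_nge = _r2(lg_sd, x_nge, adjusted)
    r2_overlap = r2_gc + r2_nge - r2_full
    pure_gc = r2_gc - r2_overlap
    pure_nge = r2_nge - r2_overlap
    components = (r2_full, r2_gc, r2_nge, r2_overlap, pure_gc, pure_nge)
    return PartitionResult(
        r2_full=r2_full,
        r2_gc=r2_gc,
        r2_nge=r2_nge,
        r2_overlap=r2_overlap,
        pure_gc=pure_gc,
        pure_nge=pure_nge,
        n=n,
        adjusted=adjusted,
        has_negative_component=any(c < 0 for c in components),
    )
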