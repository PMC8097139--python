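"""Geometric model of stomatal density.

Stomatal density (SD, mm^-2) is tied to stomatal size (SS, um^2) and
stomatal index (SI, percent of epidermal units that are stomata) through a
simple packing identity.  If a leaf surface is tiled by ``m`` stomata of
area SS and ``n`` pavement cells of area ES, the density of stomata is

    SD = 10^6 / (SS + ES * (n/m))          [per mm^2, areas in um^2]

With SI = 100*m/(m+n) we have n/m = 100/SI - 1, and writing ``a = ES/SS``
for the epidermal-to-stomatal area ratio,

    SD = 10^6 / (SS * c(SI, a)),     c(SI, a) = 1 + a*(100/SI - 1)

so SD is exactly proportional to SS^-1 at fixed SI and a (the *geometric
constraint*: enlarging stomata dilutes their density).  Since a single
stoma's plan area is well approximated by the ellipse-like form
SS = (pi/2) * SL * SW with SW ~ 0.36 * SL, the same law reads
SD ~ 1.77e6 / c(SI, a) * SL^-2 in terms of stomatal length alone.

This module implements the forward density model, its inverse (predicting
SI from SD and SS), and two ways of putting a number on ``a`` from data:
a direct proportionality fit of ES on SS, and a calibration that makes
predicted SI match observed SI in least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .traitio import TraitTable

__all__ = [
    "UM2_PER_MM2",
    "GeometricParams",
    "SquareTessellation",
    "square_density",
    "denom_factor",
    "predict_density",
    "predict_si",
    "length_coefficient",
    "density_from_length",
    "AEstimate",
    "estimate_a",
    "ACalibration",
    "calibrate_a",
]

#: um^2 per mm^2 — the unit factor linking areas in um^2 to densities per mm^2.
UM2_PER_MM2 = 1.0e6

#: Default epidermal/stomatal area ratio after calibration against observed SI.
DEFAULT_A = 1.06

#: Default stomatal width/length ratio.
DEFAULT_WIDTH_RATIO = 0.36


@dataclass(frozen=True)
class GeometricParams:
    """Constants of the geometric model.

    Parameters
    ----------
    a
        Epidermal-to-stomatal area ratio ES/SS (dimensionless, > 0).
        1.06 is the SI-calibrated value; 2.78 the directly fitted one.
    width_ratio
        Stomatal width/length ratio SW/SL (dimensionless, in (0, 1]).
    """

    a: float = DEFAULT_A
    width_ratio: float = DEFAULT_WIDTH_RATIO
    unit_factor: float = field(default=UM2_PER_MM2, init=False)

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if not 0 < self.width_ratio <= 1:
            raise ValueError(
                f"width_ratio must be in (0, 1], got {self.width_ratio}"
            )


@dataclass(frozen=True)
class SquareTessellation:
    """A surface tiled by M equal squares of side ``l_side`` um.

    Density is independent of M: D = M / (M * L^2) = 10^6 / L^2 per mm^2.
    """

    m_squares: int
    l_side: float

    def __post_init__(self) -> None:
        if self.m_squares < 1:
            raise ValueError("m_squares must be >= 1")
        if not self.l_side > 0:
            raise ValueError("l_side must be positive")

    @property
    def area(self) -> float:
        """Per-square area, um^2."""
        return self.l_side**2

    @property
    def density(self) -> float:
        """Squares per mm^2."""
        return UM2_PER_MM2 / self.area


def square_density(l_side):
    """Density (per mm^2) of a tessellation of equal squares of side ``l_side`` um.

    D = 10^6 / L^2, independent of how many squares there are.
    """
    l_side = np.asarray(l_side, dtype=float)
    if np.any(l_side <= 0):
        raise ValueError("square side length must be positive")
    out = UM2_PER_MM2 / l_side**2
    return out.item() if out.ndim == 0 else out


def denom_factor(si, a):
    """Dimensionless denominator c(SI, a) = 1 + a*(100/SI - 1).

    Multiplies SS in the density law SD = 10^6 / (SS * c).  With the
    calibrated a = 1.06 it reduces to 106/SI - 0.06.  At SI = 100 (every
    epidermal unit a stoma) c = 1 and density is pure dilution.
    """
    si = np.asarray(si, dtype=float)
    if np.any((si <= 0) | (si > 100)):
        raise ValueError("si must lie in (0, 100]")
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("a must be positive")
    out = 1.0 + a * (100.0 / si - 1.0)
    return out.item() if out.ndim == 0 else out


def predict_density(ss, si, a=DEFAULT_A):
    """Stomatal density (per mm^2) from stomatal size and index.

    SD = 10^6 / (SS * c(SI, a)).  Homogeneous of degree -1 in SS: scaling
    SS by k divides SD by k at fixed SI and a.

    Parameters
    ----------
    ss : stomatal size, um^2 (> 0)
    si : stomatal index, percent (0 < si <= 100)
    a  : epidermal/stomatal area ratio
    """
    ss = np.asarray(ss, dtype=float)
    if np.any(ss <= 0):
        raise ValueError("ss must be positive")
    out = UM2_PER_MM2 / (ss * denom_factor(si, a))
    return out.item() if np.ndim(out) == 0 else out


def predict_si(sd, ss, a=DEFAULT_A):
    """Stomatal index (percent) implied by observed density and size.

    SI = 100 / [ (1/a) * (10^6/(SD*SS) - 1) + 1 ]; the exact inverse of
    :func:`predict_density` at the same ``a``.

    Raises
    ------
    ValueError
        If SD*SS >= 10^6: the stomata alone would exceed the leaf surface.
    """
    sd = np.asarray(sd, dtype=float)
    ss = np.asarray(ss, dtype=float)
    if np.any(sd <= 0) or np.any(ss <= 0):
        raise ValueError("sd and ss must be positive")
    frac = sd * ss / UM2_PER_MM2  # fraction of surface occupied by stomata
    if np.any(frac > 1):
        raise ValueError(
            "infeasible geometry: sd*ss exceeds 10^6 um^2 per mm^2 "
            "(stomata alone would exceed the surface)"
        )
    a = np.asarray(a, dtype=float)
    out = 100.0 / ((1.0 / a) * (UM2_PER_MM2 / (sd * ss) - 1.0) + 1.0)
    return out.item() if np.ndim(out) == 0 else out


def length_coefficient(width_ratio=DEFAULT_WIDTH_RATIO):
    """Leading coefficient K = 1/((pi/2)*width_ratio) of the SL^-2 density law.

    With width_ratio = 0.36, K = 1.768..., conventionally printed as 1.77
    (times 10^6) in the SD = K*10^6/c * SL^-2 form.
    """
    if not 0 < width_ratio <= 1:
        raise ValueError("width_ratio must be in (0, 1]")
    return 1.0 / ((np.pi / 2.0) * width_ratio)


def density_from_length(sl, si, params: GeometricParams | None = None):
    """Stomatal density from stomatal length, via SS = (pi/2)*SL*(w*SL).

    Equals ``predict_density(ss, si, a)`` with SS derived from SL and the
    width ratio; follows the intrinsic SL^-2 law at fixed SI.
    """
    if params is None:
        params = GeometricParams()
    sl = np.asarray(sl, dtype=float)
    if np.any(sl <= 0):
        raise ValueError("sl must be positive")
    ss = (np.pi / 2.0) * params.width_ratio * sl**2
    return predict_density(ss, si, params.a)


@dataclass(frozen=True)
class AEstimate:
    """Result of a direct ES-vs-SS proportionality fit."""

    a: float
    method: str
    n: int
    residual_ss: float  # sum of squared residuals of es around a*ss


def estimate_a(table: TraitTable, method: str = "origin") -> AEstimate:
    """Estimate a = ES/SS from records with both areas observed.

    Methods
    -------
    ``origin``
        Through-origin least squares slope of ES on SS (default: ``a`` is
        defined as a ratio, so the line has no offset).
    ``ratio_mean``
        Arithmetic mean of the per-record ES/SS ratios.
    ``loglog``
        10**(mean(lg ES - lg SS)), the geometric-mean ratio.
    """
    df = table.to_dataframe()
    mask = df["es_um2"].notna() & df["ss_um2"].notna()
    es = df.loc[mask, "es_um2"].to_numpy(dtype=float)
    ss = df.loc[mask, "ss_um2"].to_numpy(dtype=float)
    n = len(es)
    if n < 3:
        raise ValueError(
            f"need >= 3 records with both es and ss, found {n}"
        )
    if method == "origin":
        a = float(np.sum(es * ss) / np.sum(ss**2))
    elif method == "ratio_mean":
        a = float(np.mean(es / ss))
    elif method == "loglog":
        a = float(10 ** np.mean(np.log10(es) - np.log10(ss)))
    else:
        raise ValueError(f"unknown method {method!r}")
    resid = float(np.sum((es - a * ss) ** 2))
    return AEstimate(a=a, method=method, n=n, residual_ss=resid)


@dataclass(frozen=True)
class ACalibration:
    """Result of calibrating ``a`` against observed stomatal index."""

    a: float
    n: int
    sse: float  # sum of squared (predicted - observed) SI at the optimum


def calibrate_a(
    table: TraitTable,
    bounds: tuple[float, float] = (0.01, 100.0),
    xatol: float = 1e-8,
) -> ACalibration:
    """Choose ``a`` so that predicted SI best matches observed SI.

    Minimizes sum_i (predict_si(sd_i, ss_i, a) - si_i)^2 over a in
    ``bounds`` by deterministic bounded scalar minimization.  Only records
    with sd, ss and an *observed* (not derived) si enter; records violating
    the sd*ss < 10^6 feasibility bound are excluded.
    """
    df = table.to_dataframe()
    flags = [r.derived_flags for r in table.records]
    observed_si = np.array(
        [f.get("si", "observed") == "observed" for f in flags]
    )
    mask = (
        df["sd_per_mm2"].notna().to_numpy()
        & df["ss_um2"].notna().to_numpy()
        & df["si_pct"].notna().to_numpy()
        & observed_si
    )
    sd = df.loc[mask, "sd_per_mm2"].to_numpy(dtype=float)
    ss = df.loc[mask, "ss_um2"].to_numpy(dtype=float)
    si = df.loc[mask, "si_pct"].to_numpy(dtype=float)
    feasible = sd * ss < UM2_PER_MM2
    sd, ss, si = sd[feasible], ss[feasible], si[feasible]
    n = len(sd)
    if n < 3:
        raise ValueError(
            f"need >= 3 feasible records with sd, ss and observed si, found {n}"
        )

    def objective(a: float) -> float:
        return float(np.sum((predict_si(sd, ss, a) - si) ** 2))

    res = minimize_scalar(
        objective, bounds=bounds, method="bounded", options={"xatol": xatol}
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"calibration did not converge: {res.message}")
    return ACalibration(a=float(res.x), n=n, sse=float(res.fun))
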