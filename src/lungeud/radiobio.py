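"""Generalized EUD, the alpha-sweep group statistic and NTCP models.

The generalized equivalent uniform dose (gEUD) summarizes a non-uniform dose
distribution as the uniform dose with the same presumed biological effect:

    EUD(alpha) = (sum_i v_i d_i^alpha)^(1/alpha)

a weighted power mean over DVH bins with fractional volumes v_i and
representative doses d_i. ``alpha`` encodes the organ's volume effect: large
positive values emphasize hot spots (serial organs), values near 0-1 average
over the organ (parallel organs such as lung), and negative values emphasize
cold spots (tumors). ``alpha = 0`` is the geometric-mean limit and
``alpha = 1`` is the mean dose.

The alpha sweep computes, on a labelled cohort, the relative difference

    R(alpha) = 100 * (mean EUD in RP group - mean EUD in non-RP group)
                     / (mean EUD in non-RP group)

over a grid of alpha values and locates the maximizing ``alpha_star`` - the
exponent at which the pneumonitis and non-pneumonitis groups separate most.

Two normal tissue complication probability (NTCP) models are provided: the
Lyman-Kutcher-Burman (LKB) probit model on an effective-volume DVH reduction,
and a logistic model driven directly by lung EUD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr

from .dvh import Cohort, DoseVolumeHistogram, mean_dose

__all__ = [
    "EUDParams",
    "LKBParams",
    "AlphaSweepResult",
    "default_alpha_grid",
    "eud",
    "eud_curve",
    "relative_difference",
    "alpha_sweep",
    "veff",
    "ntcp_lkb",
    "ntcp_logistic_eud",
    "gamma50_from_m",
    "m_from_gamma50",
]


def default_alpha_grid() -> np.ndarray:
    """Default alpha grid: unit steps on [-50, -5] and [5, 50], 0.1 steps between.

    The +/-50 bounds reflect the range planning systems typically allow for
    the gEUD exponent; the fine 0.1 resolution around zero covers the
    physiologically interesting parallel-organ region.
    """
    coarse_neg = np.arange(-50.0, -5.0, 1.0)
    fine = np.round(np.arange(-5.0, 5.0, 0.1), 10)
    coarse_pos = np.arange(5.0, 51.0, 1.0)
    return np.concatenate([coarse_neg, fine, coarse_pos])


@dataclass
class EUDParams:
    """Parameters of the gEUD computation and alpha sweep.

    ``dose_floor`` (Gy) replaces smaller representative doses before raising
    to negative powers, so cold bins do not drive EUD to zero for alpha <= 0.
    """

    alpha: float = 0.3
    dose_floor: float = 0.01
    alpha_grid: np.ndarray = field(default_factory=default_alpha_grid)

    def __post_init__(self) -> None:
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if self.dose_floor <= 0:
            raise ValueError("dose_floor must be > 0")
        if self.alpha_grid.ndim != 1 or self.alpha_grid.size < 2:
            raise ValueError("alpha_grid must be a 1-D grid")
        if np.any(np.diff(self.alpha_grid) <= 0):
            raise ValueError("alpha_grid must be strictly increasing")
        for required in (0.3, 1.0):
            if not np.any(np.isclose(self.alpha_grid, required)):
                raise ValueError(f"alpha_grid must contain {required}")


@dataclass
class LKBParams:
    """Dose-response parameters shared by the two NTCP models.

    ``td50`` is the uniform whole-organ dose giving 50% complication
    probability. ``m`` (probit) and ``gamma50`` (normalized slope) both set
    the steepness of the dose-response curve; they parameterize different
    model forms and are not forced to be mutually consistent. ``n`` sets the
    strength of the volume dependence (n = 1 for a parallel organ such as
    lung), and ``dref`` (Gy) is the reference dose of the effective-volume
    reduction.

    ``formula_mode`` selects how the LKB probit argument is assembled:

    ``"printed"``
        t = (dref - TD50 * veff^-n) / (m * TD50 * veff^-n) with veff taken
        at ``dref``.
    ``"standard"``
        the classical Kutcher-Burman reduction: the DVH is reduced to an
        effective volume at the maximum bin dose D_max, and
        t = (D_max - TD50 * veff^-n) / (m * TD50 * veff^-n).
    """

    td50: float = 24.5
    m: float = 2.0
    gamma50: float = 2.0
    dref: float = 2.0
    n: float = 1.0
    formula_mode: str = "printed"

    def __post_init__(self) -> None:
        for name in ("td50", "m", "gamma50", "dref", "n"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.formula_mode not in ("printed", "standard"):
            raise ValueError(
                f"formula_mode must be 'printed' or 'standard', got "
                f"{self.formula_mode!r}"
            )


def eud(
    dvh: DoseVolumeHistogram,
    alpha: float,
    dose_floor: float = 0.01,
) -> float:
    """Generalized EUD of a DVH at exponent ``alpha``, in Gy.

    Computed as the weighted power mean over bins,
    ``(sum_i v_i max(d_i, floor)^alpha)^(1/alpha)``, evaluated in log space
    for numerical stability at large ``|alpha|``. ``alpha = 0`` uses the
    geometric-mean limit.
    """
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    if dose_floor <= 0:
        raise ValueError("dose_floor must be > 0")
    v = dvh.diff_volume
    mask = v > 0
    if not np.any(mask):
        raise ValueError("DVH has no volume")
    v = v[mask]
    log_d = np.log(np.maximum(dvh.midpoints[mask], dose_floor))
    if alpha == 0.0:
        return float(math.exp(float(np.dot(v, log_d))))
    return float(math.exp(logsumexp(alpha * log_d, b=v) / alpha))


def eud_curve(
    dvh: DoseVolumeHistogram,
    alphas: np.ndarray,
    dose_floor: float = 0.01,
) -> np.ndarray:
    """Vector of gEUD values over a grid of alpha exponents."""
    alphas = np.asarray(alphas, dtype=float)
    v = dvh.diff_volume
    mask = v > 0
    if not np.any(mask):
        raise ValueError("DVH has no volume")
    v = v[mask]
    log_d = np.log(np.maximum(dvh.midpoints[mask], dose_floor))
    out = np.empty(alphas.size)
    nonzero = alphas != 0.0
    if np.any(nonzero):
        a = alphas[nonzero]
        out[nonzero] = np.exp(
            logsumexp(a[:, None] * log_d[None, :], b=v[None, :], axis=1) / a
        )
    if np.any(~nonzero):
        out[~nonzero] = math.exp(float(np.dot(v, log_d)))
    return out


def relative_difference(eud_grp: float, eud_gnrp: float) -> float:
    """Relative EUD difference between outcome groups, in percent.

    ``100 * (EUD_RP - EUD_nonRP) / EUD_nonRP``.
    """
    if eud_gnrp <= 0:
        raise ValueError("non-RP group EUD must be > 0")
    return 100.0 * (eud_grp - eud_gnrp) / eud_gnrp


@dataclass
class AlphaSweepResult:
    """Group-mean EUD curves, relative difference and its maximizer."""

    alpha_grid: np.ndarray
    mean_eud_grp: np.ndarray
    mean_eud_gnrp: np.ndarray
    relative_diff: np.ndarray
    alpha_star: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alpha_grid,
                "mean_eud_grp": self.mean_eud_grp,
                "mean_eud_gnrp": self.mean_eud_gnrp,
                "relative_diff_pct": self.relative_diff,
            }
        )


def alpha_sweep(
    cohort: Cohort,
    lung: str = "whole",
    params: EUDParams | None = None,
) -> AlphaSweepResult:
    """Sweep the gEUD exponent and locate the alpha maximizing group separation.

    For every alpha on the grid, the RP 2+ and non-RP 2+ group-mean EUDs and
    their relative difference R(alpha) are computed; ``alpha_star`` is the
    grid argmax of R. Exact ties are broken toward the smallest ``|alpha|``,
    then toward negative alpha.
    """
    if lung not in ("whole", "affected"):
        raise ValueError(f"lung must be 'whole' or 'affected', got {lung!r}")
    params = params if params is not None else EUDParams()
    cohort.require_both_classes()
    attr = "dvh_whole_lung" if lung == "whole" else "dvh_affected_lung"
    grid = params.alpha_grid
    curves = {0: [], 1: []}
    for rec in cohort:
        curves[rec.rp2_label].append(
            eud_curve(getattr(rec, attr), grid, params.dose_floor)
        )
    mean_grp = np.mean(curves[1], axis=0)
    mean_gnrp = np.mean(curves[0], axis=0)
    rel = 100.0 * (mean_grp - mean_gnrp) / mean_gnrp
    r_max = float(rel.max())
    tol = 1e-9 * max(1.0, abs(r_max))
    candidates = grid[rel >= r_max - tol]
    alpha_star = float(min(candidates, key=lambda a: (abs(a), a))) + 0.0  # drop -0.0
    return AlphaSweepResult(
        alpha_grid=grid,
        mean_eud_grp=mean_grp,
        mean_eud_gnrp=mean_gnrp,
        relative_diff=rel,
        alpha_star=alpha_star,
    )


def veff(dvh: DoseVolumeHistogram, n: float = 1.0, dref: float = 2.0) -> float:
    """Effective volume of the Kutcher-Burman DVH reduction.

    ``veff = sum_i v_i (d_i / dref)^(1/n)`` maps a non-uniform dose
    distribution onto an equivalent uniform irradiation of a fraction
    ``veff`` of the organ at the reference dose ``dref``.
    """
    if n <= 0 or dref <= 0:
        raise ValueError("n and dref must be > 0")
    ratios = dvh.midpoints / dref
    return float(np.dot(dvh.diff_volume, np.power(ratios, 1.0 / n)))


def ntcp_lkb(dvh: DoseVolumeHistogram, params: LKBParams | None = None) -> float:
    """LKB probit NTCP of a DVH.

    The tolerance dose is scaled to the effective volume via the power law
    ``TD50(veff) = TD50 * veff^-n``; the probit argument ``t`` is assembled
    according to ``params.formula_mode`` (see :class:`LKBParams`) and the
    complication probability is ``Phi(t)``, the standard normal CDF evaluated
    via the error function.
    """
    params = params if params is not None else LKBParams()
    if params.formula_mode == "printed":
        d_point = params.dref
        ve = veff(dvh, params.n, params.dref)
    else:
        active = dvh.diff_volume > 0
        d_max = float(dvh.midpoints[active].max())
        if d_max <= 0:
            return 0.0
        d_point = d_max
        ve = veff(dvh, params.n, d_max)
    if ve <= 0:
        return 0.0
    td50_eff = params.td50 * ve ** (-params.n)
    t = (d_point - td50_eff) / (params.m * td50_eff)
    return float(ndtr(t))


def ntcp_logistic_eud(lung_eud: float, params: LKBParams | None = None) -> float:
    """EUD-calibrated logistic NTCP.

    ``NTCP = 1 / (1 + (TD50 / EUD)^(4 * gamma50))``: equals 0.5 at
    ``EUD = TD50``, is strictly increasing in EUD, and its normalized slope
    ``d NTCP / d ln(EUD)`` at TD50 equals ``gamma50``.
    """
    params = params if params is not None else LKBParams()
    if lung_eud < 0:
        raise ValueError("lung EUD must be >= 0")
    if lung_eud == 0:
        return 0.0
    return float(1.0 / (1.0 + (params.td50 / lung_eud) ** (4.0 * params.gamma50)))


def gamma50_from_m(m: float) -> float:
    """Normalized slope gamma50 equivalent to a probit slope parameter m."""
    if m <= 0:
        raise ValueError("m must be > 0")
    return 1.0 / (m * math.sqrt(2.0 * math.pi))


def m_from_gamma50(gamma50: float) -> float:
    """Probit slope parameter m equivalent to a normalized slope gamma50."""
    if gamma50 <= 0:
        raise ValueError("gamma50 must be > 0")
    return 1.0 / (gamma50 * math.sqrt(2.0 * math.pi))
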