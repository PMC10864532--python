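"""Cohort statistics: feature assembly, group tests, correlation, logistic regression, ROC.

This module assembles the per-patient predictor table (dosimetric V_x metrics,
mean lung dose, lung EUD, the multiplicative physical-dose composite and the
four NTCP variants) and runs the statistical chain used to screen predictors
of grade >= 2 radiation pneumonitis: independent two-sample t-tests between
outcome groups, Pearson correlation between EUD and physical metrics,
multivariate logistic regression, ROC/AUC analysis with Youden-index cutoffs
and DeLong confidence intervals, and cutoff-based risk stratification.

Unit conventions in the feature table mirror clinical reporting: V_x in
percent of lung volume, MLD and lung EUD in cGy, NTCP as probabilities. The
physical composite is MLD (cGy) times the four V_x values expressed as
fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .dvh import Cohort, mean_dose, v_dose
from .radiobio import LKBParams, eud, ntcp_lkb, ntcp_logistic_eud

__all__ = [
    "ConvergenceError",
    "TTestResult",
    "RocResult",
    "StratifyResult",
    "physical_composite",
    "build_feature_table",
    "two_sample_t",
    "group_comparison_table",
    "pearson",
    "correlation_table",
    "multivariate_logistic",
    "roc_analysis",
    "stratify",
]

#: Predictor columns of the assembled feature table, in reporting order.
FEATURE_COLUMNS = [
    "vol_lung_cc",
    "vol_ptv_cc",
    "ptv_to_lung_ratio",
    "v5",
    "v10",
    "v20",
    "v30",
    "mld_cgy",
    "lung_eud_cgy",
    "lung_eud1_cgy",
    "physical_composite",
    "ntcp_lkb_sick",
    "ntcp_lkb_total",
    "ntcp_eud_sick",
    "ntcp_eud_total",
    "saa_deg",
]


class ConvergenceError(RuntimeError):
    """Raised when a maximum-likelihood fit does not converge cleanly."""


def physical_composite(
    mld_cgy: float,
    v5: float,
    v10: float,
    v20: float,
    v30: float,
) -> float:
    """Multiplicative physical-dose score: MLD (cGy) x V5 x V10 x V20 x V30.

    The V_x terms enter as fractions (percent / 100); under this convention
    typical lung plans score in the low single digits. Strictly increasing
    in every component; zero whenever any component is zero.
    """
    values = [mld_cgy, v5, v10, v20, v30]
    if any(v is None or not np.isfinite(v) for v in values):
        raise ValueError("physical composite requires all five dose metrics")
    return float(
        mld_cgy * (v5 / 100.0) * (v10 / 100.0) * (v20 / 100.0) * (v30 / 100.0)
    )


def build_feature_table(
    cohort: Cohort,
    eud_alpha: float = 0.3,
    lkb: LKBParams | None = None,
    dose_floor: float = 0.01,
) -> pd.DataFrame:
    """Assemble the per-patient predictor matrix with RP 2+ labels.

    Columns: outcome ``rp2``, structure volumes, V5-V30 (% of whole lung),
    MLD (cGy), whole-lung EUD at ``eud_alpha`` and at alpha = 1 (cGy), the
    physical composite, and the four NTCP variants (``sick`` = affected lung,
    ``total`` = whole lung). The EUD-calibrated NTCP uses the EUD of the
    respective lung at ``eud_alpha``.
    """
    lkb = lkb if lkb is not None else LKBParams()
    rows = []
    for rec in cohort:
        whole = rec.dvh_whole_lung
        affected = rec.dvh_affected_lung
        eud_whole = eud(whole, eud_alpha, dose_floor)
        eud_affected = eud(affected, eud_alpha, dose_floor)
        row = {
            "patient_id": rec.patient_id,
            "rp2": rec.rp2_label,
            "vol_lung_cc": rec.vol_lung_cc,
            "vol_ptv_cc": rec.vol_ptv_cc,
            "ptv_to_lung_ratio": rec.ptv_to_lung_ratio,
            "saa_deg": rec.saa_deg if rec.saa_deg is not None else np.nan,
            "v5": v_dose(whole, 5.0),
            "v10": v_dose(whole, 10.0),
            "v20": v_dose(whole, 20.0),
            "v30": v_dose(whole, 30.0),
            "mld_cgy": 100.0 * mean_dose(whole),
            "lung_eud_cgy": 100.0 * eud_whole,
            "lung_eud1_cgy": 100.0 * eud(whole, 1.0, dose_floor),
            "ntcp_lkb_sick": ntcp_lkb(affected, lkb),
            "ntcp_lkb_total": ntcp_lkb(whole, lkb),
            "ntcp_eud_sick": ntcp_logistic_eud(eud_affected, lkb),
            "ntcp_eud_total": ntcp_logistic_eud(eud_whole, lkb),
        }
        row["physical_composite"] = physical_composite(
            row["mld_cgy"], row["v5"], row["v10"], row["v20"], row["v30"]
        )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("patient_id")
    return df[["rp2"] + FEATURE_COLUMNS]


# ---------------------------------------------------------------------------
# Group tests and correlation
# ---------------------------------------------------------------------------


@dataclass
class TTestResult:
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    t: float
    p: float
    variant: str


def two_sample_t(x, y, variant: str = "pooled") -> TTestResult:
    """Independent two-sample t-test with ``t = (mean_y - mean_x) / SE``.

    ``variant="pooled"`` is the classical equal-variance Student test;
    ``variant="welch"`` drops the equal-variance assumption. When both groups
    are constant and equal the statistic is reported as t = 0, p = 1.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate zero-variance input
        res = sps.ttest_ind(y, x, equal_var=(variant == "pooled"))
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):  # zero variance in both groups
        if np.isclose(x.mean(), y.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = np.sign(y.mean() - x.mean()) * np.inf, 0.0
    return TTestResult(
        n_x=int(x.size),
        n_y=int(y.size),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        sd_x=float(x.std(ddof=1)),
        sd_y=float(y.std(ddof=1)),
        t=t,
        p=p,
        variant=variant,
    )


def group_comparison_table(
    features: pd.DataFrame,
    variables: list | None = None,
    variant: str = "pooled",
) -> pd.DataFrame:
    """Per-variable group means/SDs and t-test between RP 2+ and non-RP 2+.

    Sign convention: ``t = (mean_nonRP - mean_RP) / SE``, so variables that
    are larger in the pneumonitis group carry a negative t.
    """
    if "rp2" not in features.columns:
        raise ValueError("feature table must contain an 'rp2' label column")
    if variables is None:
        variables = [
            c
            for c in features.columns
            if c != "rp2" and features[c].notna().all()
        ]
    grp = features[features["rp2"] == 1]
    gnrp = features[features["rp2"] == 0]
    if len(grp) < 2 or len(gnrp) < 2:
        raise ValueError("each outcome group needs at least two patients")
    rows = []
    for var in variables:
        res = two_sample_t(grp[var], gnrp[var], variant=variant)
        rows.append(
            {
                "variable": var,
                "n_grp": res.n_x,
                "mean_grp": res.mean_x,
                "sd_grp": res.sd_x,
                "n_gnrp": res.n_y,
                "mean_gnrp": res.mean_y,
                "sd_gnrp": res.sd_y,
                "t": res.t,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson requires paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def correlation_table(
    features: pd.DataFrame,
    score_cols: tuple = ("lung_eud_cgy", "lung_eud1_cgy"),
    metric_cols: tuple = ("v5", "v10", "v20", "v30", "mld_cgy"),
) -> pd.DataFrame:
    """Pearson r (and p) of each EUD column against each dosimetric metric."""
    rows = []
    for score in score_cols:
        for metric in metric_cols:
            r, p = pearson(features[score], features[metric])
            rows.append({"score": score, "metric": metric, "r": r, "p": p})
    return pd.DataFrame(rows).set_index(["score", "metric"])


# ---------------------------------------------------------------------------
# Multivariate logistic regression
# ---------------------------------------------------------------------------


def multivariate_logistic(
    X: pd.DataFrame,
    y,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> pd.DataFrame:
    """Maximum-likelihood logistic regression of a binary outcome on features.

    Fits by Newton iteration (iteratively reweighted least squares) and
    returns per-term coefficient B, standard error SE, Wald statistic
    ``(B / SE)^2`` and two-sided p-value, with the intercept as ``const``.
    Perfect separation or non-convergence raises :class:`ConvergenceError`
    rather than returning silent output.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if y.size != len(X):
        raise ValueError("X and y lengths differ")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome must contain both classes")
    if not set(classes).issubset({0.0, 1.0}):
        raise ValueError("outcome must be binary 0/1")
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need more observations than model terms")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(
            f"constant feature columns {constant} would duplicate the intercept"
        )
    # Fit on z-standardized features (clinical units span five orders of
    # magnitude, which defeats raw-scale Newton), then map the estimate and
    # its covariance back: the MLE is invariant under this linear
    # reparameterization, so coefficients are reported in the input units.
    mu = X.mean(axis=0).to_numpy()
    sd = X.std(axis=0, ddof=0).to_numpy()
    Z = (X - mu) / sd
    Zc = sm.add_constant(Z, has_constant="raise")
    model = sm.Logit(y, Zc)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # overflow en route
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(method="newton", tol=tol, maxiter=maxiter, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ConvergenceError(
            "logistic regression did not converge: perfect separation detected"
        ) from exc
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(
            "logistic regression did not converge: singular Hessian"
        ) from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"logistic regression did not converge in {maxiter} iterations"
        )
    p_terms = X.shape[1]
    # linear map from standardized-scale to raw-scale coefficients
    transform = np.zeros((p_terms + 1, p_terms + 1))
    transform[0, 0] = 1.0
    transform[0, 1:] = -mu / sd
    transform[1:, 1:] = np.diag(1.0 / sd)
    params = transform @ res.params.to_numpy()
    cov = transform @ res.cov_params().to_numpy() @ transform.T
    se = np.sqrt(np.diag(cov))
    wald = (params / se) ** 2
    pvals = 2.0 * sps.norm.sf(np.abs(params / se))
    out = pd.DataFrame(
        {"B": params, "SE": se, "Wald": wald, "p": pvals},
        index=["const"] + list(X.columns),
    )
    out.index.name = "term"
    return out


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    auc_se: float
    ci95: tuple
    cutoff: float
    youden_j: float
    roc_points: pd.DataFrame


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """Standard error of the empirical AUC by DeLong's structural components."""
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    rank_all = sps.rankdata(combined)
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    v01 = (rank_all[:m] - rank_pos) / n  # per-positive placement values
    v10 = 1.0 - (rank_all[m:] - rank_neg) / m  # per-negative placement values
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s01 / m + s10 / n))


def roc_analysis(scores, labels) -> RocResult:
    """Empirical ROC curve with AUC, Youden-index cutoff and DeLong 95% CI.

    The AUC is the Mann-Whitney concordance probability with tie correction.
    The operating cutoff maximizes Youden's J = sensitivity + specificity - 1
    under the rule "positive when score >= cutoff"; it is reported as the
    midpoint between the optimal score threshold and the next score below it
    so the cutoff separates the observed values.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size != labels.size:
        raise ValueError("scores and labels lengths differ")
    if np.unique(labels).size < 2:
        raise ValueError("ROC analysis requires both classes")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    finite = np.isfinite(thresholds)
    j = tpr - fpr
    j_finite = j[finite]
    thr_finite = thresholds[finite]
    best = int(np.argmax(j_finite))
    best_thr = float(thr_finite[best])
    below = scores[scores < best_thr]
    cutoff = float(0.5 * (best_thr + below.max())) if below.size else best_thr
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    se = _delong_se(pos, neg)
    half = 1.959963984540054 * se
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return RocResult(
        auc=auc,
        auc_se=se,
        ci95=ci,
        cutoff=cutoff,
        youden_j=float(j_finite[best]),
        roc_points=points,
    )


def roc_table(
    features: pd.DataFrame,
    predictors: list | None = None,
    label_col: str = "rp2",
) -> pd.DataFrame:
    """AUC, cutoff and 95% CI for each predictor column against the outcome."""
    if predictors is None:
        predictors = [
            "physical_composite",
            "lung_eud_cgy",
            "ptv_to_lung_ratio",
            "ntcp_lkb_sick",
            "ntcp_eud_sick",
            "ntcp_eud_total",
            "ntcp_lkb_total",
        ]
    rows = []
    for col in predictors:
        res = roc_analysis(features[col], features[label_col])
        rows.append(
            {
                "predictor": col,
                "auc": res.auc,
                "cutoff": res.cutoff,
                "ci_low": res.ci95[0],
                "ci_high": res.ci95[1],
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


# ---------------------------------------------------------------------------
# Risk stratification
# ---------------------------------------------------------------------------


@dataclass
class StratifyResult:
    variable: str
    cutoff: float
    low: pd.DataFrame
    high: pd.DataFrame
    summaries: pd.DataFrame


def stratify(
    features: pd.DataFrame,
    variable: str,
    cutoff: float,
    selected: list | None = None,
) -> StratifyResult:
    """Split patients into low-risk (< cutoff) and high-risk (>= cutoff) groups.

    For every other selected variable, per-group distribution summaries are
    emitted split by RP 2+ status (n, mean, SD and quartiles) - the data
    behind risk-group violin plots. An empty risk group is reported, not an
    error.
    """
    if variable not in features.columns:
        raise ValueError(f"variable {variable!r} not in feature table")
    if selected is None:
        selected = [
            c
            for c in features.columns
            if c not in (variable, "rp2")
            and pd.api.types.is_numeric_dtype(features[c])
        ]
    low = features[features[variable] < cutoff]
    high = features[features[variable] >= cutoff]
    rows = []
    for risk_name, part in (("low", low), ("high", high)):
        for rp2 in (0, 1):
            sub = part[part["rp2"] == rp2]
            for var in selected:
                vals = sub[var].dropna()
                rows.append(
                    {
                        "variable": var,
                        "risk_group": risk_name,
                        "rp2": rp2,
                        "n": int(vals.size),
                        "mean": float(vals.mean()) if vals.size else np.nan,
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                        "q25": float(vals.quantile(0.25)) if vals.size else np.nan,
                        "median": float(vals.median()) if vals.size else np.nan,
                        "q75": float(vals.quantile(0.75)) if vals.size else np.nan,
                    }
                )
    columns = [
        "variable", "risk_group", "rp2", "n", "mean", "sd", "q25", "median", "q75",
    ]
    summaries = pd.DataFrame(rows, columns=columns).set_index(
        ["variable", "risk_group", "rp2"]
    )
    return StratifyResult(
        variable=variable,
        cutoff=float(cutoff),
        low=low,
        high=high,
        summaries=summaries,
    )
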