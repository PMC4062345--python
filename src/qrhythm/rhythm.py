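"""Single-harmonic cosinor fitting and the two-part daily-rhythmicity call.

The model is ``y(t) = M + A*cos(2*pi*t/period - phi)`` with a fixed
period (24 h by default). Writing it as ``M + beta_c*cos(omega*t) +
beta_s*sin(omega*t)`` makes the fit ordinary least squares; amplitude and
acrophase follow from the rectangular coefficients and the amplitude
standard error from the delta method on the OLS covariance.

The rhythmicity significance statistic is the amplitude noise/signal
ratio ``P = SE(A)/A``; a gene is called rhythmic when ``P < 0.3`` *and* a
time-of-day omnibus test (one-way ANOVA when per-group normality and
equal variance hold, Kruskal-Wallis otherwise) gives p < 0.05. Both
inequalities are strict: boundary values are non-rhythmic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

DEFAULT_PERIOD_H = 24.0
DEFAULT_PNS_THRESHOLD = 0.3
DEFAULT_OMNIBUS_ALPHA = 0.05
GATE_ALPHA = 0.05  # normality / equal-variance gates for the omnibus test


@dataclass(frozen=True)
class CosinorFit:
    """Least-squares cosinor parameters for one gene.

    ``phase_rad`` is in [0, 2*pi); ``acrophase_h = phase_rad * period_h /
    (2*pi)`` is the fitted peak time in hours. ``p_ns = se_amplitude /
    amplitude`` is the noise/signal statistic (+inf when the fitted
    amplitude is exactly zero, flagged by ``amplitude_zero``).
    """

    gene: str
    mesor: float
    amplitude: float
    phase_rad: float
    acrophase_h: float
    se_amplitude: float
    p_ns: float
    n_obs: int
    residual_df: int
    period_h: float
    amplitude_zero: bool = False


@dataclass(frozen=True)
class OmnibusResult:
    p_value: float
    method: str  # "anova" | "kruskal_wallis"
    n_groups: int


@dataclass(frozen=True)
class RhythmCall:
    gene: str
    p_ns: float
    omnibus_p: float
    omnibus_method: str
    rhythmic: bool


def fit_cosinor(
    times_h,
    values,
    period_h: float = DEFAULT_PERIOD_H,
    gene: str = "?",
) -> CosinorFit:
    """Fit ``M + A*cos(2*pi*t/period - phi)`` by OLS.

    Requires at least 4 observations covering at least 3 distinct phases
    (otherwise the three-column design is rank deficient). SE(A) comes
    from the delta method: with g = (beta_c, beta_s)/A,
    ``SE(A)^2 = g' Cov(beta_c, beta_s) g``.
    """
    if period_h <= 0:
        raise ValueError("period_h must be > 0")
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = ~(np.isnan(t) | np.isnan(y))
    t, y = t[keep], y[keep]
    if t.size < 4:
        raise ValueError(f"{gene}: cosinor fit needs >=4 observations, got {t.size}")
    omega = 2 * math.pi / period_h
    phase = np.mod(t, period_h)
    if np.unique(np.round(phase, 9)).size < 3:
        raise ValueError(f"{gene}: need >=3 distinct phases for a cosinor fit")

    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    model = sm.OLS(y, X).fit()
    mesor, beta_c, beta_s = model.params
    amplitude = float(math.hypot(beta_c, beta_s))
    phi = float(math.atan2(beta_s, beta_c) % (2 * math.pi))
    cov = np.asarray(model.cov_params())
    # a constant series gives amplitude at rounding-error level; treat
    # anything below machine precision of the data scale as exactly flat
    flat_tol = 1e-12 * max(1.0, float(np.max(np.abs(y))))
    if amplitude > flat_tol:
        grad = np.array([beta_c, beta_s]) / amplitude
        se_a = float(math.sqrt(grad @ cov[1:, 1:] @ grad))
        p_ns = se_a / amplitude
        amp_zero = False
    else:
        # flat fit: amplitude 0, direction undefined
        amplitude = 0.0
        se_a = float(math.sqrt(max(cov[1, 1], cov[2, 2])))
        p_ns = math.inf
        amp_zero = True
    return CosinorFit(
        gene=gene,
        mesor=float(mesor),
        amplitude=amplitude,
        phase_rad=phi,
        acrophase_h=phi * period_h / (2 * math.pi),
        se_amplitude=se_a,
        p_ns=float(p_ns),
        n_obs=int(t.size),
        residual_df=int(t.size - 3),
        period_h=float(period_h),
        amplitude_zero=amp_zero,
    )


def _group_normality_ok(groups: list[np.ndarray], alpha: float) -> bool:
    """Pooled Shapiro-Wilk decision: any group failing (p < alpha) fails.

    A constant group has no defined Shapiro statistic and counts as a
    failure (the parametric path is not trusted for it).
    """
    for g in groups:
        if np.ptp(g) == 0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = stats.shapiro(g).pvalue
        if p < alpha:
            return False
    return True


def _equal_variance_ok(groups: list[np.ndarray], alpha: float) -> bool:
    """Brown-Forsythe test (Levene centered at the median)."""
    if all(np.ptp(g) == 0 for g in groups):
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.levene(*groups, center="median").pvalue
    if np.isnan(p):
        return False
    return p >= alpha


def omnibus_time_test(
    times_h, values, gate_alpha: float = GATE_ALPHA
) -> OmnibusResult:
    """Omnibus test for any expression difference between timepoints.

    Runs one-way ANOVA when every timepoint group passes Shapiro-Wilk
    normality and the groups pass the Brown-Forsythe equal-variance test
    (both at ``gate_alpha``); otherwise Kruskal-Wallis. Groups with fewer
    than 2 observations are dropped with a warning. All-identical data
    (omnibus undefined) returns p = 1 on the Kruskal-Wallis path.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = ~(np.isnan(t) | np.isnan(y))
    t, y = t[keep], y[keep]
    groups = []
    for tp in np.unique(t):
        g = y[t == tp]
        if g.size < 2:
            log.warning("omnibus_time_test: dropping timepoint %s with %d observation(s)",
                        tp, g.size)
            continue
        groups.append(g)
    if len(groups) < 2:
        raise ValueError("omnibus test needs >=2 groups with >=2 observations each")

    parametric = _group_normality_ok(groups, gate_alpha) and _equal_variance_ok(
        groups, gate_alpha
    )
    if parametric:
        p = float(stats.f_oneway(*groups).pvalue)
        method = "anova"
    else:
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            p = 1.0  # no variation anywhere: no evidence of a time effect
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(stats.kruskal(*groups).pvalue)
        method = "kruskal_wallis"
    return OmnibusResult(p_value=p, method=method, n_groups=len(groups))


def classify_rhythmic(
    fit: CosinorFit,
    omnibus: OmnibusResult,
    p_ns_threshold: float = DEFAULT_PNS_THRESHOLD,
    omnibus_alpha: float = DEFAULT_OMNIBUS_ALPHA,
) -> RhythmCall:
    """Two-part rhythmicity call: P = SE(A)/A below threshold AND a
    significant omnibus time effect. Strict inequalities on both."""
    rhythmic = (fit.p_ns < p_ns_threshold) and (omnibus.p_value < omnibus_alpha)
    return RhythmCall(
        gene=fit.gene,
        p_ns=fit.p_ns,
        omnibus_p=omnibus.p_value,
        omnibus_method=omnibus.method,
        rhythmic=bool(rhythmic),
    )


@dataclass
class RhythmScreen:
    """Per-gene cosinor fits and rhythm calls for a whole matrix."""

    table: pd.DataFrame
    fits: dict[str, CosinorFit]
    calls: dict[str, RhythmCall]
    unfit: dict[str, str]

    @property
    def n_rhythmic(self) -> int:
        return int(self.table["rhythmic"].fillna(False).sum())

    @property
    def rhythmic_genes(self) -> list[str]:
        return list(self.table.loc[self.table["rhythmic"] == True, "gene"])  # noqa: E712


def rhythm_screen(
    expr: ExpressionMatrix,
    period_h: float = DEFAULT_PERIOD_H,
    p_ns_threshold: float = DEFAULT_PNS_THRESHOLD,
    omnibus_alpha: float = DEFAULT_OMNIBUS_ALPHA,
    collapse_means: bool = False,
) -> RhythmScreen:
    """Fit, test and classify every gene of an expression matrix.

    By default the cosinor is fitted to replicate-level observations; with
    ``collapse_means=True`` it is fitted to per-timepoint mean profiles
    (the omnibus test always uses replicate-level data). Genes that
    violate fit preconditions are reported in ``unfit`` rather than
    aborting the screen. Gene order follows the input matrix.
    """
    times = expr.zt_hours
    fits: dict[str, CosinorFit] = {}
    calls: dict[str, RhythmCall] = {}
    unfit: dict[str, str] = {}
    rows = []
    for gene in expr.genes:
        y = expr.gene_values(gene)
        try:
            if collapse_means:
                prof = expr.subset_genes([gene]).timepoint_means()
                fit = fit_cosinor(prof.columns.to_numpy(float), prof.iloc[0].to_numpy(),
                                  period_h, gene=gene)
            else:
                fit = fit_cosinor(times, y, period_h, gene=gene)
            omnibus = omnibus_time_test(times, y)
        except ValueError as exc:
            unfit[gene] = str(exc)
            rows.append({"gene": gene, "mesor": np.nan, "amplitude": np.nan,
                         "acrophase_h": np.nan, "se_amplitude": np.nan, "p_ns": np.nan,
                         "omnibus_p": np.nan, "omnibus_method": "unfit",
                         "rhythmic": pd.NA})
            continue
        call = classify_rhythmic(fit, omnibus, p_ns_threshold, omnibus_alpha)
        fits[gene] = fit
        calls[gene] = call
        rows.append({
            "gene": gene,
            "mesor": fit.mesor,
            "amplitude": fit.amplitude,
            "acrophase_h": fit.acrophase_h,
            "se_amplitude": fit.se_amplitude,
            "p_ns": fit.p_ns,
            "omnibus_p": omnibus.p_value,
            "omnibus_method": omnibus.method,
            "rhythmic": call.rhythmic,
        })
    table = pd.DataFrame(rows)
    return RhythmScreen(table=table, fits=fits, calls=calls, unfit=unfit)
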