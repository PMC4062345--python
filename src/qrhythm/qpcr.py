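"""Raw Ct tables to normalized relative expression.

Four stages, each usable on its own:

1. :func:`fit_standard_curve` — OLS of Ct on log10(relative concentration)
   for a dilution series; amplification efficiency ``E = 10**(-1/slope)``.
2. :func:`relative_quantity` — efficiency-corrected relative quantities
   ``RQ = E**(Ct_cal - Ct)`` with the per-gene minimum Ct as calibrator.
3. :func:`genorm_rank` — geNorm stability ranking of candidate reference
   genes (mean pairwise variation of log2 ratios, iterative exclusion).
4. :func:`normalize` — division by the geometric mean of the selected
   reference genes, removing per-sample loading factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, validate_ct_table

log = logging.getLogger(__name__)


class QuantificationError(ValueError):
    """Raised when a Ct table or standard curve violates the model."""


@dataclass(frozen=True)
class StandardCurve:
    """Dilution-series fit for one gene.

    ``slope`` is in cycles per log10(dilution) and must be negative;
    ``efficiency = 10**(-1/slope)`` is the fold-increase per cycle
    (2.0 for perfect doubling).
    """

    gene: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_levels: int

    def __post_init__(self) -> None:
        if self.efficiency > 2.1 or self.efficiency < 1.6:
            warnings.warn(
                f"{self.gene}: amplification efficiency {self.efficiency:.3f} outside"
                " the usual 1.6-2.1 range",
                stacklevel=2,
            )


@dataclass
class StabilityRanking:
    """geNorm result: per-gene M values, exclusion order, selected pair.

    ``m_values`` holds the M value each gene had at the step it was
    excluded (for the final pair, the M of the two-gene stage);
    ``steps`` records the full M table of every iteration.
    """

    m_values: dict[str, float]
    exclusion_order: list[str]
    selected_pair: tuple[str, str]
    steps: list[dict[str, float]] = field(default_factory=list)


def fit_standard_curve(dilution_rows: pd.DataFrame, gene: str | None = None) -> StandardCurve:
    """Fit a standard curve by OLS of Ct on log10(relative concentration).

    ``dilution_rows`` needs columns ``log10_dilution`` and ``ct`` (a
    ``gene`` column is used for the label when present). At least three
    distinct dilution levels are required and the slope must be negative.
    """
    if gene is None:
        gene = str(dilution_rows["gene"].iloc[0]) if "gene" in dilution_rows else "?"
    x = dilution_rows["log10_dilution"].to_numpy(dtype=float)
    y = dilution_rows["ct"].to_numpy(dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n_levels = len(np.unique(x))
    if n_levels < 3:
        raise QuantificationError(
            f"{gene}: standard curve needs >=3 distinct dilution levels, got {n_levels}"
        )
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise QuantificationError(f"{gene}: invalid curve (slope {res.slope:.3f} >= 0)")
    return StandardCurve(
        gene=gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(10 ** (-1.0 / res.slope)),
        n_levels=int(n_levels),
    )


def fit_standard_curves(dilution_table: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one curve per gene from a long dilution table (gene, log10_dilution, ct)."""
    return {
        str(g): fit_standard_curve(rows, gene=str(g))
        for g, rows in dilution_table.groupby("gene", sort=False)
    }


def relative_quantity(
    ct_table: pd.DataFrame, curves: dict[str, StandardCurve]
) -> ExpressionMatrix:
    """Efficiency-corrected relative quantities from a tidy Ct table.

    For gene ``g`` and sample ``s``, ``RQ = E_g**(Ct_cal(g) - Ct(g, s))``
    where the calibrator ``Ct_cal(g)`` is the minimum observed Ct of the
    gene (its most-expressed sample, so RQ = 1 there and RQ <= 1
    elsewhere). The calibrator is an arbitrary per-gene scale: cosinor P,
    acrophase, omnibus p and Pearson r are all invariant to it. Missing Ct
    propagates to missing RQ.
    """
    ct = validate_ct_table(ct_table)
    missing_curves = sorted(set(ct["gene"]) - set(curves))
    if missing_curves:
        raise QuantificationError(f"no standard curve for gene(s): {missing_curves}")

    wide = ExpressionMatrix.from_tidy(ct.rename(columns={"ct": "value"}))
    rq_rows = {}
    for gene in wide.genes:
        e = curves[gene].efficiency
        ct_g = wide.values.loc[gene].to_numpy(dtype=float)
        if np.all(np.isnan(ct_g)):
            rq_rows[gene] = np.full_like(ct_g, np.nan)
            continue
        ct_cal = np.nanmin(ct_g)
        rq_rows[gene] = np.power(e, ct_cal - ct_g)
    values = pd.DataFrame(rq_rows, index=wide.sample_ids).T
    return ExpressionMatrix(values, wide.sample_meta.copy())


def _genorm_m_values(log2_rq: pd.DataFrame) -> pd.Series:
    """M_j = mean over k != j of SD_samples(log2 RQ_j - log2 RQ_k)."""
    genes = list(log2_rq.index)
    m = {}
    for j in genes:
        v = [
            float(np.std(log2_rq.loc[j] - log2_rq.loc[k], ddof=1))
            for k in genes
            if k != j
        ]
        m[j] = float(np.mean(v))
    return pd.Series(m)


def genorm_rank(rq: ExpressionMatrix | pd.DataFrame, candidates: list[str] | None = None) -> StabilityRanking:
    """Rank candidate reference genes by geNorm expression stability.

    The pairwise variation of genes j and k is the standard deviation over
    samples of log2(RQ_j/RQ_k); a gene's M value is its mean pairwise
    variation against all remaining candidates. The least stable gene
    (highest M, ties broken by reverse lexical order so the alphabetically
    earlier gene survives) is excluded and M recomputed, until the two
    most stable genes remain.
    """
    values = rq.values if isinstance(rq, ExpressionMatrix) else rq
    if candidates is not None:
        missing = sorted(set(candidates) - set(values.index))
        if missing:
            raise QuantificationError(f"candidate(s) not in matrix: {missing}")
        values = values.loc[candidates]
    if values.shape[0] < 3:
        raise QuantificationError("geNorm needs >=3 candidate reference genes")
    if values.shape[1] < 2:
        raise QuantificationError("geNorm needs >=2 samples")
    arr = values.to_numpy(dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise QuantificationError("geNorm requires strictly positive, finite RQ values")

    log2_rq = np.log2(values)
    remaining = list(values.index)
    exclusion_order: list[str] = []
    final_m: dict[str, float] = {}
    steps: list[dict[str, float]] = []
    while len(remaining) > 2:
        m = _genorm_m_values(log2_rq.loc[remaining])
        steps.append(m.to_dict())
        worst_m = m.max()
        # highest M leaves; among ties the lexically last name leaves
        worst = max(g for g in remaining if m[g] == worst_m)
        final_m[worst] = float(m[worst])
        exclusion_order.append(worst)
        remaining.remove(worst)
    m = _genorm_m_values(log2_rq.loc[remaining])
    steps.append(m.to_dict())
    for g in remaining:
        final_m[g] = float(m[g])
    pair = tuple(sorted(remaining))
    return StabilityRanking(final_m, exclusion_order, pair, steps)


def normalize(
    rq: ExpressionMatrix, references: list[str] | tuple[str, ...]
) -> ExpressionMatrix:
    """Normalize target RQs by the geometric mean of the reference genes.

    Reference genes are removed from the output. Samples where any
    reference RQ is missing or non-positive get all-missing normalized
    values (with a logged warning); nothing is imputed.
    """
    references = list(references)
    missing = sorted(set(references) - set(rq.values.index))
    if missing:
        raise QuantificationError(f"reference gene(s) not in matrix: {missing}")
    ref_vals = rq.values.loc[references].to_numpy(dtype=float)
    bad = ~np.isfinite(ref_vals) | (ref_vals <= 0)
    bad_samples = bad.any(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        geo = np.exp(np.mean(np.log(ref_vals), axis=0))
    geo[bad_samples] = np.nan
    if bad_samples.any():
        names = [s for s, b in zip(rq.sample_ids, bad_samples) if b]
        log.warning("normalize: reference RQ missing/non-positive in samples %s; "
                    "their normalized values set missing", names)

    targets = [g for g in rq.genes if g not in references]
    out = rq.values.loc[targets].divide(pd.Series(geo, index=rq.sample_ids), axis=1)
    norm = ExpressionMatrix(out, rq.sample_meta.copy(), dict(rq.attrs))
    norm.attrs["references"] = references
    return norm


def quantify_and_normalize(
    ct_table: pd.DataFrame,
    dilution_table: pd.DataFrame,
    reference_candidates: list[str],
    references: list[str] | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """Full quantification stage: curves -> RQ -> reference choice -> normalize.

    When ``references`` is None, the two most stable candidates selected
    by geNorm are used. Returns the normalized matrix plus a report dict
    (per-gene efficiency/R^2, M values, selected references).
    """
    curves = fit_standard_curves(dilution_table)
    rq = relative_quantity(ct_table, curves)
    ranking = None
    if references is None:
        ranking = genorm_rank(rq, reference_candidates)
        references = list(ranking.selected_pair)
    expr = normalize(rq, references)
    report = {
        "curves": {
            g: {
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "efficiency": c.efficiency,
                "n_levels": c.n_levels,
            }
            for g, c in sorted(curves.items())
        },
        "reference_candidates": list(reference_candidates),
        "genorm_m_values": ranking.m_values if ranking else None,
        "genorm_exclusion_order": ranking.exclusion_order if ranking else None,
        "selected_references": list(references),
    }
    return expr, report
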