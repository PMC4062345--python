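"""Pearson correlation screening between gene expression profiles.

Every unordered pair drawn from two gene sets is correlated (over
per-timepoint mean profiles by default, or over sample-matched replicate
values) and retained when |r| exceeds a threshold and at least one member
of the pair was called rhythmic. Retained pairs carry a magnitude
category: moderate for 0.5 < |r| < 0.70, strong for |r| >= 0.70.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix
from .rhythm import RhythmScreen

MODERATE_THRESHOLD = 0.5
STRONG_THRESHOLD = 0.70


@dataclass(frozen=True)
class CorrelationPair:
    gene_a: str
    gene_b: str
    r: float
    n_points: int
    category: str  # "none" | "moderate" | "strong"
    sign: str  # "positive" | "negative"
    has_rhythmic_partner: bool


def categorize(r: float) -> str:
    """Magnitude category on |r|: strong >= 0.70, moderate above 0.5."""
    a = abs(r)
    if a >= STRONG_THRESHOLD:
        return "strong"
    if a > MODERATE_THRESHOLD:
        return "moderate"
    return "none"


def _profiles(expr: ExpressionMatrix, gene_a: str, gene_b: str, mode: str):
    if mode == "means":
        means = expr.subset_genes([gene_a, gene_b]).timepoint_means()
        x = means.loc[gene_a].to_numpy(dtype=float)
        y = means.loc[gene_b].to_numpy(dtype=float)
    elif mode == "replicates":
        x = expr.gene_values(gene_a)
        y = expr.gene_values(gene_b)
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'means' or 'replicates')")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson_profile(
    expr: ExpressionMatrix, gene_a: str, gene_b: str, mode: str = "means"
) -> tuple[float, int]:
    """Pearson r between two genes' profiles; returns (r, n_points).

    In ``means`` mode the profiles are per-timepoint means (n = number of
    timepoints); in ``replicates`` mode values are paired sample-by-sample.
    """
    x, y = _profiles(expr, gene_a, gene_b, mode)
    if x.size < 3:
        raise ValueError(f"({gene_a}, {gene_b}): need >=3 paired points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"({gene_a}, {gene_b}): undefined correlation (zero variance)")
    r = float(stats.pearsonr(x, y).statistic)
    return r, int(x.size)


def screen_pairs(
    expr: ExpressionMatrix,
    rhythmic: dict[str, bool] | RhythmScreen,
    gene_set_a: list[str],
    gene_set_b: list[str] | None = None,
    threshold: float = MODERATE_THRESHOLD,
    mode: str = "means",
) -> list[CorrelationPair]:
    """Correlation screen with the rhythmic-partner filter.

    All unordered pairs (a, b) with a in ``gene_set_a`` and b in
    ``gene_set_b`` (within-set pairs when the sets overlap or
    ``gene_set_b`` is None) are computed; a pair is retained iff
    |r| > ``threshold`` and at least one member is rhythmic. Output is
    sorted positive pairs first, then by descending |r|, then by gene
    names. Self-pairs are never emitted.
    """
    if isinstance(rhythmic, RhythmScreen):
        rhythmic = {g: c.rhythmic for g, c in rhythmic.calls.items()}
    if gene_set_b is None:
        gene_set_b = gene_set_a
    involved = set(gene_set_a) | set(gene_set_b)
    missing_calls = sorted(g for g in involved if g not in rhythmic)
    if missing_calls:
        raise ValueError(f"no rhythm call for gene(s): {missing_calls}")

    seen: set[tuple[str, str]] = set()
    out: list[CorrelationPair] = []
    for a in gene_set_a:
        for b in gene_set_b:
            if a == b:
                continue
            key = tuple(sorted((a, b)))
            if key in seen:
                continue
            seen.add(key)
            r, n = pearson_profile(expr, key[0], key[1], mode=mode)
            if abs(r) <= threshold:
                continue
            partner = bool(rhythmic[key[0]] or rhythmic[key[1]])
            if not partner:
                continue
            out.append(
                CorrelationPair(
                    gene_a=key[0],
                    gene_b=key[1],
                    r=r,
                    n_points=n,
                    category=categorize(r),
                    sign="positive" if r > 0 else "negative",
                    has_rhythmic_partner=partner,
                )
            )
    out.sort(key=lambda p: (p.sign != "positive", -abs(p.r), p.gene_a, p.gene_b))
    return out


def pairs_to_frame(pairs: list[CorrelationPair]) -> pd.DataFrame:
    cols = ["gene_a", "gene_b", "r", "n_points", "category", "sign",
            "has_rhythmic_partner"]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in pairs], columns=cols)


def correlation_matrix(
    expr: ExpressionMatrix, genes: list[str] | None = None, mode: str = "means"
) -> pd.DataFrame:
    """Symmetric gene-by-gene Pearson r matrix (diagonal 1)."""
    genes = genes or expr.genes
    n = len(genes)
    mat = pd.DataFrame(np.eye(n), index=genes, columns=genes)
    for i in range(n):
        for j in range(i + 1, n):
            r, _ = pearson_profile(expr, genes[i], genes[j], mode=mode)
            mat.iloc[i, j] = mat.iloc[j, i] = r
    return mat
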