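"""Synthetic qPCR study generator with known cosinor ground truth.

Emulates a daily-sampling qPCR experiment: a fixed set of zeitgeber
timepoints over one 24-h cycle, several biological replicates per
timepoint (each replicate an independent animal/tank, so ZT0 and ZT24 are
distinct samples at the same circadian phase), target genes with known
mesor/amplitude/acrophase, candidate reference genes of varying stability,
gene-specific amplification efficiencies, and a simple noise model:
additive Gaussian noise on the expression scale plus a shared
log-normal per-sample technical factor (the loading variation that
reference-gene normalization is meant to remove).

Ct values are generated by inverting the efficiency-corrected
quantification model (``Ct = ct0 - log_E(expression)``); no fluorescence
traces are simulated.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .matrix import CT_COLUMNS, ExpressionMatrix

#: Zeitgeber sampling grids shipped as presets. ``ZT_PRINTED`` is the
#: nine-point daily design with the irregular ZT20 point; ``ZT_UNIFORM``
#: is the strictly 3-hourly variant (ZT21 instead of ZT20).
ZT_PRINTED = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 20.0, 24.0)
ZT_UNIFORM = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0, 24.0)

EXPRESSION_FLOOR = 1e-6


@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth cosinor parameters and assay efficiency for one gene.

    ``mesor`` and ``amplitude`` are on the linear normalized-expression
    scale; ``acrophase_h`` is the peak time in hours within [0, 24);
    ``noise_sd`` is the additive Gaussian SD on the same scale;
    ``efficiency`` is the qPCR fold-per-cycle in (1, 2].
    """

    name: str
    mesor: float
    amplitude: float = 0.0
    acrophase_h: float = 0.0
    noise_sd: float = 0.0
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"{self.name}: amplitude must be >= 0")
        if not 0 <= self.acrophase_h < 24:
            raise ValueError(f"{self.name}: acrophase_h must be in [0, 24)")
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd must be >= 0")
        if not 1 < self.efficiency <= 2:
            raise ValueError(f"{self.name}: efficiency must be in (1, 2]")

    def expression_at(self, t_hours: np.ndarray, period_h: float = 24.0) -> np.ndarray:
        """Noise-free cosinor value M + A*cos(2*pi*t/period - phi)."""
        omega = 2 * math.pi / period_h
        phi = omega * self.acrophase_h
        return self.mesor + self.amplitude * np.cos(omega * np.asarray(t_hours, float) - phi)


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design: timepoints, replication, references, noise, seed."""

    timepoints_h: tuple[float, ...] = ZT_PRINTED
    n_replicates: int = 6
    reference_specs: tuple[GeneSpec, ...] = ()
    sample_factor_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints_h) == 0:
            raise ValueError("timepoints_h must be non-empty")
        if any(not 0 <= t <= 24 for t in self.timepoints_h):
            raise ValueError("timepoints_h values must lie in [0, 24]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sample_factor_sd < 0:
            raise ValueError("sample_factor_sd must be >= 0")
        object.__setattr__(self, "timepoints_h", tuple(float(t) for t in self.timepoints_h))
        object.__setattr__(self, "reference_specs", tuple(self.reference_specs))

    @property
    def n_samples(self) -> int:
        return len(self.timepoints_h) * self.n_replicates

    def sample_frame(self) -> pd.DataFrame:
        """One row per sample: id, zt_hours, replicate (timepoint-major)."""
        rows = [
            (f"ZT{t:04.1f}_r{r}", t, r)
            for t in self.timepoints_h
            for r in range(1, self.n_replicates + 1)
        ]
        return pd.DataFrame(rows, columns=["sample_id", "zt_hours", "replicate"]).set_index(
            "sample_id"
        )


@dataclass
class SimulatedExpression:
    """Bundle returned by :func:`generate_expression`."""

    expression: ExpressionMatrix
    truth: pd.DataFrame
    n_clipped: int


@dataclass
class SimulatedCtStudy:
    """Bundle returned by :func:`generate_ct_table`."""

    ct_table: pd.DataFrame
    truth: pd.DataFrame
    expression: ExpressionMatrix
    ct_at_unit_expression: float
    n_missing: int


def truth_table(genes: list[GeneSpec]) -> pd.DataFrame:
    """Ground-truth parameters, one row per gene; rhythmic iff amplitude > 0."""
    return pd.DataFrame(
        {
            "gene": [g.name for g in genes],
            "mesor": [g.mesor for g in genes],
            "amplitude": [g.amplitude for g in genes],
            "acrophase_h": [g.acrophase_h for g in genes],
            "rhythmic": [g.amplitude > 0 for g in genes],
        }
    )


def _all_specs(design: DesignSpec, genes: list[GeneSpec]) -> list[GeneSpec]:
    specs = list(genes) + list(design.reference_specs)
    names = [g.name for g in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene names across targets and references")
    return specs


def generate_expression(
    design: DesignSpec,
    genes: list[GeneSpec],
    floor: float | None = EXPRESSION_FLOOR,
) -> SimulatedExpression:
    """Simulate a normalized-expression matrix for the given design.

    Each value is ``factor_s * (M_g + A_g*cos(2*pi*t/24 - phi_g) + eps)``
    with ``eps ~ N(0, noise_sd_g)`` and ``factor_s = exp(N(0,
    sample_factor_sd))`` shared by all genes of sample ``s``. Values below
    ``floor`` (default 1e-6) are clipped up to it; the clip count is
    reported and also stored in ``expression.attrs['n_clipped']``.
    """
    specs = _all_specs(design, genes)
    rng = np.random.default_rng(design.seed)
    samples = design.sample_frame()
    t = samples["zt_hours"].to_numpy()

    factors = np.exp(rng.normal(0.0, design.sample_factor_sd, size=len(samples)))
    rows = []
    for g in specs:
        base = g.expression_at(t)
        eps = rng.normal(0.0, g.noise_sd, size=len(samples)) if g.noise_sd > 0 else 0.0
        rows.append(factors * (base + eps))
    values = pd.DataFrame(rows, index=[g.name for g in specs], columns=samples.index)

    n_clipped = 0
    if floor is not None:
        below = values.to_numpy() < floor
        n_clipped = int(below.sum())
        values = values.clip(lower=floor)

    expr = ExpressionMatrix(values, samples.copy(), {"n_clipped": n_clipped})
    return SimulatedExpression(expr, truth_table(specs), n_clipped)


def expression_to_ct(
    expression: np.ndarray, efficiency: float, ct_at_unit_expression: float
) -> np.ndarray:
    """Invert the quantification model: Ct = ct0 - log_E(expression).

    Non-positive expression has no finite Ct and maps to NaN; positive
    values below the expression floor are raised to it first.
    """
    x = np.asarray(expression, dtype=float)
    out = np.full_like(x, np.nan)
    pos = x > 0
    clipped = np.where(x[pos] < EXPRESSION_FLOOR, EXPRESSION_FLOOR, x[pos])
    out[pos] = ct_at_unit_expression - np.log(clipped) / np.log(efficiency)
    return out


def generate_ct_table(
    design: DesignSpec,
    genes: list[GeneSpec],
    ct_at_unit_expression: float = 30.0,
    ct_noise_sd: float = 0.0,
) -> SimulatedCtStudy:
    """Simulate a raw Ct table by inverting the quantification model.

    Quantifying the returned table with the true per-gene efficiencies
    recovers the expression matrix up to noise and one scale factor per
    gene (the calibrator choice).
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    sim = generate_expression(design, genes, floor=None)
    expr = sim.expression
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))

    records = []
    for g in _all_specs(design, genes):
        ct = expression_to_ct(expr.gene_values(g.name), g.efficiency, ct_at_unit_expression)
        if ct_noise_sd > 0:
            ct = ct + rng.normal(0.0, ct_noise_sd, size=ct.shape)
        for sample_id, zt, rep, c in zip(
            expr.sample_ids,
            expr.sample_meta["zt_hours"],
            expr.sample_meta["replicate"],
            ct,
        ):
            records.append((sample_id, g.name, zt, rep, c))
    table = pd.DataFrame(records, columns=CT_COLUMNS)
    n_missing = int(table["ct"].isna().sum())
    return SimulatedCtStudy(table, sim.truth, expr, ct_at_unit_expression, n_missing)


def generate_dilution_series(
    gene: GeneSpec,
    points: int = 5,
    fold: float = 2.0,
    base_ct: float = 20.0,
    ct_noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Standard-curve input rows for one gene's dilution series.

    Step ``i`` (0-based) has relative concentration ``fold**-i``, i.e.
    ``log10_dilution = -i*log10(fold)``, and Ct rising by
    ``log(fold)/log(E)`` cycles per step. With zero Ct noise the fitted
    efficiency equals the specified one exactly.
    """
    if points < 3:
        raise ValueError("points must be >= 3")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    i = np.arange(points, dtype=float)
    log10_dil = -i * math.log10(fold)
    ct = base_ct + i * math.log(fold) / math.log(gene.efficiency)
    if ct_noise_sd > 0:
        rng = np.random.default_rng(seed)
        ct = ct + rng.normal(0.0, ct_noise_sd, size=points)
    return pd.DataFrame({"gene": gene.name, "log10_dilution": log10_dil, "ct": ct})


# ---------------------------------------------------------------------------
# Demo study: a full synthetic dataset mirroring the daily-rhythm design
# (9 timepoints x 6 replicates, 16 targets, 3 candidate references).

DEMO_TARGET_SPECS = (
    GeneSpec("arntl1", 10.0, 0.6, 14.6, 1.2, 1.92),
    GeneSpec("arntl2", 10.0, 3.6, 16.1, 1.0, 1.95),
    GeneSpec("clock", 10.0, 2.8, 9.0, 1.0, 1.88),
    GeneSpec("npas2", 10.0, 2.6, 4.4, 1.0, 1.97),
    GeneSpec("cry1a", 10.0, 0.5, 15.6, 1.2, 1.90),
    GeneSpec("cry1b", 10.0, 0.5, 19.3, 1.2, 1.86),
    GeneSpec("cry-dash", 10.0, 0.0, 0.0, 1.2, 1.93),
    GeneSpec("cry2", 10.0, 2.9, 1.0, 1.0, 1.94),
    GeneSpec("cry3", 10.0, 2.4, 2.5, 1.1, 1.89),
    GeneSpec("per1", 10.0, 0.0, 0.0, 1.2, 1.91),
    GeneSpec("per2a", 10.0, 2.7, 17.5, 1.0, 1.96),
    GeneSpec("per2b", 10.0, 0.4, 21.4, 1.2, 1.87),
    GeneSpec("tim", 10.0, 0.7, 6.3, 1.2, 1.92),
    GeneSpec("nr1d1", 10.0, 2.5, 6.0, 1.1, 1.94),
    GeneSpec("nr1d2a", 10.0, 3.0, 9.0, 1.0, 1.90),
    GeneSpec("nr1d2b", 10.0, 0.5, 19.3, 1.2, 1.93),
)

DEMO_REFERENCE_SPECS = (
    GeneSpec("arp", 10.0, 0.0, 0.0, 0.3, 1.95),
    GeneSpec("ubi", 10.0, 0.0, 0.0, 0.3, 1.92),
    GeneSpec("eef1a", 10.0, 1.5, 12.0, 1.5, 1.90),
)


def demo_design(seed: int = 0) -> DesignSpec:
    """The bundled demo design: ZT_PRINTED grid, n=6, three references
    (two stable, one deliberately unstable), moderate loading variation."""
    return DesignSpec(
        timepoints_h=ZT_PRINTED,
        n_replicates=6,
        reference_specs=DEMO_REFERENCE_SPECS,
        sample_factor_sd=0.2,
        seed=seed,
    )


def gene_spec_from_dict(d: dict) -> GeneSpec:
    return GeneSpec(**d)


def design_from_dict(d: dict) -> DesignSpec:
    d = dict(d)
    d["reference_specs"] = tuple(gene_spec_from_dict(g) for g in d.get("reference_specs", ()))
    d["timepoints_h"] = tuple(d.get("timepoints_h", ZT_PRINTED))
    return DesignSpec(**d)


def design_to_dict(design: DesignSpec) -> dict:
    d = asdict(design)
    d["timepoints_h"] = list(design.timepoints_h)
    d["reference_specs"] = [asdict(g) for g in design.reference_specs]
    return d
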