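"""End-to-end pipeline driver, configuration and the published-table check.

``run_pipeline`` composes the stages — quantify (standard curves + RQ +
geNorm + normalization), rhythm screen, correlation screen — from a
single config, writes every stage output as CSV/JSON and a manifest with
content hashes, and is deterministic: identical inputs give
byte-identical outputs.

``reclassify_table1`` re-applies the noise/signal threshold P < 0.3 to a
transcribed table of published per-gene cosinor statistics for clock
genes in Atlantic cod fast skeletal muscle (a packaged fixture). The
published table prints acrophase and P only, so this checks the
P-threshold arm of the rhythmicity call; the omnibus arm needs raw data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .matrix import ExpressionMatrix, read_ct_table
from .qpcr import quantify_and_normalize
from .rhythm import (
    DEFAULT_OMNIBUS_ALPHA,
    DEFAULT_PERIOD_H,
    DEFAULT_PNS_THRESHOLD,
    rhythm_screen,
)
from .correlate import MODERATE_THRESHOLD, pairs_to_frame, screen_pairs

log = logging.getLogger(__name__)

TABLE1_RESOURCE = "table1_clock_rhythmicity.csv"


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips losslessly through YAML."""

    ct_csv: str | None = None
    dilution_csv: str | None = None
    expression_csv: str | None = None
    reference_candidates: list[str] = field(default_factory=list)
    references: list[str] | None = None
    period_h: float = DEFAULT_PERIOD_H
    p_ns_threshold: float = DEFAULT_PNS_THRESHOLD
    omnibus_alpha: float = DEFAULT_OMNIBUS_ALPHA
    correlation_threshold: float = MODERATE_THRESHOLD
    correlation_mode: str = "means"
    gene_set_a: list[str] | None = None
    gene_set_b: list[str] | None = None
    seed: int = 0
    out_dir: str = "qrhythm_out"

    def __post_init__(self) -> None:
        for name in ("p_ns_threshold", "omnibus_alpha", "correlation_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.period_h <= 0:
            raise ValueError("period_h must be > 0")
        if self.correlation_mode not in ("means", "replicates"):
            raise ValueError("correlation_mode must be 'means' or 'replicates'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    expression: ExpressionMatrix
    rhythm_table: pd.DataFrame
    correlation_table: pd.DataFrame
    quantification_report: dict | None
    manifest: dict
    out_dir: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"pipeline config does not specify {what}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute quantify -> normalize -> rhythm screen -> correlation screen.

    Input is either a Ct table plus dilution series (full quantification)
    or a pre-normalized expression matrix. Every stage output is written
    under ``config.out_dir`` along with ``manifest.json`` listing content
    hashes of all files, the config hash and the package version.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = None

    if config.expression_csv is not None:
        expr = ExpressionMatrix.from_csv(_require(config.expression_csv, "expression CSV"))
    else:
        ct = read_ct_table(_require(config.ct_csv, "Ct table CSV"))
        dil = pd.read_csv(_require(config.dilution_csv, "dilution-series CSV"))
        try:
            expr, report = quantify_and_normalize(
                ct, dil, config.reference_candidates, config.references
            )
        except Exception as exc:
            raise RuntimeError(f"stage quantify failed: {exc}") from exc

    try:
        screen = rhythm_screen(
            expr,
            period_h=config.period_h,
            p_ns_threshold=config.p_ns_threshold,
            omnibus_alpha=config.omnibus_alpha,
        )
    except Exception as exc:
        raise RuntimeError(f"stage rhythm failed: {exc}") from exc
    if screen.unfit:
        log.warning("rhythm screen: %d gene(s) unfit: %s", len(screen.unfit),
                    sorted(screen.unfit))

    set_a = config.gene_set_a or expr.genes
    set_b = config.gene_set_b  # None => within-set screen over set_a
    try:
        rhythmic = {row["gene"]: bool(row["rhythmic"]) if row["rhythmic"] is not pd.NA
                    else False for _, row in screen.table.iterrows()}
        pairs = screen_pairs(
            expr, rhythmic, set_a, set_b,
            threshold=config.correlation_threshold, mode=config.correlation_mode,
        )
    except Exception as exc:
        raise RuntimeError(f"stage correlate failed: {exc}") from exc
    pair_table = pairs_to_frame(pairs)

    expr_path = out_dir / "expression.csv"
    expr.to_csv(expr_path)
    rhythm_path = out_dir / "rhythm.csv"
    screen.table.to_csv(rhythm_path, index=False)
    corr_path = out_dir / "correlations.csv"
    pair_table.to_csv(corr_path, index=False)
    files = [expr_path, rhythm_path, corr_path]
    if report is not None:
        qpath = out_dir / "quantification.json"
        qpath.write_text(json.dumps(report, indent=2, sort_keys=True))
        files.append(qpath)

    manifest = {
        "package": "qrhythm",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_rhythmic": screen.n_rhythmic,
        "rhythmic_genes": screen.rhythmic_genes,
        "n_correlation_pairs": int(len(pair_table)),
        "files": {f.name: _sha256(f) for f in files},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(expr, screen.table, pair_table, report, manifest, out_dir)


def load_table1() -> pd.DataFrame:
    """The packaged transcription of the published clock-gene cosinor table
    (16 rows: gene, acrophase_h, p_ns)."""
    with resources.files("qrhythm.data").joinpath(TABLE1_RESOURCE).open("r") as fh:
        return pd.read_csv(fh)


def reclassify_table1(
    table: pd.DataFrame | None = None,
    p_ns_threshold: float = DEFAULT_PNS_THRESHOLD,
) -> tuple[list[str], int]:
    """Apply the P < 0.3 rule to a (gene, acrophase_h, p_ns) table.

    Returns the rhythmic gene list (table order) and its count. With no
    argument the packaged published-values fixture is used.
    """
    if table is None:
        table = load_table1()
    required = {"gene", "p_ns"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    genes: list[str] = []
    for i, row in table.reset_index(drop=True).iterrows():
        try:
            gene = str(row["gene"])
            p = float(row["p_ns"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed row {i}: {exc}") from exc
        if not gene or pd.isna(p):
            raise ValueError(f"malformed row {i}: gene={row['gene']!r} p_ns={row['p_ns']!r}")
        if p < p_ns_threshold:
            genes.append(gene)
    return genes, len(genes)
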