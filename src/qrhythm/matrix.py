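"""Core tabular containers shared across the pipeline.

Two representations are used throughout:

* a *tidy* long table (one row per well / observation) for on-disk CSV,
  with columns ``sample_id, gene, zt_hours, replicate, value`` (or ``ct``
  for raw thermocycler readout);
* an :class:`ExpressionMatrix` (genes x samples) for in-memory analysis,
  carrying the zeitgeber time and replicate of every sample alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CT_COLUMNS = ["sample_id", "gene", "zt_hours", "replicate", "ct"]
TIDY_COLUMNS = ["sample_id", "gene", "zt_hours", "replicate", "value"]


@dataclass
class ExpressionMatrix:
    """Genes-by-samples matrix with per-sample time metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene name, one column per sample id. Entries
        are relative expression (strictly positive where present; NaN for
        missing observations).
    sample_meta
        DataFrame indexed by sample id with columns ``zt_hours`` (float,
        zeitgeber time in hours) and ``replicate`` (int). Column order must
        match ``values.columns``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValueError("sample_meta index must match values columns")
        for col in ("zt_hours", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def zt_hours(self) -> np.ndarray:
        return self.sample_meta["zt_hours"].to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[genes].copy(), self.sample_meta.copy(),
                                dict(self.attrs))

    def timepoint_means(self) -> pd.DataFrame:
        """Mean profile per gene over replicates; columns sorted by ZT."""
        zt = self.sample_meta["zt_hours"]
        means = self.values.T.groupby(zt).mean().T
        return means.reindex(sorted(means.columns), axis=1)

    def to_tidy(self, value_name: str = "value") -> pd.DataFrame:
        long = (
            self.values.rename_axis("gene")
            .reset_index()
            .melt(id_vars="gene", var_name="sample_id", value_name=value_name)
        )
        meta = self.sample_meta.rename_axis("sample_id").reset_index()
        tidy = long.merge(meta[["sample_id", "zt_hours", "replicate"]], on="sample_id")
        cols = ["sample_id", "gene", "zt_hours", "replicate", value_name]
        # preserve sample-major, gene-minor order for byte-stable output
        order = {s: i for i, s in enumerate(self.sample_ids)}
        gorder = {g: i for i, g in enumerate(self.genes)}
        tidy = tidy.sort_values(
            by=["sample_id", "gene"],
            key=lambda c: c.map(order if c.name == "sample_id" else gorder),
            kind="stable",
        )
        return tidy[cols].reset_index(drop=True)

    def to_csv(self, path, value_name: str = "value") -> None:
        self.to_tidy(value_name).to_csv(path, index=False)

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, value_name: str = "value") -> "ExpressionMatrix":
        required = {"sample_id", "gene", "zt_hours", "replicate", value_name}
        missing = required - set(tidy.columns)
        if missing:
            raise ValueError(f"tidy table missing columns: {sorted(missing)}")
        sample_order = tidy["sample_id"].drop_duplicates().tolist()
        gene_order = tidy["gene"].drop_duplicates().tolist()
        values = (
            tidy.pivot_table(index="gene", columns="sample_id", values=value_name,
                             aggfunc="first", dropna=False)
            .reindex(index=gene_order, columns=sample_order)
        )
        meta = (
            tidy[["sample_id", "zt_hours", "replicate"]]
            .drop_duplicates("sample_id")
            .set_index("sample_id")
            .reindex(sample_order)
        )
        meta["zt_hours"] = meta["zt_hours"].astype(float)
        meta["replicate"] = meta["replicate"].astype(int)
        return cls(values, meta)

    @classmethod
    def from_csv(cls, path, value_name: str = "value") -> "ExpressionMatrix":
        return cls.from_tidy(pd.read_csv(path), value_name)


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Check a tidy Ct table has the expected columns and dtypes."""
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    out = ct[CT_COLUMNS].copy()
    out["zt_hours"] = out["zt_hours"].astype(float)
    out["replicate"] = out["replicate"].astype(int)
    out["ct"] = out["ct"].astype(float)
    return out


def read_ct_table(path) -> pd.DataFrame:
    return validate_ct_table(pd.read_csv(path))
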