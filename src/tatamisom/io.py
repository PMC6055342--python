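"""Tabular I/O, run configuration and bundled reference tables.

All tables are tab-separated with a header row.  Gene and protein
identifiers are opaque strings (bare numeric JGI protein IDs are valid but
nothing numeric is assumed); secretome protein IDs map to gene IDs by string
equality.  Every writer/reader pair round-trips its in-memory object.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .selectivity import CompositionRecord

__all__ = [
    "RunConfig",
    "read_count_matrix",
    "write_count_matrix",
    "read_metadata",
    "write_metadata",
    "read_secretome_table",
    "write_secretome_table",
    "read_annotation",
    "read_composition_table",
    "load_wheat_straw_composition",
    "load_aa_gene_panel",
]

DEFAULT_TIMEPOINTS = ("D4", "D10", "D15")


@dataclass
class RunConfig:
    """Resolved parameters of one analysis run.

    ``som_rows * som_cols`` is the number of map units (default 19 x 23 =
    437); ``iterations_per_unit`` scales online SOM training; the log2
    threshold separates high from low node-mean transcription.
    """

    threshold_log2: float = 12.0
    pseudocount: float = 1.0
    som_rows: int = 19
    som_cols: int = 23
    iterations_per_unit: int = 100
    seed: int = 0
    adjacency: str = "8"

    def __post_init__(self):
        if self.som_rows < 1 or self.som_cols < 1 or self.iterations_per_unit < 1:
            raise ValueError("grid dimensions and iterations must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.adjacency not in ("4", "8"):
            raise ValueError("adjacency must be '4' or '8'")
        for f in (self.threshold_log2, self.pseudocount):
            if not np.isfinite(f):
                raise ValueError("numeric config fields must be finite")

    @property
    def n_units(self) -> int:
        return self.som_rows * self.som_cols

    @property
    def total_iterations(self) -> int:
        return self.n_units * self.iterations_per_unit

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# -- count matrices --------------------------------------------------------

def read_count_matrix(path) -> pd.DataFrame:
    """Genes x samples integer counts from TSV (first column: gene IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene IDs in {path}: {dup.unique()[:5].tolist()}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            gene = df.index[numeric.isna()][0]
            raise ValueError(
                f"non-numeric count at gene {gene!r}, sample {col!r} in {path}"
            )
        if (numeric < 0).any():
            gene = df.index[numeric < 0][0]
            raise ValueError(
                f"negative count at gene {gene!r}, sample {col!r} in {path}"
            )
        df[col] = numeric
    return df


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


# -- sample metadata -------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "condition", "replicate"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in metadata")
    if (meta["replicate"] < 1).any():
        raise ValueError("replicate numbers must be positive")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# -- secretome detections --------------------------------------------------

def read_secretome_table(path, allowed_timepoints=DEFAULT_TIMEPOINTS) -> dict[str, set]:
    """protein_id -> set of detection time points.

    The second column holds a comma-separated time-point list; labels are
    validated against ``allowed_timepoints`` and empty sets are rejected.
    """
    allowed = set(allowed_timepoints)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.shape[1] < 2:
        raise ValueError("secretome table needs protein_id and timepoints columns")
    out: dict[str, set] = {}
    for _, row in df.iterrows():
        pid = str(row.iloc[0])
        labels = {t.strip() for t in str(row.iloc[1]).split(",") if t.strip()}
        if not labels:
            raise ValueError(f"protein {pid!r}: empty detection set")
        bad = labels - allowed
        if bad:
            raise ValueError(
                f"protein {pid!r}: unknown time points {sorted(bad)}; "
                f"allowed: {sorted(allowed)}"
            )
        if pid in out:
            raise ValueError(f"duplicate protein ID {pid!r}")
        out[pid] = labels
    return out


def write_secretome_table(secretome: dict[str, set], path) -> None:
    order = {t: i for i, t in enumerate(DEFAULT_TIMEPOINTS)}
    with open(path, "w") as fh:
        fh.write("protein_id\ttimepoints\n")
        for pid in sorted(secretome):
            tps = sorted(secretome[pid], key=lambda t: order.get(t, len(order)))
            fh.write(f"{pid}\t{','.join(tps)}\n")


# -- annotations -----------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """gene_id, optional cazy_family / functional_label, predicted_secreted."""
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in ann.columns:
        raise ValueError("annotation needs a gene_id column")
    if ann["gene_id"].duplicated().any():
        raise ValueError("duplicate gene IDs in annotation")
    if "predicted_secreted" in ann.columns:
        ann["predicted_secreted"] = ann["predicted_secreted"].astype(bool)
    if "cazy_family" in ann.columns:
        empty = ann["cazy_family"].notna() & (ann["cazy_family"].astype(str).str.strip() == "")
        if empty.any():
            raise ValueError("cazy_family present but empty for some genes")
    return ann.set_index("gene_id")


# -- composition tables ----------------------------------------------------

def _maybe_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    s = str(v).strip()
    if s in ("", "ND", "NA", "nan"):
        return None
    return float(s)


def read_composition_table(path) -> list[CompositionRecord]:
    """Composition-loss table (one row per culture time point)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        loss = {}
        se = {}
        for comp in ("cellulose", "holocellulose", "lignin"):
            loss[comp] = _maybe_float(row.get(f"{comp}_loss_pct"))
            se[comp] = _maybe_float(row.get(f"{comp}_loss_se"))
        records.append(
            CompositionRecord(
                label=str(row["label"]),
                weight_loss_pct=_maybe_float(row.get("weight_loss_pct")),
                loss_pct={k: v for k, v in loss.items() if v is not None},
                se_pct={k: v for k, v in se.items() if v is not None},
            )
        )
    return records


def _data_path(name: str) -> Path:
    return Path(resources.files("tatamisom") / "data" / name)


def load_wheat_straw_composition() -> list[CompositionRecord]:
    """Bundled wheat-straw composition-loss table (control, Day 4/10/15)."""
    return read_composition_table(_data_path("wheat_straw_composition.tsv"))


def load_aa_gene_panel() -> pd.DataFrame:
    """Bundled auxiliary-activity gene table: per-condition log2 expression,
    secretome detections, node IDs and the expected high/low (H/L) pattern
    over (control, D4, D10, D15)."""
    df = pd.read_csv(_data_path("aa_gene_panel.tsv"), sep="\t", dtype={"prot_id": str})
    return df.set_index("prot_id")
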