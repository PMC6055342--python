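"""Tatami maps: node-level aggregation of omics layers on the SOM grid.

A *Tatami map* attaches one scalar to every node of a trained map — the mean
log2 transcription of the genes in the node under one condition, or the
number of secreted proteins detected in the node at one time point.  High
transcription is a node-level property: a node whose mean exceeds the
threshold marks all of its genes as highly transcribed, exactly mirroring
the node-wise selection criterion (> 12 log2 by default, with nodes that are
simultaneously below threshold in the control culture defining
condition-specific sets and their intersection the core set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import percentileofscore

logger = logging.getLogger(__name__)

__all__ = [
    "TatamiMap",
    "ConditionGeneSets",
    "gene_assignment",
    "node_mean_map",
    "node_secretion_map",
    "select_high_nodes",
    "condition_specific_genes",
    "classify_genes",
    "percentile_of_threshold",
    "extract_node_clusters",
]

#: default node-mean log2 threshold for "highly transcribed"
HIGH_THRESHOLD = 12.0


@dataclass
class TatamiMap:
    """One scalar per node; ``kind`` is 'transcription' or 'secretion'.

    Transcription maps carry NaN for empty nodes; secretion maps carry 0.
    """

    values: pd.Series
    kind: str

    def __post_init__(self):
        if self.kind not in ("transcription", "secretion"):
            raise ValueError(f"unknown map kind {self.kind!r}")
        self.values = pd.Series(self.values)
        self.values.index = self.values.index.astype(int)

    @property
    def nodes(self) -> pd.Index:
        return self.values.index


@dataclass
class ConditionGeneSets:
    """Gene sets selected per SSF condition against the control map.

    ``per_condition[c]`` holds the genes of nodes above threshold at ``c``
    and below threshold in the control; ``core`` is their intersection over
    all SSF conditions; ``unique[c]`` the genes found at ``c`` only.
    """

    per_condition: dict[str, set[str]]
    core: set[str]
    unique: dict[str, set[str]] = field(default_factory=dict)

    def counts(self) -> pd.DataFrame:
        rows = [
            {
                "condition": c,
                "total": len(s),
                "unique": len(self.unique.get(c, set())),
                "shared": len(s) - len(self.unique.get(c, set())),
            }
            for c, s in self.per_condition.items()
        ]
        rows.append(
            {"condition": "core", "total": len(self.core), "unique": 0, "shared": len(self.core)}
        )
        return pd.DataFrame(rows)


def gene_assignment(som, gene_ids) -> pd.Series:
    """Gene -> 1-based node ID from a fitted map, as a named Series."""
    labels = np.asarray(som.labels_)
    if len(labels) != len(gene_ids):
        raise ValueError("gene_ids length does not match fitted profiles")
    return pd.Series(labels, index=pd.Index(gene_ids, name="gene_id"), name="node_id")


def _node_index(n_units: int) -> pd.Index:
    return pd.RangeIndex(1, n_units + 1, name="node_id")


def node_mean_map(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    condition: str,
    assignment: pd.Series,
    n_units: int,
) -> TatamiMap:
    """Node-wise mean log2 expression for one condition.

    The node value pools every (gene, replicate-sample) cell of the genes
    assigned to the node over the condition's samples.  Empty nodes are NaN.
    """
    samples = meta.loc[meta["condition"] == condition, "sample_id"]
    if samples.empty:
        raise ValueError(
            f"condition {condition!r} absent from metadata "
            f"(known: {sorted(meta['condition'].unique())})"
        )
    sub = expr.loc[:, list(samples)]
    per_gene_sum = sub.sum(axis=1)
    node_of = assignment.reindex(expr.index)
    if node_of.isna().any():
        missing = expr.index[node_of.isna()][:5].tolist()
        raise ValueError(f"genes without node assignment, e.g. {missing}")
    if node_of.min() < 1 or node_of.max() > n_units:
        raise ValueError(
            f"assignment node IDs span {int(node_of.min())}..{int(node_of.max())} "
            f"but the configured grid has {n_units} units"
        )
    sums = per_gene_sum.groupby(node_of).sum()
    cells = node_of.value_counts() * sub.shape[1]
    values = (sums / cells).reindex(_node_index(n_units))
    return TatamiMap(values, kind="transcription")


def node_secretion_map(
    secretome: dict[str, set],
    timepoint: str,
    assignment: pd.Series,
    n_units: int,
) -> TatamiMap:
    """Count of distinct secreted proteins detected per node at a time point.

    Protein IDs resolve to gene IDs by string equality; unmatched IDs are
    counted and logged, never fatal.  Each detected protein contributes one
    to the map of every time point at which it was detected.
    """
    counts = pd.Series(0, index=_node_index(n_units), dtype=int)
    unmatched = []
    for protein_id, timepoints in secretome.items():
        if timepoint not in timepoints:
            continue
        if protein_id in assignment.index:
            counts.loc[int(assignment.loc[protein_id])] += 1
        else:
            unmatched.append(protein_id)
    if unmatched:
        logger.warning(
            "%d secreted protein IDs at %s have no gene assignment: %s%s",
            len(unmatched), timepoint, unmatched[:5], "..." if len(unmatched) > 5 else "",
        )
    return TatamiMap(counts, kind="secretion")


def select_high_nodes(tatami: TatamiMap, threshold: float = HIGH_THRESHOLD) -> set[int]:
    """Nodes with mean transcription strictly above the threshold.

    NaN (empty) nodes are never selected.  Secretion maps are rejected —
    protein counts are not on the log2 expression scale.
    """
    if tatami.kind != "transcription":
        raise ValueError("high-node selection applies to transcription maps only")
    mask = tatami.values > threshold
    return set(tatami.values.index[mask.fillna(False)])


def condition_specific_genes(
    maps: dict[str, TatamiMap],
    assignment: pd.Series,
    threshold: float = HIGH_THRESHOLD,
    control: str = "control",
) -> ConditionGeneSets:
    """Genes of nodes above threshold in an SSF condition, below in control.

    Both comparisons are strict, so a node sitting exactly at the threshold
    belongs to neither side.  The core set is the intersection across all
    SSF conditions; per-condition unique sets complete the breakdown.
    """
    if control not in maps:
        raise ValueError(f"control map {control!r} missing from {sorted(maps)}")
    control_low = {
        n for n, v in maps[control].values.items() if pd.notna(v) and v < threshold
    }
    # empty nodes hold no genes either way; include them so gene lookup is total
    control_low |= set(maps[control].values.index[maps[control].values.isna()])
    ssf = [c for c in maps if c != control]
    genes_of_node = assignment.groupby(assignment).groups  # node -> gene index
    per_condition: dict[str, set[str]] = {}
    for cond in ssf:
        nodes = select_high_nodes(maps[cond], threshold) & control_low
        per_condition[cond] = set().union(
            *(set(genes_of_node.get(n, ())) for n in nodes)
        ) if nodes else set()
    core = set.intersection(*per_condition.values()) if per_condition else set()
    unique = {
        c: per_condition[c].difference(*(per_condition[o] for o in ssf if o != c))
        if len(ssf) > 1
        else set(per_condition[c])
        for c in ssf
    }
    return ConditionGeneSets(per_condition=per_condition, core=core, unique=unique)


def classify_genes(
    maps: dict[str, TatamiMap],
    assignment: pd.Series,
    threshold: float = HIGH_THRESHOLD,
    control: str = "control",
) -> pd.Series:
    """Profile-class label per gene from its node's high/low pattern.

    The label is the '+'-joined list of SSF conditions where the gene's node
    is high while low in control (e.g. ``"D4+D10+D15"`` for the core class),
    ``"control-high"`` when the node is high in the control culture, and
    ``"none"`` otherwise.  Used to compare recovered classes with planted
    co-regulation modules.
    """
    if control not in maps:
        raise ValueError(f"control map {control!r} missing")
    ssf = [c for c in maps if c != control]
    high = {c: select_high_nodes(maps[c], threshold) for c in ssf}
    control_high = select_high_nodes(maps[control], threshold)
    labels = {}
    for node in maps[control].values.index:
        if node in control_high:
            labels[node] = "control-high"
        else:
            pattern = [c for c in ssf if node in high[c]]
            labels[node] = "+".join(pattern) if pattern else "none"
    return assignment.map(labels).rename("profile_class")


def percentile_of_threshold(
    expr: pd.DataFrame, meta: pd.DataFrame, threshold: float = HIGH_THRESHOLD
) -> float:
    """Percentile rank of the threshold among per-gene per-condition means.

    A threshold chosen at the ~75th percentile marks roughly the top quarter
    of gene-condition expression states as "high".
    """
    if expr.empty:
        raise ValueError("empty expression matrix")
    cond_of = meta.set_index("sample_id")["condition"]
    means = expr.T.groupby(cond_of.reindex(expr.columns)).mean().T
    return float(percentileofscore(means.to_numpy().ravel(), threshold, kind="mean"))


_STRUCTURES = {
    "4": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    "8": np.ones((3, 3), dtype=int),
}


def extract_node_clusters(
    nodes: set[int],
    n_rows: int,
    n_cols: int,
    adjacency: str = "8",
) -> list[set[int]]:
    """Connected components of selected nodes under grid adjacency.

    Components are returned largest first; ties broken by lowest node ID.
    """
    if adjacency not in _STRUCTURES:
        raise ValueError("adjacency must be '4' or '8'")
    n_units = n_rows * n_cols
    bad = [n for n in nodes if not (1 <= n <= n_units)]
    if bad:
        raise ValueError(f"node IDs outside 1..{n_units}: {sorted(bad)[:5]}")
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    for n in nodes:
        mask[(n - 1) // n_cols, (n - 1) % n_cols] = True
    labeled, n_comp = ndimage.label(mask, structure=_STRUCTURES[adjacency])
    clusters = []
    for k in range(1, n_comp + 1):
        rows, cols = np.nonzero(labeled == k)
        clusters.append(set((rows * n_cols + cols + 1).tolist()))
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return clusters
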