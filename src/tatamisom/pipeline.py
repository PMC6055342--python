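"""End-to-end analysis: normalize, map, aggregate, correlate, summarize.

``run_full_analysis`` reads the input tables, executes every stage with the
resolved configuration and writes all result tables plus the configuration
itself into one run directory; given identical inputs and seed, the outputs
are bit-identical.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as tio
from .integration import CorrelationMatrix, correlate_trans_sec, lag_profile
from .normalization import compute_size_factors, normalize_log2
from .selectivity import selectivity_table
from .som import SelfOrganizingMap
from .tatami import (
    TatamiMap,
    condition_specific_genes,
    extract_node_clusters,
    gene_assignment,
    node_mean_map,
    node_secretion_map,
    select_high_nodes,
)

__all__ = ["AnalysisResult", "analyze", "run_full_analysis"]


@dataclass
class AnalysisResult:
    expr: pd.DataFrame
    size_factors: pd.Series
    som: SelfOrganizingMap
    assignment: pd.Series
    trans_maps: dict[str, TatamiMap]
    sec_maps: dict[str, TatamiMap]
    high_nodes: dict[str, set]
    gene_sets: object
    clusters: dict[str, list]
    correlations: dict[str, CorrelationMatrix]
    lag: object


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def analyze(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    secretome: dict[str, set],
    config: tio.RunConfig | None = None,
    secreted_genes: set | None = None,
    control: str = "control",
) -> AnalysisResult:
    """Run every stage in memory and return the assembled results.

    ``secreted_genes`` feeds the secreted-subset correlation variant; when
    None, the genes matched by secretome protein IDs stand in for the
    predicted-secreted set.
    """
    config = config or tio.RunConfig()
    with _stage("normalization"):
        factors = compute_size_factors(counts)
        expr = normalize_log2(counts, factors, pseudocount=config.pseudocount)
    with _stage("som-training"):
        som = SelfOrganizingMap(
            n_rows=config.som_rows,
            n_cols=config.som_cols,
            iterations_per_unit=config.iterations_per_unit,
            random_state=config.seed,
        ).fit(expr.to_numpy())
        assignment = gene_assignment(som, expr.index)
    conditions = list(meta["condition"].unique())
    timepoints = [c for c in conditions if c != control]
    with _stage("tatami-maps"):
        trans_maps = {
            c: node_mean_map(expr, meta, c, assignment, som.n_units_)
            for c in conditions
        }
        sec_maps = {
            t: node_secretion_map(secretome, t, assignment, som.n_units_)
            for t in timepoints
        }
    with _stage("node-selection"):
        high_nodes = {
            c: select_high_nodes(m, config.threshold_log2)
            for c, m in trans_maps.items()
        }
        gene_sets = condition_specific_genes(
            trans_maps, assignment, config.threshold_log2, control=control
        )
        clusters = {
            c: extract_node_clusters(
                nodes, config.som_rows, config.som_cols, config.adjacency
            )
            for c, nodes in high_nodes.items()
        }
    with _stage("correlation"):
        trans_by_tp = {t: trans_maps[t] for t in timepoints}
        correlations = {
            "all-genes": correlate_trans_sec(trans_by_tp, sec_maps, "all-genes")
        }
        subset = secreted_genes
        if subset is None:
            subset = set(secretome) & set(expr.index)
        subset = set(subset) & set(expr.index)
        if subset:
            sub_expr = expr.loc[sorted(subset)]
            sub_assign = assignment.reindex(sub_expr.index)
            sub_maps = {
                t: node_mean_map(sub_expr, meta, t, sub_assign, som.n_units_)
                for t in timepoints
            }
            correlations["secreted-subset"] = correlate_trans_sec(
                sub_maps, sec_maps, "secreted-subset"
            )
        lag = lag_profile(correlations["all-genes"], order=timepoints)
    return AnalysisResult(
        expr=expr,
        size_factors=factors,
        som=som,
        assignment=assignment,
        trans_maps=trans_maps,
        sec_maps=sec_maps,
        high_nodes=high_nodes,
        gene_sets=gene_sets,
        clusters=clusters,
        correlations=correlations,
        lag=lag,
    )


def _write_map(tmap: TatamiMap, path: Path) -> None:
    tmap.values.rename("value").rename_axis("node_id").to_csv(path, sep="\t")


def run_full_analysis(
    config: tio.RunConfig,
    counts_path,
    meta_path,
    secretome_path,
    outdir,
    annotation_path=None,
    composition_path=None,
    control: str = "control",
) -> Path:
    """Read inputs, run :func:`analyze`, write every result table to outdir.

    Emits: normalized matrix (+ size factors), SOM assignment (+ codebook,
    quality), per-condition transcription and per-time-point secretion
    Tatami tables, high-node / gene-set / cluster lists, correlation
    matrices with the lag summary, and — when a composition table is given —
    the selectivity table.  The resolved configuration is written alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with _stage("input"):
        counts = tio.read_count_matrix(counts_path)
        meta = tio.read_metadata(meta_path)
        timepoints = tuple(c for c in meta["condition"].unique() if c != control)
        secretome = tio.read_secretome_table(secretome_path, timepoints)
        secreted = None
        if annotation_path is not None:
            ann = tio.read_annotation(annotation_path)
            if "predicted_secreted" in ann.columns:
                secreted = set(ann.index[ann["predicted_secreted"]])
    res = analyze(counts, meta, secretome, config, secreted_genes=secreted, control=control)
    with _stage("output"):
        config.to_yaml(outdir / "config.yaml")
        res.expr.rename_axis("gene_id").to_csv(outdir / "expr.tsv", sep="\t")
        res.size_factors.rename_axis("sample_id").to_csv(
            outdir / "size_factors.tsv", sep="\t"
        )
        grid = res.som.grid_
        assign = pd.DataFrame(
            {
                "gene_id": res.assignment.index,
                "node_id": res.assignment.to_numpy(),
                "row": grid[res.assignment.to_numpy() - 1, 0],
                "col": grid[res.assignment.to_numpy() - 1, 1],
            }
        )
        assign.to_csv(outdir / "assignment.tsv", sep="\t", index=False)
        pd.DataFrame(
            res.som.codebook_, index=pd.RangeIndex(1, res.som.n_units_ + 1, name="node_id")
        ).to_csv(outdir / "codebook.tsv", sep="\t")
        pd.DataFrame(
            [{"quantization_error": res.som.quantization_error(res.expr.to_numpy())}]
        ).to_csv(outdir / "quality.tsv", sep="\t", index=False)
        for c, m in res.trans_maps.items():
            _write_map(m, outdir / f"tatami_transcription_{c}.tsv")
        for t, m in res.sec_maps.items():
            _write_map(m, outdir / f"tatami_secretion_{t}.tsv")
        pd.DataFrame(
            [
                {"condition": c, "node_id": n}
                for c, nodes in res.high_nodes.items()
                for n in sorted(nodes)
            ]
        ).to_csv(outdir / "high_nodes.tsv", sep="\t", index=False)
        rows = [
            {"set": c, "gene_id": g}
            for c, genes in res.gene_sets.per_condition.items()
            for g in sorted(genes)
        ] + [{"set": "core", "gene_id": g} for g in sorted(res.gene_sets.core)]
        pd.DataFrame(rows, columns=["set", "gene_id"]).to_csv(
            outdir / "gene_sets.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                {"condition": c, "cluster": i + 1, "node_id": n}
                for c, comps in res.clusters.items()
                for i, comp in enumerate(comps)
                for n in sorted(comp)
            ],
            columns=["condition", "cluster", "node_id"],
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        for variant, cm in res.correlations.items():
            tag = "all" if variant == "all-genes" else "secreted"
            cm.rho.to_csv(outdir / f"correlations_{tag}.tsv", sep="\t")
            cm.pvalue.to_csv(outdir / f"correlations_{tag}_pvalues.tsv", sep="\t")
        pd.DataFrame(
            {"delta_rho": res.lag.delta, "lagged": res.lag.lagged}
        ).rename_axis("transcriptome").to_csv(outdir / "lag_summary.tsv", sep="\t")
        if composition_path is not None:
            records = tio.read_composition_table(composition_path)
            selectivity_table(records).to_csv(
                outdir / "selectivity.tsv", sep="\t", index=False
            )
    return outdir
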