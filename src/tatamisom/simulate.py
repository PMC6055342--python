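"""Synthetic time-course counts and secretome with planted structure.

The generator emulates the statistical shape of a solid-state-fermentation
(SSF) time course: triplicate libraries for a control culture and three SSF
time points (D4, D10, D15), negative-binomial counts with a shared
dispersion, and co-regulated gene modules mirroring the profile classes a
genome-wide map recovers —

* ``early``         high at D4 only, low in control,
* ``core``          high at D4, D10 and D15, low in control,
* ``late``          high at D10 and D15,
* ``control_high``  high in the control culture only,
* ``flat``          uniform baseline.

A subset of genes is flagged secreted; their detection in the secretome at
time t is Bernoulli with a logistic link to the gene's mean expression at
the *preceding* time point (``lag_steps`` conditions earlier, defaulting to
one).  Times before the first SSF point fall back to the control-culture
expression — the pre-induction transcriptional state — so that the planted
transcription-to-secretion lag is visible at the first SSF time point too.
Every operation is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SyntheticTruth",
    "MODULES",
    "DEFAULT_FRACTIONS",
    "DEFAULT_MODULE_MEANS",
    "generate_truth",
    "make_metadata",
    "simulate_counts",
    "simulate_secretome",
    "simulate_dataset",
]

CONDITIONS = ("control", "D4", "D10", "D15")
MODULES = ("early", "core", "late", "control_high", "flat")

DEFAULT_FRACTIONS = {
    "early": 0.10,
    "core": 0.125,
    "late": 0.10,
    "control_high": 0.05,
    "flat": 0.625,
}

# log2 mean expression per (module, condition); high (14) vs baseline (8)
# states sit 6 log2 apart, straddling the 12-log2 selection threshold.
DEFAULT_MODULE_MEANS = pd.DataFrame(
    {
        "control": [7.0, 7.0, 7.0, 14.0, 8.0],
        "D4": [14.0, 14.0, 8.0, 8.0, 8.0],
        "D10": [8.0, 14.0, 14.0, 8.0, 8.0],
        "D15": [8.0, 14.0, 14.0, 8.0, 8.0],
    },
    index=list(MODULES),
)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset."""

    module_of_gene: pd.Series
    module_mean_log2: pd.DataFrame
    dispersion: float = 0.05
    secreted_genes: frozenset = field(default_factory=frozenset)
    lag_steps: int = 1
    detection_slope: float = 1.0
    detection_intercept: float = -12.0

    def __post_init__(self):
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        unknown = set(self.secreted_genes) - set(self.module_of_gene.index)
        if unknown:
            raise ValueError(f"secreted genes not in gene set: {sorted(unknown)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.module_of_gene.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module": self.module_of_gene,
                "secreted": self.module_of_gene.index.isin(self.secreted_genes),
            }
        ).rename_axis("gene_id")


def _module_sizes(n_genes: int, fractions: dict[str, float]) -> dict[str, int]:
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"module fractions sum to {total}, not 1")
    raw = {m: n_genes * f for m, f in fractions.items()}
    sizes = {m: int(np.floor(v)) for m, v in raw.items()}
    # largest-remainder rounding so sizes sum exactly to n_genes
    remainder = n_genes - sum(sizes.values())
    order = sorted(raw, key=lambda m: raw[m] - sizes[m], reverse=True)
    for m in order[:remainder]:
        sizes[m] += 1
    return sizes


def generate_truth(
    n_genes: int,
    module_fractions: dict[str, float] | None = None,
    seed: int = 0,
    module_means: pd.DataFrame | None = None,
    dispersion: float = 0.05,
    secreted_fraction: float = 0.2,
    lag_steps: int = 1,
    detection_slope: float = 1.0,
    detection_intercept: float = -12.0,
) -> SyntheticTruth:
    """Plant co-regulation modules and a secreted-gene subset.

    Module sizes follow the fractions to within largest-remainder rounding;
    gene-to-module assignment is a seeded shuffle so modules interleave
    across gene IDs.  Secreted genes are a uniform sample of all genes.
    """
    fractions = dict(module_fractions or DEFAULT_FRACTIONS)
    means = (module_means if module_means is not None else DEFAULT_MODULE_MEANS).copy()
    unknown = set(fractions) - set(means.index)
    if unknown:
        raise ValueError(f"modules without mean profiles: {sorted(unknown)}")
    sizes = _module_sizes(n_genes, fractions)
    rng = np.random.default_rng(seed)
    labels = np.repeat(list(sizes.keys()), list(sizes.values()))
    rng.shuffle(labels)
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id")
    module_of_gene = pd.Series(labels, index=genes, name="module")
    n_secreted = int(round(secreted_fraction * n_genes))
    secreted = frozenset(rng.choice(genes, size=n_secreted, replace=False))
    return SyntheticTruth(
        module_of_gene=module_of_gene,
        module_mean_log2=means,
        dispersion=dispersion,
        secreted_genes=secreted,
        lag_steps=lag_steps,
        detection_slope=detection_slope,
        detection_intercept=detection_intercept,
    )


def make_metadata(
    conditions: tuple[str, ...] = CONDITIONS, n_replicates: int = 3
) -> pd.DataFrame:
    """Sample sheet: one row per library, ``<condition>_r<replicate>``."""
    rows = [
        {"sample_id": f"{c}_r{r}", "condition": c, "replicate": r}
        for c in conditions
        for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def simulate_counts(
    truth: SyntheticTruth,
    meta: pd.DataFrame,
    size_factors: pd.Series | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial counts, genes x samples.

    The mean of gene g in sample j is ``size_factor[j] * 2**mu`` where mu is
    the planted module mean for the sample's condition; the NB size
    parameter is ``1/dispersion`` (shared across genes).  Dispersion 0 is
    the Poisson limit.
    """
    if size_factors is None:
        size_factors = pd.Series(1.0, index=meta["sample_id"])
    size_factors = pd.Series(size_factors).reindex(meta["sample_id"])
    if size_factors.isna().any() or (size_factors <= 0).any():
        raise ValueError("size factors must be positive for every sample")
    missing = set(meta["condition"]) - set(truth.module_mean_log2.columns)
    if missing:
        raise ValueError(f"conditions without planted means: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    mu_log2 = truth.module_mean_log2.loc[
        truth.module_of_gene, meta["condition"]
    ].to_numpy()
    mu = size_factors.to_numpy()[None, :] * np.exp2(mu_log2)
    if truth.dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / truth.dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    return pd.DataFrame(
        counts, index=truth.genes, columns=pd.Index(meta["sample_id"], name="sample_id")
    )


def _condition_means(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    cond_of = meta.set_index("sample_id")["condition"]
    return expr.T.groupby(cond_of.reindex(expr.columns)).mean().T


def simulate_secretome(
    truth: SyntheticTruth,
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    seed: int = 0,
    control: str = "control",
) -> dict[str, set]:
    """Lag-coupled Bernoulli secretome detections.

    Detection of secreted gene g at SSF time t has probability
    ``logistic(intercept + slope * m)`` with m the gene's mean log2
    expression ``lag_steps`` time points earlier; times before the first SSF
    point use the control-culture mean (or the first SSF value when no
    control condition exists).  Non-secreted genes are never detected, and
    proteins with no detection at any time point are omitted entirely.
    """
    timepoints = [c for c in meta["condition"].unique() if c != control]
    if truth.lag_steps >= len(timepoints):
        raise ValueError(
            f"lag_steps={truth.lag_steps} >= {len(timepoints)} SSF time points"
        )
    secreted = sorted(truth.secreted_genes)
    missing = set(secreted) - set(expr.index)
    if missing:
        raise ValueError(f"expression missing for secreted genes: {sorted(missing)[:5]}")
    means = _condition_means(expr, meta)
    baseline_col = control if control in means.columns else timepoints[0]
    rng = np.random.default_rng(seed)
    detections: dict[str, set] = {}
    for k, tp in enumerate(timepoints):
        src = k - truth.lag_steps
        col = timepoints[src] if src >= 0 else baseline_col
        p = expit(
            truth.detection_intercept
            + truth.detection_slope * means.loc[secreted, col].to_numpy()
        )
        hits = rng.random(len(secreted)) < p
        for g, hit in zip(secreted, hits):
            if hit:
                detections.setdefault(g, set()).add(tp)
    return detections


def simulate_dataset(
    n_genes: int = 2000,
    n_replicates: int = 3,
    seed: int = 0,
    **truth_kwargs,
):
    """Full synthetic study: (counts, meta, secretome, truth).

    Defaults to the study scale the analysis assumes: 4 conditions x 3
    replicates and 2,000 genes.  The three stage seeds are derived from
    ``seed`` so one integer reproduces the whole dataset.
    """
    truth = generate_truth(n_genes, seed=seed, **truth_kwargs)
    meta = make_metadata(n_replicates=n_replicates)
    counts = simulate_counts(truth, meta, seed=seed + 1)
    from .normalization import compute_size_factors, normalize_log2

    expr = normalize_log2(counts, compute_size_factors(counts))
    secretome = simulate_secretome(truth, expr, meta, seed=seed + 2)
    return counts, meta, secretome, truth
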