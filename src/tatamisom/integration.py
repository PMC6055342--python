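"""Node-wise Spearman correlation between transcriptome and secretome.

The two omics layers live on the same trained map, so each time-point pair
(i, j) yields one correlation: node-wise mean transcription at time j
against node-wise secreted-protein count at time i, across nodes.  A
positive off-diagonal excess — transcription at an early time correlating
more strongly with later secretomes than with the concurrent one — is the
signature of a transcription-to-secretion lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .tatami import TatamiMap

__all__ = ["CorrelationMatrix", "correlate_trans_sec", "lag_profile", "LagSummary"]

MIN_NODES = 4


@dataclass
class CorrelationMatrix:
    """Spearman rho and p per (secretome time, transcriptome time) pair.

    Rows are secretome time points, columns transcriptome time points.
    ``variant`` records which gene set fed the transcription node means
    ('all-genes' or 'secreted-subset').
    """

    rho: pd.DataFrame
    pvalue: pd.DataFrame
    variant: str


@dataclass
class LagSummary:
    """Per transcriptome time point: does a later secretome correlate better?

    ``delta`` is max_{i>j} rho(i, j) − rho(j, j); the lag flag is
    ``delta > 0``.  The last time point has no later secretome and carries
    NaN / False.
    """

    delta: pd.Series
    lagged: pd.Series


def _spearman(x: np.ndarray, y: np.ndarray, exact: bool = False) -> tuple[float, float]:
    rho, p = stats.spearmanr(x, y)
    if exact:
        # exact permutation p-value (two-sided), feasible for small node sets
        n = len(x)
        observed = abs(rho)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r, _ = stats.spearmanr(x, y[list(perm)])
            total += 1
            if abs(r) >= observed - 1e-12:
                count += 1
        p = count / total
    return float(rho), float(p)


def correlate_trans_sec(
    trans_maps: dict[str, TatamiMap],
    sec_maps: dict[str, TatamiMap],
    variant: str = "all-genes",
    exact_p: bool = False,
) -> CorrelationMatrix:
    """Spearman correlation for every (secretome, transcriptome) time pair.

    Nodes with no genes (NaN transcription) are dropped pairwise.  Ties get
    average ranks; p-values use the large-sample t approximation unless
    ``exact_p`` (permutation; only sensible for <= 12 usable nodes).
    """
    t_times = list(trans_maps)
    s_times = list(sec_maps)
    rho = pd.DataFrame(index=s_times, columns=t_times, dtype=float)
    pval = pd.DataFrame(index=s_times, columns=t_times, dtype=float)
    for st in s_times:
        for tt in t_times:
            tv = trans_maps[tt].values
            sv = sec_maps[st].values.reindex(tv.index)
            ok = tv.notna() & sv.notna()
            if ok.sum() < MIN_NODES:
                raise ValueError(
                    f"only {int(ok.sum())} usable nodes for ({st}, {tt}); "
                    f"need at least {MIN_NODES}"
                )
            if exact_p and ok.sum() > 12:
                raise ValueError("exact permutation p limited to <= 12 nodes")
            r, p = _spearman(tv[ok].to_numpy(), sv[ok].to_numpy(), exact=exact_p)
            rho.loc[st, tt] = r
            pval.loc[st, tt] = p
    rho.index.name = pval.index.name = "secretome"
    rho.columns.name = pval.columns.name = "transcriptome"
    return CorrelationMatrix(rho=rho, pvalue=pval, variant=variant)


def lag_profile(matrix: CorrelationMatrix, order: list[str] | None = None) -> LagSummary:
    """Assess the transcription-to-secretion lag from a correlation matrix.

    For each transcriptome time j (in ``order``, default the matrix column
    order), compares the best correlation with a strictly later secretome
    against the same-time correlation rho(j, j).
    """
    rho = matrix.rho
    times = order if order is not None else list(rho.columns)
    if len(times) < 2:
        raise ValueError("lag assessment needs at least two time points")
    if set(times) - set(rho.index):
        raise ValueError("matrix is not square over the given time points")
    delta = {}
    for j, tt in enumerate(times):
        later = times[j + 1:]
        if not later:
            delta[tt] = np.nan
            continue
        delta[tt] = float(rho.loc[later, tt].max() - rho.loc[tt, tt])
    delta = pd.Series(delta, name="delta_rho")
    lagged = (delta > 0).rename("lagged")
    return LagSummary(delta=delta, lagged=lagged)
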