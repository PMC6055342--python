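"""Biomass mass-balance losses and delignification-selectivity ratios.

White-rot pretreatment aims to remove lignin while sparing the
polysaccharides.  Given component losses over a fermentation interval, the
selectivity ratios L/C (lignin loss / cellulose loss) and L/H (lignin loss /
holocellulose loss) quantify that preference: ratios above 1 indicate
selective delignification.  Carbohydrate net conversion yields express
enzymatically released sugar as a percentage of the substrate's
carbohydrate content, with the standard anhydro correction (0.9 for
glucose -> glucan, 0.88 for pentoses).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "CompositionRecord",
    "component_loss",
    "selectivity_ratios",
    "net_conversion_yield",
    "round_half_up",
    "selectivity_table",
]


@dataclass
class CompositionRecord:
    """Weight loss and per-component composition losses for one time point."""

    label: str
    weight_loss_pct: float | None = None
    loss_pct: dict[str, float] = field(default_factory=dict)
    se_pct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.loss_pct.items():
            if v is not None and not math.isfinite(v):
                raise ValueError(f"non-finite loss for {k!r}")


def component_loss(
    initial_mass: float,
    final_mass: float,
    initial_fraction: float,
    final_fraction: float,
) -> float:
    """Percent loss of one component by mass balance.

    100 * (m0*x0 - mf*xf) / (m0*x0) for total masses m0, mf and component
    mass fractions x0, xf.  A gain (negative loss) is returned with a
    warning rather than raised — compositional assays can overshoot.
    """
    if initial_mass <= 0 or final_mass <= 0:
        raise ValueError("masses must be positive")
    for x in (initial_fraction, final_fraction):
        if not 0 <= x <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    m0 = initial_mass * initial_fraction
    if m0 == 0:
        raise ValueError("initial component mass is zero; loss undefined")
    loss = 100.0 * (m0 - final_mass * final_fraction) / m0
    if loss < 0:
        warnings.warn(
            f"final component mass exceeds initial (loss {loss:.2f}%)",
            stacklevel=2,
        )
    return loss


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (so 2.085 -> 2.09), as printed tables round."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def selectivity_ratios(losses: CompositionRecord | dict[str, float]) -> dict[str, float]:
    """L/C and L/H from component losses, full precision plus 2-decimal display.

    Keys: ``L/C``, ``L/H`` (full precision) and ``L/C_rounded``,
    ``L/H_rounded``.  A zero (or missing) denominator yields NaN — the
    printed tables' "ND".
    """
    loss = losses.loss_pct if isinstance(losses, CompositionRecord) else losses
    lignin = loss.get("lignin")
    out: dict[str, float] = {}
    for key, denom_name in (("L/C", "cellulose"), ("L/H", "holocellulose")):
        denom = loss.get(denom_name)
        if lignin is None or denom is None or denom == 0 or not math.isfinite(denom):
            out[key] = math.nan
        else:
            out[key] = lignin / denom
        out[f"{key}_rounded"] = (
            round_half_up(out[key]) if math.isfinite(out[key]) else math.nan
        )
    return out


def net_conversion_yield(
    sugar_released: float,
    carbohydrate_content: float,
    anhydro_factor: float = 0.9,
) -> float:
    """Percent of a carbohydrate converted to soluble sugar.

    ``100 * sugar_released * anhydro_factor / carbohydrate_content``; the
    anhydro factor maps monomer mass back to polymer mass (0.9 glucose ->
    glucan, 0.88 pentose -> xylan/araban, 1.0 passthrough).
    """
    if carbohydrate_content <= 0:
        raise ValueError("carbohydrate content must be positive")
    if sugar_released < 0 or anhydro_factor < 0:
        raise ValueError("inputs must be non-negative")
    return 100.0 * sugar_released * anhydro_factor / carbohydrate_content


def selectivity_table(records: list[CompositionRecord]) -> pd.DataFrame:
    """Per-record losses and selectivity ratios as one tidy table.

    Ratios are reported at the printed 2-decimal precision ("ND" cells stay
    NaN); full-precision values sit in ``lc_full`` / ``lh_full``.
    """
    rows = []
    for rec in records:
        ratios = selectivity_ratios(rec)
        rows.append(
            {
                "label": rec.label,
                "weight_loss_pct": rec.weight_loss_pct,
                "cellulose_loss_pct": rec.loss_pct.get("cellulose"),
                "holocellulose_loss_pct": rec.loss_pct.get("holocellulose"),
                "lignin_loss_pct": rec.loss_pct.get("lignin"),
                "lc": ratios["L/C_rounded"],
                "lh": ratios["L/H_rounded"],
                "lc_full": ratios["L/C"],
                "lh_full": ratios["L/H"],
            }
        )
    return pd.DataFrame(rows)
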