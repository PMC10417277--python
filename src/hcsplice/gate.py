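"""Transfection gating, G/R ratio classification and well summaries.

Gates come from the corrected-intensity distribution of cells in
untransfected (negative-control) wells: ``gate = mean + k·sd`` per channel,
with k = 3 by default.  A cell is transfected when it clears the gate in
either channel ("double-threshold" gating: G-positive OR R-positive).

Each transfected cell's regularised green/red ratio
``(corr_g + ε)/(corr_r + ε)`` is classified against a lower threshold K
(default 2) and an upper threshold J (default 5):

* ratio > J   -> ``E10minus_GFP``  (exon skipped, green)
* ratio < K   -> ``E10plus_RFP``   (exon included, red)
* K <= ratio <= J -> ``dual``      (both isoforms expressed)

Boundary values go to ``dual``, the conservative bucket.  Well summaries
report total cells, % transfected over all cells, the median G/R of
transfected cells, and the three class percentages over transfected cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, GatingError

CLASS_RFP = "E10plus_RFP"
CLASS_GFP = "E10minus_GFP"
CLASS_DUAL = "dual"
CLASSES = (CLASS_RFP, CLASS_GFP, CLASS_DUAL)


@dataclass(frozen=True)
class GateThresholds:
    """Per-channel transfection gates (corrected counts) and provenance."""

    gate_g: float
    gate_r: float
    k_sigma: float = 3.0
    source: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.gate_g < 0 or self.gate_r < 0:
            raise ConfigError("gates must be >= 0")


@dataclass(frozen=True)
class ClassifierParams:
    """G/R ratio thresholds: lower K, upper J, and the ratio regulariser ε."""

    K: float = 2.0
    J: float = 5.0
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.K < self.J:
            raise ConfigError(f"require 0 < K < J, got K={self.K}, J={self.J}")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be > 0")


@dataclass
class WellSummary:
    """Per-well feature outputs.

    ``pct_transfected`` is over all cells; the class percentages and
    ``median_g_over_r`` are over transfected cells only.  When the well has
    no cells (or no transfected cells) the undefined quantities are NaN and
    ``valid`` is False rather than silently zero.
    """

    well: str
    condition: str
    total_cells: int
    pct_transfected: float
    median_g_over_r: float
    pct_rfp: float
    pct_gfp: float
    pct_dual: float
    valid: bool = True

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def derive_gates(
    neg_cells: pd.DataFrame,
    k_sigma: float = 3.0,
    min_cells: int = 50,
    source: Sequence[str] = (),
) -> GateThresholds:
    """Gate per channel as mean + k_sigma·sd of negative-control cells."""
    n = len(neg_cells)
    if n < min_cells:
        raise GatingError(
            f"only {n} negative_control cells available "
            f"(need >= {min_cells}); check wells with role 'negative_control'"
        )
    g = neg_cells["corr_g"].to_numpy(dtype=float)
    r = neg_cells["corr_r"].to_numpy(dtype=float)
    sd_g = float(np.std(g, ddof=1)) if n > 1 else 0.0
    sd_r = float(np.std(r, ddof=1)) if n > 1 else 0.0
    return GateThresholds(
        gate_g=float(np.mean(g)) + k_sigma * sd_g,
        gate_r=float(np.mean(r)) + k_sigma * sd_r,
        k_sigma=k_sigma,
        source=tuple(source),
    )


def is_transfected(corr_g, corr_r, gates: GateThresholds):
    """True where the cell clears the gate in either channel (vectorised)."""
    return (np.asarray(corr_g) >= gates.gate_g) | (np.asarray(corr_r) >= gates.gate_r)


def g_over_r(corr_g, corr_r, epsilon: float = 1.0):
    """Regularised per-cell green/red ratio; always finite and positive."""
    return (np.asarray(corr_g, dtype=float) + epsilon) / (
        np.asarray(corr_r, dtype=float) + epsilon
    )


def classify_ratio(ratio: float, params: ClassifierParams | None = None) -> str:
    """Class of a single G/R ratio (boundaries at K and J go to dual)."""
    params = params or ClassifierParams()
    if ratio > params.J:
        return CLASS_GFP
    if ratio < params.K:
        return CLASS_RFP
    return CLASS_DUAL


def classify_ratios(ratios, params: ClassifierParams | None = None) -> np.ndarray:
    """Vectorised :func:`classify_ratio`."""
    params = params or ClassifierParams()
    r = np.asarray(ratios, dtype=float)
    out = np.full(r.shape, CLASS_DUAL, dtype=object)
    out[r > params.J] = CLASS_GFP
    out[r < params.K] = CLASS_RFP
    return out


def augment_cells(
    cells: pd.DataFrame,
    gates: GateThresholds,
    params: ClassifierParams | None = None,
) -> pd.DataFrame:
    """Add ``transfected``, ``g_over_r`` and ``splice_class`` columns.

    ``splice_class`` is empty for untransfected cells (they are excluded
    from population percentages).
    """
    params = params or ClassifierParams()
    out = cells.copy()
    out["transfected"] = is_transfected(out["corr_g"], out["corr_r"], gates)
    out["g_over_r"] = g_over_r(out["corr_g"], out["corr_r"], params.epsilon)
    cls = classify_ratios(out["g_over_r"], params)
    cls[~out["transfected"].to_numpy()] = ""
    out["splice_class"] = cls
    return out


def summarize_well(
    cells: pd.DataFrame,
    gates: GateThresholds,
    params: ClassifierParams | None = None,
    well: str = "",
    condition: str = "",
    median_over: str = "transfected",
) -> WellSummary:
    """Feature outputs for one well's cells.

    ``median_over`` selects the population for the median G/R:
    ``"transfected"`` (default; untransfected cells carry only noise) or
    ``"all"``.
    """
    params = params or ClassifierParams()
    if median_over not in ("transfected", "all"):
        raise ConfigError("median_over must be 'transfected' or 'all'")
    total = len(cells)
    if total == 0:
        return WellSummary(
            well, condition, 0, math.nan, math.nan, math.nan, math.nan, math.nan, valid=False
        )
    aug = augment_cells(cells, gates, params)
    n_trans = int(aug["transfected"].sum())
    pct_transfected = 100.0 * n_trans / total
    if n_trans == 0:
        return WellSummary(
            well, condition, total, pct_transfected,
            math.nan, math.nan, math.nan, math.nan, valid=False,
        )
    pop = aug if median_over == "all" else aug[aug["transfected"]]
    median_ratio = float(pop["g_over_r"].median())
    tcls = aug.loc[aug["transfected"], "splice_class"]
    return WellSummary(
        well=well,
        condition=condition,
        total_cells=total,
        pct_transfected=pct_transfected,
        median_g_over_r=median_ratio,
        pct_rfp=100.0 * float((tcls == CLASS_RFP).mean()),
        pct_gfp=100.0 * float((tcls == CLASS_GFP).mean()),
        pct_dual=100.0 * float((tcls == CLASS_DUAL).mean()),
    )
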