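"""Plate quality control and condition statistics.

The Z′ (Z-prime) factor scores how well the negative- and positive-control
readout distributions separate::

    SNR = (sigma_neg + sigma_pos) / |mu_neg - mu_pos|
    Z'  = 1 - 3 * SNR

Z′ has a theoretical maximum of 1.0 (noise-free controls); values above
~0.4 are considered sufficient for a screening assay and above ~0.6 robust.
Condition comparisons use the Welch (unequal-variance) two-sided t-test on
per-well replicate summaries, with Bonferroni correction across the family
of comparisons.  Dose-response tables report per-dose class-percentage
deltas of treated wells against matched scramble-control wells at the same
dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

ZPRIME_ROBUST = 0.6
ZPRIME_SUFFICIENT = 0.4


@dataclass(frozen=True)
class ControlStats:
    """Location/scale summary of one control population's readout."""

    mu: float
    sigma: float
    n: int
    role: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")

    @classmethod
    def from_values(cls, values: Sequence[float], role: str = "") -> "ControlStats":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise DataError(f"need >= 2 replicate values for {role or 'control'} stats")
        return cls(mu=float(v.mean()), sigma=float(v.std(ddof=1)), n=int(v.size), role=role)


@dataclass(frozen=True)
class QcResult:
    """Z′ outcome: the statistic, the SNR it derives from, and the verdict
    band (robust >= 0.6, sufficient >= 0.4, insufficient otherwise)."""

    zprime: float
    snr: float
    verdict: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def zprime(neg: ControlStats, pos: ControlStats) -> QcResult:
    """Z′ factor from negative/positive control summaries."""
    sep = abs(neg.mu - pos.mu)
    if sep == 0:
        raise DataError("control means are equal; Z' undefined (zero separation)")
    snr = (neg.sigma + pos.sigma) / sep
    z = 1.0 - 3.0 * snr
    if z >= ZPRIME_ROBUST:
        verdict = "robust"
    elif z >= ZPRIME_SUFFICIENT:
        verdict = "sufficient"
    else:
        verdict = "insufficient"
    return QcResult(zprime=z, snr=snr, verdict=verdict)


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch t-test on per-replicate summaries.

    Returns ``(t, p)``; identical degenerate samples (zero variance on both
    sides, equal means) are reported as no effect, ``(0.0, 1.0)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each sample needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DataError("both samples have zero variance with distinct means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bonferroni(pvalues: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values: ``min(1, p * m)``.

    ``m`` defaults to the family size ``len(pvalues)`` and must be at least
    that large.
    """
    p = list(pvalues)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ConfigError(f"m={m} smaller than number of p-values ({len(p)})")
    return [min(1.0, v * m) for v in p]


DOSE_COLUMNS = (
    "condition",
    "dose",
    "n_treated",
    "n_control",
    "treated_pct_rfp",
    "treated_pct_gfp",
    "treated_pct_dual",
    "control_pct_rfp",
    "control_pct_gfp",
    "control_pct_dual",
    "delta_rfp",
    "delta_gfp",
    "delta_dual",
    "sd_delta_rfp",
)


def dose_response(
    summaries: pd.DataFrame,
    treated_role: str = "sample",
    control_role: str = "scramble_control",
) -> pd.DataFrame:
    """Per-dose class-percentage deltas against matched scramble controls.

    ``summaries`` is a per-well table with at least ``condition``, ``role``,
    ``dose``, ``pct_rfp``, ``pct_gfp``, ``pct_dual`` columns.  Each treated
    (condition, dose) group is compared with the control wells at the same
    dose; deltas are treated-minus-control means in percentage points and,
    since the three class percentages each sum to 100, the three deltas sum
    to ~0.  Raises :class:`DataError` when a dose lacks a matched control.
    """
    req = {"condition", "role", "dose", "pct_rfp", "pct_gfp", "pct_dual"}
    missing = req - set(summaries.columns)
    if missing:
        raise DataError(f"summaries table missing columns: {sorted(missing)}")
    treated = summaries[summaries["role"] == treated_role]
    controls = summaries[summaries["role"] == control_role]
    if treated.empty:
        raise DataError(f"no wells with role {treated_role!r}")
    rows = []
    for (cond, dose), grp in treated.groupby(["condition", "dose"], dropna=False):
        ctl = controls[controls["dose"] == dose]
        if ctl.empty:
            raise DataError(
                f"no {control_role!r} wells matched to dose {dose!r} "
                f"(condition {cond!r})"
            )
        t_mean = grp[["pct_rfp", "pct_gfp", "pct_dual"]].mean()
        c_mean = ctl[["pct_rfp", "pct_gfp", "pct_dual"]].mean()
        n_pairs = min(len(grp), len(ctl))
        delta_r = grp["pct_rfp"].to_numpy() - c_mean["pct_rfp"]
        rows.append(
            {
                "condition": cond,
                "dose": dose,
                "n_treated": len(grp),
                "n_control": len(ctl),
                "treated_pct_rfp": t_mean["pct_rfp"],
                "treated_pct_gfp": t_mean["pct_gfp"],
                "treated_pct_dual": t_mean["pct_dual"],
                "control_pct_rfp": c_mean["pct_rfp"],
                "control_pct_gfp": c_mean["pct_gfp"],
                "control_pct_dual": c_mean["pct_dual"],
                "delta_rfp": t_mean["pct_rfp"] - c_mean["pct_rfp"],
                "delta_gfp": t_mean["pct_gfp"] - c_mean["pct_gfp"],
                "delta_dual": t_mean["pct_dual"] - c_mean["pct_dual"],
                "sd_delta_rfp": float(np.std(delta_r, ddof=1)) if len(delta_r) > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows, columns=list(DOSE_COLUMNS))
    return out.sort_values(["condition", "dose"]).reset_index(drop=True)
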