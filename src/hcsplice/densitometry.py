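"""Semiquantitative gel densitometry on 1-D lane profiles.

Reproduces the validation arithmetic of the splicing-reporter RT-PCR
readout: a DNA ladder lane calibrates migration position against
log10(fragment size), bands are detected on baseline-subtracted lane
profiles, assigned to the expected amplicons — the exon-included isoform
(E10+, 300 bp with the reporter primer set), the exon-skipped isoform
(E10−, 207 bp) and the Beta-Actin housekeeping control (650 bp) — and
quantified as actin-normalised levels.  The exon-inclusion percentage of a
lane is ``E10+ / (E10+ + E10−) · 100`` (actin cancels within a lane but the
normalised levels are what cross-lane fold-changes use).

Baseline estimation is a morphological opening (moving minimum followed by
moving maximum) with a configurable window; band area is the integral of
the baseline-subtracted signal over the peak's support between flanking
minima.  Migration follows the standard electrophoresis approximation
``position ≈ slope · log10(bp) + intercept`` with slope < 0 for the usual
orientation (larger fragments migrate less).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import find_peaks

from .errors import BandAssignmentError, CalibrationError, ConfigError, DataError

#: Expected amplicon sizes (bp) of the reporter primer set.
REPORTER_AMPLICONS = {"E10plus": 300.0, "E10minus": 207.0, "actin": 650.0}
#: Expected amplicon sizes (bp) of the endogenous primer set.
ENDOGENOUS_AMPLICONS = {"E10plus": 368.0, "E10minus": 275.0, "actin": 650.0}

#: Rung sizes (bp) of a typical 1 kb-plus ladder subset used here.
DEFAULT_LADDER_SIZES = (100.0, 200.0, 300.0, 400.0, 500.0, 650.0, 850.0, 1000.0, 1500.0)


@dataclass
class LaneProfile:
    """One gel lane reduced to a 1-D densitometric profile."""

    lane_id: str
    positions: np.ndarray
    intensities: np.ndarray
    role: str = "sample"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise DataError("positions and intensities must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise DataError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise DataError("intensities must be >= 0")

    @classmethod
    def from_csv(cls, path, lane_id: str | None = None, role: str = "sample") -> "LaneProfile":
        df = pd.read_csv(path)
        return cls(
            lane_id=lane_id or str(path),
            positions=df.iloc[:, 0].to_numpy(),
            intensities=df.iloc[:, 1].to_numpy(),
            role=role,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"position": self.positions, "intensity": self.intensities}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class LadderCalibration:
    """Least-squares line of migration position vs log10(size in bp)."""

    slope: float
    intercept: float
    rungs: tuple[tuple[float, float], ...]  # (position, size_bp)

    def predict_position(self, size_bp: float) -> float:
        return self.slope * np.log10(size_bp) + self.intercept

    def predict_size(self, position: float) -> float:
        return float(10.0 ** ((position - self.intercept) / self.slope))

    @property
    def position_range(self) -> tuple[float, float]:
        pos = [p for p, _ in self.rungs]
        return min(pos), max(pos)


@dataclass
class Band:
    """One detected band: centre (px), baseline-subtracted integrated area
    (counts·px), estimated size (bp) and amplicon assignment."""

    center: float
    area: float
    size_bp: float | None = None
    assignment: str = "unassigned"


def calibrate_ladder(
    rung_positions: Sequence[float], rung_sizes: Sequence[float]
) -> LadderCalibration:
    """Fit position = slope·log10(bp) + intercept from ladder rungs."""
    pos = np.asarray(rung_positions, dtype=float)
    sizes = np.asarray(rung_sizes, dtype=float)
    if pos.size != sizes.size:
        raise CalibrationError("rung positions and sizes differ in length")
    if pos.size < 3:
        raise CalibrationError(f"need >= 3 ladder rungs, got {pos.size}")
    diffs = np.diff(pos)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise CalibrationError("rung positions must be monotone")
    slope, intercept = np.polyfit(np.log10(sizes), pos, deg=1)
    return LadderCalibration(
        slope=float(slope),
        intercept=float(intercept),
        rungs=tuple(zip(pos.tolist(), sizes.tolist())),
    )


def detect_bands(
    profile: LaneProfile,
    baseline_window: int = 61,
    min_prominence: float = 10.0,
) -> list[Band]:
    """Detect bands on a lane profile.

    Baseline is a grey-scale morphological opening of the intensities with
    the given window; peaks are found on the baseline-subtracted signal by
    prominence; each band's area integrates the corrected signal over the
    peak's support between the flanking minima (or profile ends).
    """
    n = profile.intensities.size
    if baseline_window >= n:
        raise ConfigError(
            f"baseline_window ({baseline_window}) must be smaller than the "
            f"profile length ({n})"
        )
    baseline = ndi.grey_opening(profile.intensities, size=baseline_window)
    residual = profile.intensities - baseline
    # the opening rides the lower noise envelope; re-centre on the median
    # residual (bands occupy a minority of the profile) before rectifying
    corrected = np.clip(residual - np.median(residual), 0.0, None)
    peaks, _ = find_peaks(corrected, prominence=min_prominence)
    if peaks.size == 0:
        return []
    # support boundaries: minimum of the corrected signal between peaks
    bounds = [0]
    for left, right in zip(peaks[:-1], peaks[1:]):
        bounds.append(int(left + np.argmin(corrected[left:right + 1])))
    bounds.append(n - 1)
    bands = []
    for i, pk in enumerate(peaks):
        lo, hi = bounds[i], bounds[i + 1]
        area = float(np.trapezoid(corrected[lo:hi + 1], profile.positions[lo:hi + 1]))
        bands.append(Band(center=float(profile.positions[pk]), area=area))
    return bands


def assign_bands(
    bands: Sequence[Band],
    cal: LadderCalibration,
    expected: dict[str, float] | None = None,
    tolerance: float = 0.10,
) -> list[Band]:
    """Assign detected bands to expected amplicons by calibrated size.

    Each band gets a size estimate from the ladder calibration; each
    expected amplicon takes the single band within ``tolerance`` relative
    size error.  Two candidate bands for one amplicon raise
    :class:`BandAssignmentError` listing them, as does a missing actin
    (housekeeping) band.  Bands matching nothing stay ``unassigned``.
    """
    expected = expected or REPORTER_AMPLICONS
    out = [
        Band(center=b.center, area=b.area, size_bp=cal.predict_size(b.center))
        for b in bands
    ]
    for name, size in expected.items():
        candidates = [
            b for b in out
            if b.assignment == "unassigned" and abs(b.size_bp - size) / size <= tolerance
        ]
        if len(candidates) > 1:
            sizes = [round(b.size_bp, 1) for b in candidates]
            raise BandAssignmentError(
                f"{len(candidates)} bands compete for the {name} amplicon "
                f"({size:.0f} bp): estimated sizes {sizes}"
            )
        if candidates:
            candidates[0].assignment = name
    if not any(b.assignment == "actin" for b in out):
        raise BandAssignmentError(
            f"missing housekeeping (actin, {expected['actin']:.0f} bp) band"
        )
    return out


@dataclass(frozen=True)
class IsoformQuant:
    """Actin-normalised isoform levels and inclusion percentage of a lane."""

    lane_id: str
    norm_e10plus: float
    norm_e10minus: float
    pct_e10plus: float


def isoform_percent(bands: Sequence[Band], lane_id: str = "") -> IsoformQuant:
    """Actin-normalise the two isoform bands and compute % exon inclusion."""
    by_name = {b.assignment: b for b in bands}
    for need in ("E10plus", "E10minus", "actin"):
        if need not in by_name:
            raise DataError(f"lane {lane_id!r}: no band assigned to {need}")
    actin = by_name["actin"].area
    if actin <= 0:
        raise DataError(f"lane {lane_id!r}: actin band has zero area")
    norm_p = by_name["E10plus"].area / actin
    norm_m = by_name["E10minus"].area / actin
    total = norm_p + norm_m
    pct = 100.0 * norm_p / total if total > 0 else float("nan")
    return IsoformQuant(lane_id=lane_id, norm_e10plus=norm_p, norm_e10minus=norm_m, pct_e10plus=pct)


def fold_change(q_case: IsoformQuant, q_ref: IsoformQuant) -> float:
    """Ratio of actin-normalised E10+ levels, case over reference."""
    if q_ref.norm_e10plus <= 0:
        raise DataError("reference lane has zero normalised E10+ level")
    return q_case.norm_e10plus / q_ref.norm_e10plus


def synth_gel(
    band_spec: Sequence[tuple[float, float]],
    cal: LadderCalibration,
    noise_sd: float = 1.0,
    seed: int = 0,
    band_sigma: float = 4.0,
    baseline_level: float = 20.0,
    baseline_slope: float = 5.0,
    lane_id: str = "synthetic",
) -> LaneProfile:
    """Synthesise a lane profile with Gaussian bands of specified areas.

    ``band_spec`` is a list of ``(size_bp, area)``; each band is placed at
    its calibrated migration position with a Gaussian shape integrating to
    the given area, on a smooth linear baseline plus seeded noise.  Sizes
    outside the calibration range are rejected.
    """
    lo, hi = cal.position_range
    pad = 6 * band_sigma
    positions = np.arange(min(lo, hi) - pad, max(lo, hi) + pad + 1, 1.0)
    signal = baseline_level + baseline_slope * (positions - positions[0]) / (
        positions[-1] - positions[0]
    )
    for size, area in band_spec:
        center = cal.predict_position(size)
        if not (min(lo, hi) <= center <= max(lo, hi)):
            raise ConfigError(
                f"band of {size:.0f} bp maps to position {center:.1f}, "
                f"outside the calibrated range [{min(lo, hi):.1f}, {max(lo, hi):.1f}]"
            )
        amp = area / (band_sigma * np.sqrt(2 * np.pi))
        signal = signal + amp * np.exp(-0.5 * ((positions - center) / band_sigma) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=positions.size)
    return LaneProfile(
        lane_id=lane_id, positions=positions, intensities=np.clip(signal, 0.0, None)
    )


def default_ladder() -> LadderCalibration:
    """A synthetic ladder calibration on the standard log-mobility law.

    Rung positions follow ``position = -450·log10(bp) + 1450`` for the
    :data:`DEFAULT_LADDER_SIZES`, spanning roughly 20–550 px.
    """
    sizes = np.asarray(DEFAULT_LADDER_SIZES)
    positions = -450.0 * np.log10(sizes) + 1450.0
    order = np.argsort(positions)
    return calibrate_ladder(positions[order], sizes[order])


def bands_table(bands: Sequence[Band]) -> pd.DataFrame:
    """Detected/assigned bands as a tidy table."""
    return pd.DataFrame(
        [
            {
                "center": b.center,
                "area": b.area,
                "size_bp": b.size_bp,
                "assignment": b.assignment,
            }
            for b in bands
        ]
    )
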