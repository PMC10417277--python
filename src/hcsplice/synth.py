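"""Synthetic plate-image generator with per-cell ground truth.

Emulates multiwell fluorescence fields of adherent cells carrying a
two-colour splicing reporter: inclusion of the alternative exon produces
RFP, skipping produces GFP, so each cell's green/red balance reads out its
exon-inclusion fraction (here called ``psi``).  Cells are rendered as
concentric discs (nucleus inside cytoplasm) with homogeneous reporter
intensity; per cell the GFP reporter signal is ``expression * (1 - psi)``
and the RFP signal is ``expression * psi``, so green + red is conserved
across splice outcomes.  Fields carry a constant background plus a smooth
low-order polynomial gradient, autofluorescence inside every cell
(transfected or not), nuclear Hoechst signal, and Gaussian detector noise,
quantised to the configured bit depth.

Every stochastic operation takes an explicit seed and is deterministic
under it; the generator returns exact per-cell ground truth (position,
radii, transfection flag, psi, expression) so downstream segmentation,
intensity measurement and classification can be checked against an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError, PlacementError

if TYPE_CHECKING:  # pragma: no cover
    from .layout import PlateLayout

CHANNELS = ("hoechst", "gfp", "rfp")

ROLES = ("sample", "negative_control", "positive_control", "scramble_control")

#: Columns of a cell-truth table, in stable order.
TRUTH_COLUMNS = (
    "cell_id",
    "field_id",
    "y",
    "x",
    "nucleus_radius",
    "cell_radius",
    "transfected",
    "psi",
    "expression",
)


# ---------------------------------------------------------------------------
# condition / optics specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionSpec:
    """Biological condition of one well, as generator parameters.

    Parameters
    ----------
    name
        Condition label (e.g. ``"WT"``, ``"N279K"``).
    cells_per_field
        Number of cells plated per imaged field.
    transfection_rate
        Bernoulli probability that a cell carries the reporter, in [0, 1].
    inclusion_mean
        Mean exon-inclusion fraction ``psi`` of the condition, in [0, 1].
        A wild-type-like reporter sits low (~0.35); a splice-switching
        mutant like N279K sits high (~0.85).
    inclusion_concentration
        Concentration of the per-cell Beta distribution of psi
        (``a + b`` in the Beta(a, b) parameterisation); small values
        (< 2) give a bimodal, U-shaped population, large values a tight
        unimodal one.
    expression_log_mean, expression_log_sd
        Natural-log-scale parameters of the log-normal per-cell reporter
        expression level, in detector counts.
    role
        Control role of wells carrying this condition.
    """

    name: str
    cells_per_field: int = 100
    transfection_rate: float = 0.7
    inclusion_mean: float = 0.5
    inclusion_concentration: float = 8.0
    expression_log_mean: float = math.log(800.0)
    expression_log_sd: float = 0.5
    role: str = "sample"

    def __post_init__(self) -> None:
        if not 0.0 <= self.transfection_rate <= 1.0:
            raise ConfigError(
                f"transfection_rate must be in [0, 1], got {self.transfection_rate}"
            )
        if not 0.0 <= self.inclusion_mean <= 1.0:
            raise ConfigError(
                f"inclusion_mean must be in [0, 1], got {self.inclusion_mean}"
            )
        if self.inclusion_concentration <= 0:
            raise ConfigError("inclusion_concentration must be > 0")
        if self.cells_per_field < 0:
            raise ConfigError("cells_per_field must be >= 0")
        if self.role not in ROLES:
            raise ConfigError(f"unknown role {self.role!r}; expected one of {ROLES}")


def _default_background() -> dict[str, float]:
    return {"hoechst": 100.0, "gfp": 80.0, "rfp": 80.0}


def _default_autofluorescence() -> dict[str, float]:
    return {"hoechst": 8.0, "gfp": 15.0, "rfp": 15.0}


@dataclass(frozen=True)
class OpticsSpec:
    """Imaging geometry and detector model of one field.

    Background per channel is a constant level plus a smooth low-order
    polynomial gradient of the given amplitude (counts); autofluorescence
    is added inside every cell disc regardless of transfection; noise is
    i.i.d. Gaussian per pixel; images are clipped and quantised to
    ``bit_depth`` bits.
    """

    field_shape: tuple[int, int] = (360, 360)
    background_level: Mapping[str, float] = field(default_factory=_default_background)
    background_gradient_amplitude: float = 20.0
    autofluorescence: Mapping[str, float] = field(
        default_factory=_default_autofluorescence
    )
    noise_sd: float = 5.0
    bit_depth: int = 16
    # cell geometry (pixels)
    nucleus_radius_mean: float = 5.5
    nucleus_radius_sd: float = 0.6
    cell_radius_factor: float = 1.8
    hoechst_nucleus_level: float = 600.0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ConfigError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        for ch in CHANNELS:
            if self.background_level[ch] < 0 or self.autofluorescence[ch] < 0:
                raise ConfigError("background and autofluorescence must be >= 0")
        if self.noise_sd < 0 or self.background_gradient_amplitude < 0:
            raise ConfigError("noise_sd and gradient amplitude must be >= 0")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


@dataclass(frozen=True)
class FieldImage:
    """One imaged field: the three single-plane channels plus identity."""

    hoechst: np.ndarray
    gfp: np.ndarray
    rfp: np.ndarray
    well: str = ""
    field_id: int = 0

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class WellData:
    """Rendered fields and ground truth of one well."""

    well: str
    condition: str
    role: str
    dose: float | None
    replicate: int | None
    fields: list[FieldImage]
    truth: pd.DataFrame


@dataclass
class PlateDataset:
    """A full synthetic plate: per-well images and truth, plus the seed."""

    wells: dict[str, WellData]
    seed: int

    def truth_table(self) -> pd.DataFrame:
        """All truth rows, with a leading ``well`` column."""
        frames = []
        for wid, wd in self.wells.items():
            t = wd.truth.copy()
            t.insert(0, "well", wid)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def n_fields(self) -> int:
        return sum(len(w.fields) for w in self.wells.values())


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_condition_cells(
    spec: ConditionSpec,
    n_fields: int,
    geometry: OpticsSpec,
    seed: int,
    max_retries: int = 200,
) -> pd.DataFrame:
    """Draw per-cell ground truth for ``n_fields`` fields of one condition.

    Cells are placed uniformly at random with rejection sampling so that no
    two nuclei overlap (centre distance >= sum of nucleus radii + 1 px) and
    whole cells fit inside the field.  Transfection is Bernoulli, psi is
    Beta with the spec's mean and concentration, expression is log-normal.

    Returns a DataFrame with :data:`TRUTH_COLUMNS`; raises
    :class:`PlacementError` if a cell cannot be placed within
    ``max_retries`` attempts (field too crowded).
    """
    if n_fields < 1:
        raise ConfigError("n_fields must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = geometry.field_shape
    rows: list[tuple] = []
    cell_id = 0
    for fid in range(n_fields):
        placed: list[tuple[float, float, float]] = []  # (y, x, nucleus_radius)
        for _ in range(spec.cells_per_field):
            nr = float(
                np.clip(
                    rng.normal(geometry.nucleus_radius_mean, geometry.nucleus_radius_sd),
                    3.0,
                    geometry.nucleus_radius_mean + 3 * geometry.nucleus_radius_sd,
                )
            )
            cr = nr * geometry.cell_radius_factor
            for attempt in range(max_retries):
                y = rng.uniform(cr + 1, h - cr - 2)
                x = rng.uniform(cr + 1, w - cr - 2)
                ok = all(
                    (y - py) ** 2 + (x - px) ** 2 >= (nr + pr + 1.0) ** 2
                    for py, px, pr in placed
                )
                if ok:
                    break
            else:
                raise PlacementError(
                    f"could not place cell {len(placed) + 1} of "
                    f"{spec.cells_per_field} in field {fid} after "
                    f"{max_retries} attempts; reduce cells_per_field"
                )
            placed.append((y, x, nr))
            transfected = bool(rng.random() < spec.transfection_rate)
            psi = _sample_psi(rng, spec.inclusion_mean, spec.inclusion_concentration)
            expression = float(
                rng.lognormal(spec.expression_log_mean, spec.expression_log_sd)
            )
            rows.append((cell_id, fid, y, x, nr, cr, transfected, psi, expression))
            cell_id += 1
    df = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    df["transfected"] = df["transfected"].astype(bool)
    return df


def _sample_psi(rng: np.random.Generator, mean: float, concentration: float) -> float:
    if mean <= 0.0:
        return 0.0
    if mean >= 1.0:
        return 1.0
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return float(rng.beta(a, b))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_field(
    cells: pd.DataFrame,
    optics: OpticsSpec,
    seed: int,
    well: str = "",
    field_id: int = 0,
) -> FieldImage:
    """Render one field's three channels from a cell-truth table.

    The signal model per channel is
    ``background + gradient + autofluorescence·cell + reporter·cell + noise``
    with the reporter present only in transfected cells: GFP carries
    ``expression·(1−psi)``, RFP carries ``expression·psi``, and Hoechst
    carries a fixed nuclear level inside the nucleus disc only.
    """
    h, w = optics.field_shape
    if len(cells):
        if (cells["y"] + cells["cell_radius"]).max() > h or (
            cells["x"] + cells["cell_radius"]
        ).max() > w:
            raise ConfigError("cells do not fit in field_shape")
    rng = np.random.default_rng(seed)

    # smooth low-order polynomial background gradient, shared across channels
    u = np.linspace(0.0, 1.0, h)[:, None]
    v = np.linspace(0.0, 1.0, w)[None, :]
    c = rng.uniform(-1.0, 1.0, size=3)
    poly = c[0] * u + c[1] * v + c[2] * u * v
    span = poly.max() - poly.min()
    gradient = (
        optics.background_gradient_amplitude * (poly - poly.min()) / span
        if span > 0
        else np.zeros((h, w))
    )

    cell_mask = np.zeros((h, w), dtype=bool)
    nucleus_mask = np.zeros((h, w), dtype=bool)
    gfp_signal = np.zeros((h, w), dtype=np.float64)
    rfp_signal = np.zeros((h, w), dtype=np.float64)
    for row in cells.itertuples(index=False):
        sl, disc_c = _disc(h, w, row.y, row.x, row.cell_radius)
        cell_mask[sl] |= disc_c
        if row.transfected:
            gfp_signal[sl][disc_c] += row.expression * (1.0 - row.psi)
            rfp_signal[sl][disc_c] += row.expression * row.psi
        sln, disc_n = _disc(h, w, row.y, row.x, row.nucleus_radius)
        nucleus_mask[sln] |= disc_n

    channels = {}
    for ch in CHANNELS:
        img = np.full((h, w), float(optics.background_level[ch])) + gradient
        img[cell_mask] += optics.autofluorescence[ch]
        if ch == "hoechst":
            img[nucleus_mask] += optics.hoechst_nucleus_level
        elif ch == "gfp":
            img += gfp_signal
        else:
            img += rfp_signal
        if optics.noise_sd > 0:
            img += rng.normal(0.0, optics.noise_sd, size=(h, w))
        channels[ch] = np.clip(np.rint(img), 0, optics.max_count).astype(optics.dtype)
    return FieldImage(well=well, field_id=field_id, **channels)


def _disc(
    h: int, w: int, cy: float, cx: float, r: float
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Bounding-box slice plus local boolean disc mask for one cell."""
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    yy = np.arange(y0, y1)[:, None]
    xx = np.arange(x0, x1)[None, :]
    return (slice(y0, y1), slice(x0, x1)), (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


# ---------------------------------------------------------------------------
# whole plates
# ---------------------------------------------------------------------------


def generate_plate(
    layout: "PlateLayout",
    optics: OpticsSpec | None = None,
    seed: int = 0,
    n_fields: int | None = None,
) -> PlateDataset:
    """Generate a full plate dataset from a layout.

    Each well gets ``layout.min_fields`` fields (default 12, matching the
    acquisition minimum the assay prescribes) unless ``n_fields`` overrides
    it.  Deterministic under ``seed``: wells are processed in sorted order
    and each well/field draws from an independent child seed.
    """
    optics = optics or OpticsSpec()
    fields_per_well = n_fields if n_fields is not None else layout.min_fields
    if fields_per_well < 1:
        raise ConfigError("fields per well must be >= 1")
    root = np.random.SeedSequence(seed)
    wells: dict[str, WellData] = {}
    well_ids = sorted(layout.wells)
    children = root.spawn(len(well_ids))
    for wid, ss in zip(well_ids, children):
        wspec = layout.wells[wid]
        cond = layout.conditions[wspec.condition]
        cell_seed, render_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
        truth = sample_condition_cells(cond, fields_per_well, optics, cell_seed)
        field_rngs = np.random.SeedSequence(render_seed).spawn(fields_per_well)
        images = []
        for fid, fss in enumerate(field_rngs):
            fcells = truth[truth["field_id"] == fid]
            images.append(
                render_field(
                    fcells,
                    optics,
                    int(fss.generate_state(1)[0] % (2**31)),
                    well=wid,
                    field_id=fid,
                )
            )
        wells[wid] = WellData(
            well=wid,
            condition=wspec.condition,
            role=wspec.role,
            dose=wspec.dose,
            replicate=wspec.replicate,
            fields=images,
            truth=truth,
        )
    return PlateDataset(wells=wells, seed=seed)


def with_offset(dataset: PlateDataset, offset: int) -> PlateDataset:
    """Return a copy of the dataset with ``offset`` counts added to every
    pixel of every channel (saturating at the dtype maximum).

    Useful for checking that background subtraction makes downstream
    results invariant to a global additive shift.
    """
    wells = {}
    for wid, wd in dataset.wells.items():
        new_fields = []
        for fi in wd.fields:
            chans = {}
            for ch in CHANNELS:
                img = fi.channel(ch)
                info = np.iinfo(img.dtype)
                shifted = np.clip(img.astype(np.int64) + offset, 0, info.max)
                chans[ch] = shifted.astype(img.dtype)
            new_fields.append(FieldImage(well=fi.well, field_id=fi.field_id, **chans))
        wells[wid] = WellData(
            well=wd.well,
            condition=wd.condition,
            role=wd.role,
            dose=wd.dose,
            replicate=wd.replicate,
            fields=new_fields,
            truth=wd.truth,
        )
    return PlateDataset(wells=wells, seed=dataset.seed)


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------


def field_filename(well: str, field_id: int, channel: str) -> str:
    return f"{well}_f{field_id:02d}_{channel}.tiff"


def write_dataset(dataset: PlateDataset, out_dir: str | Path) -> None:
    """Write one TIFF per channel per field plus a plate truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for wid, wd in dataset.wells.items():
        for fi in wd.fields:
            for ch in CHANNELS:
                tifffile.imwrite(out / field_filename(wid, fi.field_id, ch), fi.channel(ch))
    dataset.truth_table().to_csv(out / "truth.csv", index=False)


def read_fields(
    image_dir: str | Path, well: str, n_fields: int
) -> list[FieldImage]:
    """Read the per-channel TIFFs of one well back into FieldImages."""
    image_dir = Path(image_dir)
    fields = []
    for fid in range(n_fields):
        chans = {}
        for ch in CHANNELS:
            path = image_dir / field_filename(well, fid, ch)
            if not path.exists():
                raise FileNotFoundError(path)
            chans[ch] = tifffile.imread(path)
        fields.append(FieldImage(well=well, field_id=fid, **chans))
    return fields


def noise_free(optics: OpticsSpec) -> OpticsSpec:
    """The same optics with detector noise switched off."""
    return replace(optics, noise_sd=0.0)
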