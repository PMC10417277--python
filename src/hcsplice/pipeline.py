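"""End-to-end plate analysis: images -> per-cell table -> well summaries -> QC.

Per field, the workflow is: segment nuclei on the Hoechst channel, expand
them into perinuclear ROIs, estimate per-channel background on the
cell-free area (per field, which tolerates field-to-field illumination
drift), and measure background-corrected per-cell GFP/RFP means.  Cells
are then pooled per well, transfection gates are derived from the
negative-control wells, each transfected cell is classified by its G/R
ratio, and wells are summarised.  When both negative- and positive-control
wells are present (>= 2 each), the Z′ factor is computed on per-well mean
corrected RFP as the readout.

Deterministic given inputs and seed; every parameter value used is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .errors import GatingError
from .gate import ClassifierParams, GateThresholds, augment_cells, derive_gates, summarize_well
from .intensity import background_level, measure_cells
from .layout import PlateLayout
from .segment import SegmentationParams, cell_free_mask, expand_rois, find_nuclei
from .synth import FieldImage, OpticsSpec, PlateDataset, generate_plate, read_fields

log = logging.getLogger("hcsplice")

WELL_COLUMNS = (
    "well",
    "condition",
    "role",
    "dose",
    "replicate",
    "total_cells",
    "pct_transfected",
    "median_g_over_r",
    "pct_rfp",
    "pct_gfp",
    "pct_dual",
    "mean_corr_g",
    "mean_corr_r",
    "valid",
)


@dataclass
class PipelineResult:
    """Everything one plate run produces."""

    cells: pd.DataFrame
    wells: pd.DataFrame
    gates: GateThresholds
    qc: qc_mod.QcResult | None

    def qc_report(self) -> dict:
        report = {
            "gates": {
                "gate_g": self.gates.gate_g,
                "gate_r": self.gates.gate_r,
                "k_sigma": self.gates.k_sigma,
                "source_wells": list(self.gates.source),
            }
        }
        if self.qc is not None:
            report["zprime"] = self.qc.to_dict()
        return report


def measure_field(
    field: FieldImage,
    seg_params: SegmentationParams,
    bg_margin: float = 4.0,
) -> pd.DataFrame:
    """Segment and measure one field into a per-cell record table."""
    nuclei = find_nuclei(field.hoechst, seg_params)
    rois = expand_rois(nuclei, seg_params.roi_expansion_radius)
    if rois.n_objects == 0:
        return measure_cells(field.gfp, field.rfp, rois, 0.0, 0.0, field.well, field.field_id)
    mask, _ = cell_free_mask(rois, margin=bg_margin)
    bg_g = background_level(field.gfp, mask)
    bg_r = background_level(field.rfp, mask)
    return measure_cells(field.gfp, field.rfp, rois, bg_g, bg_r, field.well, field.field_id)


def analyze_plate(
    dataset: PlateDataset,
    layout: PlateLayout,
    seg_params: SegmentationParams | None = None,
    classifier: ClassifierParams | None = None,
    median_over: str = "transfected",
) -> PipelineResult:
    """Run the analysis stages on an in-memory plate dataset."""
    seg_params = seg_params or SegmentationParams()
    classifier = classifier or ClassifierParams()
    log.info("segmentation params: %s", seg_params)
    log.info("classifier params: %s", classifier)

    frames = []
    for wid in sorted(dataset.wells):
        wd = dataset.wells[wid]
        if len(wd.fields) < layout.min_fields:
            log.warning(
                "well %s has %d fields, below the layout minimum of %d",
                wid, len(wd.fields), layout.min_fields,
            )
        for fi in wd.fields:
            frames.append(measure_field(fi, seg_params))
    cells = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    neg_wells = layout.wells_with_role("negative_control")
    if not neg_wells:
        raise GatingError(
            "layout has no wells with role 'negative_control'; "
            "transfection gates cannot be derived"
        )
    neg_cells = cells[cells["well"].isin(neg_wells)]
    gates = derive_gates(neg_cells, source=neg_wells)
    log.info("gates: gate_g=%.2f gate_r=%.2f (from %s)", gates.gate_g, gates.gate_r, neg_wells)

    cells = augment_cells(cells, gates, classifier)

    rows = []
    for wid in sorted(dataset.wells):
        wd = dataset.wells[wid]
        wcells = cells[cells["well"] == wid]
        summary = summarize_well(
            wcells, gates, classifier, well=wid, condition=wd.condition, median_over=median_over
        )
        row = summary.to_dict()
        row["role"] = wd.role
        row["dose"] = wd.dose
        row["replicate"] = wd.replicate
        row["mean_corr_g"] = float(wcells["corr_g"].mean()) if len(wcells) else float("nan")
        row["mean_corr_r"] = float(wcells["corr_r"].mean()) if len(wcells) else float("nan")
        rows.append(row)
    wells = pd.DataFrame(rows)[list(WELL_COLUMNS)]

    qc_result = _plate_zprime(wells)
    return PipelineResult(cells=cells, wells=wells, gates=gates, qc=qc_result)


def _plate_zprime(wells: pd.DataFrame, readout: str = "mean_corr_r") -> qc_mod.QcResult | None:
    """Z′ on per-well means of the corrected RFP readout, WT-reporter
    (negative) vs mutant-reporter (positive) control wells; None when the
    plate lacks enough control replicates."""
    neg = wells.loc[wells["role"] == "negative_control", readout].dropna()
    pos = wells.loc[wells["role"] == "positive_control", readout].dropna()
    if len(neg) < 2 or len(pos) < 2:
        return None
    try:
        return qc_mod.zprime(
            qc_mod.ControlStats.from_values(neg, role="negative"),
            qc_mod.ControlStats.from_values(pos, role="positive"),
        )
    except Exception as exc:  # zero separation etc. — QC is advisory here
        log.warning("Z' not computable: %s", exc)
        return None


def run_pipeline(
    layout: PlateLayout,
    optics: OpticsSpec | None = None,
    seg_params: SegmentationParams | None = None,
    classifier: ClassifierParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    image_dir: str | Path | None = None,
    n_fields: int | None = None,
) -> PipelineResult:
    """Full pipeline: obtain images (synthetic or from disk), analyse, write.

    With ``image_dir`` the per-channel field TIFFs are read from disk;
    otherwise a synthetic plate is generated under ``seed``.  With
    ``out_dir`` the per-cell CSV, per-well CSV and QC JSON are written.
    """
    if image_dir is not None:
        dataset = load_dataset(image_dir, layout, n_fields=n_fields)
    else:
        dataset = generate_plate(layout, optics, seed=seed, n_fields=n_fields)
    result = analyze_plate(dataset, layout, seg_params, classifier)
    if out_dir is not None:
        write_result(result, out_dir)
    return result


def load_dataset(
    image_dir: str | Path, layout: PlateLayout, n_fields: int | None = None
) -> PlateDataset:
    """Read a plate's per-channel TIFFs from disk into a dataset (no truth)."""
    from .synth import WellData  # local import to keep module surfaces clean

    wells = {}
    for wid, w in layout.wells.items():
        fields = read_fields(image_dir, wid, n_fields or layout.min_fields)
        wells[wid] = WellData(
            well=wid, condition=w.condition, role=w.role, dose=w.dose,
            replicate=w.replicate, fields=fields, truth=pd.DataFrame(),
        )
    return PlateDataset(wells=wells, seed=-1)


def write_result(result: PipelineResult, out_dir: str | Path) -> None:
    """Write per-cell CSV, per-well CSV, scatter table and QC JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.cells.to_csv(out / "cells.csv", index=False)
    result.wells.to_csv(out / "wells.csv", index=False)
    scatter_table(result.cells).to_csv(out / "scatter.csv", index=False)
    (out / "qc.json").write_text(json.dumps(result.qc_report(), indent=2, sort_keys=True))


def scatter_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-cell corrected G vs R with class labels, for scatter plots."""
    if cells.empty:
        return pd.DataFrame(columns=["well", "corr_g", "corr_r", "splice_class"])
    cols = ["well", "corr_g", "corr_r"]
    if "splice_class" in cells.columns:
        cols.append("splice_class")
    return cells[cols].copy()


def save_scatter(cells: pd.DataFrame, path: str | Path) -> None:
    """Optional scatter-plot image of corrected G vs R coloured by class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = scatter_table(cells)
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"E10plus_RFP": "tab:red", "E10minus_GFP": "tab:green", "dual": "tab:orange", "": "0.7"}
    for cls, grp in table.groupby(table.get("splice_class", "")):
        ax.scatter(grp["corr_r"], grp["corr_g"], s=4, alpha=0.5,
                   color=colors.get(cls, "0.5"), label=cls or "untransfected")
    ax.set_xlabel("corrected RFP (counts)")
    ax.set_ylabel("corrected GFP (counts)")
    ax.set_xscale("symlog")
    ax.set_yscale("symlog")
    ax.legend(markerscale=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
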