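"""Batch orchestration and standard-format I/O.

Ties the pipeline together: a session configuration (one global pixel->mm
calibration for all images, exactly like the "global" set-scale checkbox),
per-image processing (threshold -> label -> order -> measure -> summarize),
a batch driver that logs and skips failing images, and readers/writers for
the measurement CSV dialect used by the classic image-analysis workflow
(leading unnamed index column, ``Area``/``Perim.``/``Feret``/``MinFeret``
etc.), so externally produced measurement exports can feed the ISVAD
computation directly.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .isvad import ISVADSummary, isvad, summaries_to_frame, summarize_spike
from .morphometry import GrainMorphometrics, measure_spike
from .segment import (ScaleCalibration, SpikeLayout, label_particles,
                      order_grains, set_scale, threshold_binarize)

__all__ = [
    "SessionConfig",
    "RESULT_COLUMNS",
    "process_image",
    "batch_process",
    "results_frame",
    "write_results_csv",
    "read_results_csv",
    "results_to_summary",
]

log = logging.getLogger("spikegrain")

#: measurement-CSV column order (classic dialect; first column is unnamed)
RESULT_COLUMNS = [" ", "Label", "Area", "Perim.", "Circ.", "Feret",
                  "FeretAngle", "MinFeret", "Major", "Minor", "Angle",
                  "AR", "Round", "Solidity"]
PROVENANCE_COLUMNS = ["image", "spike_id", "row_index", "region"]
MANDATORY_COLUMNS = ["Area", "Perim.", "Feret", "MinFeret"]


@dataclass
class SessionConfig:
    """Configuration of one batch-processing session.

    The scale (pixel length of the reference line and its known length in
    mm) is global: every image of the session is calibrated identically.
    Defaults reproduce the standard protocol settings (per-image auto
    threshold, 2.5 mm^2 particle lower limit).
    """

    images: list[str] = field(default_factory=list)
    scale_px: float = 100.0
    scale_mm: float = 10.0
    global_scale: bool = True
    threshold_method: str = "otsu"
    min_area_mm2: float = 2.5
    rows_hint: int | None = None
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"
    full_precision: bool = False

    @property
    def calibration(self) -> ScaleCalibration:
        return set_scale(self.scale_px, self.scale_mm,
                         global_flag=self.global_scale)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def process_image(
    image: np.ndarray | str | Path,
    calibration: ScaleCalibration,
    threshold_method: str = "otsu",
    min_area_mm2: float = 2.5,
    rows_hint: int | None = None,
    spike_id: str = "spike",
) -> tuple[list[GrainMorphometrics], SpikeLayout, ISVADSummary]:
    """Full single-image pipeline: threshold, label, order, measure, ISVAD."""
    if not isinstance(image, np.ndarray):
        image = iio.imread(image)
        if image.dtype == np.uint8:
            image = image.astype(float) / 255.0
    mask = threshold_binarize(image, method=threshold_method)
    labeled = label_particles(mask, calibration, min_area_mm2=min_area_mm2)
    if labeled.n_grains == 0:
        raise ValueError("no grains above the area limit")
    layout = order_grains(labeled, rows_hint=rows_hint)
    morphs = measure_spike(labeled, layout, calibration)
    summary = summarize_spike(morphs, layout, spike_id=spike_id)
    return morphs, layout, summary


def results_frame(morphs: list[GrainMorphometrics], layout: SpikeLayout,
                  image: str = "", spike_id: str = "spike") -> pd.DataFrame:
    """Measurement table in the classic CSV dialect plus provenance columns."""
    rows = []
    for m, row_idx, region in zip(morphs, layout.row_index, layout.region):
        rows.append({
            " ": m.grain_id,
            "Label": f"{spike_id}:{m.grain_id}",
            "Area": m.area_mm2,
            "Perim.": m.perimeter_mm,
            "Circ.": m.circularity,
            "Feret": m.feret_mm,
            "FeretAngle": m.feret_angle_deg,
            "MinFeret": m.minferet_mm,
            "Major": m.major_mm,
            "Minor": m.minor_mm,
            "Angle": m.ellipse_angle_deg,
            "AR": m.aspect_ratio,
            "Round": m.roundness,
            "Solidity": m.solidity,
            "image": image,
            "spike_id": spike_id,
            "row_index": row_idx,
            "region": region if layout.regions_defined else "",
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS + PROVENANCE_COLUMNS)


def write_results_csv(frame: pd.DataFrame, path,
                      full_precision: bool = False) -> None:
    """Write a measurement CSV; mm quantities fixed at 3 decimals unless
    ``full_precision`` (fixed formatting makes re-runs byte-identical)."""
    frame = frame.copy()
    if not full_precision:
        num = frame.select_dtypes(include=[float]).columns
        frame[num] = frame[num].map(lambda v: f"{v:.3f}")
    frame.to_csv(path, index=False)


def read_results_csv(path) -> pd.DataFrame:
    """Read a measurement CSV (tolerant to the classic export dialect).

    Accepts a leading unnamed index column and missing optional columns;
    requires Area, Perim., Feret and MinFeret (named in the error if
    absent).  Units are assumed mm / mm^2, i.e. a calibrated session.
    A header-only file yields an empty frame with a warning.
    """
    frame = pd.read_csv(path)
    frame.columns = [("" if c.startswith("Unnamed") else c).strip() or " "
                     for c in frame.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {', '.join(missing)}")
    if frame.empty:
        log.warning("%s contains a header but no grain rows", path)
    return frame


def results_to_summary(frame: pd.DataFrame,
                       spike_id: str = "spike") -> ISVADSummary:
    """ISVAD summary from a measurement table (e.g. an external export).

    Region-level statistics are computed when the table carries
    ``row_index``/``region`` provenance columns spanning >= 3 rows;
    otherwise they are reported missing.
    """
    if frame.empty:
        raise ValueError("no grains in results table")
    trait_cols = {"width": "MinFeret", "length": "Feret",
                  "area": "Area", "perimeter": "Perim."}
    values = {t: frame[c].to_numpy(dtype=float)
              for t, c in trait_cols.items()}
    mean = {t: float(v.mean()) for t, v in values.items()}
    sigma = {t: isvad(v) for t, v in values.items()}
    lw = float(np.mean(values["length"] / values["width"]))

    region_n = region_mean = region_isvad = None
    n_rows = 0
    if "row_index" in frame.columns and frame["row_index"].notna().all():
        n_rows = int(frame["row_index"].nunique())
    if (n_rows >= 3 and "region" in frame.columns
            and frame["region"].astype(str).str.len().gt(0).all()):
        region_n, region_mean, region_isvad = {}, {}, {}
        reg = frame["region"].astype(str).to_numpy()
        for r in ("bottom", "middle", "top"):
            sel = reg == r
            region_n[r] = int(sel.sum())
            if region_n[r]:
                region_mean[r] = {t: float(v[sel].mean())
                                  for t, v in values.items()}
                region_isvad[r] = {t: isvad(v[sel]) for t, v in values.items()}
            else:
                region_mean[r] = {t: float("nan") for t in values}
                region_isvad[r] = {t: float("nan") for t in values}
    return ISVADSummary(spike_id=spike_id, n_grains=len(frame), mean=mean,
                        isvad=sigma, mean_length_width_ratio=lw,
                        region_n=region_n, region_mean=region_mean,
                        region_isvad=region_isvad, n_rows=n_rows)


@dataclass
class BatchResult:
    """Outcome of a batch run; ``failures`` maps image -> error message."""

    results_paths: list[Path]
    summary_path: Path
    summaries: list[ISVADSummary]
    failures: dict[str, str]

    @property
    def ok(self) -> bool:
        return not self.failures


def batch_process(config: SessionConfig) -> BatchResult:
    """Process every image of a session with the same global calibration.

    Per image, a measurement CSV is written to the output directory; one
    combined ISVAD summary CSV covers the whole session.  Failing images
    are logged and skipped, never fatal; inspect ``BatchResult.failures``
    (the CLI maps them to a non-zero exit status).
    """
    logging.basicConfig(level=config.log_level)
    if not config.images:
        raise ValueError("no images to process")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("session config: %s", asdict(config))
    calibration = config.calibration

    results_paths: list[Path] = []
    summaries: list[ISVADSummary] = []
    failures: dict[str, str] = {}
    for img in config.images:
        spike_id = Path(img).stem
        try:
            morphs, layout, summary = process_image(
                img, calibration, threshold_method=config.threshold_method,
                min_area_mm2=config.min_area_mm2,
                rows_hint=config.rows_hint, spike_id=spike_id)
        except Exception as exc:  # noqa: BLE001 - per-image fault barrier
            log.error("skipping %s: %s", img, exc)
            failures[str(img)] = str(exc)
            continue
        frame = results_frame(morphs, layout, image=str(img),
                              spike_id=spike_id)
        path = out_dir / f"{spike_id}_results.csv"
        write_results_csv(frame, path, full_precision=config.full_precision)
        results_paths.append(path)
        summaries.append(summary)

    summary_path = out_dir / "isvad_summary.csv"
    if summaries:
        sframe = summaries_to_frame(summaries)
        write_results_csv(sframe, summary_path,
                          full_precision=config.full_precision)
    else:
        summary_path.write_text("")
    return BatchResult(results_paths, summary_path, summaries, failures)
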