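"""File I/O, annotated images, CSV export, experiment store and batch runs.

The experiment store replaces a relational database with a diff-able
on-disk layout, one directory per experiment::

    experiment.json           # id, plate records (file, flies, group, params)
    audit.csv                 # one row per processed image (timestamp, file, params)
    summaries.csv             # one row per plate (full variable set)
    deposits_<plate_id>.csv   # per-plate deposit table, editable include column

Manual curation happens by editing the ``include`` column of a deposit
CSV (the headless equivalent of unticking a checkbox) and re-running
:func:`resummarize`.  All CSVs are comma-separated, decimal-point,
UTF-8, header row, missing values as empty fields.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw, UnidentifiedImageError

from .detect import DetectionParams, RgbImage, detect_spots
from .features import DEFAULT_ROD_CUTOFF, Deposit, build_deposit
from .plate import PlateSummary, summarize_plate

logger = logging.getLogger(__name__)

__all__ = [
    "read_plate_image",
    "write_annotated_image",
    "export_csv",
    "deposits_to_frame",
    "frame_to_deposits",
    "analyze_image",
    "PlateJob",
    "PlateRecord",
    "ExperimentStore",
    "batch_process",
    "resummarize",
]

DEPOSIT_COLUMNS = [
    "plate_id", "deposit_id", "x", "y", "area", "perimeter", "circularity",
    "rod", "iod", "mean_r", "mean_g", "mean_b", "mean_h", "mean_s", "mean_l",
    "include",
]

ROD_LABEL_COLOUR = (40, 60, 255)       # blue, as on annotated plate figures
NON_ROD_LABEL_COLOUR = (230, 70, 20)   # contrasting orange-red
EXCLUDED_LABEL_COLOUR = (128, 128, 128)


def read_plate_image(path: str | Path, default_dpi: float = 1200.0) -> RgbImage:
    """Load a PNG/TIFF/JPEG plate scan as an RgbImage in [0, 1].

    8-bit channels are divided by 255 and 16-bit by 65535; greyscale
    files are promoted to RGB.  The dpi tag is read from the file's
    metadata when present, otherwise ``default_dpi`` is assumed with a
    warning.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            dpi_info = im.info.get("dpi")
            if im.mode in ("I;16", "I;16B", "I;16L", "I"):
                arr = np.asarray(im, dtype=np.float64) / 65535.0
            else:
                arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    except FileNotFoundError as exc:
        raise IOError(f"cannot read plate image {path}: file not found") from exc
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read plate image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if dpi_info:
        dpi = float(dpi_info[0] if isinstance(dpi_info, (tuple, list)) else dpi_info)
        # PNG stores resolution in pixels per metre; undo the rounding noise
        dpi = float(round(dpi))
    else:
        logger.warning("%s carries no dpi metadata; assuming %.0f dpi", path, default_dpi)
        dpi = default_dpi
    return RgbImage(np.clip(arr, 0.0, 1.0), dpi=dpi)


def _border_pixels(pixel_set: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pixels of the set with a 4-neighbour outside it (outline for drawing)."""
    pix = {(int(x), int(y)) for x, y in pixel_set}
    border = [
        (x, y)
        for x, y in pix
        if any((x + dx, y + dy) not in pix for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)))
    ]
    return np.asarray(border, dtype=int).reshape(-1, 2)


def write_annotated_image(
    image: RgbImage, deposits: Sequence[Deposit], path: str | Path
) -> None:
    """Render the plate with each deposit outlined and labelled.

    Labels carry the deposit id; ROD labels are blue, non-ROD labels a
    contrasting colour, and excluded deposits are drawn grey with the
    label struck through.  The output has the input's dimensions.
    """
    path = Path(path)
    arr = (image.pixels * 255).round().astype(np.uint8)
    for dep in deposits:
        if dep.pixel_set is None:
            continue
        colour = _label_colour(dep)
        border = _border_pixels(dep.pixel_set, (image.height, image.width))
        if len(border):
            arr[border[:, 1], border[:, 0]] = colour
    im = Image.fromarray(arr, mode="RGB")
    draw = ImageDraw.Draw(im)
    for dep in deposits:
        colour = _label_colour(dep)
        text = str(dep.deposit_id)
        xy = (dep.x + 3, dep.y + 3)
        draw.text(xy, text, fill=colour)
        if not dep.include:
            x0, y0, x1, y1 = draw.textbbox(xy, text)
            draw.line([(x0, (y0 + y1) / 2), (x1, (y0 + y1) / 2)], fill=colour)
    try:
        im.save(path)
    except OSError as exc:
        raise IOError(f"cannot write annotated image {path}: {exc}") from exc


def _label_colour(dep: Deposit) -> tuple[int, int, int]:
    if not dep.include:
        return EXCLUDED_LABEL_COLOUR
    return ROD_LABEL_COLOUR if dep.is_rod else NON_ROD_LABEL_COLOUR


def deposits_to_frame(deposits: Iterable[Deposit]) -> pd.DataFrame:
    """Deposit table with the full, stable column set (pixel data omitted)."""
    rows = []
    for d in deposits:
        rows.append(
            {
                "plate_id": d.plate_id, "deposit_id": d.deposit_id,
                "x": d.x, "y": d.y, "area": d.area, "perimeter": d.perimeter,
                "circularity": d.circularity, "rod": int(d.is_rod), "iod": d.iod,
                "mean_r": d.mean_r, "mean_g": d.mean_g, "mean_b": d.mean_b,
                "mean_h": d.mean_h, "mean_s": d.mean_s, "mean_l": d.mean_l,
                "include": int(d.include),
            }
        )
    return pd.DataFrame(rows, columns=DEPOSIT_COLUMNS)


def frame_to_deposits(frame: pd.DataFrame) -> list[Deposit]:
    """Rebuild Deposit objects from an exported (possibly edited) table."""
    deposits = []
    for row in frame.itertuples(index=False):
        deposits.append(
            Deposit(
                plate_id=str(row.plate_id), deposit_id=int(row.deposit_id),
                x=float(row.x), y=float(row.y), area=int(row.area),
                perimeter=float(row.perimeter), circularity=float(row.circularity),
                is_rod=bool(row.rod), iod=float(row.iod),
                mean_r=float(row.mean_r), mean_g=float(row.mean_g),
                mean_b=float(row.mean_b), mean_h=int(row.mean_h),
                mean_s=float(row.mean_s), mean_l=float(row.mean_l),
                include=bool(row.include), pixel_set=None,
            )
        )
    return deposits


def export_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as comma-separated UTF-8 with a header row.

    Missing values become empty fields; the dialect is fixed (comma
    separator, decimal point) for cross-tool portability.
    """
    if table is None:
        raise ValueError("table must not be None")
    path = Path(path)
    try:
        table.to_csv(path, index=False, encoding="utf-8", na_rep="")
    except OSError as exc:
        raise IOError(f"cannot write CSV {path}: {exc}") from exc


def analyze_image(
    image: RgbImage,
    plate_id: str,
    params: DetectionParams | None = None,
    rod_cutoff: float = DEFAULT_ROD_CUTOFF,
) -> list[Deposit]:
    """Detect deposits and compute their variables; ids follow detection order."""
    components = detect_spots(image, params)
    return [
        build_deposit(c, image, plate_id, deposit_id=i, rod_cutoff=rod_cutoff)
        for i, c in enumerate(components, start=1)
    ]


@dataclass
class PlateJob:
    """One batch entry: an image to process with its experimental context."""

    image_path: str | Path
    n_flies: int
    group: str = ""
    params: DetectionParams | None = None
    plate_id: str | None = None

    def resolved_plate_id(self) -> str:
        return self.plate_id if self.plate_id is not None else Path(self.image_path).stem


@dataclass
class PlateRecord:
    plate_id: str
    image_filename: str
    n_flies: int
    group: str
    params: DetectionParams
    summary: PlateSummary | None  # None when processing failed


@dataclass
class ExperimentStore:
    """In-memory experiment: plate records, deposit tables and the audit trail."""

    experiment_id: str = "experiment"
    plates: dict[str, PlateRecord] = field(default_factory=dict)
    deposits: dict[str, list[Deposit]] = field(default_factory=dict)
    audit: list[dict[str, object]] = field(default_factory=list)

    @property
    def failures(self) -> list[str]:
        return [pid for pid, rec in self.plates.items() if rec.summary is None]

    def summaries(self) -> list[PlateSummary]:
        return [rec.summary for rec in self.plates.values() if rec.summary is not None]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pid, rec in self.plates.items():
            if rec.summary is not None and rec.group:
                out.setdefault(rec.group, []).append(pid)
        return out

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "experiment_id": self.experiment_id,
            "plates": [
                {
                    "plate_id": rec.plate_id,
                    "image_filename": rec.image_filename,
                    "n_flies": rec.n_flies,
                    "group": rec.group,
                    "params": asdict(rec.params),
                    "failed": rec.summary is None,
                }
                for rec in self.plates.values()
            ],
        }
        (directory / "experiment.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        export_csv(pd.DataFrame(self.audit), directory / "audit.csv")
        from .stats import summaries_to_frame

        export_csv(summaries_to_frame(self.summaries()), directory / "summaries.csv")
        for pid in sorted(self.deposits):
            export_csv(deposits_to_frame(self.deposits[pid]), directory / f"deposits_{pid}.csv")

    def content_hash(self) -> str:
        """SHA-256 over the sorted CSV content of deposits and summaries.

        Timestamps are excluded; with a fixed clock the saved files are
        byte-identical as well.
        """
        from .stats import summaries_to_frame

        h = hashlib.sha256()
        frame = summaries_to_frame(self.summaries())
        if not frame.empty:
            frame = frame.sort_values("plate_id").drop(columns=["timestamp"])
        h.update(frame.to_csv(index=False).encode())
        for pid in sorted(self.deposits):
            h.update(deposits_to_frame(self.deposits[pid]).to_csv(index=False).encode())
        return h.hexdigest()


def _utc_now() -> str:
    return datetime.now(timezone.utc).isoformat()


def batch_process(
    jobs: Sequence[PlateJob],
    experiment_id: str = "experiment",
    rod_cutoff: float = DEFAULT_ROD_CUTOFF,
    clock: Callable[[], str] | None = None,
) -> ExperimentStore:
    """Process a batch of plate images into an experiment store.

    Each image runs the full pipeline (detection → deposit variables →
    plate summary); one audit entry is written per image attempted, and
    a failing image is recorded as failed without aborting the batch.
    Results are keyed by plate id, so they are independent of the order
    of the job list.
    """
    if not jobs:
        raise ValueError("batch configuration must list at least one image")
    paths = [str(job.image_path) for job in jobs]
    if len(set(paths)) != len(paths):
        raise ValueError("batch image paths must be distinct")
    clock = clock or _utc_now
    store = ExperimentStore(experiment_id=experiment_id)
    for job in sorted(jobs, key=lambda j: j.resolved_plate_id()):
        pid = job.resolved_plate_id()
        params = job.params or DetectionParams()
        entry: dict[str, object] = {
            "timestamp": clock(),
            "image_filename": str(job.image_path),
            "plate_id": pid,
            "params": json.dumps(asdict(params), sort_keys=True),
        }
        try:
            image = read_plate_image(job.image_path)
            deposits = analyze_image(image, pid, params, rod_cutoff)
            summary = summarize_plate(
                deposits,
                job.n_flies,
                plate_id=pid,
                image_filename=str(job.image_path),
                timestamp=str(entry["timestamp"]),
                protocol_params=asdict(params),
            )
            entry["status"] = "ok"
            store.deposits[pid] = deposits
        except Exception as exc:  # recorded, not raised: the batch continues
            logger.error("plate %s failed: %s", pid, exc)
            entry["status"] = f"failed: {exc}"
            summary = None
        store.plates[pid] = PlateRecord(
            plate_id=pid,
            image_filename=str(job.image_path),
            n_flies=job.n_flies,
            group=job.group,
            params=params,
            summary=summary,
        )
        store.audit.append(entry)
    return store


def resummarize(
    directory: str | Path, clock: Callable[[], str] | None = None
) -> ExperimentStore:
    """Reload a saved experiment and rebuild summaries from the deposit CSVs.

    This honours any edits to the ``include`` column — the headless
    replacement for the interactive artefact-curation checkboxes.  The
    refreshed store is saved back in place and returned.
    """
    directory = Path(directory)
    clock = clock or _utc_now
    meta = json.loads((directory / "experiment.json").read_text())
    store = ExperimentStore(experiment_id=meta["experiment_id"])
    audit_path = directory / "audit.csv"
    if audit_path.exists():
        store.audit = pd.read_csv(audit_path).to_dict("records")
    for rec in meta["plates"]:
        pid = rec["plate_id"]
        params_dict = dict(rec["params"])
        params_dict["greyscale_weights"] = tuple(params_dict["greyscale_weights"])
        params = DetectionParams(**params_dict)
        dep_path = directory / f"deposits_{pid}.csv"
        if rec.get("failed") or not dep_path.exists():
            summary = None
            deposits: list[Deposit] = []
        else:
            deposits = frame_to_deposits(pd.read_csv(dep_path))
            summary = summarize_plate(
                deposits,
                rec["n_flies"],
                plate_id=pid,
                image_filename=rec["image_filename"],
                timestamp=clock(),
                protocol_params=dict(rec["params"]),
            )
            store.deposits[pid] = deposits
        store.plates[pid] = PlateRecord(
            plate_id=pid,
            image_filename=rec["image_filename"],
            n_flies=rec["n_flies"],
            group=rec["group"],
            params=params,
            summary=summary,
        )
    store.save(directory)
    return store
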