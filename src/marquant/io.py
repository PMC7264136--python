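"""Reading, validating and writing image stacks and analysis reports.

Axial stacks arrive either as a directory of lossless bitmap-family files
(BMP/PNG/TIFF, one file per slice, natural-sorted by filename so that
``slice2`` precedes ``slice10``) or as a DICOM series (sorted by instance
number, mapped through rescale slope/intercept, then min-max scaled to the
8-bit range per stack so inter-slice contrast is preserved).  Results go
out as spreadsheet-compatible CSV or a JSON mirror, and edge maps as 1-bit
PNG for visual inspection.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .canny import EdgeMap
from .metrics import EdgeCountSeries, ReductionReport
from .types import (
    EmptyStackError,
    ImageStack,
    InconsistentStackError,
    StackLabel,
    StackPair,
)

__all__ = [
    "FormatError",
    "read_stack",
    "write_stack",
    "trim_blank_slices",
    "pair_stacks",
    "write_report",
    "read_report",
    "write_edge_map",
]

_BITMAP_EXTS = {".png", ".bmp", ".tif", ".tiff"}
_LUMA = np.array([0.299, 0.587, 0.114])  # ITU-R BT.601


class FormatError(ValueError):
    """A slice file could not be decoded."""


def _natural_key(name: str) -> tuple:
    return tuple(
        int(tok) if tok.isdigit() else tok.lower()
        for tok in re.split(r"(\d+)", name)
    )


def _to_gray_8bit(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr @ _LUMA
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise FormatError(f"unsupported channel count in {path}")
    elif arr.ndim != 2:
        raise FormatError(f"not a 2-D image: {path}")
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        scaled = arr.astype(np.float64) * (255.0 / info.max)
    else:
        scaled = np.asarray(arr, dtype=np.float64)
        if scaled.size and scaled.max() > 255:
            scaled = scaled * (255.0 / scaled.max())
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def _read_bitmap_dir(path: Path, label: StackLabel) -> ImageStack:
    import imageio.v3 as iio

    files = sorted(
        (f for f in path.iterdir() if f.suffix.lower() in _BITMAP_EXTS),
        key=lambda f: _natural_key(f.name),
    )
    if not files:
        raise EmptyStackError(f"no bitmap-family slice files in {path}")
    slices = []
    for f in files:
        try:
            arr = np.asarray(iio.imread(f))
        except Exception as exc:  # noqa: BLE001 - rewrap with the file name
            raise FormatError(f"unreadable slice file {f}: {exc}") from exc
        slices.append(_to_gray_8bit(arr, f))
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise InconsistentStackError(f"mixed slice dimensions in {path}: {sorted(shapes)}")
    return ImageStack.from_array(slices, label=label)


def _read_dicom_series(path: Path, label: StackLabel) -> ImageStack:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue  # skip non-DICOM clutter (e.g. DICOMDIR fragments)
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise EmptyStackError(f"no readable DICOM slices in {path}")
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    vols = []
    spacing: Optional[float] = None
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        vols.append(arr * slope + intercept)
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            spacing = float(ps[0])
    shapes = {v.shape for v in vols}
    if len(shapes) > 1:
        raise InconsistentStackError(f"mixed slice dimensions in {path}: {sorted(shapes)}")
    vol = np.stack(vols)
    lo, hi = vol.min(), vol.max()
    if hi > lo:  # min-max per stack, not per slice
        vol = (vol - lo) * (255.0 / (hi - lo))
    else:
        vol = np.zeros_like(vol)
    vol = np.clip(np.rint(vol), 0, 255).astype(np.uint8)
    return ImageStack.from_array(vol, label=label, pixel_spacing=spacing)


def read_stack(
    path: str | Path,
    format_hint: str = "auto",
    label: Optional[StackLabel] = None,
) -> ImageStack:
    """Read one acquisition from a slice directory or DICOM series.

    ``format_hint`` is ``bitmap``, ``dicom`` or ``auto`` (sniff: bitmap
    extensions win, otherwise try DICOM).  ``label`` defaults to a
    synthetic MAR-off descriptor; pass the real acquisition label when
    known.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"stack path does not exist: {p}")
    if not p.is_dir():
        raise FormatError(f"stack path must be a directory of slices: {p}")
    lbl = label or StackLabel(mar_state="off")
    if format_hint == "bitmap":
        return _read_bitmap_dir(p, lbl)
    if format_hint == "dicom":
        return _read_dicom_series(p, lbl)
    if format_hint != "auto":
        raise ValueError(f"unknown format_hint {format_hint!r}")
    if any(f.suffix.lower() in _BITMAP_EXTS for f in p.iterdir()):
        return _read_bitmap_dir(p, lbl)
    return _read_dicom_series(p, lbl)


def write_stack(stack: ImageStack, out_dir: str | Path) -> None:
    """Write slices as ``slice_000.png`` ... (lossless, natural-sort safe)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in stack:
        iio.imwrite(out / f"slice_{s.index:03d}.png", s.pixels)


def trim_blank_slices(
    stack: ImageStack, blank_threshold: float = 10.0, min_fraction: float = 0.005
) -> ImageStack:
    """Drop leading/trailing blank slices (those without the object).

    A slice is blank when fewer than ``min_fraction`` of its pixels exceed
    ``blank_threshold``.  Interior blanks are never removed; the operation
    is idempotent and re-bases slice indices to 0.
    """
    if not 0 <= blank_threshold <= 255:
        raise ValueError("blank_threshold must be in [0, 255]")
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    blank = [
        (s.pixels > blank_threshold).mean() < min_fraction for s in stack
    ]
    first = 0
    while first < len(blank) and blank[first]:
        first += 1
    if first == len(blank):
        raise EmptyStackError("all slices are blank after trimming")
    last = len(blank) - 1
    while blank[last]:
        last -= 1
    if first == 0 and last == len(blank) - 1:
        return stack
    return ImageStack(slices=stack.slices[first : last + 1], label=stack.label)


def pair_stacks(off: ImageStack, on: ImageStack) -> StackPair:
    """Pair trimmed MAR_off / MAR_on stacks slice-by-slice (validates invariants)."""
    return StackPair(off_stack=off, on_stack=on)


def _label_to_dict(label: StackLabel) -> dict:
    return {
        "mar_state": label.mar_state,
        "prosthesis": label.prosthesis,
        "voxel_mm": label.voxel_mm,
        "kvp": label.kvp,
    }


def _label_from_dict(d: dict) -> StackLabel:
    return StackLabel(
        mar_state=d["mar_state"],
        prosthesis=d.get("prosthesis", "synthetic"),
        voxel_mm=d.get("voxel_mm"),
        kvp=d.get("kvp"),
    )


def report_to_dict(report: ReductionReport) -> dict:
    return {
        "off_label": _label_to_dict(report.off_counts.stack_label),
        "on_label": _label_to_dict(report.on_counts.stack_label),
        "off_counts": list(report.off_counts.counts),
        "on_counts": list(report.on_counts.counts),
        "per_slice_diff": list(report.per_slice_diff),
        "total_off": report.total_off,
        "total_on": report.total_on,
        "reduction_ratio_pct": report.reduction_ratio_pct,
        "mean_diff": report.mean_diff,
        "sd_diff": report.sd_diff,
    }


def report_from_dict(d: dict) -> ReductionReport:
    return ReductionReport(
        off_counts=EdgeCountSeries(
            counts=tuple(d["off_counts"]), stack_label=_label_from_dict(d["off_label"])
        ),
        on_counts=EdgeCountSeries(
            counts=tuple(d["on_counts"]), stack_label=_label_from_dict(d["on_label"])
        ),
        per_slice_diff=tuple(d["per_slice_diff"]),
        total_off=int(d["total_off"]),
        total_on=int(d["total_on"]),
        reduction_ratio_pct=float(d["reduction_ratio_pct"]),
        mean_diff=float(d["mean_diff"]),
        sd_diff=float(d["sd_diff"]),
    )


def write_report(report: ReductionReport, path: str | Path, format: str = "csv") -> None:
    """Serialize a ReductionReport; the round trip is lossless.

    CSV layout: metadata comment lines (``# key = value`` with full float
    precision), a header, one row per slice and a ``total`` summary row.
    JSON is a direct mirror of the report fields.
    """
    p = Path(path)
    if format == "json":
        p.write_text(json.dumps(report_to_dict(report), indent=2) + "\n")
        return
    if format != "csv":
        raise ValueError(f"unknown report format {format!r}")
    meta = {
        "reduction_ratio_pct": report.reduction_ratio_pct,
        "mean_diff": report.mean_diff,
        "sd_diff": report.sd_diff,
        "off_label": json.dumps(_label_to_dict(report.off_counts.stack_label)),
        "on_label": json.dumps(_label_to_dict(report.on_counts.stack_label)),
    }
    lines = [f"# {k} = {v!r}" if isinstance(v, float) else f"# {k} = {v}" for k, v in meta.items()]
    lines.append("slice,off_count,on_count,diff")
    for i, (a, b, d) in enumerate(
        zip(report.off_counts.counts, report.on_counts.counts, report.per_slice_diff)
    ):
        lines.append(f"{i},{a},{b},{d}")
    lines.append(f"total,{report.total_off},{report.total_on},{sum(report.per_slice_diff)}")
    p.write_text("\n".join(lines) + "\n")


def read_report(path: str | Path, format: str = "auto") -> ReductionReport:
    """Read a report written by :func:`write_report` (format sniffed by suffix)."""
    p = Path(path)
    if format == "auto":
        format = "json" if p.suffix.lower() == ".json" else "csv"
    if format == "json":
        return report_from_dict(json.loads(p.read_text()))
    meta: dict[str, str] = {}
    off_counts: list[int] = []
    on_counts: list[int] = []
    diffs: list[int] = []
    for line in p.read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
        elif line and not line.startswith("slice"):
            first, a, b, d = line.split(",")
            if first == "total":
                continue
            off_counts.append(int(a))
            on_counts.append(int(b))
            diffs.append(int(d))
    return ReductionReport(
        off_counts=EdgeCountSeries(
            counts=tuple(off_counts),
            stack_label=_label_from_dict(json.loads(meta["off_label"])),
        ),
        on_counts=EdgeCountSeries(
            counts=tuple(on_counts),
            stack_label=_label_from_dict(json.loads(meta["on_label"])),
        ),
        per_slice_diff=tuple(diffs),
        total_off=sum(off_counts),
        total_on=sum(on_counts),
        reduction_ratio_pct=float(meta["reduction_ratio_pct"]),
        mean_diff=float(meta["mean_diff"]),
        sd_diff=float(meta["sd_diff"]),
    )


def write_edge_map(edge_map: EdgeMap, path: str | Path) -> None:
    """Write a binary edge image as 1-bit PNG."""
    from PIL import Image

    img = Image.fromarray(edge_map.pixels.astype(np.uint8) * 255).convert("1")
    img.save(Path(path), format="PNG")
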