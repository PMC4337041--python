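"""Reading cine stacks and writing segmentation outputs.

Two input routes are supported: a DICOM series directory (slices sorted by
spatial position along the slice normal, phases by trigger time, rescale
slope/intercept applied) and a 4D NIfTI volume stored ``(row, col, slice,
phase)`` with a JSON sidecar declaring the voxel geometry.

Outputs are one NIfTI mask volume per phase (values 0/1), a tab-separated
metrics table (one row per phase plus EDV/ESV/EF footer lines) and a PNG of
the volume filling curve.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np

import nibabel as nib

from .continuity import SegResult
from .geometry import CineStack, VoxelGeometry
from .quantify import LVMetrics

__all__ = [
    "load_cine",
    "write_outputs",
    "write_phantom",
    "read_metrics",
    "MetadataError",
]

_SIDECAR_FIELDS = ("pixel_spacing_row", "pixel_spacing_col", "slice_spacing")


class MetadataError(RuntimeError):
    """Required geometry or ordering metadata is missing or inconsistent."""


# --------------------------------------------------------------------------
# loading


def load_cine(path, format_hint: str = "auto") -> CineStack:
    """Load a 4D cine stack from a NIfTI file or a DICOM series directory.

    Slices are returned sorted base→apex by spatial position and phases by
    trigger time.  ``format_hint`` may be ``"auto"``, ``"dicom"`` or
    ``"nifti"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint == "auto":
        format_hint = "dicom" if path.is_dir() else "nifti"
    if format_hint == "nifti":
        return _load_nifti(path)
    if format_hint == "dicom":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format hint {format_hint!r}")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _load_nifti(path: Path) -> CineStack:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        raise MetadataError("cine requires a phase dimension (input is 3D)")
    if data.ndim != 4:
        raise MetadataError(f"cine input must be 4D, got ndim={data.ndim}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(
            f"missing geometry sidecar {sidecar.name} "
            f"(fields: {', '.join(_SIDECAR_FIELDS)})"
        )
    meta = json.loads(sidecar.read_text())
    for fieldname in _SIDECAR_FIELDS:
        if fieldname not in meta:
            raise MetadataError(f"sidecar missing required field '{fieldname}'")
    geom = VoxelGeometry(
        pixel_spacing_row=float(meta["pixel_spacing_row"]),
        pixel_spacing_col=float(meta["pixel_spacing_col"]),
        slice_spacing=float(meta["slice_spacing"]),
    )
    # stored (row, col, slice, phase) -> (slice, phase, row, col)
    return CineStack(intensities=data.transpose(2, 3, 0, 1), geometry=geom)


def _load_dicom_series(path: Path) -> CineStack:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue  # non-DICOM files in the directory are ignored
    if not datasets:
        raise MetadataError(f"no readable DICOM files in {path}")

    first = datasets[0]
    if "PixelSpacing" not in first:
        raise MetadataError("DICOM series missing required field 'PixelSpacing'")
    if "ImageOrientationPatient" not in first:
        raise MetadataError(
            "DICOM series missing required field 'ImageOrientationPatient'"
        )
    orient = np.array(first.ImageOrientationPatient, dtype=float)
    normal = np.cross(orient[:3], orient[3:])

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise MetadataError(f"mixed in-plane matrix sizes in series: {shapes}")

    by_position: dict[float, list] = {}
    for ds in datasets:
        if "ImagePositionPatient" not in ds:
            raise MetadataError(
                "DICOM series missing required field 'ImagePositionPatient'"
            )
        proj = round(float(np.dot(np.array(ds.ImagePositionPatient, float), normal)), 3)
        by_position.setdefault(proj, []).append(ds)

    positions = sorted(by_position)
    n_phases = {len(v) for v in by_position.values()}
    if len(n_phases) > 1:
        raise MetadataError(
            f"inconsistent phase counts across slice positions: {n_phases}"
        )

    def phase_key(ds):
        if "TriggerTime" in ds:
            return float(ds.TriggerTime)
        if "InstanceNumber" in ds:
            return int(ds.InstanceNumber)
        raise MetadataError(
            "DICOM series missing required field 'TriggerTime' (or 'InstanceNumber')"
        )

    frames = []
    for pos in positions:
        stack_at = sorted(by_position[pos], key=phase_key)
        plane = []
        for ds in stack_at:
            arr = ds.pixel_array.astype(float)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            plane.append(arr * slope + intercept)
        frames.append(plane)
    data = np.array(frames)  # (slice, phase, row, col)

    spacing = [float(v) for v in first.PixelSpacing]  # (row, col)
    if len(positions) > 1:
        slice_spacing = float(np.median(np.diff(positions)))
    elif "SpacingBetweenSlices" in first:
        slice_spacing = float(first.SpacingBetweenSlices)
    else:
        raise MetadataError(
            "DICOM series missing required field 'SpacingBetweenSlices'"
        )
    geom = VoxelGeometry(spacing[0], spacing[1], abs(slice_spacing))
    return CineStack(intensities=data, geometry=geom)


# --------------------------------------------------------------------------
# writing


def _affine(geometry: VoxelGeometry) -> np.ndarray:
    return np.diag(
        [
            geometry.pixel_spacing_row,
            geometry.pixel_spacing_col,
            geometry.slice_spacing,
            1.0,
        ]
    )


def write_outputs(seg: SegResult, metrics: LVMetrics, out_dir) -> list[Path]:
    """Write per-phase mask volumes, the metrics table and the filling curve.

    Returns the list of written paths.  Masks go to ``mask_phase{p:02d}.nii.gz``
    (stored ``(row, col, slice)``, values 0/1), metrics to ``metrics.tsv``
    and the filling curve to ``filling_curve.png``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    if seg.n_phases != metrics.n_phases:
        raise ValueError(
            f"seg has {seg.n_phases} phases but metrics has {metrics.n_phases}"
        )

    geometry = seg.geometry or VoxelGeometry(1.0, 1.0, 1.0)
    affine = _affine(geometry)
    written: list[Path] = []
    for p in range(seg.n_phases):
        vol = seg.masks[:, p].transpose(1, 2, 0).astype(np.uint8)
        path = out_dir / f"mask_phase{p:02d}.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), str(path))
        written.append(path)

    table = out_dir / "metrics.tsv"
    with table.open("w") as fh:
        fh.write("phase\tvolume_ml\tapical_slice\tbasal_slice\n")
        for p in range(metrics.n_phases):
            fh.write(
                f"{p}\t{metrics.volume_ml[p]:.9g}\t"
                f"{int(metrics.apical_slice[p])}\t{int(metrics.basal_slice[p])}\n"
            )
        status = "ok" if metrics.edv_ml > 0 else "segmentation failed"
        fh.write(f"# EDV_mL\t{metrics.edv_ml:.9g}\n")
        fh.write(f"# ESV_mL\t{metrics.esv_ml:.9g}\n")
        fh.write(f"# EF_pct\t{metrics.ef_pct:.9g}\n")
        fh.write(f"# ed_phase\t{metrics.ed_phase}\n")
        fh.write(f"# es_phase\t{metrics.es_phase}\n")
        fh.write(f"# status\t{status}\n")
    written.append(table)

    written.append(_plot_filling_curve(metrics, out_dir / "filling_curve.png"))
    return written


def _plot_filling_curve(metrics: LVMetrics, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    phases = np.arange(metrics.n_phases)
    ax.plot(phases, metrics.volume_ml, "o-", color="tab:red")
    ax.axvline(metrics.ed_phase, ls=":", color="grey", label=f"ED (phase {metrics.ed_phase})")
    ax.axvline(metrics.es_phase, ls="--", color="grey", label=f"ES (phase {metrics.es_phase})")
    ax.set_xlabel("cardiac phase")
    ax.set_ylabel("LV volume (mL)")
    ax.set_title(
        f"EDV {metrics.edv_ml:.1f} mL   ESV {metrics.esv_ml:.1f} mL   "
        f"EF {metrics.ef_pct:.1f}%"
    )
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def read_metrics(path) -> LVMetrics:
    """Re-parse a ``metrics.tsv`` written by :func:`write_outputs`."""
    path = Path(path)
    volumes, apical, basal = [], [], []
    footer: dict[str, str] = {}
    with path.open() as fh:
        header = fh.readline()
        assert header.startswith("phase")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, value = line[1:].strip().split("\t")
                footer[key] = value
                continue
            p, v, a, b = line.split("\t")
            volumes.append(float(v))
            apical.append(int(a))
            basal.append(int(b))
    return LVMetrics(
        volume_ml=np.array(volumes),
        edv_ml=float(footer["EDV_mL"]),
        esv_ml=float(footer["ESV_mL"]),
        ef_pct=float(footer["EF_pct"]),
        ed_phase=int(footer["ed_phase"]),
        es_phase=int(footer["es_phase"]),
        apical_slice=np.array(apical, dtype=int),
        basal_slice=np.array(basal, dtype=int),
    )


def write_phantom(stack: CineStack, truth, out_dir) -> dict[str, Path]:
    """Write a generated phantom as NIfTI + sidecar + truth masks + table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geom = stack.geometry
    affine = _affine(geom)
    # (slice, phase, row, col) -> (row, col, slice, phase)
    data = stack.intensities.transpose(2, 3, 0, 1)
    stack_path = out_dir / "phantom.nii.gz"
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine), str(stack_path))
    sidecar = out_dir / "phantom.json"
    sidecar.write_text(
        json.dumps(
            {
                "pixel_spacing_row": geom.pixel_spacing_row,
                "pixel_spacing_col": geom.pixel_spacing_col,
                "slice_spacing": geom.slice_spacing,
            },
            indent=2,
        )
    )
    truth_path = out_dir / "truth_masks.nii.gz"
    nib.save(
        nib.Nifti1Image(
            truth.masks.transpose(2, 3, 0, 1).astype(np.uint8), affine
        ),
        str(truth_path),
    )
    table = out_dir / "truth.tsv"
    with table.open("w") as fh:
        fh.write("phase\tvolume_ml\ttrue_apical_slice\ttrue_basal_slice\n")
        for p, v in enumerate(truth.volume_per_phase):
            fh.write(
                f"{p}\t{v:.9g}\t{int(truth.true_apical_slice[p])}\t"
                f"{int(truth.true_basal_slice[p])}\n"
            )
        fh.write(f"# EDV_mL\t{truth.edv:.9g}\n")
        fh.write(f"# ESV_mL\t{truth.esv:.9g}\n")
        fh.write(f"# EF_pct\t{truth.ef:.9g}\n")
    return {
        "stack": stack_path,
        "sidecar": sidecar,
        "truth_masks": truth_path,
        "truth_table": table,
    }
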