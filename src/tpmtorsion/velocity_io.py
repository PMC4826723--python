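"""Reading and writing tissue-phase-mapping (TPM) velocity cine data.

A TPM acquisition delivers, for each short-axis slice of the left ventricle,
a magnitude cine plus three velocity-encoded cines (in-plane x/y and
through-plane z).  This module defines the in-memory container
(:class:`TPMSeries`), the stored-phase-to-velocity conversion, and readers /
writers for three on-disk representations:

``container``
    A single zip archive holding ``magnitude.npy``, ``velocity.npy`` and a
    JSON metadata block.  Lossless and byte-deterministic (fixed zip
    timestamps), so repeated writes of the same series are identical files.
``nifti``
    One 5-D NIfTI file shaped (rows, cols, 1, frames, 4) with channel order
    (magnitude, vx, vy, vz) plus a JSON sidecar for metadata NIfTI headers
    cannot hold (venc, slice label).
``dicom``
    A directory with one sub-directory per channel (``mag``, ``vx``, ``vy``,
    ``vz``) and one file per frame; velocities are stored as rescaled uint16
    with venc/timing metadata in a private block.

Conventions used throughout the package
---------------------------------------
* Pixel indices are 0-based, ordered (row, col); the row axis increases
  downward in display.
* Velocity component 0 is x (along columns, rightward), component 1 is y
  (along rows, downward), component 2 is z (through-plane).
* Velocities are in mm/s, time in ms, distances in mm.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "TPMSeries",
    "SliceSet",
    "phase_to_velocity",
    "read_tpm",
    "write_tpm",
]

SLICE_LABELS = ("base", "mid", "apex")

#: fixed timestamp used inside container archives so writes are reproducible
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)

_PRIVATE_CREATOR = "TPMTORSION"


class TPMIOError(IOError):
    """Raised when a TPM dataset cannot be read or written."""


@dataclass
class TPMSeries:
    """One short-axis slice's magnitude + three-component velocity cine.

    Attributes
    ----------
    slice_label : str
        One of ``base``, ``mid``, ``apex``.
    magnitude : ndarray, shape (frames, rows, cols)
        Magnitude images, arbitrary intensity units.
    velocity : ndarray, shape (3, frames, rows, cols)
        Velocity in mm/s; component order (x, y, z).
    pixel_spacing : (float, float)
        (row, col) spacing in mm.
    dt_ms : float
        Temporal resolution in ms.
    slice_position_mm : float
        Slice position along the LV long axis in mm.
    venc_mm_s : float
        Velocity-encoding limit in mm/s (phase of ±π maps to ±venc).
    """

    slice_label: str
    magnitude: np.ndarray
    velocity: np.ndarray
    pixel_spacing: tuple[float, float]
    dt_ms: float
    slice_position_mm: float
    venc_mm_s: float

    def __post_init__(self) -> None:
        if self.slice_label not in SLICE_LABELS:
            raise ValueError(
                f"slice_label must be one of {SLICE_LABELS}, got {self.slice_label!r}"
            )
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        if self.magnitude.ndim != 3:
            raise ValueError("magnitude must be (frames, rows, cols)")
        if self.velocity.ndim != 4 or self.velocity.shape[0] != 3:
            raise ValueError("velocity must be (3, frames, rows, cols)")
        if self.velocity.shape[1:] != self.magnitude.shape:
            raise ValueError(
                "magnitude and velocity must share (frames, rows, cols): "
                f"{self.magnitude.shape} vs {self.velocity.shape[1:]}"
            )
        if self.n_frames < 2:
            raise ValueError(f"need at least 2 frames, got {self.n_frames}")
        sp = tuple(float(s) for s in self.pixel_spacing)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ValueError(f"pixel_spacing must be two positive mm values, got {sp}")
        self.pixel_spacing = sp
        for name in ("dt_ms", "venc_mm_s"):
            if not float(getattr(self, name)) > 0:
                raise ValueError(f"{name} must be strictly positive")
        self.dt_ms = float(self.dt_ms)
        self.slice_position_mm = float(self.slice_position_mm)
        self.venc_mm_s = float(self.venc_mm_s)

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of one frame."""
        return self.magnitude.shape[1:]

    def velocity_over_venc(self) -> int:
        """Number of voxels whose |velocity| exceeds the encoding limit."""
        return int(np.count_nonzero(np.abs(self.velocity) > self.venc_mm_s * (1 + 1e-12)))

    def copy_with_velocity(self, velocity: np.ndarray) -> "TPMSeries":
        return replace(self, velocity=np.asarray(velocity, dtype=np.float64))


@dataclass
class SliceSet:
    """The slices of one exam, keyed by slice label, with pairwise distances."""

    series: dict[str, TPMSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = list(self.series)
        for lab in labels:
            if lab not in SLICE_LABELS:
                raise ValueError(f"unknown slice label {lab!r}")
        dts = [s.dt_ms for s in self.series.values()]
        if dts and (max(dts) - min(dts)) > 0.1 * min(dts):
            raise ValueError(
                f"slice temporal resolutions differ by more than 10%: {dts}"
            )
        for a, b in (("base", "mid"), ("mid", "apex"), ("base", "apex")):
            if a in self.series and b in self.series:
                if self.distance_mm(a, b) <= 0:
                    raise ValueError(f"slice pair ({a},{b}) has non-positive separation")
        if all(lab in self.series for lab in SLICE_LABELS):
            h_ba = self.distance_mm("base", "apex")
            if h_ba < max(self.distance_mm("base", "mid"), self.distance_mm("mid", "apex")):
                raise ValueError("base-apex distance smaller than a sub-interval")

    def distance_mm(self, upper: str, lower: str) -> float:
        """Inter-slice distance h along the long axis, in mm."""
        return abs(
            self.series[upper].slice_position_mm - self.series[lower].slice_position_mm
        )


# ---------------------------------------------------------------------------
# phase -> velocity
# ---------------------------------------------------------------------------

def phase_to_velocity(stored_phase: np.ndarray, venc_mm_s: float) -> np.ndarray:
    """Convert stored phase (radians in [-pi, pi)) to velocity in mm/s.

    The standard linear phase-contrast convention is used: a phase of ±π
    corresponds to ±venc, so ``v = phase / π * venc``.  The result saturates
    at ±venc.
    """
    if not venc_mm_s > 0:
        raise ValueError("venc_mm_s must be positive")
    phase = np.asarray(stored_phase, dtype=np.float64)
    bad = ~np.isfinite(phase)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite phase value at index {idx}")
    v = phase / np.pi * venc_mm_s
    return np.clip(v, -venc_mm_s, venc_mm_s)


# ---------------------------------------------------------------------------
# container format
# ---------------------------------------------------------------------------

def _npy_bytes(arr: np.ndarray) -> bytes:
    buf = io.BytesIO()
    np.lib.format.write_array(buf, np.ascontiguousarray(arr), allow_pickle=False)
    return buf.getvalue()


def _series_meta(series: TPMSeries) -> dict:
    return {
        "slice_label": series.slice_label,
        "pixel_spacing": list(series.pixel_spacing),
        "dt_ms": series.dt_ms,
        "slice_position_mm": series.slice_position_mm,
        "venc_mm_s": series.venc_mm_s,
        "n_frames": series.n_frames,
    }


def _write_container(series: TPMSeries, path: Path) -> None:
    members = [
        ("meta.json", json.dumps(_series_meta(series), sort_keys=True, indent=1).encode()),
        ("magnitude.npy", _npy_bytes(series.magnitude)),
        ("velocity.npy", _npy_bytes(series.velocity)),
    ]
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name, data in members:
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.external_attr = 0o644 << 16
            zf.writestr(info, data)


def _read_container(path: Path) -> TPMSeries:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        magnitude = np.lib.format.read_array(io.BytesIO(zf.read("magnitude.npy")))
        velocity = np.lib.format.read_array(io.BytesIO(zf.read("velocity.npy")))
    return TPMSeries(
        slice_label=meta["slice_label"],
        magnitude=magnitude,
        velocity=velocity,
        pixel_spacing=tuple(meta["pixel_spacing"]),
        dt_ms=meta["dt_ms"],
        slice_position_mm=meta["slice_position_mm"],
        venc_mm_s=meta["venc_mm_s"],
    )


# ---------------------------------------------------------------------------
# NIfTI format
# ---------------------------------------------------------------------------

def _write_nifti(series: TPMSeries, path: Path) -> None:
    import nibabel as nib

    # (rows, cols, 1, frames, channel); channel order mag, vx, vy, vz
    data = np.empty(series.shape + (1, series.n_frames, 4), dtype=np.float64)
    data[..., 0, :, 0] = np.moveaxis(series.magnitude, 0, -1)
    for c in range(3):
        data[..., 0, :, 1 + c] = np.moveaxis(series.velocity[c], 0, -1)
    affine = np.diag([series.pixel_spacing[0], series.pixel_spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(
        (series.pixel_spacing[0], series.pixel_spacing[1], 1.0, series.dt_ms / 1000.0, 1.0)
    )
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(json.dumps(_series_meta(series), sort_keys=True, indent=1))


def _nifti_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if path.name.endswith(".nii.gz"):
        sidecar = path.parent / (path.name[: -len(".nii.gz")] + ".json")
    if not sidecar.exists():
        raise TPMIOError(
            f"NIfTI series {path} has no metadata sidecar {sidecar.name}; "
            "venc and slice label cannot be guessed"
        )
    return json.loads(sidecar.read_text())


def _read_nifti(path: Path) -> TPMSeries:
    import nibabel as nib

    meta = _nifti_sidecar(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 5 or data.shape[4] != 4:
        if data.ndim == 5:
            raise TPMIOError(
                f"expected 4 channels (magnitude + 3 velocity components), got {data.shape[4]}"
            )
        raise TPMIOError(f"expected a 5-D multi-channel NIfTI, got shape {data.shape}")
    magnitude = np.moveaxis(data[..., 0, :, 0], -1, 0)
    velocity = np.stack(
        [np.moveaxis(data[..., 0, :, 1 + c], -1, 0) for c in range(3)], axis=0
    )
    for key in ("venc_mm_s", "pixel_spacing"):
        if key not in meta:
            raise TPMIOError(f"metadata sidecar for {path} lacks required field {key!r}")
    return TPMSeries(
        slice_label=meta["slice_label"],
        magnitude=magnitude,
        velocity=velocity,
        pixel_spacing=tuple(meta["pixel_spacing"]),
        dt_ms=meta["dt_ms"],
        slice_position_mm=meta["slice_position_mm"],
        venc_mm_s=meta["venc_mm_s"],
    )


# ---------------------------------------------------------------------------
# DICOM format
# ---------------------------------------------------------------------------

_DICOM_CHANNELS = ("mag", "vx", "vy", "vz")


def _write_dicom(series: TPMSeries, path: Path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    path.mkdir(parents=True, exist_ok=True)
    series_uids = {ch: generate_uid() for ch in _DICOM_CHANNELS}
    study_uid = generate_uid()
    mag_max = float(series.magnitude.max()) or 1.0

    for ch_idx, ch in enumerate(_DICOM_CHANNELS):
        chdir = path / ch
        chdir.mkdir(exist_ok=True)
        if ch == "mag":
            slope, intercept = mag_max / 65535.0, 0.0
            frames = series.magnitude
        else:
            # map [-venc, venc] onto uint16 so a saturated voxel round-trips
            slope = 2.0 * series.venc_mm_s / 65535.0
            intercept = -series.venc_mm_s
            frames = series.velocity[ch_idx - 1]
        for t in range(series.n_frames):
            ds = Dataset()
            ds.SOPClassUID = pydicom.uid.MRImageStorage
            ds.SOPInstanceUID = generate_uid()
            ds.StudyInstanceUID = study_uid
            ds.SeriesInstanceUID = series_uids[ch]
            ds.Modality = "MR"
            ds.SeriesDescription = f"TPM {ch}"
            ds.InstanceNumber = t + 1
            ds.TriggerTime = f"{t * series.dt_ms:.6g}"
            ds.SliceLocation = f"{series.slice_position_mm:.6g}"
            ds.Rows, ds.Columns = series.shape
            ds.PixelSpacing = [f"{series.pixel_spacing[0]:.6g}", f"{series.pixel_spacing[1]:.6g}"]
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.RescaleSlope = f"{slope:.12g}"
            ds.RescaleIntercept = f"{intercept:.12g}"
            block = ds.private_block(0x0021, _PRIVATE_CREATOR, create=True)
            block.add_new(0x01, "DS", f"{series.venc_mm_s:.12g}")
            block.add_new(0x02, "DS", f"{series.dt_ms:.12g}")
            block.add_new(0x03, "LO", series.slice_label)
            block.add_new(0x04, "LO", ch)
            raw = np.round((frames[t] - intercept) / slope)
            ds.PixelData = np.clip(raw, 0, 65535).astype("<u2").tobytes()
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = ds.SOPClassUID
            meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.file_meta = meta
            pydicom.dcmwrite(chdir / f"{t:04d}.dcm", ds, enforce_file_format=True)


def _read_dicom(path: Path, venc_mm_s: float | None = None) -> TPMSeries:
    import pydicom

    channels: dict[str, list] = {ch: [] for ch in _DICOM_CHANNELS}
    for f in sorted(path.rglob("*.dcm")):
        ds = pydicom.dcmread(f)
        try:
            block = ds.private_block(0x0021, _PRIVATE_CREATOR)
            ch = str(block[0x04].value)
        except KeyError:
            desc = str(getattr(ds, "SeriesDescription", "")).split()
            ch = desc[-1] if desc and desc[-1] in _DICOM_CHANNELS else None
        if ch in channels:
            channels[ch].append(ds)
    missing = [ch for ch in _DICOM_CHANNELS if not channels[ch]]
    if missing:
        n_vel = sum(bool(channels[c]) for c in _DICOM_CHANNELS[1:])
        raise TPMIOError(
            f"DICOM series at {path} is missing channel(s) {missing} "
            f"({n_vel} of 3 velocity components found)"
        )

    ref = channels["mag"][0]
    try:
        block = ref.private_block(0x0021, _PRIVATE_CREATOR)
        venc = float(block[0x01].value)
        dt_ms = float(block[0x02].value)
        slice_label = str(block[0x03].value)
    except KeyError:
        if venc_mm_s is None:
            raise TPMIOError(
                f"DICOM series at {path} carries no velocity-encoding (venc) metadata "
                "and none was supplied; refusing to guess"
            )
        venc, slice_label = float(venc_mm_s), "mid"
        times = sorted(float(getattr(ds, "TriggerTime", i)) for i, ds in enumerate(channels["mag"]))
        dt_ms = times[1] - times[0] if len(times) > 1 else 0.0
    if venc_mm_s is not None:
        venc = float(venc_mm_s)
    if "PixelSpacing" not in ref:
        raise TPMIOError(f"DICOM series at {path} lacks PixelSpacing; refusing to guess")

    def stack(dsets):
        dsets = sorted(dsets, key=lambda d: int(d.InstanceNumber))
        out = []
        for ds in dsets:
            arr = ds.pixel_array.astype(np.float64)
            out.append(arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept))
        return np.stack(out, axis=0)

    magnitude = stack(channels["mag"])
    velocity = np.stack([stack(channels[c]) for c in _DICOM_CHANNELS[1:]], axis=0)
    return TPMSeries(
        slice_label=slice_label,
        magnitude=magnitude,
        velocity=velocity,
        pixel_spacing=tuple(float(s) for s in ref.PixelSpacing),
        dt_ms=dt_ms,
        slice_position_mm=float(getattr(ref, "SliceLocation", 0.0)),
        venc_mm_s=venc,
    )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _guess_format(path: Path) -> str:
    if path.is_dir():
        return "dicom"
    name = path.name
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    return "container"


def read_tpm(path, format_hint: str | None = None, venc_mm_s: float | None = None) -> TPMSeries:
    """Read a TPM series from ``path``.

    Parameters
    ----------
    path : str or Path
        Container file, NIfTI file, or DICOM directory.
    format_hint : {"container", "nifti", "dicom"}, optional
        Explicit format; inferred from the path when omitted.
    venc_mm_s : float, optional
        Override/supply the velocity-encoding limit (DICOM only).
    """
    path = Path(path)
    if not path.exists():
        raise TPMIOError(f"no such file or directory: {path}")
    fmt = format_hint or _guess_format(path)
    if fmt == "container":
        return _read_container(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom":
        return _read_dicom(path, venc_mm_s=venc_mm_s)
    raise ValueError(f"unknown format {fmt!r}")


def write_tpm(series: TPMSeries, path, format: str | None = None) -> None:
    """Write ``series`` to ``path`` in the requested format.

    Refuses to write a series whose velocities exceed its own encoding limit,
    since such data cannot have come from a valid phase reconstruction.
    """
    n_over = series.velocity_over_venc()
    if n_over:
        raise ValueError(
            f"{n_over} voxel(s) exceed the encoding limit venc={series.venc_mm_s} mm/s; "
            "refusing to write"
        )
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "container":
        _write_container(series, path)
    elif fmt == "nifti":
        _write_nifti(series, path)
    elif fmt == "dicom":
        _write_dicom(series, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
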