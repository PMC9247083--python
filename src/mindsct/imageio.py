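"""Reading, writing and preprocessing of 2-D grayscale medical images.

The preprocessing mirrors a standard chest MRI→CT training pipeline:

* CT volumes arrive in Hounsfield units and are display-windowed to [0, 1]
  with window level 350 HU / window width 2000 HU (a bone-friendly window:
  −650 HU maps to 0, +1350 HU to 1);
* background air is removed by thresholding, keeping the largest connected
  component and filling its interior holes (so dark cavities such as lungs
  stay inside the body mask);
* MRI intensities are normalised to the median tissue value inside the
  body mask (with an optional percentile cap for mapping into [0, 1]);
* a smooth multiplicative bias field can be removed by dividing out a
  Gaussian low-pass estimate of the in-mask intensity (a deliberately
  simple stand-in for full histogram-sharpening bias correction);
* everything is resampled bilinearly to a square training resolution
  (256×256 at clinical scale).

Supported container formats: PNG (8-bit), NIfTI (via nibabel) and DICOM
(via pydicom; rescale slope/intercept are applied on read so CT values come
back in HU).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "WindowingParams",
    "window_ct",
    "remove_background",
    "normalize_mri",
    "estimate_bias_field",
    "correct_bias",
    "resize",
    "read_image",
    "write_image",
]


@dataclass(frozen=True)
class WindowingParams:
    """CT display window in Hounsfield units."""

    level: float = 350.0
    width: float = 2000.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")


def window_ct(hu_image, params: WindowingParams | None = None) -> np.ndarray:
    """Map HU values linearly onto [0, 1] over the display window.

    ``level - width/2`` maps to 0 and ``level + width/2`` to 1; values
    outside are clipped.  Monotone non-decreasing in HU.
    """
    params = params or WindowingParams()
    hu = np.asarray(hu_image, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU image contains non-finite values")
    lo = params.level - params.width / 2.0
    return np.clip((hu - lo) / params.width, 0.0, 1.0)


def hu_to_window_value(hu: float, params: WindowingParams | None = None) -> float:
    """Windowed [0, 1] intensity of a single HU value (same map as above)."""
    return float(window_ct(np.array([hu]), params)[0])


def remove_background(image, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Strip background by thresholding and filling-in.

    Keeps the largest 8-connected component of ``image >= threshold``,
    fills its interior holes (so internal dark cavities belong to the
    body), zeroes everything outside and returns ``(masked_image, mask)``.

    Raises ``ValueError`` when no pixel exceeds the threshold.
    """
    img = np.asarray(image, dtype=np.float64)
    fg = img >= threshold
    if not fg.any():
        raise ValueError(f"no foreground above threshold {threshold}")
    labels, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndi.sum(fg, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        fg = labels == keep
    mask = ndi.binary_fill_holes(fg)
    out = np.where(mask, img, 0.0)
    return out, mask


def normalize_mri(image, body_mask, rescale: bool = False,
                  cap_percentile: float = 99.5) -> np.ndarray:
    """Normalise an MRI to its median in-mask tissue value.

    After division the median over the mask is exactly 1 (and the result is
    invariant to rescaling the input).  With ``rescale=True`` the image is
    additionally divided by the ``cap_percentile`` in-mask intensity and
    clipped to [0, 1] for training.
    """
    img = np.asarray(image, dtype=np.float64)
    mask = np.asarray(body_mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty body mask")
    med = float(np.median(img[mask]))
    if med == 0.0:
        raise ValueError("median tissue intensity is zero")
    out = img / med
    if rescale:
        cap = float(np.percentile(out[mask], cap_percentile))
        if cap <= 0:
            raise ValueError("non-positive intensity cap")
        out = np.clip(out / cap, 0.0, 1.0)
    return out


def estimate_bias_field(image, body_mask, sigma: float = 8.0) -> np.ndarray:
    """Gaussian low-pass estimate of the in-mask intensity (normalised
    convolution), scaled to mean 1 inside the mask."""
    img = np.asarray(image, dtype=np.float64)
    mask = np.asarray(body_mask, dtype=float)
    num = ndi.gaussian_filter(img * mask, sigma)
    den = ndi.gaussian_filter(mask, sigma)
    field = np.where(den > 1e-8, num / np.maximum(den, 1e-8), 1.0)
    inside = mask.astype(bool)
    mean_in = field[inside].mean()
    if mean_in <= 0:
        raise ValueError("degenerate bias-field estimate")
    field = field / mean_in
    return np.clip(field, 0.05, None)


def correct_bias(image, body_mask, sigma: float = 8.0) -> np.ndarray:
    """Divide out the low-pass bias estimate inside the mask."""
    field = estimate_bias_field(image, body_mask, sigma)
    img = np.asarray(image, dtype=np.float64)
    return np.where(np.asarray(body_mask, dtype=bool), img / field, img)


def resize(image, target: int) -> np.ndarray:
    """Bilinear resample to ``target × target`` (pixel-centre alignment).

    Output pixel centre ``(i, j)`` samples the input at
    ``((i + 0.5) * H / target - 0.5, (j + 0.5) * W / target - 0.5)`` with
    edge-clamped reads; values stay within the input range.
    """
    if target < 8:
        raise ValueError("target size must be at least 8")
    img = np.asarray(image, dtype=np.float64)
    H, W = img.shape
    if (H, W) == (target, target):
        return img.copy()
    rows = (np.arange(target) + 0.5) * H / target - 0.5
    cols = (np.arange(target) + 0.5) * W / target - 0.5
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndi.map_coordinates(img, grid, order=1, mode="nearest")


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------

def _format_of(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("png", "nifti", "dicom"):
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith(".png"):
        return "png"
    if suffix.endswith(".nii") or suffix.endswith(".nii.gz"):
        return "nifti"
    if suffix.endswith(".dcm") or suffix.endswith(".dicom"):
        return "dicom"
    raise ValueError(f"cannot infer image format from {path.name!r}")


def read_image(path, fmt: str | None = None) -> np.ndarray:
    """Read a single 2-D grayscale image.

    PNG values are scaled to [0, 1]; NIfTI volumes return their middle
    axial slice; DICOM pixel data are mapped through rescale slope and
    intercept, so CT reads come back in Hounsfield units.
    """
    path = Path(path)
    fmt = _format_of(path, fmt)
    if not path.exists():
        raise IOError(f"cannot read {path}: file does not exist")
    try:
        if fmt == "png":
            import imageio.v3 as iio
            arr = np.asarray(iio.imread(path), dtype=np.float64)
            if arr.ndim == 3:
                arr = arr[..., 0]
            maxval = 65535.0 if arr.max() > 255 else 255.0
            return arr / maxval
        if fmt == "nifti":
            import nibabel as nib
            vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
            vol = np.squeeze(vol)
            if vol.ndim == 3:
                vol = vol[:, :, vol.shape[2] // 2]
            if vol.ndim != 2:
                raise ValueError(f"unsupported NIfTI dimensionality {vol.ndim}")
            return vol
        # DICOM
        import pydicom
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept
    except (ValueError, IOError):
        raise
    except Exception as exc:  # pragma: no cover - backend-specific failures
        raise IOError(f"cannot read {path}: {exc}") from exc


def write_image(image, path, fmt: str | None = None) -> None:
    """Write a 2-D image: PNG (8-bit, expects [0, 1]), NIfTI (float32) or
    DICOM (int16 with identity rescale)."""
    path = Path(path)
    fmt = _format_of(path, fmt)
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        import imageio.v3 as iio
        data = np.clip(np.round(np.clip(img, 0.0, 1.0) * 255.0), 0, 255)
        iio.imwrite(path, data.astype(np.uint8))
        return
    if fmt == "nifti":
        import nibabel as nib
        nib.save(nib.Nifti1Image(img.astype(np.float32), np.eye(4)), str(path))
        return
    _write_dicom(img, path)


def _write_dicom(img: np.ndarray, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = img.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.RescaleSlope = 1
    ds.RescaleIntercept = 0
    data = np.clip(np.round(img), -32768, 32767).astype(np.int16)
    ds.PixelData = data.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
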