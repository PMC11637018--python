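"""Volume I/O, preprocessing and sliding-window whole-volume inference.

NIfTI files are read and written with nibabel; gzip members are written with
a zeroed timestamp so regenerating a dataset from the same spec yields
byte-identical files.  Cropping records its geometry so predictions can be
re-embedded into the original volume frame.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigurationError

__all__ = ["load_volume", "save_volume", "CropPlan", "center_crop",
           "normalize_intensity", "SlidingWindowPlan", "sliding_window_predict"]


def load_volume(path):
    """Read a 3D NIfTI volume -> (array, spacing, affine).

    4D (or higher) files are rejected explicitly rather than squeezed.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D "
                         f"shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data), spacing, img.affine


def save_volume(data: np.ndarray, spacing, path, affine=None) -> None:
    """Write a 3D volume as NIfTI (.nii or .nii.gz, deterministic bytes)."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected 3D data, got shape {data.shape}")
    if affine is None:
        affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing)
    raw = img.to_bytes()
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith(".gz"):
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(raw)
    else:
        path.write_bytes(raw)


# -- cropping --------------------------------------------------------------

@dataclass(frozen=True)
class CropPlan:
    """Geometry of a center crop: per-axis (pad_before, pad_after) applied to
    the source, then (offset, extent) taken from the padded array."""

    original_shape: tuple
    target_shape: tuple
    pad: tuple          # ((lo, hi),) * 3 padding applied before cropping
    offset: tuple       # crop start in the padded frame

    def embed(self, cropped: np.ndarray, fill=0) -> np.ndarray:
        """Map a crop-frame array back into the original volume frame."""
        if tuple(cropped.shape) != tuple(self.target_shape):
            raise ValueError("array shape does not match crop target")
        padded_shape = tuple(o + lo + hi for o, (lo, hi)
                             in zip(self.original_shape, self.pad))
        out = np.full(padded_shape, fill, dtype=cropped.dtype)
        sl = tuple(slice(off, off + t) for off, t in zip(self.offset, self.target_shape))
        out[sl] = cropped
        unpad = tuple(slice(lo, lo + o) for o, (lo, hi)
                      in zip(self.original_shape, self.pad))
        return out[unpad]


def center_crop(volume: np.ndarray, target_shape, fill=0.0):
    """Centered crop to ``target_shape``; smaller axes are symmetrically
    padded with ``fill`` first.  Odd differences put the extra voxel on the
    high side (floor/ceil convention).  Returns (cropped, CropPlan)."""
    target_shape = tuple(int(t) for t in target_shape)
    if any(t <= 0 for t in target_shape):
        raise ConfigurationError("target_shape must be positive")
    pads, offsets = [], []
    for o, t in zip(volume.shape, target_shape):
        if o >= t:
            pads.append((0, 0))
            offsets.append((o - t) // 2)
        else:
            lo = (t - o) // 2
            pads.append((lo, t - o - lo))
            offsets.append(0)
    padded = np.pad(volume, pads, constant_values=fill) if any(
        p != (0, 0) for p in pads) else volume
    sl = tuple(slice(off, off + t) for off, t in zip(offsets, target_shape))
    plan = CropPlan(tuple(volume.shape), target_shape, tuple(pads), tuple(offsets))
    return padded[sl].copy(), plan


# -- intensity normalisation ----------------------------------------------

def normalize_intensity(volume: np.ndarray, mode: str = "zscore") -> np.ndarray:
    volume = np.asarray(volume, dtype=np.float32)
    if mode == "zscore":
        std = float(volume.std())
        if std == 0.0:
            return np.zeros_like(volume)
        return (volume - float(volume.mean())) / std
    if mode == "minmax":
        lo, hi = float(volume.min()), float(volume.max())
        if hi == lo:
            return np.zeros_like(volume)
        return (volume - lo) / (hi - lo)
    raise ConfigurationError(f"unknown normalisation mode {mode!r}")


# -- sliding-window inference ----------------------------------------------

@dataclass(frozen=True)
class SlidingWindowPlan:
    window_shape: tuple = (64, 64, 16)
    stride: tuple | None = None  # default: window // 2

    def strides(self) -> tuple:
        if self.stride is not None:
            return tuple(int(s) for s in self.stride)
        return tuple(max(1, w // 2) for w in self.window_shape)


def _starts(dim: int, win: int, stride: int) -> list[int]:
    if win >= dim:
        return [0]
    starts = list(range(0, dim - win + 1, stride))
    if starts[-1] != dim - win:
        starts.append(dim - win)  # flush final window so every voxel is covered
    return starts


def sliding_window_predict(network, volume: np.ndarray,
                           plan: SlidingWindowPlan | None = None) -> np.ndarray:
    """Whole-volume class probabilities by tiling deterministic forward passes.

    Overlapping windows are averaged (softmax space), which keeps each voxel
    on the probability simplex.  The volume is padded with its minimum value
    when smaller than the window, then unpadded.
    """
    plan = plan or SlidingWindowPlan()
    win = tuple(int(w) for w in plan.window_shape)
    vol = np.asarray(volume, dtype=np.float32)
    if vol.ndim != 3:
        raise ConfigurationError("expected a 3D volume")
    pads = []
    for o, w in zip(vol.shape, win):
        extra = max(0, w - o)
        pads.append((extra // 2, extra - extra // 2))
    if any(p != (0, 0) for p in pads):
        vol = np.pad(vol, pads, constant_values=float(vol.min()))
    stride = plan.strides()
    num_classes = network.spec.num_classes
    acc = np.zeros((num_classes,) + vol.shape, dtype=np.float64)
    count = np.zeros(vol.shape, dtype=np.float64)
    for sx in _starts(vol.shape[0], win[0], stride[0]):
        for sy in _starts(vol.shape[1], win[1], stride[1]):
            for sz in _starts(vol.shape[2], win[2], stride[2]):
                sl = (slice(sx, sx + win[0]), slice(sy, sy + win[1]),
                      slice(sz, sz + win[2]))
                probs = network.predict_proba(vol[sl][None])
                acc[(slice(None),) + sl] += probs
                count[sl] += 1.0
    if count.min() < 1:
        raise ConfigurationError("sliding-window plan leaves voxels uncovered")
    acc /= count
    unpad = tuple(slice(lo, lo + o) for o, (lo, hi) in zip(volume.shape, pads))
    return acc[(slice(None),) + unpad]


def label_from_proba(probs: np.ndarray) -> np.ndarray:
    """Argmax label map; exact ties go to background (class 0)."""
    best = probs.max(axis=0)
    label = probs.argmax(axis=0)
    # argmax returns the first maximal index; ensure ties include class 0
    tie_with_bg = (probs[0] == best)
    return np.where(tie_with_bg, 0, label).astype(np.uint8)
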