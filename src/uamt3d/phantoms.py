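"""Synthetic paired CT-like / CBCT-like phantom volumes with target masks.

Each case contains a half-ellipsoid soft-tissue target (breast-like region,
intermediate intensity) sitting on a high-intensity planar slab (chest-wall
stand-in) over a low-intensity background.  The degraded companion volume
mimics cone-beam acquisition: a low-frequency multiplicative shading field,
additive zero-mean Gaussian noise, and lateral truncation (outer columns
zeroed, as in a limited field of view).

Geometry and degradations are abstract-intensity, not Hounsfield units;
normalisation is downstream's job.  Every case is generated from its own RNG
stream derived from (seed, case_index), so any single case can be regenerated
independently and the whole dataset is a pure function of its spec.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError

__all__ = ["PhantomSpec", "PhantomCase", "generate_case", "generate_dataset",
           "load_manifest"]

BACKGROUND = 0.0
SLAB_INTENSITY = 1.0
TARGET_INTENSITY = 0.6
SLAB_THICKNESS_FRACTION = 0.12
#: labeled cases use clean (CT-like) vs degraded (CBCT-like) input 5:3
CLEAN_TO_DEGRADED_RATIO = (5, 3)


@dataclass(frozen=True)
class PhantomSpec:
    volume_shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    n_cases: int = 20
    labeled_fraction: float = 0.10
    test_fraction: float = 0.2
    noise_sigma: float = 0.30
    shading_amp: float = 0.30
    truncation_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if len(self.volume_shape) != 3 or any(s < 8 for s in self.volume_shape):
            raise ConfigurationError("volume_shape must be 3 dims of >= 8 voxels")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be positive")
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be positive")
        if not 0.0 < self.labeled_fraction <= 1.0:
            raise ConfigurationError("labeled_fraction must lie in (0, 1]")
        if not 0.0 <= self.test_fraction < 1.0:
            raise ConfigurationError("test_fraction must lie in [0, 1)")
        if self.noise_sigma < 0 or self.shading_amp < 0:
            raise ConfigurationError("noise_sigma and shading_amp must be >= 0")
        if not 0.0 <= self.truncation_fraction < 0.5:
            raise ConfigurationError("truncation_fraction must lie in [0, 0.5)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["volume_shape"] = list(self.volume_shape)
        d["spacing"] = list(self.spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["volume_shape"] = tuple(d["volume_shape"])
        d["spacing"] = tuple(d["spacing"])
        return cls(**d)


@dataclass
class PhantomCase:
    clean_volume: np.ndarray
    degraded_volume: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    labeled: bool
    case_id: str


def _case_rng(spec: PhantomSpec, case_index: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) % (2 ** 31), int(case_index)])


def _shading_field(shape, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 +- amp from an upsampled coarse grid."""
    coarse = rng.uniform(-1.0, 1.0, size=(4, 4, 3))
    zoom = [s / c for s, c in zip(shape, coarse.shape)]
    field = ndimage.zoom(coarse, zoom, order=1, mode="nearest", grid_mode=True)
    return 1.0 + amp * field


def generate_case(spec: PhantomSpec, case_index: int) -> PhantomCase:
    """Generate one paired clean/degraded phantom case.

    The target half-ellipsoid is attached to the face of the slab and kept
    away from volume borders; the degraded volume applies shading, noise and
    lateral truncation to the same anatomy (the mask is shared).
    """
    spec.validate()
    if not 0 <= case_index < spec.n_cases:
        raise ConfigurationError(
            f"case_index {case_index} outside [0, {spec.n_cases})")
    rng = _case_rng(spec, case_index)
    nx, ny, nz = spec.volume_shape

    clean = np.full(spec.volume_shape, BACKGROUND, dtype=np.float32)
    slab_t = max(2, int(round(SLAB_THICKNESS_FRACTION * nx)))
    clean[:slab_t] = SLAB_INTENSITY

    # half-ellipsoid seated on the slab face, extending along +x
    # wide per-case ranges: target size/position vary as much across phantom
    # "patients" as breast CTVs do across real ones
    rx = rng.uniform(0.40, 0.75) * (nx - slab_t) / 2.0
    ry = rng.uniform(0.25, 0.45) * ny / 2.0
    rz = rng.uniform(0.45, 0.66) * nz / 2.0
    cy = ny / 2.0 + rng.uniform(-0.10, 0.10) * ny
    cz = nz / 2.0 + rng.uniform(-0.04, 0.04) * nz
    x, y, z = np.ogrid[:nx, :ny, :nz]
    ell = (((x - slab_t) / rx) ** 2 + ((y - cy) / ry) ** 2
           + ((z - cz) / rz) ** 2) <= 1.0
    mask = (ell & (x >= slab_t)).astype(np.uint8)
    clean[mask.astype(bool)] = TARGET_INTENSITY
    # mild intra-case texture so the task is not pure thresholding
    clean += 0.02 * rng.standard_normal(spec.volume_shape).astype(np.float32)

    degraded = clean * _shading_field(spec.volume_shape, spec.shading_amp, rng)
    if spec.noise_sigma > 0:
        degraded = degraded + spec.noise_sigma * rng.standard_normal(spec.volume_shape)
    n_trunc = int(math.floor(spec.truncation_fraction * ny))
    if n_trunc > 0:
        degraded[:, ny - n_trunc:, :] = BACKGROUND
    return PhantomCase(
        clean_volume=clean.astype(np.float32),
        degraded_volume=degraded.astype(np.float32),
        mask=mask,
        spacing=spec.spacing,
        labeled=case_index < n_labeled(spec),
        case_id=f"case_{case_index:03d}",
    )


def n_labeled(spec: PhantomSpec) -> int:
    return int(math.ceil(spec.labeled_fraction * spec.n_cases))


def split_assignment(spec: PhantomSpec) -> list[tuple[bool, str]]:
    """(labeled, split) per case index: first ceil(lf*n) cases labeled (always
    train); the last round(test_fraction*n) unlabeled positions are test."""
    nl = n_labeled(spec)
    n_test = min(int(round(spec.test_fraction * spec.n_cases)), spec.n_cases - nl)
    return [(i < nl, "test" if i >= spec.n_cases - n_test else "train")
            for i in range(spec.n_cases)]


def generate_dataset(spec: PhantomSpec, out_dir) -> dict:
    """Write all cases as NIfTI triplets plus a JSON manifest.

    The first ``ceil(labeled_fraction * n_cases)`` cases are labeled; the last
    ``round(test_fraction * n_cases)`` *unlabeled* positions form the test
    split (labeled cases always train).  Returns the manifest dict.
    """
    from .io_inference import save_volume  # local import to avoid cycle

    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assignment = split_assignment(spec)
    cases = []
    for i in range(spec.n_cases):
        case = generate_case(spec, i)
        paths = {}
        for kind, arr in (("clean", case.clean_volume),
                          ("degraded", case.degraded_volume),
                          ("mask", case.mask)):
            p = out_dir / f"{case.case_id}_{kind}.nii.gz"
            save_volume(arr, spec.spacing, p)
            paths[kind] = p.name
        labeled, split = assignment[i]
        cases.append({"case_id": case.case_id, "paths": paths,
                      "labeled": bool(labeled), "split": split})
    manifest = {"spec": spec.to_dict(), "cases": cases}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_manifest(path) -> dict:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    with open(path) as fh:
        return json.load(fh)
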