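"""Synthetic 3D phantoms and NIfTI volume I/O.

The phantom generator produces small grayscale volumes with binary masks:
ellipsoid or irregular-blob foreground objects on a darker background, plus
additive Gaussian noise. A per-image ``difficulty`` knob in [0, 1] lowers the
foreground/background contrast and (for blobs) roughens the boundary, so a
dataset sampled over a difficulty range contains both easy and hard cases —
the per-image variability that makes image-specific inference paths
meaningful. Volumes are indexed (z, y, x) = (D, H, W), 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

try:
    import nibabel as nib
except ImportError:  # pragma: no cover - nibabel is a hard dependency
    nib = None

#: fraction of contrast removed at difficulty 1
CONTRAST_LOSS = 0.7
#: default desk-scale volume: in-plane dims divisible by the backbone stride 8
DEFAULT_SHAPE = (16, 64, 64)


@dataclass
class Volume:
    """A 3D scalar intensity grid with optional voxel spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class Case:
    """A volume/mask pair with provenance metadata."""

    id: str
    volume: Volume
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.mask.shape != self.volume.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != volume shape {self.volume.shape}"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


@dataclass
class PhantomSpec:
    """Recipe for one synthetic phantom."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    n_objects: int = 1
    object_kind: str = "ellipsoid"
    radius_range: tuple[float, float] = (4.0, 12.0)
    fg_intensity: float = 1.0
    bg_intensity: float = 0.0
    noise_sd: float = 0.2
    difficulty: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.object_kind not in ("ellipsoid", "blob"):
            raise ValueError(f"unknown object_kind {self.object_kind!r}")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] <= 0:
            raise ValueError("invalid radius_range")
        if self.n_objects > 0 and self.fg_intensity == self.bg_intensity and self.difficulty < 1:
            raise ValueError("foreground and background intensities must differ")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    val = (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    )
    return val, val <= 1.0


def generate_phantom(spec: PhantomSpec) -> Case:
    """Deterministically generate one phantom from its spec.

    Foreground is the union of the generated objects; intensities are the two
    class means (contrast shrunk by difficulty) plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    d, h, w = spec.shape
    mask = np.zeros(spec.shape, dtype=bool)
    rmin, rmax = spec.radius_range
    objects = []
    for _ in range(spec.n_objects):
        # per-axis radius bounds: requested range capped so the object fits;
        # the z cap matters for the thin slice dimension
        radii = []
        for extent in (d, h, w):
            hi = min(rmax, (extent - 2) / 2)
            if hi < 1.0:
                raise ValueError("volume too small to place an object")
            lo = min(rmin, hi)
            radii.append(float(rng.uniform(lo, hi)))
        rz, ry, rx = radii
        cz = rng.uniform(rz + 1, d - 1 - rz)
        cy = rng.uniform(ry + 1, h - 1 - ry)
        cx = rng.uniform(rx + 1, w - 1 - rx)
        val, obj = _ellipsoid_mask(spec.shape, (cz, cy, cx), (rz, ry, rx))
        if spec.object_kind == "blob":
            # roughen the implicit surface with a smooth random field
            noise = rng.standard_normal(spec.shape)
            smooth = ndimage.gaussian_filter(noise, sigma=(1.5, 3.0, 3.0))
            sd = smooth.std()
            if sd > 0:
                smooth = smooth / sd
            amp = 0.15 + 0.35 * spec.difficulty
            obj = val <= 1.0 + amp * smooth
        mask |= obj
        objects.append({"center": [cz, cy, cx], "radii": [rz, ry, rx]})

    contrast = 1.0 - CONTRAST_LOSS * spec.difficulty
    fg = spec.bg_intensity + (spec.fg_intensity - spec.bg_intensity) * contrast
    vol = np.where(mask, fg, spec.bg_intensity).astype(np.float32)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)
    meta = {"source": "phantom", "objects": objects,
            "spec": {**spec.__dict__, "shape": list(spec.shape),
                     "radius_range": list(spec.radius_range)}}
    return Case(
        id=f"phantom_{spec.seed}",
        volume=Volume(vol),
        mask=mask.astype(np.uint8),
        meta=meta,
    )


@dataclass
class SpecRanges:
    """Sampling ranges for :func:`make_dataset`."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    n_objects: tuple[int, int] = (1, 2)
    object_kind: str = "ellipsoid"
    radius_range: tuple[float, float] = (4.0, 12.0)
    fg_intensity: float = 1.0
    bg_intensity: float = 0.0
    noise_sd: float = 0.2
    difficulty: tuple[float, float] = (0.0, 0.5)


def split_sizes(n: int) -> tuple[int, int, int]:
    """70/15/15 split; train and val sizes rounded half-up, test gets the rest."""
    n_train = int(np.floor(0.70 * n + 0.5))
    n_val = int(np.floor(0.15 * n + 0.5))
    n_val = min(n_val, n - n_train)
    return n_train, n_val, n - n_train - n_val


def make_dataset(
    n_cases: int, spec_ranges: SpecRanges | None = None, seed: int = 0
) -> list[Case]:
    """Generate ``n_cases`` phantoms with specs sampled from ``spec_ranges``.

    Each case carries its split ("train"/"val"/"test") in ``meta``; the
    assignment is a deterministic function of ``seed``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    ranges = spec_ranges if spec_ranges is not None else SpecRanges()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDA7A]))
    cases = []
    for i in range(n_cases):
        spec = PhantomSpec(
            shape=ranges.shape,
            n_objects=int(rng.integers(ranges.n_objects[0], ranges.n_objects[1] + 1)),
            object_kind=ranges.object_kind,
            radius_range=ranges.radius_range,
            fg_intensity=ranges.fg_intensity,
            bg_intensity=ranges.bg_intensity,
            noise_sd=ranges.noise_sd,
            difficulty=float(rng.uniform(*ranges.difficulty)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        case = generate_phantom(spec)
        case.id = f"case_{i:04d}"
        cases.append(case)
    n_train, n_val, _ = split_sizes(n_cases)
    order = rng.permutation(n_cases)
    for rank, idx in enumerate(order):
        split = "train" if rank < n_train else ("val" if rank < n_train + n_val else "test")
        cases[idx].meta["split"] = split
    return cases


def split_cases(cases: list[Case]) -> tuple[list[Case], list[Case], list[Case]]:
    train = [c for c in cases if c.meta.get("split") == "train"]
    val = [c for c in cases if c.meta.get("split") == "val"]
    test = [c for c in cases if c.meta.get("split") == "test"]
    return train, val, test


# ---------------------------------------------------------------------------
# NIfTI I/O (real-data path)

HU_WINDOW = (-200.0, 250.0)


def apply_window(data: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    """Clip to the intensity window and min-max scale to [0, 1]."""
    lo, hi = window
    return ((np.clip(data, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def read_nifti(
    volume_path, mask_path=None, *, window: bool = False, case_id: str | None = None
) -> Case:
    """Load a volume (and optional mask) from NIfTI, reoriented to RAS.

    Masks are binarized at > 0.5. With ``window`` on, CT intensities are
    clipped to [-200, 250] HU and min-max scaled to [0, 1].
    """
    img = nib.as_closest_canonical(nib.load(str(volume_path)))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D in {volume_path}")
    zooms = img.header.get_zooms()[:3]
    if any(z == 0 for z in zooms):
        warnings.warn(f"missing voxel spacing in {volume_path}; assuming isotropic 1.0")
        zooms = (1.0, 1.0, 1.0)
    if window:
        data = apply_window(data)
    # nibabel loads (x, y, z); store (D, H, W) = (z, y, x)
    data = np.ascontiguousarray(data.transpose(2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    meta = {"source": str(volume_path), "orientation": "RAS", "windowed": bool(window)}
    if mask_path is not None:
        mimg = nib.as_closest_canonical(nib.load(str(mask_path)))
        mdata = np.asarray(mimg.dataobj, dtype=np.float32)
        if mdata.ndim != 3:
            raise ValueError(f"expected a 3D mask, got {mdata.ndim}D in {mask_path}")
        mask = (mdata > 0.5).astype(np.uint8).transpose(2, 1, 0)
        meta["mask_source"] = str(mask_path)
    else:
        mask = np.zeros(data.shape, dtype=np.uint8)
    cid = case_id if case_id is not None else Path(str(volume_path)).name.split(".")[0]
    return Case(id=cid, volume=Volume(data, spacing=spacing), mask=mask, meta=meta)


def write_nifti(case: Case, volume_path, mask_path=None) -> None:
    """Write volume (float32) and optionally mask (uint8) as NIfTI."""
    spacing = case.volume.spacing or (1.0, 1.0, 1.0)
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    vol_xyz = np.ascontiguousarray(case.volume.data.transpose(2, 1, 0))
    nib.save(nib.Nifti1Image(vol_xyz, affine), str(volume_path))
    if mask_path is not None:
        mask_xyz = np.ascontiguousarray(case.mask.astype(np.uint8).transpose(2, 1, 0))
        nib.save(nib.Nifti1Image(mask_xyz, affine), str(mask_path))


def write_manifest(cases: list[Case], directory, manifest_name: str = "manifest.json") -> Path:
    """Write all cases as NIfTI pairs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for case in cases:
        vpath = directory / f"{case.id}_vol.nii.gz"
        mpath = directory / f"{case.id}_mask.nii.gz"
        write_nifti(case, vpath, mpath)
        entries.append(
            {
                "id": case.id,
                "volume_path": vpath.name,
                "mask_path": mpath.name,
                "split": case.meta.get("split", "train"),
            }
        )
    manifest = directory / manifest_name
    manifest.write_text(json.dumps(entries, indent=1))
    return manifest


def read_manifest(manifest_path) -> list[Case]:
    manifest_path = Path(manifest_path)
    entries = json.loads(manifest_path.read_text())
    cases = []
    for e in entries:
        case = read_nifti(
            manifest_path.parent / e["volume_path"],
            manifest_path.parent / e["mask_path"],
            case_id=e["id"],
        )
        case.meta["split"] = e.get("split", "train")
        cases.append(case)
    return cases
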