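"""Synthetic non-contrast-CT phantoms with segment-labeled coronary calcifications.

A phantom emulates the data a segment-level calcium-scoring pipeline consumes:

* a Hounsfield-valued cardiac volume (soft-tissue background, a blood-pool
  ellipsoid, additive Gaussian image noise),
* 13 tubular coronary segment regions laid out as connected vessel trees
  (RCA chain with a side branch; LM bifurcating into the LAD and LCX chains),
* ellipsoidal calcified lesions (>= 130 HU) of controllable size, density and
  segment placed on the segment centerlines,
* the matching ground truth: a segment-labeled calcification mask, a weak
  region mask (the dilated tubes), and a lesion truth table.

Everything is deterministic given (config, seed). The geometry is parametric
(piecewise-linear centerlines in fractional coordinates), not anatomical: it is
built for correctness testing of scoring, training and evaluation code, not for
visual realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .segments import SEGMENT_LABELS

__all__ = [
    "CTVolume",
    "LabelVolume",
    "PhantomCase",
    "PhantomConfig",
    "generate_phantom",
    "degrade_with_noise",
    "weak_region_annotation",
    "read_volume",
    "write_volume",
    "write_case",
    "read_case",
]

HU_MIN, HU_MAX = -2048.0, 4096.0
CALCIUM_THRESHOLD_HU = 130.0


@dataclass(frozen=True)
class CTVolume:
    """A CT volume in Hounsfield units.

    ``voxels`` is indexed ``(slice, row, column)``; ``in_plane_spacing`` is the
    (row, column) voxel size in mm and ``slice_thickness`` the through-plane
    size in mm. All area/volume computations downstream use the spacing, never
    raw voxel counts.
    """

    voxels: np.ndarray
    in_plane_spacing: tuple[float, float] = (0.7, 0.7)
    slice_thickness: float = 3.0

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float64)
        object.__setattr__(self, "voxels", v)
        if v.ndim != 3:
            raise ValueError("CT volume must be 3-D (slice, row, column)")
        if v.min() < HU_MIN or v.max() > HU_MAX:
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: "
                f"range ({v.min():.1f}, {v.max():.1f})"
            )
        if self.slice_thickness <= 0 or min(self.in_plane_spacing) <= 0:
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.in_plane_spacing[0] * self.in_plane_spacing[1])

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_area_mm2 * self.slice_thickness


@dataclass(frozen=True)
class LabelVolume:
    """Integer label volume paired with a CT volume.

    Encoding: 0 = background, ``i`` = ``SEGMENT_LABELS[i - 1]`` for 1..13.
    """

    voxels: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if not np.issubdtype(v.dtype, np.integer):
            v = v.astype(np.int16)
        object.__setattr__(self, "voxels", v)
        if v.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if v.min() < 0 or v.max() > len(SEGMENT_LABELS):
            raise ValueError("labels must lie in {0..13}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


# Default vessel-tree centerlines in fractional (slice, row, column) coordinates.
# The RCA runs down the left of the volume, the left tree (LM -> LAD, LM -> LCX)
# down the right; side branches fork at the proximal/mid junctions.
DEFAULT_CENTERLINES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "p-RCA": ((0.08, 0.15, 0.22), (0.30, 0.30, 0.20)),
    "m-RCA": ((0.30, 0.30, 0.20), (0.55, 0.48, 0.20)),
    "d-RCA": ((0.55, 0.48, 0.20), (0.85, 0.68, 0.26)),
    "s-RCA": ((0.30, 0.30, 0.20), (0.46, 0.44, 0.04)),
    "LM": ((0.06, 0.10, 0.56), (0.16, 0.20, 0.66)),
    "p-LAD": ((0.16, 0.20, 0.66), (0.36, 0.34, 0.62)),
    "m-LAD": ((0.36, 0.34, 0.62), (0.58, 0.50, 0.60)),
    "d-LAD": ((0.58, 0.50, 0.60), (0.84, 0.68, 0.56)),
    "s-LAD": ((0.36, 0.34, 0.62), (0.52, 0.50, 0.40)),
    "p-LCX": ((0.16, 0.20, 0.66), (0.34, 0.30, 0.84)),
    "m-LCX": ((0.34, 0.30, 0.84), (0.55, 0.46, 0.88)),
    "d-LCX": ((0.55, 0.46, 0.88), (0.80, 0.62, 0.86)),
    "s-LCX": ((0.34, 0.30, 0.84), (0.50, 0.14, 0.95)),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic phantom.

    Defaults emulate the acquisition the scoring convention assumes: 3.0 mm
    slices (2.4-3.0 mm allowed), sub-millimetre in-plane spacing, soft-tissue
    background around 40 HU with a 50 HU blood pool, and ~10 HU image noise.
    Lesion attenuation spans the typical calcified-plaque range (all four
    Agatston density bins are reachable).
    """

    shape: tuple[int, int, int] = (12, 64, 64)
    in_plane_spacing: tuple[float, float] = (0.7, 0.7)
    slice_thickness: float = 3.0
    n_lesions: int = 6
    lesion_hu_range: tuple[float, float] = (180.0, 900.0)
    lesion_radius_range: tuple[float, float] = (1.3, 2.4)  # in-plane, voxels
    lesion_z_radius_range: tuple[float, float] = (0.6, 1.2)  # slices
    noise_sd: float = 10.0
    zero_cac: bool = False
    background_hu: float = 40.0
    blood_pool_hu: float = 50.0
    tube_radius: float = 3.2  # in-plane, voxels
    tube_z_radius: float = 1.6  # slices
    centerlines: dict[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_CENTERLINES)
    )

    def __post_init__(self) -> None:
        if min(self.shape) <= 0:
            raise ValueError("volume shape must be positive")
        lo, hi = self.lesion_hu_range
        if not (CALCIUM_THRESHOLD_HU <= lo <= hi <= 1500.0):
            raise ValueError("lesion HU range must lie within [130, 1500]")
        if not (2.4 <= self.slice_thickness <= 3.0):
            raise ValueError("slice thickness must lie in [2.4, 3.0] mm")
        if set(self.centerlines) != set(SEGMENT_LABELS):
            raise ValueError("centerlines must cover exactly the 13 segments")
        if self.lesion_radius_range[1] > self.tube_radius - 0.5:
            raise ValueError(
                "lesion radius range exceeds the segment tube: lesions of "
                f"radius {self.lesion_radius_range[1]} do not fit inside "
                f"tube radius {self.tube_radius}"
            )
        if self.lesion_z_radius_range[1] > self.tube_z_radius - 0.2:
            raise ValueError("lesion z-radius exceeds the segment tube")


@dataclass(frozen=True)
class PhantomCase:
    """A phantom with its full ground truth.

    ``lesion_table`` columns: lesion_id, segment, n_voxels, peak_hu, cz, cy, cx.
    """

    image: CTVolume
    cac_mask: LabelVolume
    region_mask: LabelVolume
    lesion_table: pd.DataFrame
    seed: int
    config: PhantomConfig = field(default=PhantomConfig(), repr=False)


def _sample_centerline(points: np.ndarray, step: float = 0.4) -> np.ndarray:
    """Densely sample a piecewise-linear curve at roughly ``step`` voxels."""
    out = []
    for a, b in zip(points[:-1], points[1:]):
        seg_len = float(np.linalg.norm(b - a))
        n = max(int(np.ceil(seg_len / step)) + 1, 2)
        t = np.linspace(0.0, 1.0, n)[:, None]
        out.append(a + t * (b - a))
    return np.vstack(out)


def _scaled(points: np.ndarray, z_scale: float) -> np.ndarray:
    pts = points.copy()
    pts[:, 0] *= z_scale
    return pts


def _centerlines_voxels(cfg: PhantomConfig) -> dict[str, np.ndarray]:
    """Control points converted from fractional to voxel coordinates."""
    scale = np.asarray(cfg.shape, dtype=float) - 1.0
    return {
        lab: np.asarray(pts, dtype=float) * scale
        for lab, pts in cfg.centerlines.items()
    }


def _validate_separation(cfg: PhantomConfig, lines: dict[str, np.ndarray],
                         z_scale: float) -> None:
    """Tubes of segments that share no junction point must not touch."""
    sampled = {lab: _scaled(_sample_centerline(p), z_scale) for lab, p in lines.items()}
    endpoints = {
        lab: {tuple(np.round(p, 3)) for p in (pts[0], pts[-1])}
        for lab, pts in lines.items()
    }
    labs = list(lines)
    min_gap = 2.0 * cfg.tube_radius
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            if endpoints[a] & endpoints[b]:
                continue  # joined at a junction: contact allowed
            d = cKDTree(sampled[a]).query(sampled[b])[0].min()
            if d < min_gap:
                raise ValueError(
                    f"segment tubes {a!r} and {b!r} overlap "
                    f"(centerline gap {d:.2f} < {min_gap:.2f} voxels)"
                )


def _rasterize_regions(cfg: PhantomConfig) -> np.ndarray:
    """Assign each voxel within tube radius to its nearest segment centerline."""
    z_scale = cfg.tube_radius / cfg.tube_z_radius
    lines = _centerlines_voxels(cfg)
    _validate_separation(cfg, lines, z_scale)

    pts, ids = [], []
    for lab, ctrl in lines.items():
        s = _sample_centerline(ctrl)
        pts.append(s)
        ids.append(np.full(len(s), SEGMENT_LABELS.index(lab) + 1))
    pts = _scaled(np.vstack(pts), z_scale)
    ids = np.concatenate(ids)

    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) for n in cfg.shape),
                             indexing="ij")
    coords = np.stack([zz.ravel() * z_scale, yy.ravel(), xx.ravel()], axis=1)
    dist, idx = cKDTree(pts).query(coords)
    region = np.where(dist <= cfg.tube_radius, ids[idx], 0)
    return region.reshape(cfg.shape).astype(np.int16)


def _ellipsoid_voxels(shape, center, r_inplane, r_z):
    """Voxel indices inside an axis-aligned ellipsoid, clipped to the volume."""
    cz, cy, cx = center
    z0, z1 = max(int(np.floor(cz - r_z)), 0), min(int(np.ceil(cz + r_z)), shape[0] - 1)
    y0, y1 = max(int(np.floor(cy - r_inplane)), 0), min(int(np.ceil(cy + r_inplane)), shape[1] - 1)
    x0, x1 = max(int(np.floor(cx - r_inplane)), 0), min(int(np.ceil(cx + r_inplane)), shape[2] - 1)
    zz, yy, xx = np.meshgrid(np.arange(z0, z1 + 1), np.arange(y0, y1 + 1),
                             np.arange(x0, x1 + 1), indexing="ij")
    inside = (((zz - cz) / r_z) ** 2
              + ((yy - cy) / r_inplane) ** 2
              + ((xx - cx) / r_inplane) ** 2) <= 1.0
    return zz[inside], yy[inside], xx[inside]


def generate_phantom(config: PhantomConfig | None = None, seed: int = 0) -> PhantomCase:
    """Generate a seeded phantom case.

    Lesions are ellipsoids centred on the centerline of a (cyclically chosen)
    segment, mutually separated so that connected-component analysis recovers
    exactly the truth table. With ``zero_cac`` the calcification mask and the
    truth table are empty. Raises if a requested lesion cannot be placed
    without touching another one.
    """
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    region = _rasterize_regions(cfg)

    img = np.full(cfg.shape, cfg.background_hu, dtype=np.float64)
    # blood pool: central ellipsoid between the two vessel trees
    bz, by, bx = _ellipsoid_voxels(
        cfg.shape,
        ((cfg.shape[0] - 1) / 2, cfg.shape[1] * 0.45, cfg.shape[2] * 0.42),
        cfg.shape[1] * 0.18, cfg.shape[0] * 0.3,
    )
    img[bz, by, bx] = cfg.blood_pool_hu

    cac = np.zeros(cfg.shape, dtype=np.int16)
    z_scale = cfg.tube_radius / cfg.tube_z_radius
    lines = _centerlines_voxels(cfg)
    rows = []
    if not cfg.zero_cac:
        placed: list[tuple[np.ndarray, float]] = []
        order = [SEGMENT_LABELS[i % 13] for i in range(cfg.n_lesions)]
        for lesion_id, lab in enumerate(order, start=1):
            ctrl = lines[lab]
            ends_sc = [np.array([p[0] * z_scale, p[1], p[2]])
                       for p in (ctrl[0], ctrl[-1])]
            seg_len = float(np.linalg.norm(ends_sc[1] - ends_sc[0]))
            r = rng.uniform(*cfg.lesion_radius_range)
            rz = rng.uniform(*cfg.lesion_z_radius_range)
            # effective radius in the tube metric (z is scaled by z_scale)
            r_eff = max(r, rz * z_scale)
            margin = r_eff + 0.8  # keep clear of junctions with adjoining tubes
            if seg_len <= 2 * margin:
                raise RuntimeError(
                    f"lesion {lesion_id} (radius {r:.2f}) does not fit inside "
                    f"the {lab!r} segment tube"
                )
            hu = rng.uniform(*cfg.lesion_hu_range)
            for _ in range(200):
                t = rng.uniform(margin / seg_len, 1.0 - margin / seg_len)
                center = ctrl[0] + t * (ctrl[-1] - ctrl[0])
                c_sc = np.array([center[0] * z_scale, center[1], center[2]])
                ok = all(
                    np.linalg.norm(c_sc - p_sc) >= (r_eff + p_r + 2.0)
                    for p_sc, p_r in placed
                )
                if ok:
                    break
            else:
                raise RuntimeError(
                    f"could not place lesion {lesion_id} in segment {lab!r}: "
                    "segment tube too crowded for the requested lesion count"
                )
            placed.append((c_sc, r_eff))
            lz, ly, lx = _ellipsoid_voxels(cfg.shape, center, r, rz)
            if lz.size == 0:
                raise RuntimeError(f"lesion {lesion_id} does not fit inside the volume")
            cac[lz, ly, lx] = SEGMENT_LABELS.index(lab) + 1
            img[lz, ly, lx] = hu
            rows.append((lesion_id, lab, int(lz.size), float(hu),
                         float(lz.mean()), float(ly.mean()), float(lx.mean())))

    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=cfg.shape)
    # calcified voxels stay above the scoring threshold by construction
    les = cac > 0
    img[les] = np.maximum(img[les], CALCIUM_THRESHOLD_HU)
    img = np.clip(img, HU_MIN, HU_MAX)

    # refresh truth table values that noise may have changed
    table = pd.DataFrame(rows, columns=["lesion_id", "segment", "n_voxels",
                                        "peak_hu", "cz", "cy", "cx"])
    for i, row in table.iterrows():
        m = cac == SEGMENT_LABELS.index(row["segment"]) + 1
        # restrict to this lesion's component (segments may hold several lesions)
        comp, _ = ndimage.label(m, structure=np.ones((3, 3, 3)))
        cid = comp[int(round(row["cz"])), int(round(row["cy"])), int(round(row["cx"]))]
        sel = comp == cid
        table.loc[i, "peak_hu"] = float(img[sel].max())
        table.loc[i, "n_voxels"] = int(sel.sum())

    image = CTVolume(img, cfg.in_plane_spacing, cfg.slice_thickness)
    case = PhantomCase(image, LabelVolume(cac), LabelVolume(region), table, seed, cfg)
    _check_invariants(case)
    return case


def _check_invariants(case: PhantomCase) -> None:
    cac = case.cac_mask.voxels
    les = cac > 0
    if les.any():
        if case.image.voxels[les].min() < CALCIUM_THRESHOLD_HU:
            raise AssertionError("calcified voxel below 130 HU")
        region = case.region_mask.voxels
        if (region[les] == 0).any():
            raise AssertionError("region mask is not a superset of the CAC mask")
    n_comp = ndimage.label(les, structure=np.ones((3, 3, 3)))[1]
    if n_comp != len(case.lesion_table):
        raise AssertionError(
            f"{n_comp} connected components vs {len(case.lesion_table)} table rows"
        )


def degrade_with_noise(image: CTVolume, noise_sd: float, seed: int = 0) -> CTVolume:
    """Add seeded Gaussian HU noise; ``noise_sd=0`` returns the input volume."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return image
    rng = np.random.default_rng(seed)
    noisy = np.clip(image.voxels + rng.normal(0.0, noise_sd, image.shape),
                    HU_MIN, HU_MAX)
    return CTVolume(noisy, image.in_plane_spacing, image.slice_thickness)


def weak_region_annotation(
    region_mask: LabelVolume, subsample_fraction: float, seed: int = 0
) -> tuple[LabelVolume, np.ndarray]:
    """Keep region labels on a random subset of slices only.

    Emulates weak annotation where only a small fraction of image slices
    receives coronary-region labels. Returns the subsampled label volume and a
    boolean per-slice flag array (True = slice is annotated).
    """
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must lie in (0, 1]")
    n_slices = region_mask.shape[0]
    n_keep = max(int(round(subsample_fraction * n_slices)), 1)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n_slices, size=n_keep, replace=False))
    flags = np.zeros(n_slices, dtype=bool)
    flags[keep] = True
    out = np.zeros_like(region_mask.voxels)
    out[flags] = region_mask.voxels[flags]
    return LabelVolume(out), flags


# ---------------------------------------------------------------------------
# NIfTI I/O

def _affine(in_plane_spacing, slice_thickness) -> np.ndarray:
    sy, sx = in_plane_spacing
    return np.diag([sx, sy, slice_thickness, 1.0])


def write_volume(path: str | Path, voxels: np.ndarray, in_plane_spacing,
                 slice_thickness) -> None:
    """Write a (slice, row, column) array as NIfTI with correct voxel spacing."""
    data = np.asarray(voxels).transpose(2, 1, 0)  # -> (x, y, z)
    nib.save(nib.Nifti1Image(data, _affine(in_plane_spacing, slice_thickness)),
             str(path))


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI volume into a :class:`CTVolume`."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # noqa: BLE001 - surface filename in the error
        raise ValueError(f"cannot parse {path!r} as a NIfTI volume: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"{path!r}: expected a 3-D volume, got shape {data.shape}")
    # NIfTI zooms are float32; round to recover the written decimal spacing
    sx, sy, sz = (round(float(z), 5) for z in img.header.get_zooms()[:3])
    return CTVolume(data.transpose(2, 1, 0), (sy, sx), sz)


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI label volume (0 = background, 1-13 = segments)."""
    vol = read_volume(path)
    return LabelVolume(np.rint(vol.voxels).astype(np.int16))


def write_case(case: PhantomCase, directory: str | Path) -> dict[str, Path]:
    """Write a phantom case (image, masks, lesion table, metadata) to disk."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sp, st = case.image.in_plane_spacing, case.image.slice_thickness
    paths = {
        "image": d / "image.nii.gz",
        "cac_mask": d / "cac_mask.nii.gz",
        "region_mask": d / "region_mask.nii.gz",
        "lesions": d / "lesions.csv",
        "meta": d / "meta.json",
    }
    write_volume(paths["image"], case.image.voxels, sp, st)
    write_volume(paths["cac_mask"], case.cac_mask.voxels.astype(np.int16), sp, st)
    write_volume(paths["region_mask"], case.region_mask.voxels.astype(np.int16), sp, st)
    case.lesion_table.to_csv(paths["lesions"], index=False)
    paths["meta"].write_text(json.dumps(
        {"seed": case.seed, "slice_thickness": st, "in_plane_spacing": list(sp)},
        indent=2))
    return paths


def read_case(directory: str | Path) -> PhantomCase:
    """Read back a phantom case written by :func:`write_case`."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    return PhantomCase(
        image=read_volume(d / "image.nii.gz"),
        cac_mask=read_label_volume(d / "cac_mask.nii.gz"),
        region_mask=read_label_volume(d / "region_mask.nii.gz"),
        lesion_table=pd.read_csv(d / "lesions.csv"),
        seed=int(meta["seed"]),
    )
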