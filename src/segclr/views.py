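"""Segmentation-masked local 3D views and training augmentations.

A view is a cubic cutout of the intensity volume centered on a skeleton
node, masked by the segmentation of the segment at the center so that
surrounding context is excluded. Intensities are centered on the dataset
mean so that the masked-out fill value of zero is photometrically neutral.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import SegmentedVolume

FILL_VALUE = 0.0


@dataclass
class LocalView:
    intensity: np.ndarray          # (V, V, V) float32, fill outside mask
    mask: np.ndarray               # (V, V, V) bool, center-segment support
    center_xyz_nm: tuple[float, float, float]
    segment_id: int

    @property
    def view_size(self) -> int:
        return self.intensity.shape[0]

    def copy(self) -> "LocalView":
        return LocalView(self.intensity.copy(), self.mask.copy(),
                         self.center_xyz_nm, self.segment_id)


def extract_masked_view(volume: SegmentedVolume, center_xyz_nm,
                        segment_id: int, view_size: int = 129) -> LocalView:
    """Cut a ``view_size``-voxel cube around ``center_xyz_nm``, masked to
    the segment at the center.

    The center must fall on a voxel of ``segment_id``. Voxels belonging to
    other segments or background are set to the fill value; regions outside
    the volume are padded with the fill value and carry a false mask.
    """
    if not volume.in_bounds(center_xyz_nm):
        raise ValueError(f"center {center_xyz_nm} outside volume")
    cidx = volume.voxel_index(center_xyz_nm)
    actual = int(volume.segmentation[cidx])
    if actual != segment_id:
        raise ValueError(
            f"segment mismatch at center: expected {segment_id}, found {actual}")
    half = view_size // 2
    lo = [c - half for c in cidx]
    hi = [c + half + 1 for c in cidx]
    src_lo = [max(0, l) for l in lo]
    src_hi = [min(s, h) for s, h in zip(volume.shape, hi)]
    out_lo = [sl - l for sl, l in zip(src_lo, lo)]
    out_hi = [ol + (sh - sl) for ol, sl, sh in zip(out_lo, src_lo, src_hi)]
    intensity = np.full((view_size,) * 3, FILL_VALUE, dtype=np.float32)
    mask = np.zeros((view_size,) * 3, dtype=bool)
    src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    dst = tuple(slice(a, b) for a, b in zip(out_lo, out_hi))
    seg_win = volume.segmentation[src] == segment_id
    mask[dst] = seg_win
    # center intensities on the dataset mean so fill=0 is neutral
    vals = volume.intensity[src] - volume.intensity_mean
    intensity[dst] = np.where(seg_win, vals, FILL_VALUE)
    return LocalView(intensity, mask, tuple(float(c) for c in center_xyz_nm),
                     segment_id)


def _rot90_3d(a: np.ndarray, axis_pair: tuple[int, int], k: int) -> np.ndarray:
    return np.rot90(a, k=k, axes=axis_pair)


def augment(view: LocalView, seed: int, mode: str = "contrastive",
            brightness: float = 0.1, contrast: float = 0.1) -> LocalView:
    """Apply training augmentations.

    ``contrastive``: independent per-axis reflections (p=0.5 each) plus a
    photometric affine jitter of the masked-in intensities (brightness
    shift and contrast scaling); the mask itself is only reflected.
    ``supervised``: reflections plus axis-aligned 90-degree rotations, no
    photometric jitter. ``none``: identity.
    """
    if mode == "none":
        return view.copy()
    if mode not in ("contrastive", "supervised"):
        raise ValueError(f"unknown augmentation mode {mode!r}")
    rng = np.random.default_rng(seed)
    intensity = view.intensity.copy()
    mask = view.mask.copy()
    for ax in range(3):
        if rng.random() < 0.5:
            intensity = np.flip(intensity, axis=ax)
            mask = np.flip(mask, axis=ax)
    if mode == "supervised":
        for pair in ((0, 1), (0, 2), (1, 2)):
            k = int(rng.integers(0, 4))
            if k:
                intensity = _rot90_3d(intensity, pair, k)
                mask = _rot90_3d(mask, pair, k)
    else:
        delta = rng.uniform(-brightness, brightness)
        gamma = 1.0 + rng.uniform(-contrast, contrast)
        vals = intensity[mask]
        intensity[mask] = vals * gamma + delta
    return LocalView(np.ascontiguousarray(intensity),
                     np.ascontiguousarray(mask),
                     view.center_xyz_nm, view.segment_id)


def reflect(view: LocalView, axes: tuple[bool, bool, bool]) -> LocalView:
    """Deterministic per-axis reflection (used for involution checks)."""
    intensity, mask = view.intensity, view.mask
    for ax, flip in enumerate(axes):
        if flip:
            intensity = np.flip(intensity, axis=ax)
            mask = np.flip(mask, axis=ax)
    return LocalView(np.ascontiguousarray(intensity),
                     np.ascontiguousarray(mask),
                     view.center_xyz_nm, view.segment_id)


def views_to_batch(views: list[LocalView]) -> np.ndarray:
    """Stack views into an (N, 1, V, V, V) float32 network input batch."""
    return np.stack([v.intensity for v in views])[:, None].astype(np.float32)


def save_view_batch(views: list[LocalView], path) -> None:
    """Serialize a batch of views to HDF5 (datasets intensity/mask plus
    per-view center coordinates and segment ids)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("intensity",
                         data=np.stack([v.intensity for v in views]))
        f.create_dataset("mask", data=np.stack([v.mask for v in views]))
        f.create_dataset("center_xyz_nm",
                         data=np.array([v.center_xyz_nm for v in views]))
        f.create_dataset("segment_id",
                         data=np.array([v.segment_id for v in views],
                                       dtype=np.int64))


def load_view_batch(path) -> list[LocalView]:
    import h5py

    with h5py.File(path, "r") as f:
        intensity = f["intensity"][...]
        mask = f["mask"][...]
        centers = f["center_xyz_nm"][...]
        segs = f["segment_id"][...]
    return [LocalView(intensity[i], mask[i], tuple(centers[i]), int(segs[i]))
            for i in range(len(segs))]


def clahe_normalize(intensity: np.ndarray, kernel_size: int | None = None,
                    clip_limit: float = 0.01) -> np.ndarray:
    """Optional CLAHE pre-normalization hook for real intensity volumes."""
    from skimage import exposure

    return exposure.equalize_adapthist(intensity, kernel_size=kernel_size,
                                       clip_limit=clip_limit).astype(np.float32)
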