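"""Procedural generation of segmented volumes with ground truth.

The generator emulates the four inputs a segmentation-guided embedding
pipeline consumes from a real connectomic dataset: an intensity volume
with a dense instance segmentation, per-segment skeletons, label tables,
and a synapse table. Each "cell" is a persistent random-walk tube
(optionally branched) swept through the volume with a class-specific
radius regime and intensity texture; the generating centerline is kept as
the exact skeleton, so all geometric ground truth is known by
construction.

Voxels may be anisotropic (nm per voxel differs per axis); tube
rasterization honors this by sweeping per-axis-scaled ellipsoids.
Voxel collisions between cells resolve first-writer-wins and are counted.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage

from .skeleton import Skeleton


class PlacementError(RuntimeError):
    """Raised when a cell start point cannot be placed after bounded retries."""


@dataclass(frozen=True)
class TextureSpec:
    """Intra-segment intensity statistics: mean level, contrast (std of the
    fluctuation) and smoothness (Gaussian correlation length in voxels,
    i.e. inverse spatial frequency)."""
    mean: float
    contrast: float
    smoothness_vox: float


@dataclass(frozen=True)
class ClassSpec:
    name: str
    radius_range_nm: tuple[float, float]
    branch_rate_per_um: float
    texture: TextureSpec


def default_class_specs() -> tuple[ClassSpec, ...]:
    """Three morphologically and photometrically distinct cell classes:
    thin axon-like processes, mid-caliber dendrite-like processes, and
    wide irregular glia-like processes. Texture means are disjoint so a
    mean-intensity baseline can separate the classes."""
    return (
        ClassSpec("excitatory", (70.0, 150.0), 0.05,
                  TextureSpec(0.30, 0.06, 1.0)),
        ClassSpec("inhibitory", (170.0, 300.0), 0.08,
                  TextureSpec(0.55, 0.07, 2.0)),
        ClassSpec("glia", (120.0, 450.0), 0.12,
                  TextureSpec(0.80, 0.07, 3.0)),
    )


@dataclass(frozen=True)
class SynthConfig:
    volume_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_nm: tuple[float, float, float] = (32.0, 32.0, 33.0)
    n_cells: int = 12
    class_specs: tuple[ClassSpec, ...] = field(default_factory=default_class_specs)
    background_noise: float = 0.05
    background_mean: float = 0.1
    synapse_density_per_um: float = 0.5
    seed: int = 0
    # walk discretization
    step_nm: float = 64.0
    node_spacing_nm: float = 300.0
    target_length_nm: float = 25_000.0
    turn_sigma: float = 0.25
    radius_walk_sigma_nm: float = 12.0
    max_branches_per_cell: int = 3
    max_placement_tries: int = 200
    # node-level subcompartment labeling by local radius regime
    subcompartment_thresholds_nm: tuple[float, float] = (160.0, 320.0)
    subcompartment_names: tuple[str, str, str] = ("axon", "dendrite", "soma")

    def __post_init__(self):
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        for spec in self.class_specs:
            if spec.radius_range_nm[0] < min(self.voxel_size_nm):
                raise ValueError(
                    f"class {spec.name}: radius must be at least one voxel")


@dataclass
class SegmentedVolume:
    """Intensity + instance-ID arrays with nm-per-voxel resolution."""

    intensity: np.ndarray      # float32 in [0, 1]
    segmentation: np.ndarray   # uint32; 0 = background
    voxel_size_nm: tuple[float, float, float]

    def __post_init__(self):
        if self.intensity.shape != self.segmentation.shape:
            raise ValueError("intensity and segmentation shapes differ")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensity.shape

    @property
    def extent_nm(self) -> np.ndarray:
        return np.asarray(self.shape, float) * np.asarray(self.voxel_size_nm)

    def voxel_index(self, xyz_nm) -> tuple[int, int, int]:
        idx = np.floor(np.asarray(xyz_nm, float)
                       / np.asarray(self.voxel_size_nm)).astype(int)
        return tuple(int(i) for i in idx)

    def in_bounds(self, xyz_nm) -> bool:
        idx = self.voxel_index(xyz_nm)
        return all(0 <= i < s for i, s in zip(idx, self.shape))

    def segment_at(self, xyz_nm) -> int:
        return int(self.segmentation[self.voxel_index(xyz_nm)])

    @cached_property
    def intensity_mean(self) -> float:
        return float(self.intensity.mean())

    def voxel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.segmentation, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i != 0}


@dataclass
class LabelTable:
    """Cell-level class labels and node-level subcompartment labels."""

    cells: pd.DataFrame   # segment_id, class_name
    nodes: pd.DataFrame   # segment_id, node_id, subcompartment

    def __post_init__(self):
        if self.cells["segment_id"].duplicated().any():
            raise ValueError("duplicate segment_id in cell labels")

    def class_of(self, segment_id: int) -> str:
        row = self.cells.loc[self.cells.segment_id == segment_id, "class_name"]
        if row.empty:
            raise KeyError(f"segment {segment_id} has no label")
        return str(row.iloc[0])


@dataclass
class SynapseTable:
    table: pd.DataFrame  # synapse_id, pre_segment_id, post_segment_id, x, y, z

    def __len__(self):
        return len(self.table)


@dataclass
class SynthOutput:
    volume: SegmentedVolume
    skeletons: dict[int, Skeleton]
    labels: LabelTable
    synapses: SynapseTable
    config: SynthConfig
    n_collision_voxels: int = 0


# ---------------------------------------------------------------------------


def _smooth_noise(rng, shape, sigma) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def _stamp_ellipsoid(seg: np.ndarray, center_nm, radius_nm, voxel_size,
                     seg_id: int) -> int:
    """First-writer-wins stamp; returns number of collision voxels skipped."""
    vs = np.asarray(voxel_size, float)
    c_vox = np.asarray(center_nm, float) / vs
    r_vox = np.maximum(radius_nm / vs, 1.0)
    lo = np.maximum(np.floor(c_vox - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + r_vox).astype(int) + 1,
                    np.asarray(seg.shape))
    if np.any(lo >= hi):
        return 0
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    dist2 = sum(((g + 0.5 - c) / r) ** 2
                for g, c, r in zip(grids, c_vox, r_vox))
    ball = dist2 <= 1.0
    sub = seg[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    collisions = int(np.count_nonzero(ball & (sub != 0) & (sub != seg_id)))
    sub[ball & (sub == 0)] = seg_id
    return collisions


def _region_free(seg, pos_nm, radius_nm, vs, seg_id) -> bool:
    """Probe the center and six axis poles of the sphere at ``pos_nm``;
    free means background or already owned by this segment."""
    shape = np.asarray(seg.shape)
    probes = [pos_nm]
    for ax in range(3):
        for sgn in (-1.0, 1.0):
            p = np.array(pos_nm, float)
            p[ax] += sgn * radius_nm
            probes.append(p)
    for p in probes:
        idx = np.floor(p / vs).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            return False
        owner = seg[tuple(idx)]
        if owner != 0 and owner != seg_id:
            return False
    return True


def _reflect(pos, direction, lo, hi):
    for ax in range(3):
        if pos[ax] < lo[ax]:
            pos[ax] = 2 * lo[ax] - pos[ax]
            direction[ax] = abs(direction[ax])
        elif pos[ax] > hi[ax]:
            pos[ax] = 2 * hi[ax] - pos[ax]
            direction[ax] = -abs(direction[ax])
    return pos, direction


def _grow_cell(rng, seg, config: SynthConfig, spec: ClassSpec, seg_id: int):
    """Random-walk tube growth; returns (nodes, edges, radii, collisions)."""
    vs = np.asarray(config.voxel_size_nm)
    extent = np.asarray(config.volume_shape) * vs
    r_lo, r_hi = spec.radius_range_nm
    margin = r_hi + 2 * vs.max()
    lo, hi = np.full(3, margin), extent - margin
    if np.any(lo >= hi):
        raise PlacementError("volume too small for cell radius margin")

    start = None
    r_start = rng.uniform(r_lo, r_hi)
    for _ in range(config.max_placement_tries):
        cand = rng.uniform(lo, hi)
        if _region_free(seg, cand, r_start, vs, seg_id):
            start = cand
            break
    if start is None:
        raise PlacementError(
            f"could not place cell {seg_id} after "
            f"{config.max_placement_tries} tries")

    nodes: dict[int, tuple[float, float, float]] = {}
    edges: list[tuple[int, int]] = []
    radii: dict[int, float] = {}
    collisions = 0
    next_id = 0
    node_every = max(1, int(round(config.node_spacing_nm / config.step_nm)))

    def new_node(pos, radius):
        nonlocal next_id
        nid = next_id
        next_id += 1
        nodes[nid] = tuple(pos)
        radii[nid] = float(radius)
        return nid

    # queue of branches: (position, direction, radius, remaining length, parent node)
    d0 = rng.standard_normal(3)
    d0 /= np.linalg.norm(d0)
    branch_budget = config.max_branches_per_cell
    queue = [(start.copy(), d0, r_start, config.target_length_nm, None)]
    while queue:
        pos, direction, radius, remaining, parent = queue.pop(0)
        last_node = parent if parent is not None else new_node(pos, radius)
        collisions += _stamp_ellipsoid(seg, pos, radius, vs, seg_id)
        steps_since_node = 0
        while remaining > 0:
            # steer away from other cells: retry the step with fresh
            # directions; give up on this branch when boxed in
            stepped = False
            cand_dir = direction + config.turn_sigma * rng.standard_normal(3)
            for attempt in range(8):
                cand_dir /= np.linalg.norm(cand_dir)
                cand_pos = pos + cand_dir * config.step_nm
                cand_pos, cand_dir = _reflect(cand_pos, cand_dir, lo, hi)
                if _region_free(seg, cand_pos, radius, vs, seg_id):
                    stepped = True
                    break
                cand_dir = rng.standard_normal(3)
            if not stepped:
                break
            pos, direction = cand_pos, cand_dir
            radius = float(np.clip(
                radius + config.radius_walk_sigma_nm * rng.standard_normal(),
                r_lo, r_hi))
            collisions += _stamp_ellipsoid(seg, pos, radius, vs, seg_id)
            remaining -= config.step_nm
            steps_since_node += 1
            if steps_since_node >= node_every:
                nid = new_node(pos, radius)
                edges.append((last_node, nid))
                last_node = nid
                steps_since_node = 0
            if (branch_budget > 0 and remaining > 4 * config.node_spacing_nm
                    and rng.random() < spec.branch_rate_per_um
                    * config.step_nm / 1000.0):
                branch_budget -= 1
                bdir = direction + rng.standard_normal(3)
                bdir /= np.linalg.norm(bdir)
                queue.append((pos.copy(), bdir, radius, remaining * 0.5,
                              last_node))
    return nodes, edges, radii, collisions


def _place_synapses(rng, volume: SegmentedVolume, skeletons, config: SynthConfig):
    """Sample synapse points where two segments lie within 2 voxels."""
    rows = []
    seg = volume.segmentation
    vs = np.asarray(config.voxel_size_nm)
    struct = ndimage.generate_binary_structure(3, 1)
    next_id = 0
    for seg_id in sorted(skeletons):
        mask = seg == seg_id
        if not mask.any():
            continue
        dil = ndimage.binary_dilation(mask, structure=struct, iterations=2)
        contact = dil & (seg != 0) & ~mask
        coords = np.argwhere(contact)
        if len(coords) == 0:
            continue
        length_um = skeletons[seg_id].total_path_length() / 1000.0
        n_syn = min(len(coords),
                    rng.poisson(config.synapse_density_per_um * length_um))
        if n_syn == 0:
            continue
        pick = rng.choice(len(coords), size=n_syn, replace=False)
        for idx in pick:
            v = coords[idx]
            post = int(seg[tuple(v)])
            xyz = (v + 0.5) * vs
            rows.append((next_id, seg_id, post, *xyz))
            next_id += 1
    df = pd.DataFrame(rows, columns=["synapse_id", "pre_segment_id",
                                     "post_segment_id", "x", "y", "z"])
    return SynapseTable(df)


def _subcompartment(radius_nm: float, config: SynthConfig) -> str:
    t1, t2 = config.subcompartment_thresholds_nm
    names = config.subcompartment_names
    if radius_nm < t1:
        return names[0]
    if radius_nm < t2:
        return names[1]
    return names[2]


def generate(config: SynthConfig) -> SynthOutput:
    """Generate a segmented volume, skeletons, labels and synapses.

    Fully determined by ``config.seed``: the same config yields
    bit-identical arrays and tables.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.volume_shape)
    seg = np.zeros(shape, dtype=np.uint32)

    skeletons: dict[int, Skeleton] = {}
    cell_rows = []
    node_rows = []
    total_collisions = 0
    specs = config.class_specs
    for i in range(config.n_cells):
        spec = specs[i % len(specs)]
        seg_id = i + 1
        nodes, edges, radii, coll = _grow_cell(rng, seg, config, spec, seg_id)
        total_collisions += coll
        skeletons[seg_id] = Skeleton(seg_id, nodes, edges, radii)
        cell_rows.append((seg_id, spec.name))
        for nid, r in radii.items():
            node_rows.append((seg_id, nid, _subcompartment(r, config)))

    # intensity: per-class texture inside segments, noise background
    intensity = np.clip(config.background_mean + config.background_noise
                        * _smooth_noise(rng, shape, 1.0), 0.0, 1.0)
    class_of = {sid: name for sid, name in cell_rows}
    for spec in specs:
        members = [sid for sid, name in cell_rows if name == spec.name]
        if not members:
            continue
        tex = np.clip(spec.texture.mean + spec.texture.contrast
                      * _smooth_noise(rng, shape, spec.texture.smoothness_vox),
                      0.0, 1.0)
        mask = np.isin(seg, members)
        intensity[mask] = tex[mask]

    volume = SegmentedVolume(intensity.astype(np.float32), seg,
                             tuple(config.voxel_size_nm))
    labels = LabelTable(
        cells=pd.DataFrame(cell_rows, columns=["segment_id", "class_name"]),
        nodes=pd.DataFrame(node_rows,
                           columns=["segment_id", "node_id", "subcompartment"]))
    synapses = _place_synapses(rng, volume, skeletons, config)
    return SynthOutput(volume, skeletons, labels, synapses, config,
                       total_collisions)


def merge_segments(output: SynthOutput, keep_id: int, merge_id: int) -> SynthOutput:
    """Relabel ``merge_id`` as ``keep_id``, emulating a segmentation merge
    error; the skeletons are joined by an edge between their closest nodes.
    Used to construct out-of-distribution fixtures."""
    seg = output.volume.segmentation.copy()
    seg[seg == merge_id] = keep_id
    volume = SegmentedVolume(output.volume.intensity.copy(), seg,
                             output.volume.voxel_size_nm)
    sk_a, sk_b = output.skeletons[keep_id], output.skeletons[merge_id]
    offset = max(sk_a.node_ids) + 1
    nodes = {nid: tuple(sk_a.coords(nid)) for nid in sk_a.node_ids}
    radii = dict(sk_a.radii)
    edges = [(a, b) for a, b in sk_a.graph.edges]
    for nid in sk_b.node_ids:
        nodes[nid + offset] = tuple(sk_b.coords(nid))
        radii[nid + offset] = sk_b.radii.get(nid, 0.0)
    edges += [(a + offset, b + offset) for a, b in sk_b.graph.edges]
    # bridge at the closest node pair
    a_ids = sk_a.node_ids
    b_ids = sk_b.node_ids
    pa = sk_a.coords_array(a_ids)
    pb = sk_b.coords_array(b_ids)
    d2 = ((pa[:, None] - pb[None]) ** 2).sum(-1)
    ia, ib = np.unravel_index(np.argmin(d2), d2.shape)
    edges.append((a_ids[ia], b_ids[ib] + offset))
    skeletons = {sid: sk for sid, sk in output.skeletons.items()
                 if sid != merge_id}
    skeletons[keep_id] = Skeleton(keep_id, nodes, edges, radii)
    labels = LabelTable(
        cells=output.labels.cells[output.labels.cells.segment_id != merge_id]
        .reset_index(drop=True),
        nodes=output.labels.nodes[output.labels.nodes.segment_id != merge_id]
        .reset_index(drop=True))
    return SynthOutput(volume, skeletons, labels, output.synapses,
                       output.config, output.n_collision_voxels)


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixtures(output: SynthOutput, directory: str | Path) -> dict:
    """Write volume (HDF5), skeletons (SWC), tables (TSV) and a manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    vol_path = d / "volume.h5"
    with h5py.File(vol_path, "w") as f:
        f.create_dataset("intensity", data=output.volume.intensity)
        f.create_dataset("segmentation", data=output.volume.segmentation)
        f.attrs["voxel_size_nm"] = list(output.volume.voxel_size_nm)
    skel_dir = d / "skeletons"
    skel_dir.mkdir(exist_ok=True)
    skel_paths = {}
    for sid, sk in output.skeletons.items():
        p = skel_dir / f"{sid}.swc"
        sk.to_swc(p)
        skel_paths[str(sid)] = str(p.relative_to(d))
    output.labels.cells.to_csv(d / "labels_cells.tsv", sep="\t", index=False)
    output.labels.nodes.to_csv(d / "labels_nodes.tsv", sep="\t", index=False)
    output.synapses.table.to_csv(d / "synapses.tsv", sep="\t", index=False)
    manifest = {
        "seed": output.config.seed,
        "n_cells": output.config.n_cells,
        "volume": "volume.h5",
        "skeletons": skel_paths,
        "labels_cells": "labels_cells.tsv",
        "labels_nodes": "labels_nodes.tsv",
        "synapses": "synapses.tsv",
        "n_collision_voxels": output.n_collision_voxels,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_volume(path: str | Path) -> SegmentedVolume:
    with h5py.File(path, "r") as f:
        return SegmentedVolume(f["intensity"][...], f["segmentation"][...],
                               tuple(float(v) for v in f.attrs["voxel_size_nm"]))


def read_fixtures(directory: str | Path):
    """Round-trip reader for :func:`write_fixtures` output."""
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    volume = read_volume(d / manifest["volume"])
    skeletons = {int(sid): Skeleton.from_swc(d / rel)
                 for sid, rel in manifest["skeletons"].items()}
    labels = LabelTable(
        cells=pd.read_csv(d / manifest["labels_cells"], sep="\t"),
        nodes=pd.read_csv(d / manifest["labels_nodes"], sep="\t"))
    synapses = SynapseTable(pd.read_csv(d / manifest["synapses"], sep="\t"))
    return volume, skeletons, labels, synapses, manifest
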