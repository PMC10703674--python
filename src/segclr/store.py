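"""Embedding inference, storage, lookup and radius aggregation.

Embeddings are computed at skeleton nodes resampled to ~1,500 nm path
spacing and stored keyed by (segment_id, x, y, z nm). Downstream tasks
aggregate them by taking the per-dimension mean over all embedding nodes
within a path-length radius R of a center node on the segment's own
skeleton; the distance to the furthest contributing node (R_max) is kept
as a fragment-size proxy.

The on-disk format mirrors the released sharded-CSV layout: plain rows
``segment_id,x,y,z,e0,...,e63`` split into shards by a hash of the
segment id, optionally zipped.
"""
from __future__ import annotations

import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contrastive import embed_views
from .nn import Encoder
from .skeleton import Skeleton
from .synth import SegmentedVolume
from .views import extract_masked_view, views_to_batch

DEFAULT_SPACING_NM = 1500.0
DEFAULT_MIN_VOXELS = 1000


@dataclass(frozen=True)
class AggregatedEmbedding:
    segment_id: int
    center_node_id: int
    center_xyz_nm: tuple[float, float, float]
    r_nm: float
    mean_vector: np.ndarray
    n_nodes: int
    r_max_nm: float


class EmbeddingStore:
    """Rows of 64-d embeddings keyed by (segment_id, x, y, z nm)."""

    def __init__(self, dim: int = 64):
        self.dim = dim
        self._frames: list[pd.DataFrame] = []
        self._df: pd.DataFrame | None = None
        # (segment_id -> {node_id -> row index}) when rows come from skeleton nodes
        self.node_index: dict[int, dict[int, int]] = {}

    # -- construction ------------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return ["segment_id", "x", "y", "z"] + [f"e{i}" for i in range(self.dim)]

    def add_rows(self, segment_id: int, xyz_nm: np.ndarray,
                 embeddings: np.ndarray,
                 node_ids: list[int] | None = None) -> None:
        xyz = np.asarray(xyz_nm, dtype=float).reshape(-1, 3)
        emb = np.asarray(embeddings, dtype=np.float32).reshape(-1, self.dim)
        if len(xyz) != len(emb):
            raise ValueError("coordinate/embedding row mismatch")
        if not np.isfinite(emb).all():
            raise ValueError("non-finite embedding values")
        start = sum(len(f) for f in self._frames)
        df = pd.DataFrame(
            np.column_stack([np.full(len(xyz), segment_id), xyz, emb]),
            columns=self.columns)
        df["segment_id"] = df["segment_id"].astype(np.int64)
        self._frames.append(df)
        self._df = None
        if node_ids is not None:
            idx = self.node_index.setdefault(int(segment_id), {})
            for offset, nid in enumerate(node_ids):
                idx[int(nid)] = start + offset

    @property
    def frame(self) -> pd.DataFrame:
        if self._df is None:
            if self._frames:
                self._df = pd.concat(self._frames, ignore_index=True)
            else:
                self._df = pd.DataFrame(columns=self.columns)
        return self._df

    def __len__(self) -> int:
        return sum(len(f) for f in self._frames)

    @property
    def segment_ids(self) -> list[int]:
        if not len(self):
            return []
        return sorted(self.frame.segment_id.unique().tolist())

    def rows_for_segment(self, segment_id: int) -> pd.DataFrame:
        df = self.frame
        return df[df.segment_id == segment_id]

    def vectors(self, rows: pd.DataFrame) -> np.ndarray:
        return rows[[f"e{i}" for i in range(self.dim)]].to_numpy(np.float32)

    # -- lookup ------------------------------------------------------------
    def nearest_node(self, xyz_nm, segment_id: int) -> pd.Series:
        """Row of ``segment_id`` closest (Euclidean) to ``xyz_nm``.

        Exact ties are broken toward lexicographically smaller (x, y, z).
        """
        rows = self.rows_for_segment(segment_id)
        if rows.empty:
            raise KeyError(f"segment {segment_id} absent from store")
        p = np.asarray(xyz_nm, dtype=float)
        coords = rows[["x", "y", "z"]].to_numpy(float)
        d2 = ((coords - p) ** 2).sum(axis=1)
        best = d2 == d2.min()
        cand = rows[best].sort_values(["x", "y", "z"], kind="mergesort")
        return cand.iloc[0]

    def embedding_of_node(self, segment_id: int, node_id: int) -> np.ndarray:
        idx = self.node_index.get(segment_id, {})
        if node_id not in idx:
            raise KeyError(f"no embedding row for node {node_id} "
                           f"of segment {segment_id}")
        return self.vectors(self.frame.iloc[[idx[node_id]]])[0]

    # -- aggregation -------------------------------------------------------
    def aggregate(self, skeleton: Skeleton, center_node: int,
                  r_nm: float) -> AggregatedEmbedding:
        """Per-dimension mean over embedding rows within path radius R.

        Only rows of the segment's own skeleton contribute; R_max is the
        path distance of the furthest contributing row.
        """
        seg = skeleton.segment_id
        idx = self.node_index.get(seg, {})
        if center_node not in idx:
            raise KeyError(f"center node {center_node} has no embedding row")
        window = skeleton.nodes_within_radius(center_node, r_nm)
        rows = [(nid, idx[nid]) for nid in sorted(window.collected_node_ids)
                if nid in idx]
        vecs = self.vectors(self.frame.iloc[[i for _, i in rows]])
        r_max = max(window.distances[nid] for nid, _ in rows)
        return AggregatedEmbedding(
            segment_id=seg, center_node_id=center_node,
            center_xyz_nm=tuple(skeleton.coords(center_node)),
            r_nm=float(r_nm), mean_vector=vecs.mean(axis=0),
            n_nodes=len(rows), r_max_nm=float(r_max))

    # -- persistence -------------------------------------------------------
    def to_csv_shards(self, directory: str | Path, n_shards: int = 4,
                      zipped: bool = False) -> list[Path]:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        df = self.frame
        shard_of = df.segment_id.astype(np.int64) % n_shards
        paths = []
        for s in range(n_shards):
            part = df[shard_of == s]
            p = d / f"shard_{s:04d}.csv"
            part.to_csv(p, index=False, float_format="%.8g")
            if zipped:
                zp = p.with_suffix(".csv.zip")
                with zipfile.ZipFile(zp, "w", zipfile.ZIP_DEFLATED) as zf:
                    zf.write(p, p.name)
                p.unlink()
                p = zp
            paths.append(p)
        return paths

    @classmethod
    def from_csv_shards(cls, directory: str | Path) -> "EmbeddingStore":
        d = Path(directory)
        frames = []
        for p in sorted(d.glob("shard_*.csv")) + sorted(d.glob("shard_*.csv.zip")):
            if p.suffix == ".zip":
                with zipfile.ZipFile(p) as zf:
                    with zf.open(zf.namelist()[0]) as fh:
                        frames.append(pd.read_csv(fh))
            else:
                frames.append(pd.read_csv(p))
        frames = [f for f in frames if not f.empty]
        df = pd.concat(frames, ignore_index=True) if frames else None
        if df is None or df.empty:
            return cls()
        dim = sum(c.startswith("e") for c in df.columns)
        store = cls(dim=dim)
        for seg, part in df.groupby("segment_id", sort=True):
            store.add_rows(int(seg), part[["x", "y", "z"]].to_numpy(float),
                           part[[f"e{i}" for i in range(dim)]].to_numpy(np.float32))
        return store


def infer_all(encoder: Encoder, volume: SegmentedVolume,
              skeletons: dict[int, Skeleton],
              spacing_nm: float = DEFAULT_SPACING_NM,
              min_voxels: int = DEFAULT_MIN_VOXELS,
              batch_size: int = 16) -> EmbeddingStore:
    """Embed every resampled skeleton node of every non-trivial segment.

    Segments smaller than ``min_voxels`` voxels are skipped entirely.
    Deterministic given the encoder checkpoint.
    """
    if not skeletons:
        raise ValueError("empty skeleton set")
    counts = volume.voxel_counts()
    store = EmbeddingStore(dim=encoder.config.embedding_dim)
    view_size = encoder.config.view_size
    for sid in sorted(skeletons):
        if counts.get(sid, 0) < min_voxels:
            continue
        sk = skeletons[sid]
        node_ids = sk.resample_nodes(spacing_nm)
        views = [extract_masked_view(volume, sk.coords(nid), sid, view_size)
                 for nid in node_ids]
        emb = embed_views(encoder, views_to_batch(views), batch_size=batch_size)
        store.add_rows(sid, sk.coords_array(node_ids), emb, node_ids=node_ids)
    return store
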