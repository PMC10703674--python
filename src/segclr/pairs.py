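"""Positive-pair sampling for contrastive training.

Positive pairs are two skeleton nodes of the same segment separated by at
most 150 um of skeleton path length. Because long distances admit many
more pairs, candidate pairs are pre-sorted into four path-length buckets
with boundaries 0, 2,500, 10,000, 30,000 and 150,000 nm; at sampling time
a bucket is drawn uniformly among the segment's non-empty buckets, then a
pair uniformly within the bucket. Negatives are implicit: the other
examples in a batch, which are drawn from distinct segments.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeleton import Skeleton

BUCKET_EDGES_NM = (0.0, 2500.0, 10_000.0, 30_000.0, 150_000.0)
MAX_PAIR_DISTANCE_NM = BUCKET_EDGES_NM[-1]
N_BUCKETS = len(BUCKET_EDGES_NM) - 1


@dataclass(frozen=True)
class PositivePair:
    segment_id: int
    node_a: int
    node_b: int
    path_length_nm: float
    bucket_index: int


def bucket_of(distance_nm: float) -> int | None:
    """Bucket index for a positive-pair distance; half-open (lo, hi].

    Distance 0 (the same node) and distances beyond 150 um are excluded.
    """
    if distance_nm <= 0 or distance_nm > MAX_PAIR_DISTANCE_NM:
        return None
    for k in range(N_BUCKETS):
        if BUCKET_EDGES_NM[k] < distance_nm <= BUCKET_EDGES_NM[k + 1]:
            return k
    return None


def enumerate_pairs(skeleton: Skeleton) -> list[list[PositivePair]]:
    """All unordered same-segment node pairs within 150 um, per bucket."""
    pools: list[list[PositivePair]] = [[] for _ in range(N_BUCKETS)]
    for a in skeleton.node_ids:
        dists = skeleton.distances_from(a, cutoff=MAX_PAIR_DISTANCE_NM)
        for b, d in dists.items():
            if b <= a:
                continue  # dedup unordered (a, b) == (b, a)
            k = bucket_of(d)
            if k is not None:
                pools[k].append(PositivePair(skeleton.segment_id, a, b,
                                             float(d), k))
    return pools


class PairPools:
    """Per-segment bucket pools with uniform bucket-then-pair sampling."""

    def __init__(self, pools_by_segment: dict[int, list[list[PositivePair]]]):
        # keep only segments that have at least one candidate pair
        self.pools = {sid: pools for sid, pools in pools_by_segment.items()
                      if any(len(p) for p in pools)}

    @classmethod
    def from_skeletons(cls, skeletons: dict[int, Skeleton]) -> "PairPools":
        return cls({sid: enumerate_pairs(sk) for sid, sk in skeletons.items()})

    @property
    def segment_ids(self) -> list[int]:
        return sorted(self.pools)

    def sample_pair(self, segment_id: int, rng: np.random.Generator) -> PositivePair:
        pools = self.pools[segment_id]
        nonempty = [k for k in range(N_BUCKETS) if pools[k]]
        k = nonempty[rng.integers(len(nonempty))]
        return pools[k][rng.integers(len(pools[k]))]

    def sample_batch(self, n_pairs: int, seed: int) -> list[PositivePair]:
        """Draw ``n_pairs`` positive pairs from distinct segments.

        Segments are drawn without replacement so that each batch's
        negatives come from other segments; raises when fewer eligible
        segments than pairs are requested.
        """
        rng = np.random.default_rng(seed)
        segs = self.segment_ids
        if n_pairs > len(segs):
            raise ValueError(
                f"requested {n_pairs} pairs but only {len(segs)} segments "
                "have candidate pairs")
        chosen = rng.choice(len(segs), size=n_pairs, replace=False)
        return [self.sample_pair(segs[i], rng) for i in chosen]

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [(p.segment_id, p.node_a, p.node_b, p.path_length_nm,
                 p.bucket_index)
                for pools in self.pools.values()
                for bucket in pools for p in bucket]
        return pd.DataFrame(rows, columns=["segment_id", "node_a", "node_b",
                                           "distance_nm", "bucket"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PairPools":
        df = pd.read_csv(path, sep="\t")
        pools: dict[int, list[list[PositivePair]]] = {}
        for row in df.itertuples(index=False):
            seg = pools.setdefault(int(row.segment_id),
                                   [[] for _ in range(N_BUCKETS)])
            seg[int(row.bucket)].append(PositivePair(
                int(row.segment_id), int(row.node_a), int(row.node_b),
                float(row.distance_nm), int(row.bucket)))
        return cls(pools)
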