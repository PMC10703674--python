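"""Shared fixtures: one synthetic world and one trained toy encoder are
built once per session and reused by the heavier integration tests."""
from __future__ import annotations

import numpy as np
import pytest

from segclr import (EncoderConfig, LossConfig, PairPools, SynthConfig,
                    build_encoder, generate, infer_all, train)

WORLD_SEED = 1
TRAIN_SEED = 0
TOY_TRAIN_STEPS = 200
AGG_RADIUS_NM = 5000.0


@pytest.fixture(scope="session")
def world():
    """Default 3-class 128^3 synthetic volume with skeletons and tables."""
    return generate(SynthConfig(seed=WORLD_SEED))


@pytest.fixture(scope="session")
def pair_pools(world):
    return PairPools.from_skeletons(world.skeletons)


@pytest.fixture(scope="session")
def trained_encoder(world, pair_pools):
    encoder, _ = build_encoder(EncoderConfig.toy(), seed=TRAIN_SEED)
    train(pair_pools, world.volume, world.skeletons, encoder,
          LossConfig(batch_pairs=8), steps=TOY_TRAIN_STEPS, seed=TRAIN_SEED)
    return encoder


@pytest.fixture(scope="session")
def emb_store(world, trained_encoder):
    return infer_all(trained_encoder, world.volume, world.skeletons)


@pytest.fixture(scope="session")
def aggregated(world, emb_store):
    """Aggregated embeddings at R=5 um for every embedded node, with
    cell-class labels and segment ids."""
    lab = dict(zip(world.labels.cells.segment_id, world.labels.cells.class_name))
    x, y, segs, nodes = [], [], [], []
    for sid in emb_store.segment_ids:
        sk = world.skeletons[sid]
        for node in sorted(emb_store.node_index[sid]):
            agg = emb_store.aggregate(sk, node, AGG_RADIUS_NM)
            x.append(agg.mean_vector)
            y.append(lab[sid])
            segs.append(sid)
            nodes.append(node)
    return {"x": np.array(x), "y": np.array(y), "segment": np.array(segs),
            "node": np.array(nodes)}


def random_tree_skeleton(rng: np.random.Generator, n_nodes: int,
                         segment_id: int = 1, scale_nm: float = 2000.0):
    """Random tree skeleton used by geometry-oracle tests: each node
    attaches to a random earlier node with a random offset."""
    from segclr import Skeleton

    nodes = {0: tuple(rng.uniform(0, scale_nm, 3))}
    edges = []
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        offset = rng.uniform(-scale_nm, scale_nm, 3)
        while np.linalg.norm(offset) < 1.0:
            offset = rng.uniform(-scale_nm, scale_nm, 3)
        nodes[i] = tuple(np.asarray(nodes[parent]) + offset)
        edges.append((parent, i))
    return Skeleton(segment_id, nodes, edges)


def scipy_shortest_paths(skeleton):
    """Independent all-pairs path-length oracle via scipy's Dijkstra."""
    import numpy as np
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import dijkstra

    ids = skeleton.node_ids
    pos = {n: i for i, n in enumerate(ids)}
    m = lil_matrix((len(ids), len(ids)))
    for a, b, data in skeleton.graph.edges(data=True):
        m[pos[a], pos[b]] = data["weight"]
        m[pos[b], pos[a]] = data["weight"]
    dist = dijkstra(m.tocsr(), directed=False)
    return ids, np.asarray(dist)
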