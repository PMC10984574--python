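import warnings

import numpy as np
import pytest

import asrtnet as a


@pytest.fixture
def design():
    return a.AsrtDesign()


@pytest.fixture
def default_stream(design):
    return a.generate_asrt_sequence(design, seed=11)


@pytest.fixture
def small_recording():
    """8-channel theta-coupled recording, 6 segments of 2 s."""
    net = a.generate_planted_network("erdos_renyi", n_nodes=8, density=0.3, seed=5)
    return a.synthesize_coupled_recording(net, n_segments=6, seed=6)


@pytest.fixture
def quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def brute_force_triplet_labels(directions, blocks, pattern):
    """Independent window enumerator for triplet probability labels."""
    succ = {pattern[i]: pattern[(i + 1) % 4] for i in range(4)}
    out = []
    for t in range(len(directions)):
        if t < 2 or blocks[t] != blocks[t - 2]:
            out.append(None)
        elif succ[directions[t - 2]] == directions[t]:
            out.append("high")
        else:
            out.append("low")
    return out


def brute_force_clustering(adj):
    """Triangle enumeration oracle for local clustering."""
    n = adj.shape[0]
    cs = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            adj[u, v] for ai, u in enumerate(nbrs) for v in nbrs[ai + 1 :]
        )
        cs[i] = 2.0 * links / (k * (k - 1))
    return cs


def floyd_warshall_L(adj):
    """Floyd-Warshall oracle for characteristic path length (finite pairs)."""
    n = adj.shape[0]
    inf = float("inf")
    dist = [[0 if i == j else (1 if adj[i, j] else inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    finite = [dist[i][j] for i in range(n) for j in range(n) if i != j and dist[i][j] < inf]
    return (sum(finite) / len(finite)) if finite else float("nan")
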