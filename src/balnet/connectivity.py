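"""Construction of the four-population network from parameters and a seed.

The realized synapses are stored as outgoing adjacency in CSR layout over
global neuron ids g = population * N + index (populations ordered
E1, I1, E2, I2): ``targets[indptr[g]:indptr[g+1]]`` are the postsynaptic
global ids of source neuron g and ``weights`` the corresponding synaptic
strengths.  Simulation propagates state flips forward along these lists.

Within-subnetwork synapses exist with probability K/N and have strength
+1/sqrt(K) from excitatory neurons and -J_E/sqrt(K) (onto E) or
-J_I/sqrt(K) (onto I) from inhibitory ones.  Self-connections are excluded.
All-to-all cross inhibition (strength -J~*sqrt(K)/N from every inhibitory
neuron to every excitatory neuron of the other subnetwork) is never
materialized: it is exact given the opposing population count and is applied
implicitly by the simulator.  In sparse cross mode the cross synapses are
realized explicitly with probability K/N and strength -J~/sqrt(K).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .params import NetworkParams

__all__ = ["Connectivity", "build_connectivity", "cross_input_weight"]

_ROW_CHUNK = 4096  # rows of the Bernoulli block sampled at once


@dataclass
class Connectivity:
    """Realized synapses of the four-population network (outgoing CSR)."""

    params: NetworkParams
    indptr: np.ndarray          # int64, length 4N+1
    targets: np.ndarray         # int32 global ids
    weights: np.ndarray         # float64

    @property
    def N(self) -> int:
        return self.params.N

    @property
    def n_neurons(self) -> int:
        return 4 * self.params.N

    def out_degree(self) -> np.ndarray:
        return np.diff(self.indptr)

    def synapses_of(self, population: int, index: int) -> Tuple[np.ndarray, np.ndarray]:
        """(targets, weights) of one source neuron."""
        g = population * self.N + index
        s, e = self.indptr[g], self.indptr[g + 1]
        return self.targets[s:e], self.weights[s:e]

    def in_degree_matrix(self) -> np.ndarray:
        """Realized mean in-degree per (target population, source population).

        Excludes the implicit all-to-all cross coupling.
        """
        N = self.N
        out = np.zeros((4, 4))
        src_pop = np.repeat(np.arange(4), np.add.reduceat(
            np.diff(self.indptr), np.arange(0, 4 * N, N)))
        tgt_pop = self.targets // N
        for sp in range(4):
            sel = src_pop == sp
            counts = np.bincount(tgt_pop[sel], minlength=4)
            out[:, sp] = counts / N
        return out

    def to_sparse(self):
        """scipy.sparse CSR matrix W with W[source, target] = weight."""
        from scipy.sparse import csr_matrix

        n = self.n_neurons
        return csr_matrix((self.weights, self.targets, self.indptr), shape=(n, n))

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        """Write arrays to an .npz container with a text manifest alongside."""
        path = Path(path)
        np.savez_compressed(path, indptr=self.indptr, targets=self.targets,
                            weights=self.weights)
        manifest = path.with_suffix(".manifest.txt")
        from .io import write_manifest

        write_manifest(manifest, self.params, kind="connectivity")

    @classmethod
    def load(cls, path, params: NetworkParams) -> "Connectivity":
        data = np.load(Path(path))
        return cls(params=params, indptr=data["indptr"], targets=data["targets"],
                   weights=data["weights"])


def cross_input_weight(params: NetworkParams) -> float:
    """Single cross-subnetwork synaptic weight -J~*sqrt(K)/N (all-to-all mode).

    The total cross input to one excitatory neuron when the opposing
    inhibitory population has mean activity m is exactly -J~*sqrt(K)*m.
    """
    if params.cross_mode != "all_to_all":
        raise ValueError("cross_input_weight is defined only in all_to_all cross mode")
    return -params.J_tilde * math.sqrt(params.K) / params.N


def _sample_block(rng: np.random.Generator, N: int, p: float, exclude_diag: bool):
    """Bernoulli(p) adjacency of an N x N block as (src, tgt) index arrays."""
    srcs: List[np.ndarray] = []
    tgts: List[np.ndarray] = []
    for lo in range(0, N, _ROW_CHUNK):
        hi = min(lo + _ROW_CHUNK, N)
        mask = rng.random((hi - lo, N)) < p
        if exclude_diag:
            mask[np.arange(hi - lo), np.arange(lo, hi)] = False
        s, t = np.nonzero(mask)
        srcs.append((s + lo).astype(np.int64))
        tgts.append(t.astype(np.int64))
    return np.concatenate(srcs), np.concatenate(tgts)


def build_connectivity(params: NetworkParams) -> Connectivity:
    """Realize the network's synapses; deterministic given connectivity_seed.

    In mirrored mode the within-subnetwork blocks of subnetwork 2 are
    bit-exact copies of subnetwork 1's, and in sparse cross mode the two
    cross projections share one realized pattern.
    """
    N, K = params.N, params.K
    p = K / N
    sq = math.sqrt(K)
    w_E = 1.0 / sq
    w_IE = -params.J_E / sq     # I -> E
    w_II = -params.J_I / sq     # I -> I
    w_cross = -params.J_tilde / sq
    rng = np.random.default_rng(params.connectivity_seed)

    # blocks within one subnetwork: (source pop offset, target pop offset, weight)
    # pops within subnet: 0 = E, 1 = I
    def sample_subnet():
        blocks = {}
        for sp, tp, w in ((0, 0, w_E), (0, 1, w_E), (1, 0, w_IE), (1, 1, w_II)):
            s, t = _sample_block(rng, N, p, exclude_diag=(sp == tp))
            blocks[(sp, tp)] = (s, t, w)
        return blocks

    sub1 = sample_subnet()
    sub2 = sub1 if params.mirrored else sample_subnet()

    entries = []  # (src_gid, tgt_gid, weight)

    def add(blocks, base):
        for (sp, tp), (s, t, w) in blocks.items():
            entries.append(((base + sp) * N + s, (base + tp) * N + t, w))

    add(sub1, 0)
    add(sub2, 2)

    if params.cross_mode == "sparse":
        s, t = _sample_block(rng, N, p, exclude_diag=False)
        if params.mirrored:
            s2, t2 = s, t
        else:
            s2, t2 = _sample_block(rng, N, p, exclude_diag=False)
        entries.append((1 * N + s, 2 * N + t, w_cross))   # I1 -> E2
        entries.append((3 * N + s2, 0 * N + t2, w_cross))  # I2 -> E1

    src = np.concatenate([e[0] for e in entries])
    tgt = np.concatenate([e[1] for e in entries])
    wgt = np.concatenate([np.full(e[0].shape, e[2]) for e in entries])

    order = np.argsort(src, kind="stable")
    src, tgt, wgt = src[order], tgt[order], wgt[order]
    indptr = np.zeros(4 * N + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    np.cumsum(indptr, out=indptr)
    return Connectivity(params=params, indptr=indptr,
                        targets=tgt.astype(np.int32), weights=wgt.astype(np.float64))
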