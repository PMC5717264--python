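"""Synthetic bipartite networks with planted structure.

The latent-block generator emulates the low-rank community organisation
link predictors exploit in real bipartite data (drugs clustering around
target families, users around movie genres): nodes on both sides are
assigned to ``k_true`` blocks and a link appears independently with
probability ``p_in`` for same-block pairs and ``p_out`` otherwise, so
the expected biadjacency has rank ``k_true``.  Round-robin block
assignment keeps block sizes deterministic and as equal as possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network import BipartiteNetwork

__all__ = ["PlantedNetwork", "latent_block_network", "random_bipartite"]


@dataclass
class PlantedNetwork:
    """A generated network together with its planted block assignments."""

    network: BipartiteNetwork
    v_blocks: np.ndarray = field(repr=False)
    w_blocks: np.ndarray = field(repr=False)
    params: dict

    def same_block(self) -> np.ndarray:
        """Boolean n×m matrix marking same-block pairs."""
        return self.v_blocks[:, None] == self.w_blocks[None, :]


def latent_block_network(n: int, m: int, k_true: int, p_in: float,
                         p_out: float, seed: int) -> PlantedNetwork:
    """Bipartite network with planted low-rank block structure.

    Each V–W pair is linked independently with probability ``p_in`` if
    the nodes share a block and ``p_out`` otherwise; requires
    ``0 <= p_out < p_in <= 1`` so the planted signal is real.
    """
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if k_true < 1 or k_true > min(n, m):
        raise ValueError("k_true must lie in [1, min(n, m)]")
    v_blocks = np.arange(n) % k_true
    w_blocks = np.arange(m) % k_true
    probs = np.where(v_blocks[:, None] == w_blocks[None, :], p_in, p_out)
    rng = np.random.default_rng(seed)
    A = (rng.random((n, m)) < probs).astype(float)
    net = BipartiteNetwork(
        [f"v{i}" for i in range(n)], [f"w{j}" for j in range(m)], sp.csr_matrix(A)
    )
    return PlantedNetwork(
        network=net,
        v_blocks=v_blocks,
        w_blocks=w_blocks,
        params={"n": n, "m": m, "k_true": k_true, "p_in": p_in,
                "p_out": p_out, "seed": seed},
    )


def random_bipartite(n: int, m: int, density: float, seed: int) -> BipartiteNetwork:
    """Erdős–Rényi-style bipartite network: each pair linked with prob. ``density``."""
    if not (0.0 <= density <= 1.0):
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    A = (rng.random((n, m)) < density).astype(float)
    return BipartiteNetwork(
        [f"v{i}" for i in range(n)], [f"w{j}" for j in range(m)], sp.csr_matrix(A)
    )
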