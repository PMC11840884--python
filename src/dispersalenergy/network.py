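"""Dispersal-cost-weighted spatial networks over patch landscapes.

For a given species, each patch pair within its maximum dispersal distance
is linked; the link weight is the relative energy remaining after the
crossing, w = 1 − Ec(d)/Eα, clamped at 0 (an exhausted or infeasible
crossing is no link). Because cost is linear in distance this reduces to
w = max(0, 1 − d/Dmax). Connectance summarizes how much of the landscape
is reachable: the fraction of patch pairs with a link, and its
cost-weighted counterpart Σw / #pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .animals import AnimalProfile
from .energetics import DEFAULT_LAMBDA, energy_budget, max_dispersal_distance
from .landscape import Landscape, pairwise_distances
from .params import DEFAULT_PARAMETERS, ModelParameters

__all__ = ["DispersalNetwork", "build_network", "connectance", "weighted_connectance"]


@dataclass(frozen=True)
class DispersalNetwork:
    """Symmetric, self-link-free patch network for one species.

    ``distances`` and ``weights`` are (n, n) matrices; weights lie in
    [0, 1], are zero exactly where d ≥ Dmax, and have a zero diagonal by
    convention (self-links excluded).
    """

    landscape: Landscape
    animal: AnimalProfile
    lam: float
    d_max: float
    distances: np.ndarray
    weights: np.ndarray

    @property
    def n_patches(self) -> int:
        return len(self.landscape)

    @property
    def n_pairs(self) -> int:
        n = self.n_patches
        return n * (n - 1) // 2

    def _upper(self, matrix: np.ndarray) -> np.ndarray:
        iu = np.triu_indices(self.n_patches, k=1)
        return matrix[iu]

    def connectance(self) -> float:
        """Fraction of patch pairs with a present link (w > 0)."""
        return float(np.count_nonzero(self._upper(self.weights) > 0.0) / self.n_pairs)

    def weighted_connectance(self) -> float:
        """Mean link weight over all patch pairs (cost-weighted connectance)."""
        return float(self._upper(self.weights).sum() / self.n_pairs)

    # --- exports -----------------------------------------------------------
    def to_edge_frame(self, include_absent: bool = False) -> pd.DataFrame:
        """Edge list ``source,target,distance_m,weight`` (upper triangle).

        Absent links (w = 0) are dropped unless ``include_absent``.
        """
        ids = self.landscape.patch_ids
        iu = np.triu_indices(self.n_patches, k=1)
        df = pd.DataFrame(
            {
                "source": [ids[i] for i in iu[0]],
                "target": [ids[j] for j in iu[1]],
                "distance_m": self.distances[iu],
                "weight": self.weights[iu],
            }
        )
        return df if include_absent else df[df["weight"] > 0.0].reset_index(drop=True)

    def write_edgelist(self, path: str, include_absent: bool = False) -> None:
        """Write the edge-list CSV preceded by commented metric lines."""
        with open(path, "w") as fh:
            fh.write(f"# connectance = {self.connectance():.6f}\n")
            fh.write(f"# weighted_connectance = {self.weighted_connectance():.6f}\n")
            fh.write(f"# d_max_m = {self.d_max:.6f}\n")
            self.to_edge_frame(include_absent).to_csv(fh, index=False)

    def to_networkx(self) -> nx.Graph:
        """Undirected graph of present links, node positions attached."""
        g = nx.Graph(
            species_group=self.animal.group,
            body_mass_kg=self.animal.body_mass,
            lam=self.lam,
            d_max_m=self.d_max,
        )
        for pid, (x, y) in zip(self.landscape.patch_ids, self.landscape.coords):
            g.add_node(pid, x=float(x), y=float(y))
        for row in self.to_edge_frame().itertuples(index=False):
            g.add_edge(row.source, row.target, distance_m=row.distance_m, weight=row.weight)
        return g

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)


def build_network(
    animal: AnimalProfile,
    landscape: Landscape,
    lam: float = DEFAULT_LAMBDA,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> DispersalNetwork:
    """Dispersal-cost-weighted network of ``landscape`` for ``animal``.

    Weights are w_ij = max(0, 1 − Ec(d_ij)/Eα); a pair exactly at Dmax has
    used all available energy, so its weight is 0 and the link is absent.
    """
    dist = pairwise_distances(landscape)
    budget = energy_budget(animal, lam, params)
    if budget.e_available == 0.0:
        raise ValueError("lambda = 1 leaves no available energy; network undefined")
    d_max = max_dispersal_distance(animal, lam, params).d_max
    # Ec is linear in distance, so 1 - Ec(d)/Ea == 1 - d/Dmax; the latter
    # keeps the d == Dmax boundary exactly at weight 0.
    weights = np.maximum(0.0, 1.0 - dist / d_max)
    np.fill_diagonal(weights, 0.0)
    return DispersalNetwork(
        landscape=landscape,
        animal=animal,
        lam=lam,
        d_max=d_max,
        distances=dist,
        weights=weights,
    )


def connectance(network: DispersalNetwork) -> float:
    """Functional alias of :meth:`DispersalNetwork.connectance`."""
    return network.connectance()


def weighted_connectance(network: DispersalNetwork) -> float:
    """Functional alias of :meth:`DispersalNetwork.weighted_connectance`."""
    return network.weighted_connectance()
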