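"""Intersection of gene clusters with the protein-interaction network.

Each cluster keeps every member gene (isolated genes included, since the
activity normalization divides by the full cluster size) together with
the interaction edges whose endpoints both lie in the cluster.  Edges
crossing cluster boundaries are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cluster import GeneClustering
from .io import PPINetwork


@dataclass
class ClusterSubnetwork:
    """One cluster's slice of the PPI network.

    ``edges`` holds each undirected within-cluster interaction exactly once
    as a lexicographically sorted gene pair.
    """

    cluster: int
    genes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    n_k: int

    def __post_init__(self) -> None:
        members = set(self.genes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop {a!r} in cluster {self.cluster}")
            if a not in members or b not in members:
                raise ValueError(f"edge ({a!r}, {b!r}) leaves cluster {self.cluster}")
        if self.n_k != len(self.genes):
            raise ValueError("n_k must equal the member-gene count")


def match_clusters(clustering: GeneClustering, ppi: PPINetwork) -> list[ClusterSubnetwork]:
    """Build one :class:`ClusterSubnetwork` per cluster, in index order.

    Genes absent from the PPI node set stay members with no incident
    matched edges; an empty intersection is a valid outcome.
    """
    if not clustering.assignments:
        raise ValueError("empty clustering")
    subnetworks = []
    for k in range(1, clustering.K + 1):
        members = clustering.members(k)
        edges = tuple(ppi.edges_within(members))
        subnetworks.append(
            ClusterSubnetwork(cluster=k, genes=tuple(members), edges=edges, n_k=len(members))
        )
    return subnetworks
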