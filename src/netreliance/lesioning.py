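"""In silico lesioning: iterative degree-targeted attack and network reliance.

The attack removes, at every step, the surviving node with the highest
weighted degree, recomputing degrees on the surviving subgraph after each
removal. The removal order is then partitioned into equal consecutive
stages (8 stages of 33 nodes for a 264-node connectome); per-network node
losses are counted per stage, and a network's *reliance* is its mean node
loss over the early stages (1-4 by default): high reliance means the
network's nodes are the early hubs the resting brain leans on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import Atlas
from .connectome import ThresholdedGraph, weighted_degree
from .errors import ConfigurationError

#: Stages over which reliance is averaged (inclusive labels).
DEFAULT_RELIANCE_STAGES = (1, 2, 3, 4)


@dataclass(frozen=True)
class LesionTrajectory:
    """Removal order of all nodes plus (optionally) their stage labels."""

    removal_order: np.ndarray  # position k = k-th node removed
    stage_of_node: np.ndarray | None = None  # node index -> stage in 1..S
    n_stages: int | None = None
    stage_sizes: tuple | None = None

    def __post_init__(self):
        order = np.asarray(self.removal_order, dtype=int)
        n = order.size
        if sorted(order.tolist()) != list(range(n)):
            raise ConfigurationError("removal_order is not a permutation of 0..N-1")
        object.__setattr__(self, "removal_order", order)

    @property
    def n_nodes(self) -> int:
        return int(self.removal_order.size)


@dataclass(frozen=True)
class RelianceProfile:
    """Network x stage node-loss counts and the per-network reliance."""

    counts: pd.DataFrame  # index = networks, columns = 1..S
    reliance: pd.Series  # per-network mean loss over the reliance stages
    networks: tuple

    def plot(self, ax=None):
        """Line plot of node loss per stage, one line per network."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for net in self.networks:
            ax.plot(self.counts.columns, self.counts.loc[net], marker="o", label=net)
        ax.set_xlabel("lesioning stage")
        ax.set_ylabel("nodes lost")
        ax.legend(fontsize="small", ncol=2)
        return ax


def targeted_attack(g: ThresholdedGraph) -> LesionTrajectory:
    """Iteratively remove the highest-weighted-degree surviving node.

    Degrees are recomputed (incrementally) after every removal. Ties —
    including isolated nodes, all at degree 0 — are broken by lowest node
    index. Continues until all N nodes are removed.
    """
    adj = g.adjacency
    n = adj.shape[0]
    if n < 1:
        raise ConfigurationError("graph must have at least one node")
    deg = weighted_degree(g).astype(float).copy()
    edges = adj != 0.0
    n_edges = edges.sum(axis=1)  # surviving incident edges, exact integers
    order = np.empty(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    for k in range(n):
        masked = np.where(alive, deg, -np.inf)
        # treat degrees within 1e-8 of the maximum as tied and take the
        # lowest index: exact ties (e.g. two nodes whose only surviving
        # edge is their mutual one) must not be decided by float residue
        # of the incremental update
        node = int(np.argmax(masked >= masked.max() - 1e-8))
        order[k] = node
        alive[node] = False
        deg -= adj[node]  # incremental update; dead entries are never read
        n_edges -= edges[node]
        # snap exactly-isolated nodes to 0 so float residue from the
        # incremental subtraction cannot perturb the degree-0 tie order
        deg[n_edges == 0] = 0.0
    return LesionTrajectory(removal_order=order)


def assign_stages(traj: LesionTrajectory, n_stages: int) -> LesionTrajectory:
    """Partition the removal order into ``n_stages`` equal consecutive blocks.

    When N is not divisible by the stage count, earlier stages receive the
    extra node (balanced partition: sizes differ by at most one). For
    N=264 and 8 stages every stage holds exactly 33 nodes.
    """
    n = traj.n_nodes
    if not (1 <= n_stages <= n):
        raise ConfigurationError(
            f"n_stages must be in 1..{n} for {n} nodes, got {n_stages}"
        )
    base, rem = divmod(n, n_stages)
    sizes = tuple(base + 1 if s < rem else base for s in range(n_stages))
    stage_of_node = np.empty(n, dtype=int)
    pos = 0
    for s, size in enumerate(sizes, start=1):
        stage_of_node[traj.removal_order[pos : pos + size]] = s
        pos += size
    return LesionTrajectory(
        removal_order=traj.removal_order,
        stage_of_node=stage_of_node,
        n_stages=n_stages,
        stage_sizes=sizes,
    )


def stage_counts(
    traj: LesionTrajectory,
    atlas: Atlas,
    reliance_stages: tuple = DEFAULT_RELIANCE_STAGES,
) -> RelianceProfile:
    """Count nodes lost per network per stage; derive per-network reliance.

    ``counts[net, s]`` is the number of nodes of ``net`` removed in stage
    ``s``; reliance is the mean count over ``reliance_stages``.
    """
    if traj.stage_of_node is None:
        raise ConfigurationError("trajectory has no stages; call assign_stages first")
    if atlas.n_nodes != traj.n_nodes:
        raise ConfigurationError(
            f"atlas covers {atlas.n_nodes} nodes but trajectory has {traj.n_nodes}"
        )
    stages = list(range(1, traj.n_stages + 1))
    counts = pd.DataFrame(0, index=list(atlas.networks), columns=stages, dtype=int)
    for node, stage in enumerate(traj.stage_of_node):
        counts.loc[atlas.labels[node], stage] += 1
    missing = [s for s in reliance_stages if s not in counts.columns]
    if missing:
        raise ConfigurationError(f"reliance stages {missing} exceed n_stages")
    reliance = counts[list(reliance_stages)].mean(axis=1)
    reliance.name = "reliance"
    return RelianceProfile(counts=counts, reliance=reliance, networks=atlas.networks)


def cohort_reliance(
    graphs: dict,
    atlas: Atlas,
    n_stages: int = 8,
    reliance_stages: tuple = DEFAULT_RELIANCE_STAGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the attack + stage accounting for every subject in a cohort.

    Parameters
    ----------
    graphs : dict
        ``subject_id -> ThresholdedGraph``; subjects are processed
        independently in insertion order.

    Returns
    -------
    counts_long : DataFrame
        Columns subject_id, network, stage, nodes_lost.
    reliance_wide : DataFrame
        One row per subject_id, one column per network.
    """
    long_rows = []
    wide_rows = {}
    for sid, g in graphs.items():
        traj = assign_stages(targeted_attack(g), n_stages)
        prof = stage_counts(traj, atlas, reliance_stages)
        for net in prof.networks:
            for s in prof.counts.columns:
                long_rows.append(
                    {
                        "subject_id": sid,
                        "network": net,
                        "stage": int(s),
                        "nodes_lost": int(prof.counts.loc[net, s]),
                    }
                )
        wide_rows[sid] = prof.reliance
    counts_long = pd.DataFrame(
        long_rows, columns=["subject_id", "network", "stage", "nodes_lost"]
    )
    reliance_wide = pd.DataFrame(wide_rows).T
    reliance_wide.index.name = "subject_id"
    return counts_long, reliance_wide
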