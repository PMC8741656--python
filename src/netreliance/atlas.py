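"""Parcellation atlas: mapping from node index to resting-state network label.

The atlas defines the per-network accounting frame used by the lesioning
stage counts: node indices are contiguous 0..N-1 and every node carries
exactly one network label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

#: Canonical 10-network labelling used for 264-parcel connectomes.
POWER_NETWORKS = ("AUD", "CING", "DAN", "DMN", "FPN", "SMN", "SN", "SUB", "VAN", "VIS")

#: Synthetic stand-in node counts per network (sum = 264). The true
#: parcel-to-network table is not redistributable, so these block sizes
#: emulate a Power-style parcellation collapsed onto the 10 labels above,
#: with unassigned/cerebellar/memory parcels folded into SUB.
POWER_NETWORK_SIZES = {
    "AUD": 13,
    "CING": 14,
    "DAN": 11,
    "DMN": 58,
    "FPN": 25,
    "SMN": 35,
    "SN": 18,
    "SUB": 50,
    "VAN": 9,
    "VIS": 31,
}


@dataclass(frozen=True)
class Atlas:
    """Node-to-network lookup table.

    Parameters
    ----------
    labels : array of str, shape (n_nodes,)
        ``labels[i]`` is the network label of node ``i`` (0-based).
    coordinates : array, shape (n_nodes, 3), optional
        Node coordinates in mm; not used by the analysis, carried for I/O.
    """

    labels: np.ndarray
    coordinates: np.ndarray | None = None
    networks: tuple = field(init=False)

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=object)
        if labels.ndim != 1 or labels.size == 0:
            raise ConfigurationError("atlas labels must be a non-empty 1-D sequence")
        object.__setattr__(self, "labels", labels)
        # network order = first appearance, which for the default atlas is
        # the canonical AUD..VIS order
        seen: dict = {}
        for lab in labels:
            seen.setdefault(str(lab), None)
        object.__setattr__(self, "networks", tuple(seen))
        if self.coordinates is not None:
            coords = np.asarray(self.coordinates, dtype=float)
            if coords.shape != (labels.size, 3):
                raise ConfigurationError(
                    f"coordinates shape {coords.shape} does not match "
                    f"{labels.size} nodes"
                )
            object.__setattr__(self, "coordinates", coords)

    @property
    def n_nodes(self) -> int:
        return int(self.labels.size)

    def network_sizes(self) -> dict:
        """Number of nodes per network, in atlas network order."""
        return {net: int(np.sum(self.labels == net)) for net in self.networks}

    def nodes_of(self, network: str) -> np.ndarray:
        """Indices of the nodes belonging to ``network``."""
        return np.flatnonzero(self.labels == network)

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path) -> None:
        """Write the atlas as TSV: node_index, network_label[, x, y, z]."""
        df = pd.DataFrame(
            {"node_index": np.arange(self.n_nodes), "network_label": self.labels}
        )
        if self.coordinates is not None:
            df[["x", "y", "z"]] = self.coordinates
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, one_based: bool = False) -> "Atlas":
        """Read an atlas table (TSV with node_index, network_label columns).

        Set ``one_based=True`` for files whose node_index starts at 1.
        """
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"node_index", "network_label"} <= set(df.columns):
            raise FormatError(
                f"{path}: expected columns node_index, network_label; "
                f"found {list(df.columns)}"
            )
        idx = df["node_index"].to_numpy(dtype=int) - (1 if one_based else 0)
        n = len(df)
        if sorted(idx.tolist()) != list(range(n)):
            raise FormatError(f"{path}: node indices are not contiguous 0..{n - 1}")
        order = np.argsort(idx)
        labels = df["network_label"].to_numpy(dtype=object)[order]
        coords = None
        if {"x", "y", "z"} <= set(df.columns):
            coords = df[["x", "y", "z"]].to_numpy(dtype=float)[order]
        return cls(labels=labels, coordinates=coords)
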