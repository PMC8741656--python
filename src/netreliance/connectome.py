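"""Functional connectivity matrices: construction, normalization, thresholding.

The pipeline's connectivity representation is the Fisher-z transformed
Pearson correlation matrix between parcel BOLD time series (symmetric, zero
diagonal). Graphs are obtained by proportional thresholding: the top
``floor(density * N(N-1)/2)`` edges by weight are retained, everything else
is zeroed. Weighted nodal degree — the row sum of the retained adjacency —
is the hub measure used by the lesioning module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

_FISHER_EPS = 1e-7


@dataclass(frozen=True)
class Connectome:
    """Square symmetric Fisher-z connectivity matrix for one subject."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConfigurationError(f"connectome must be square, got {v.shape}")
        if not np.isfinite(v).all():
            raise ConfigurationError("connectome contains non-finite entries")
        if not np.allclose(v, v.T):
            raise ConfigurationError("connectome must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ConfigurationError("connectome diagonal must be exactly 0")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ThresholdedGraph:
    """Proportionally thresholded weighted graph (retained weights, 0 elsewhere)."""

    adjacency: np.ndarray
    density: float
    retained_edges: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


# --------------------------------------------------------------------- I/O


def read_matrix(path, subject_id: str | None = None) -> Connectome:
    """Read a dense square matrix file (whitespace or comma delimited).

    Lines starting with '#' are treated as provenance comments. A single
    non-numeric header row is detected and skipped. Asymmetric input is
    symmetrized as (M + M.T)/2 with a logged warning; the diagonal is
    forced to 0.
    """
    rows = []
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    delim = "," if "," in lines[0] else None
    start = 0
    try:
        [float(tok) for tok in lines[0].split(delim) if tok.strip()]
    except ValueError:
        start = 1  # header row
    for li, ln in enumerate(lines[start:], start=start + 1):
        toks = [t for t in ln.split(delim) if t.strip()]
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value in row {li}: {exc}") from None
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise FormatError(f"{path}: ragged rows, column counts {sorted(ncols)}")
    m = np.asarray(rows, dtype=float)
    if m.shape[0] != m.shape[1]:
        raise FormatError(
            f"{path}: matrix is {m.shape[0]}x{m.shape[1]}, expected square"
        )
    if not np.allclose(m, m.T):
        logger.warning("%s: asymmetric matrix symmetrized as (M + M.T)/2", path)
        m = (m + m.T) / 2.0
    else:
        m = (m + m.T) / 2.0  # exact symmetry regardless of rounding
    np.fill_diagonal(m, 0.0)
    if subject_id is None:
        subject_id = str(path)
    return Connectome(subject_id=subject_id, values=m)


def write_matrix(c: Connectome, path, header: str | None = None) -> None:
    """Write a connectome as a dense whitespace-delimited matrix with a
    '#'-prefixed provenance header."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# netreliance {__version__} subject={c.subject_id}\n")
        if header:
            fh.write(f"# {header}\n")
        np.savetxt(fh, c.values, fmt="%.10g")


# ---------------------------------------------------------- matrix algebra


def correlation_matrix(timeseries) -> np.ndarray:
    """Pearson correlation matrix between the columns of a T x N table.

    Raises if T < 3 or any column is constant (correlation undefined).
    """
    ts = np.asarray(
        timeseries.values if isinstance(timeseries, pd.DataFrame) else timeseries,
        dtype=float,
    )
    if ts.ndim != 2:
        raise ConfigurationError("time series must be a T x N table")
    if ts.shape[0] < 3:
        raise ConfigurationError(f"need at least 3 time points, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise ConfigurationError(
            f"constant time series for node(s) {bad.tolist()}: correlation undefined"
        )
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r: np.ndarray, subject_id: str = "") -> Connectome:
    """Fisher z-transform an r-matrix into a Connectome.

    Off-diagonal z = atanh(clip(r, -1+eps, 1-eps)) with eps = 1e-7; the
    diagonal is set to 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ConfigurationError("correlation entries must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -1.0 + _FISHER_EPS, 1.0 - _FISHER_EPS))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return Connectome(subject_id=subject_id, values=z)


def proportional_threshold(
    c: Connectome, density: float, absolute: bool = False
) -> ThresholdedGraph:
    """Retain the top ``floor(density * N(N-1)/2)`` edges by weight.

    Ranking is by signed weight (the largest z values survive) unless
    ``absolute=True``; ties are broken by lexicographic (i, j) order with
    the lower node-index pair retained first. Symmetry is preserved.
    """
    if not (0.0 < density <= 1.0):
        raise ConfigurationError(f"density must be in (0, 1], got {density}")
    v = c.values
    n = v.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = v[iu, ju]
    key = np.abs(w) if absolute else w
    m = int(np.floor(density * n * (n - 1) / 2))
    # primary: weight descending; ties: i ascending then j ascending
    order = np.lexsort((ju, iu, -key))
    keep = order[:m]
    adj = np.zeros_like(v)
    adj[iu[keep], ju[keep]] = w[keep]
    adj = adj + adj.T
    return ThresholdedGraph(adjacency=adj, density=float(density), retained_edges=m)


def weighted_degree(g: ThresholdedGraph | np.ndarray) -> np.ndarray:
    """Weighted nodal degree: sum of each node's retained edge weights."""
    adj = g.adjacency if isinstance(g, ThresholdedGraph) else np.asarray(g, float)
    return adj.sum(axis=1)
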