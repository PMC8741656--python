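"""Synthetic twin cohorts, EF scores, and block-structured connectomes.

The generator emulates the statistical structure the downstream analysis
assumes, with no real data required:

* twin pairs whose within-pair trait correlation hits a per-zygosity
  target (rMZ, rDZ) directly — parameterizing by correlations rather than
  by (a2, c2, e2) is deliberate, because empirically plausible targets can
  have rDZ < rMZ/2, which no purely additive generator can produce;
* cross-trait correlations within a subject matching a given correlation
  matrix (defaults emulate the published EF factor intercorrelations
  0.31, 0.38, -0.28 between cEF/SHI and cEF/UPD and SHI/UPD);
* connectomes with within- vs between-network block structure in Fisher-z
  units, an optional trait -> network coupling that shifts the coupled
  network's within-block edge weights (and hence its nodes' hubness), an
  optional pair-shared matrix component, and i.i.d. Gaussian edge noise
  added to the upper triangle then mirrored (exact symmetry);
* BOLD-like multivariate-normal time series whose sample correlation
  converges to a target connectome, for exercising the correlation-matrix
  path end to end.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas, POWER_NETWORKS, POWER_NETWORK_SIZES
from .connectome import Connectome
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TraitSpec:
    """Per-trait twin-similarity targets and marginal scale."""

    name: str
    target_rMZ: float
    target_rDZ: float
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if abs(self.target_rMZ) > 1 or abs(self.target_rDZ) > 1:
            raise ConfigurationError(f"{self.name}: twin correlations must be in [-1, 1]")
        if self.sd <= 0:
            raise ConfigurationError(f"{self.name}: sd must be positive")

    @classmethod
    def from_ace(cls, name: str, a2: float, c2: float, e2: float,
                 mean: float = 0.0) -> "TraitSpec":
        """Convenience constructor from variance components:
        rMZ = a2 + c2, rDZ = a2/2 + c2 (shares of total variance)."""
        if min(a2, c2, e2) < 0 or a2 + c2 + e2 <= 0:
            raise ConfigurationError("variance components must be nonnegative, V > 0")
        v = a2 + c2 + e2
        return cls(name=name, target_rMZ=(a2 + c2) / v,
                   target_rDZ=(a2 / 2 + c2) / v, mean=mean, sd=float(np.sqrt(v)))


@dataclass(frozen=True)
class CouplingSpec:
    """Planted trait -> network association.

    ``effect`` is the expected shift of the coupled network's within-block
    mean edge weight (Fisher-z units) per 1 SD of the trait.
    """

    trait: str
    network: str
    effect: float


#: Default EF trait specs: twin-correlation targets for the common EF
#: factor and the shifting-/updating-specific factors.
DEFAULT_TRAIT_SPECS = (
    TraitSpec("cEF", target_rMZ=0.81, target_rDZ=0.22),
    TraitSpec("SHI", target_rMZ=0.55, target_rDZ=0.15),
    TraitSpec("UPD", target_rMZ=0.65, target_rDZ=0.31),
)

#: Default cross-trait correlations (cEF, SHI, UPD).
DEFAULT_TRAIT_CORRELATIONS = np.array(
    [[1.0, 0.31, 0.38],
     [0.31, 1.0, -0.28],
     [0.38, -0.28, 1.0]]
)


@dataclass
class SimConfig:
    """Full configuration of one synthetic study."""

    n_mz_pairs: int = 115
    n_dz_pairs: int = 108
    n_nodes: int = 264
    network_sizes: tuple = tuple(POWER_NETWORK_SIZES[n] for n in POWER_NETWORKS)
    network_labels: tuple = POWER_NETWORKS
    trait_specs: tuple = DEFAULT_TRAIT_SPECS
    trait_correlations: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRAIT_CORRELATIONS.copy())
    couplings: tuple = ()
    base_within_network_z: float = 0.45
    base_between_network_z: float = 0.10
    noise_sd: float = 0.12
    pair_shared_sd: float = 0.0
    scanner_labels: tuple = ("TRIO", "PRISMA")
    scanner_p: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if sum(self.network_sizes) != self.n_nodes:
            raise ConfigurationError(
                f"network sizes sum to {sum(self.network_sizes)}, expected {self.n_nodes}"
            )
        if len(self.network_labels) != len(self.network_sizes):
            raise ConfigurationError("one label required per network size")
        R = np.asarray(self.trait_correlations, dtype=float)
        k = len(self.trait_specs)
        if R.shape != (k, k) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1):
            raise ConfigurationError(
                "trait_correlations must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ConfigurationError("trait_correlations is not positive semi-definite")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        for c in self.couplings:
            if c.network not in self.network_labels:
                raise ConfigurationError(f"coupling targets unknown network {c.network!r}")
            if c.trait not in [t.name for t in self.trait_specs]:
                raise ConfigurationError(f"coupling references unknown trait {c.trait!r}")

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------- atlas


def make_atlas(n_nodes: int, network_sizes, labels, seed: int = 0) -> Atlas:
    """Deterministic block atlas: contiguous label blocks of the given sizes."""
    network_sizes = list(network_sizes)
    labels = list(labels)
    if sum(network_sizes) != n_nodes:
        raise ConfigurationError(
            f"network sizes sum to {sum(network_sizes)}, expected {n_nodes}")
    if len(labels) != len(network_sizes):
        raise ConfigurationError("one label required per network size")
    lab = np.empty(n_nodes, dtype=object)
    pos = 0
    for size, name in zip(network_sizes, labels):
        lab[pos : pos + size] = name
        pos += size
    return Atlas(labels=lab)


# ---------------------------------------------------------------- traits


def _pair_covariance(R: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Joint covariance of a twin pair's trait vectors: [[R, D], [D, R]]
    with D_ij = sqrt(r_i r_j) R_ij (exact per-trait pair correlation r_t
    and exact within-subject cross-trait correlations R)."""
    if np.any(r < 0):
        # sign-aware fallback; may need PSD projection
        s = np.sign(r) * np.sqrt(np.abs(r))
    else:
        s = np.sqrt(r)
    D = np.outer(s, s) * R
    np.fill_diagonal(D, r)
    sigma = np.block([[R, D], [D, R]])
    w, v = np.linalg.eigh(sigma)
    if w.min() < -1e-10:
        logger.warning("pair covariance not PSD (min eig %.3g); clipping", w.min())
        sigma = (v * np.clip(w, 0, None)) @ v.T
        sigma = (sigma + sigma.T) / 2
    return sigma


def simulate_twin_traits(cfg: SimConfig) -> pd.DataFrame:
    """Simulate the twin cohort table: one row per subject with family id,
    zygosity, scanner label and all trait values.

    Within-pair correlation of trait t equals its zygosity target in
    expectation; cross-trait correlations follow cfg.trait_correlations;
    each trait is scaled to its (mean, sd).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 101]))
    R = np.asarray(cfg.trait_correlations, dtype=float)
    k = len(cfg.trait_specs)
    names = [t.name for t in cfg.trait_specs]
    rows = []
    for zyg, n_pairs in (("MZ", cfg.n_mz_pairs), ("DZ", cfg.n_dz_pairs)):
        r = np.array([
            t.target_rMZ if zyg == "MZ" else t.target_rDZ for t in cfg.trait_specs
        ])
        sigma = _pair_covariance(R, r)
        draws = rng.multivariate_normal(
            np.zeros(2 * k), sigma, size=n_pairs, method="eigh")
        for p in range(n_pairs):
            fam = f"{zyg}{p + 1:04d}"
            scanner = cfg.scanner_labels[
                int(rng.random() < cfg.scanner_p) % len(cfg.scanner_labels)]
            for member, sl in (("A", slice(0, k)), ("B", slice(k, 2 * k))):
                vals = draws[p, sl]
                row = {"subject_id": f"{fam}_{member}", "family_id": fam,
                       "zygosity": zyg, "scanner": scanner}
                for t, v in zip(cfg.trait_specs, vals):
                    row[t.name] = t.mean + t.sd * v
                rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "family_id", "zygosity",
                                       "scanner"] + names)


# ------------------------------------------------------------ connectomes


def simulate_connectomes(cohort: pd.DataFrame, atlas: Atlas,
                         cfg: SimConfig) -> dict:
    """Simulate one symmetric zero-diagonal connectome per cohort subject.

    Expected within-network edge weight is ``base_within_network_z`` (plus
    coupling effect x standardized trait for coupled networks), expected
    between-network weight ``base_between_network_z``. Noise is drawn on
    the upper triangle and mirrored.
    """
    n = atlas.n_nodes
    if n != cfg.n_nodes:
        raise ConfigurationError(
            f"atlas has {n} nodes but config declares {cfg.n_nodes}")
    same = atlas.labels[:, None] == atlas.labels[None, :]
    base = np.where(same, cfg.base_within_network_z, cfg.base_between_network_z)
    np.fill_diagonal(base, 0.0)
    blocks = {}
    for c in cfg.couplings:
        idx = atlas.nodes_of(c.network)
        if idx.size == 0:
            raise ConfigurationError(f"coupled network {c.network!r} not in atlas")
        mask = np.zeros((n, n), dtype=bool)
        mask[np.ix_(idx, idx)] = True
        np.fill_diagonal(mask, False)
        blocks[(c.trait, c.network)] = (mask, c.effect)
    trait_scale = {t.name: (t.mean, t.sd) for t in cfg.trait_specs}
    iu = np.triu_indices(n, k=1)
    root = np.random.SeedSequence([int(cfg.seed), 202])
    fam_ids = list(dict.fromkeys(cohort["family_id"]))
    fam_ss = dict(zip(fam_ids, root.spawn(len(fam_ids))))
    out = {}
    for _, subj in cohort.iterrows():
        w = base.copy()
        for c in cfg.couplings:
            mask, effect = blocks[(c.trait, c.network)]
            mean, sd = trait_scale[c.trait]
            z = (subj[c.trait] - mean) / sd
            w = w + mask * (effect * z)
        fam_seq = fam_ss[subj["family_id"]]
        if cfg.pair_shared_sd > 0:
            shared_rng = np.random.default_rng(fam_seq)
            shared = shared_rng.normal(0.0, cfg.pair_shared_sd, size=iu[0].size)
            w[iu] += shared
            w.T[iu] = w[iu]
        subj_rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), 203,
                                    int(hashlib.sha256(str(subj["subject_id"]).encode())
                                        .hexdigest()[:8], 16)]))
        if cfg.noise_sd > 0:
            noise = subj_rng.normal(0.0, cfg.noise_sd, size=iu[0].size)
            w[iu] += noise
        w = np.triu(w, k=1)
        w = w + w.T
        np.fill_diagonal(w, 0.0)
        out[subj["subject_id"]] = Connectome(subject_id=subj["subject_id"], values=w)
    return out


# ----------------------------------------------------------------- BOLD


def simulate_bold(connectome: Connectome, n_timepoints: int,
                  seed: int = 0) -> pd.DataFrame:
    """Draw BOLD-like samples from a multivariate normal whose correlation
    is the connectome's inverse-Fisher transform (diagonal restored to 1,
    projected to the nearest PSD correlation matrix if needed)."""
    n = connectome.n_nodes
    if n_timepoints < n + 1:
        logger.warning(
            "n_timepoints=%d < n_nodes+1=%d: sample correlation will be "
            "rank deficient", n_timepoints, n + 1)
    r = np.tanh(connectome.values)
    np.fill_diagonal(r, 1.0)
    w, v = np.linalg.eigh(r)
    if w.min() < 1e-10:
        r = (v * np.clip(w, 1e-10, None)) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
    rng = np.random.default_rng(seed)
    ts = rng.multivariate_normal(np.zeros(n), r, size=n_timepoints, method="eigh")
    return pd.DataFrame(ts, columns=[f"node{j}" for j in range(n)])


# ------------------------------------------------------------------ I/O


def write_simulation(out_dir, cohort: pd.DataFrame, atlas: Atlas,
                     connectomes: dict, cfg: SimConfig) -> Path:
    """Write cohort TSV, atlas TSV, one matrix file per subject, and a
    manifest listing all paths plus the seed and config hash."""
    from .connectome import write_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_path = out / "cohort.tsv"
    cohort.to_csv(cohort_path, sep="\t", index=False)
    atlas_path = out / "atlas.tsv"
    atlas.to_tsv(atlas_path)
    mat_dir = out / "connectomes"
    mat_dir.mkdir(exist_ok=True)
    paths = []
    for sid, conn in connectomes.items():
        p = mat_dir / f"{sid}.txt"
        write_matrix(conn, p, header=f"seed={cfg.seed}")
        paths.append(str(p.relative_to(out)))
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "cohort": cohort_path.name,
        "atlas": atlas_path.name,
        "connectomes": paths,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
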