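"""Twin-based heritability: Falconer's formula and ACE variance components.

Monozygotic (MZ) twins share all their segregating genes, dizygotic (DZ)
twins on average half, and both share their rearing environment. Under the
classical twin design a trait's variance decomposes into additive genetic
(A), common-environment (C) and unique-environment (E) components, with
expected twin covariances

    Cov_MZ = a^2 + c^2        Cov_DZ = a^2/2 + c^2

and total variance V = a^2 + c^2 + e^2. ``falconer`` gives the quick
moment estimate H^2 = 2(r_MZ - r_DZ); ``AceModel`` fits the ACE model and
its nested submodels (AE, CE, E) by maximum likelihood on the bivariate
normal pair distribution, compared by likelihood-ratio chi-square against
ACE and by AIC = minus2LL - 2*df (df = observations minus free
parameters — the bookkeeping under which lower AIC is better fit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
ACE_MODELS = ("ACE", "AE", "CE", "E")
_FREE_PARAMS = {"ACE": 4, "AE": 3, "CE": 3, "E": 2}  # mean + variance paths


class TwinCorrelations(NamedTuple):
    r_mz: float
    r_dz: float
    n_mz_pairs: int
    n_dz_pairs: int


def falconer(r_mz: float, r_dz: float) -> float:
    """Falconer heritability estimate H^2 = 2 (r_MZ - r_DZ).

    Reported as-is: values above 1 or below 0 are possible and meaningful
    as moment estimates (no clipping).
    """
    if abs(r_mz) > 1 or abs(r_dz) > 1:
        raise ConfigurationError("twin correlations must lie in [-1, 1]")
    return 2.0 * (r_mz - r_dz)


def aic(minus2ll: float, df: int) -> float:
    """AIC = minus2LL - 2*df with df = n_observations - n_free_parameters."""
    return float(minus2ll) - 2.0 * float(df)


def pair_table(cohort: pd.DataFrame, trait: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract complete MZ and DZ pair value arrays from a cohort table.

    Families must contribute exactly one pair; pairs with a missing trait
    value are dropped with a logged count.
    """
    needed = {"family_id", "zygosity", trait}
    if not needed <= set(cohort.columns):
        raise ConfigurationError(f"cohort table lacks columns {needed - set(cohort.columns)}")
    mz, dz, dropped = [], [], 0
    for (fam, zyg), grp in cohort.groupby(["family_id", "zygosity"], sort=True):
        vals = grp[trait].to_numpy(dtype=float)
        if len(vals) != 2 or not np.isfinite(vals).all():
            dropped += 1
            continue
        (mz if zyg == "MZ" else dz).append(vals)
    if dropped:
        logger.info("dropped %d incomplete families for trait %s", dropped, trait)
    to_arr = lambda x: np.asarray(x, float).reshape(-1, 2)
    return to_arr(mz), to_arr(dz)


def twin_correlations(trait: str, cohort: pd.DataFrame) -> TwinCorrelations:
    """Double-entered Pearson twin correlations per zygosity.

    Each pair contributes both (A, B) and (B, A), so the estimate is
    exactly invariant to within-pair ordering.
    """
    mz, dz = pair_table(cohort, trait)

    def double_entry_r(pairs: np.ndarray) -> float:
        if pairs.shape[0] < 3:
            raise ConfigurationError(
                f"need at least 3 complete pairs per zygosity, got {pairs.shape[0]}"
            )
        x = np.concatenate([pairs[:, 0], pairs[:, 1]])
        y = np.concatenate([pairs[:, 1], pairs[:, 0]])
        return float(np.corrcoef(x, y)[0, 1])

    return TwinCorrelations(
        r_mz=double_entry_r(mz),
        r_dz=double_entry_r(dz),
        n_mz_pairs=mz.shape[0],
        n_dz_pairs=dz.shape[0],
    )


# ------------------------------------------------------------- ACE fitting


@dataclass(frozen=True)
class AceFit:
    """Maximum-likelihood fit of one twin variance-component model."""

    model: str
    a2: float
    c2: float
    e2: float
    mean: float
    minus2ll: float
    n_obs: int
    n_params: int
    df: int
    aic: float
    comparison_p: float | None = None  # LRT p vs the ACE baseline; None for ACE

    @property
    def total_variance(self) -> float:
        return self.a2 + self.c2 + self.e2

    def standardized(self) -> tuple[float, float, float]:
        """(a2, c2, e2) as shares of the total variance."""
        v = self.total_variance
        return self.a2 / v, self.c2 / v, self.e2 / v

    def summary(self) -> str:
        sa, sc, se_ = self.standardized()
        p = "NA" if self.comparison_p is None else f"{self.comparison_p:.3f}"
        return (
            f"{self.model} model: a2={self.a2:.4f} c2={self.c2:.4f} "
            f"e2={self.e2:.4f} (shares {sa:.2f}/{sc:.2f}/{se_:.2f}), "
            f"mean={self.mean:.4f}, minus2LL={self.minus2ll:.2f}, "
            f"df={self.df}, AIC={self.aic:.2f}, p_vs_ACE={p}"
        )


def _neg2ll(mu: float, a2: float, c2: float, e2: float,
            mz: np.ndarray, dz: np.ndarray) -> float:
    """-2 log likelihood of twin pairs under the bivariate-normal ACE model."""
    v = a2 + c2 + e2
    total = 0.0
    for pairs, cov in ((mz, a2 + c2), (dz, 0.5 * a2 + c2)):
        if pairs.shape[0] == 0:
            continue
        det = v * v - cov * cov
        if det <= 0 or v <= 0:
            return np.inf
        d1 = pairs[:, 0] - mu
        d2 = pairs[:, 1] - mu
        quad = (v * (d1 * d1 + d2 * d2) - 2.0 * cov * d1 * d2) / det
        total += np.sum(2.0 * _LOG2PI + np.log(det) + quad)
    return float(total)


class AceModel:
    """Twin ACE variance-component model for one trait.

    Parameters
    ----------
    mz_pairs, dz_pairs : array, shape (n_pairs, 2)
        Trait values of the two members of each MZ / DZ pair.

    Use :meth:`from_cohort` to build the model from a long cohort table.
    ``fit(model)`` returns an :class:`AceFit`; ``fit_all()`` fits all four
    models and performs the chi-square / AIC comparison.
    """

    def __init__(self, mz_pairs, dz_pairs):
        self.mz = np.asarray(mz_pairs, dtype=float).reshape(-1, 2)
        self.dz = np.asarray(dz_pairs, dtype=float).reshape(-1, 2)
        if self.mz.shape[0] + self.dz.shape[0] == 0:
            raise ConfigurationError("no twin pairs supplied")
        for name, arr in (("MZ", self.mz), ("DZ", self.dz)):
            if arr.shape[0] < 10:
                logger.warning("only %d %s pairs; estimates may be unstable",
                               arr.shape[0], name)
        self._all = np.concatenate([self.mz.ravel(), self.dz.ravel()])
        if self._all.std() == 0:
            raise ConfigurationError("trait has zero variance")

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, trait: str) -> "AceModel":
        mz, dz = pair_table(cohort, trait)
        return cls(mz, dz)

    # ---------------------------------------------------------------- fits

    def _starts(self, model: str) -> list[np.ndarray]:
        """Deterministic starting points on the (mu, a, c, e) path scale."""
        mu0 = float(self._all.mean())
        v0 = float(self._all.var())
        rmz = self._pair_corr(self.mz)
        rdz = self._pair_corr(self.dz)
        a2 = float(np.clip(2.0 * (rmz - rdz), 0.02, 0.95)) * v0
        c2 = float(np.clip(2.0 * rdz - rmz, 0.02, 0.95)) * v0
        e2 = max(v0 - a2 - c2, 0.05 * v0)
        third = v0 / 3.0
        raw = [
            (mu0, third, third, third),                 # equal split
            (mu0, a2, c2, e2),                          # twin-correlation informed
            (mu0, 0.05 * v0, 0.05 * v0, 0.90 * v0),     # E-dominant
        ]
        starts = []
        for mu, aa, cc, ee in raw:
            full = {"mu": mu, "a": np.sqrt(aa), "c": np.sqrt(cc), "e": np.sqrt(ee)}
            starts.append(self._pack(full, model))
        return starts

    @staticmethod
    def _pair_corr(pairs: np.ndarray) -> float:
        if pairs.shape[0] < 3:
            return 0.0
        x = np.concatenate([pairs[:, 0], pairs[:, 1]])
        y = np.concatenate([pairs[:, 1], pairs[:, 0]])
        r = np.corrcoef(x, y)[0, 1]
        return float(r) if np.isfinite(r) else 0.0

    @staticmethod
    def _pack(full: dict, model: str) -> np.ndarray:
        free = ["mu"] + [p for p in "ace" if p.upper() in model]
        return np.array([full[p] for p in free], dtype=float)

    def _unpack(self, x: np.ndarray, model: str) -> tuple[float, float, float, float]:
        vals = {"a": 0.0, "c": 0.0, "e": 0.0}
        free = [p for p in "ace" if p.upper() in model]
        for p, v in zip(free, x[1:]):
            vals[p] = v
        return float(x[0]), vals["a"] ** 2, vals["c"] ** 2, vals["e"] ** 2

    def fit(self, model: str = "ACE", extra_starts=()) -> AceFit:
        """Maximize the pair likelihood for one of ACE, AE, CE, E.

        Variance components are kept nonnegative by optimizing path
        coefficients (a, c, e) whose squares are the components; a
        deterministic multi-start (no RNG) guards against local optima.
        """
        model = model.upper()
        if model not in ACE_MODELS:
            raise ConfigurationError(f"unknown model {model!r}; choose from {ACE_MODELS}")

        def objective(x):
            mu, a2, c2, e2 = self._unpack(x, model)
            return _neg2ll(mu, a2, c2, e2, self.mz, self.dz)

        best = None
        starts = self._starts(model) + [np.asarray(s, float) for s in extra_starts]
        for x0 in starts:
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConfigurationError(
                f"{model} fit failed to converge from all starting points"
            )
        mu, a2, c2, e2 = self._unpack(best.x, model)
        n_obs = self._all.size
        n_params = _FREE_PARAMS[model]
        df = n_obs - n_params
        return AceFit(
            model=model, a2=a2, c2=c2, e2=e2, mean=mu,
            minus2ll=float(best.fun), n_obs=n_obs, n_params=n_params,
            df=df, aic=aic(best.fun, df),
        )

    def fit_e_closed_form(self) -> AceFit:
        """Closed-form ML fit of the E model (independent twins).

        With a = c = 0 the likelihood factorizes over all 2n observations:
        mu_hat is the grand mean and e2_hat the ML variance.
        """
        x = self._all
        mu = float(x.mean())
        e2 = float(x.var())
        m2ll = x.size * (_LOG2PI + np.log(e2) + 1.0)
        df = x.size - _FREE_PARAMS["E"]
        return AceFit(model="E", a2=0.0, c2=0.0, e2=e2, mean=mu,
                      minus2ll=m2ll, n_obs=x.size, n_params=_FREE_PARAMS["E"],
                      df=df, aic=aic(m2ll, df))

    def fit_all(self) -> "AceComparison":
        """Fit ACE, AE, CE and E and run the chi-square / AIC selection.

        Nested solutions are fed forward as extra starting points for the
        richer models, which guarantees the likelihood-nesting inequality
        minus2LL(ACE) <= minus2LL(nested) up to optimizer tolerance.
        """
        e_fit = self.fit_e_closed_form()

        def seed_from(fit: AceFit, model: str) -> np.ndarray:
            full = {"mu": fit.mean, "a": np.sqrt(fit.a2),
                    "c": np.sqrt(fit.c2), "e": np.sqrt(max(fit.e2, 1e-12))}
            return self._pack(full, model)

        ae = self.fit("AE", extra_starts=[seed_from(e_fit, "AE")])
        ce = self.fit("CE", extra_starts=[seed_from(e_fit, "CE")])
        ace = self.fit("ACE", extra_starts=[seed_from(ae, "ACE"),
                                            seed_from(ce, "ACE")])
        return compare_models([ace, ae, ce, e_fit])


# ------------------------------------------------------------- selection


@dataclass(frozen=True)
class AceComparison:
    """Chi-square and AIC comparison of the four twin models."""

    fits: tuple
    selected: str

    @property
    def ace(self) -> AceFit:
        return next(f for f in self.fits if f.model == "ACE")

    def __getitem__(self, model: str) -> AceFit:
        return next(f for f in self.fits if f.model == model.upper())

    def table(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            rows.append({
                "model": f.model, "a2": f.a2, "c2": f.c2, "e2": f.e2,
                "minus2LL": f.minus2ll, "df": f.df, "AIC": f.aic,
                "p": np.nan if f.comparison_p is None else f.comparison_p,
                "selected": f.model == self.selected,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Twin model comparison (selected: {self.selected})"]
        for f in self.fits:
            mark = " *" if f.model == self.selected else "  "
            lines.append(mark + f.summary())
        return "\n".join(lines)


def compare_models(fits: list) -> AceComparison:
    """Likelihood-ratio chi-square of each nested model against ACE, then
    select the lowest-AIC model among those with non-significant chi-square
    (p > 0.05); ACE itself is selected only if every nested model is
    significantly worse."""
    by_model = {f.model: f for f in fits}
    if "ACE" not in by_model:
        raise ConfigurationError("comparison requires the ACE baseline fit")
    ace = by_model["ACE"]
    out = [ace]
    candidates = []
    for f in fits:
        if f.model == "ACE":
            continue
        stat = max(f.minus2ll - ace.minus2ll, 0.0)
        ddf = ace.n_params - f.n_params
        p = float(stats.chi2.sf(stat, ddf)) if ddf > 0 else np.nan
        f = AceFit(**{**f.__dict__, "comparison_p": p})
        out.append(f)
        if p > 0.05:
            candidates.append(f)
    if candidates:
        selected = min(candidates, key=lambda f: f.aic).model
    else:
        selected = "ACE"
    order = {m: i for i, m in enumerate(ACE_MODELS)}
    out.sort(key=lambda f: order[f.model])
    return AceComparison(fits=tuple(out), selected=selected)


# ---------------------------------------------------------------- reports


def heritability_report(
    cohort: pd.DataFrame,
    ef_traits=("cEF", "SHI", "UPD"),
    reliance_wide: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Falconer + SEM heritability block for EF factors and network reliance.

    Returns one row per trait (EF factors first, then one per network's
    reliance) with rMZ, rDZ, Falconer H, the selected model, and per-model
    minus2LL / df / AIC / p columns mirroring the twin-model comparison.
    """
    rows = []
    work = cohort.copy()
    traits = [(t, "EF") for t in ef_traits]
    if reliance_wide is not None:
        for net in reliance_wide.columns:
            col = f"reliance_{net}"
            work = work.merge(
                reliance_wide[net].rename(col),
                left_on="subject_id", right_index=True, how="left",
            )
            traits.append((col, "network_reliance"))
    for trait, kind in traits:
        tc = twin_correlations(trait, work)
        comp = AceModel.from_cohort(work, trait).fit_all()
        row = {
            "trait": trait.replace("reliance_", ""), "kind": kind,
            "rMZ": tc.r_mz, "rDZ": tc.r_dz,
            "falconer_H": falconer(tc.r_mz, tc.r_dz),
            "selected_model": comp.selected,
            "n_mz_pairs": tc.n_mz_pairs, "n_dz_pairs": tc.n_dz_pairs,
        }
        for f in comp.fits:
            m = f.model
            row[f"minus2LL_{m}"] = f.minus2ll
            row[f"df_{m}"] = f.df
            row[f"AIC_{m}"] = f.aic
            row[f"p_{m}"] = np.nan if f.comparison_p is None else f.comparison_p
            row[f"a2_{m}"] = f.a2
            row[f"c2_{m}"] = f.c2
            row[f"e2_{m}"] = f.e2
        rows.append(row)
    return pd.DataFrame(rows)
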