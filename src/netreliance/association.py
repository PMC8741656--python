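"""Stage-wise association between network node loss and executive function.

For every (network, stage) cell the model

    nodes_lost ~ cEF + SHI + UPD + scanner

is fitted by OLS with standard errors made robust to within-family
clustering (twins are not independent observations), and Benjamini-
Hochberg FDR is applied across the 8 stages within each network (per
predictor). A positive coefficient means individuals with higher scores
on that factor lose more of that network's nodes at that stage, i.e.
their resting-state organisation relies more on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

EF_FACTORS = ("cEF", "SHI", "UPD")
ALPHA = 0.05


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=ALPHA, method="fdr_bh")[1]


def vif(scores: pd.DataFrame, factors=EF_FACTORS) -> pd.Series:
    """Variance inflation factor per EF factor.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from regressing factor j on the
    remaining factors (with intercept). Perfect collinearity yields +inf
    with a warning.
    """
    if len(scores) < 4:
        raise ConfigurationError("need at least 4 subjects to compute VIF")
    out = {}
    for j in factors:
        if scores[j].std() == 0:
            raise ConfigurationError(f"factor {j} is constant")
        others = [f for f in factors if f != j]
        X = sm.add_constant(scores[list(others)].to_numpy(dtype=float))
        r2 = sm.OLS(scores[j].to_numpy(dtype=float), X).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            logger.warning("factor %s is perfectly collinear with the others", j)
            out[j] = np.inf
        else:
            out[j] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def _scanner_indicator(scanner: pd.Series) -> tuple[np.ndarray, str]:
    """Binary scanner code with TRIO (or the alphabetically first label)
    as the reference level."""
    labels = sorted(set(scanner.astype(str)))
    if len(labels) > 2:
        raise ConfigurationError(f"expected at most 2 scanner labels, got {labels}")
    ref = "TRIO" if "TRIO" in labels else labels[0]
    other = next((l for l in labels if l != ref), None)
    ind = (scanner.astype(str) != ref).to_numpy(dtype=float)
    return ind, (other or ref)


def fit_stage_model(
    node_loss,
    scores: pd.DataFrame,
    scanner: pd.Series,
    family: pd.Series,
) -> pd.DataFrame:
    """OLS fit of nodes_lost ~ cEF + SHI + UPD + scanner with family-
    clustered sandwich standard errors.

    Returns one row per predictor (const, cEF, SHI, UPD, scanner) with
    columns beta, se, p, n.
    """
    y = np.asarray(node_loss, dtype=float)
    n = y.size
    if n < 10:
        raise ConfigurationError(f"need at least 10 subjects, got {n}")
    fam = np.asarray(family)
    if len(np.unique(fam)) < 2:
        raise ConfigurationError("need at least 2 family clusters")
    scan_ind, _ = _scanner_indicator(pd.Series(scanner))
    X = pd.DataFrame(
        {f: scores[f].to_numpy(dtype=float) for f in EF_FACTORS}
        | {"scanner": scan_ind}
    )
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # drop-one scan to name the offending predictors
        bad = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(Xc.drop(columns=c).to_numpy()) == rank
        ]
        raise ConfigurationError(f"perfectly collinear predictors: {bad}")
    res = sm.OLS(y, Xc).fit(cov_type="cluster", cov_kwds={"groups": fam})
    p = res.pvalues.to_numpy()
    # degenerate cells (constant response within rounding) yield NaN
    # p-values; they carry no evidence against the null
    p = np.where(np.isfinite(p), p, 1.0)
    return pd.DataFrame(
        {
            "predictor": Xc.columns,
            "beta": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "p": p,
            "n": n,
        }
    )


@dataclass
class AssociationResults:
    """Results of the stage-wise association scan.

    ``table`` has one row per (network, stage, predictor) with beta,
    cluster-robust se, p, BH-adjusted q and significance flags.
    """

    table: pd.DataFrame
    fdr_scope: str
    n_subjects: int

    @property
    def significant(self) -> pd.DataFrame:
        """Rows of EF predictors surviving FDR."""
        t = self.table
        return t[(t["significant_fdr"]) & (t["predictor"].isin(EF_FACTORS))]

    def summary(self) -> str:
        lines = [
            "Stage-wise association: nodes_lost ~ cEF + SHI + UPD + scanner",
            f"subjects: {self.n_subjects}; FDR scope: {self.fdr_scope}; "
            f"alpha = {ALPHA}",
            "",
        ]
        sig = self.significant
        if sig.empty:
            lines.append("No (network, stage, factor) cell survives FDR.")
        else:
            lines.append("Cells surviving FDR (q < 0.05):")
            for _, r in sig.iterrows():
                lines.append(
                    f"  {r['network']:>5} stage {r['stage']}: "
                    f"{r['predictor']} beta={r['beta']:+.3f} "
                    f"(se={r['se']:.3f}, p={r['p']:.4f}, q={r['q']:.4f})"
                )
        return "\n".join(lines)


class StagewiseAssociation:
    """Model object for the network x stage EF association scan.

    Parameters
    ----------
    counts_long : DataFrame
        subject_id, network, stage, nodes_lost (output of
        ``lesioning.cohort_reliance``).
    cohort : DataFrame
        subject_id, family_id, scanner and the three EF factor scores.
    fdr_scope : {"network", "global"}
        BH family: the 8 stages within one network (default, applied per
        predictor), or all network x stage cells at once.
    """

    def __init__(self, counts_long: pd.DataFrame, cohort: pd.DataFrame,
                 fdr_scope: str = "network"):
        if fdr_scope not in ("network", "global"):
            raise ConfigurationError(f"unknown fdr_scope {fdr_scope!r}")
        self.counts_long = counts_long
        self.cohort = cohort
        self.fdr_scope = fdr_scope

    def fit(self) -> AssociationResults:
        cohort = self.cohort.set_index("subject_id")
        subjects = self.counts_long["subject_id"].unique()
        have = [s for s in subjects if s in cohort.index]
        dropped = len(subjects) - len(have)
        if dropped:
            logger.warning("dropping %d subjects with no EF scores", dropped)
        if not have:
            cols = ["network", "stage", "predictor", "beta", "se", "p", "q",
                    "significant_raw", "significant_fdr", "n"]
            return AssociationResults(pd.DataFrame(columns=cols),
                                      self.fdr_scope, 0)
        cohort = cohort.loc[have]
        wide = self.counts_long.pivot_table(
            index="subject_id", columns=["network", "stage"],
            values="nodes_lost", aggfunc="first",
        ).loc[have]
        rows = []
        networks = self.counts_long["network"].unique()
        stages = sorted(self.counts_long["stage"].unique())
        for net in networks:
            for s in stages:
                fit = fit_stage_model(
                    wide[(net, s)].to_numpy(),
                    cohort[list(EF_FACTORS)],
                    cohort["scanner"],
                    cohort["family_id"],
                )
                fit.insert(0, "network", net)
                fit.insert(1, "stage", s)
                rows.append(fit)
        table = pd.concat(rows, ignore_index=True)
        table = table[table["predictor"] != "const"].reset_index(drop=True)
        table["q"] = np.nan
        if self.fdr_scope == "network":
            groups = table.groupby(["network", "predictor"]).groups.values()
        else:
            groups = table.groupby("predictor").groups.values()
        for idx in groups:
            table.loc[idx, "q"] = fdr_adjust(table.loc[idx, "p"].to_numpy())
        table["significant_raw"] = table["p"] < ALPHA
        table["significant_fdr"] = table["q"] < ALPHA
        return AssociationResults(table, self.fdr_scope, len(have))


def run_association(
    counts_long: pd.DataFrame, cohort: pd.DataFrame, fdr_scope: str = "network"
) -> pd.DataFrame:
    """Functional wrapper: full (network x stage x predictor) results table."""
    return StagewiseAssociation(counts_long, cohort, fdr_scope).fit().table
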