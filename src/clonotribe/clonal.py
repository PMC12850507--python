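"""Serial-sample clonal hematopoiesis dynamics.

Mutations are called when a blood draw shows total depth >= 100, >= 3
variant reads and VAF >= 2%. Among mutations called at the first draw
(baseline VAF >= 2%), those with second-draw VAF >= 2% are persistent and
the rest transient. The annualized growth rate of a persistent clone is
the compound-interest rate r = (VAF2/VAF1)^(1/t) - 1 over the t years
between draws.

Two covariate-adjusted models quantify the genotype effect: ordinary
least squares of r on age, age^2, baseline VAF, sex, protective-allele
dosage and driver gene (one-hot, most frequent gene as reference), and a
logistic regression of transience on the same design whose exponentiated
dosage coefficient is the transience odds ratio. Per-driver-gene refits
drop the driver-gene covariate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

PERSISTENT = "persistent"
TRANSIENT = "transient"
UNCALLED = "uncalled"


class SeparationError(RuntimeError):
    """Raised when the logistic likelihood has no finite maximum."""


def _draw_called(depth: pd.Series, alt: pd.Series, vaf: pd.Series,
                 min_depth: int, min_alt: int, min_vaf: float) -> pd.Series:
    return (depth >= min_depth) & (alt >= min_alt) & (vaf >= min_vaf)


def classify_trajectories(
    records: pd.DataFrame,
    min_depth: int = 100,
    min_alt_reads: int = 3,
    min_vaf: float = 0.02,
) -> pd.DataFrame:
    """Label each trajectory persistent, transient, or uncalled.

    A record is called when at least one draw passes all three calling
    thresholds. Classification applies to the baseline-called set (first
    draw passes the thresholds): persistent iff VAF2 >= min_vaf, else
    transient. Called-only-at-follow-up records stay uncalled, as do
    records missing a second draw.
    """
    out = records.copy()
    has_m2 = out[["vaf2", "depth2", "alt2"]].notna().all(axis=1)
    called1 = _draw_called(out["depth1"], out["alt1"], out["vaf1"], min_depth, min_alt_reads, min_vaf)
    called2 = has_m2 & _draw_called(out["depth2"], out["alt2"], out["vaf2"], min_depth, min_alt_reads, min_vaf)
    baseline = called1 & has_m2

    out["class"] = UNCALLED
    out.loc[baseline & (out["vaf2"] >= min_vaf), "class"] = PERSISTENT
    out.loc[baseline & (out["vaf2"] < min_vaf), "class"] = TRANSIENT
    out["called"] = called1 | called2

    out["r"] = np.nan
    pers = out["class"] == PERSISTENT
    out.loc[pers, "r"] = growth_rate(
        out.loc[pers, "vaf1"].to_numpy(),
        out.loc[pers, "vaf2"].to_numpy(),
        out.loc[pers, "dt_years"].to_numpy(),
    )
    return out


def growth_rate(vaf1, vaf2, t):
    """Compound-interest annualized growth rate (VAF2/VAF1)^(1/t) - 1."""
    vaf1 = np.asarray(vaf1, dtype=float)
    vaf2 = np.asarray(vaf2, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(vaf1 <= 0) or np.any(vaf2 <= 0) or np.any(t <= 0):
        raise ValueError("VAF1, VAF2 and t must all be positive")
    return (vaf2 / vaf1) ** (1.0 / t) - 1.0


DEFAULT_COVARIATES = ("age", "age2", "vaf", "sex")


def _design(
    records: pd.DataFrame,
    include_gene: bool = True,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    X = pd.DataFrame(index=records.index)
    if "age" in covariates:
        X["age"] = records["age"]
    if "age2" in covariates:
        X["age2"] = records["age"] ** 2
    if "vaf" in covariates:
        X["vaf"] = records["vaf1"]
    if "sex" in covariates:
        X["sex_M"] = (records["sex"] == "M").astype(float)
    X["genotype"] = records["genotype"].astype(float)
    if include_gene:
        ref = records["gene"].mode().iloc[0]  # most frequent gene as reference level
        for g in sorted(records["gene"].unique()):
            if g != ref:
                X[f"gene_{g}"] = (records["gene"] == g).astype(float)
    X.insert(0, "const", 1.0)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased columns by greedy QR elimination
        aliased = []
        cols: list[str] = []
        for c in X.columns:
            trial = cols + [c]
            if np.linalg.matrix_rank(X[trial].to_numpy()) < len(trial):
                aliased.append(c)
            else:
                cols.append(c)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def fit_growth_model(
    persistent: pd.DataFrame,
    include_gene: bool = True,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """OLS of growth rate on the stated covariate design.

    Returns the coefficient table (coef, se, p, 95% CI) with the
    protective-allele dosage row flagged.
    """
    X = _design(persistent, include_gene=include_gene, covariates=covariates)
    _check_rank(X)
    fit = sm.OLS(persistent["r"].astype(float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "term": X.columns,
            "coef": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "p_value": fit.pvalues.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
        }
    )
    table["is_genotype"] = table["term"] == "genotype"
    return table


def fit_transience_model(
    baseline_called: pd.DataFrame,
    include_gene: bool = True,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Logistic regression of transience; OR from the dosage coefficient.

    The outcome is ``transient`` (0/1) if present, else derived from the
    ``class`` column. Complete separation raises
    :class:`SeparationError` with a diagnostic rather than reporting a
    divergent estimate.
    """
    if "transient" in baseline_called:
        y = baseline_called["transient"].astype(float)
    else:
        y = (baseline_called["class"] == TRANSIENT).astype(float)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    X = _design(baseline_called, include_gene=include_gene, covariates=covariates)
    _check_rank(X)
    # standardize non-constant columns for Newton conditioning (age^2 spans
    # orders of magnitude); the fit is reparameterization-equivariant, so
    # coefficients and SEs are mapped back exactly
    scale = X.std(axis=0).replace(0.0, 1.0)
    scale["const"] = 1.0
    Xs = X / scale
    try:
        with warnings.catch_warnings():
            # rare factor levels with zero events diverge and trip the
            # iteration cap; they are detected and flagged below instead
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = sm.Logit(y, Xs).fit(disp=0, maxiter=500)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = fit.params / scale
    bse = fit.bse / scale
    fitted = fit.predict(Xs)
    identified = np.isfinite(fit.bse) & (np.abs(fit.params) <= 15)
    perfectly_predicted = bool(np.all(np.abs(y - fitted) < 1e-6))
    if perfectly_predicted or not identified["genotype"]:
        raise SeparationError(
            "complete or quasi-complete separation on the genotype term: "
            "divergent coefficient or non-finite standard error"
        )
    table = pd.DataFrame(
        {
            "term": X.columns,
            "coef": params.to_numpy(),
            "se": bse.to_numpy(),
            "p_value": fit.pvalues.to_numpy(),
            "or": np.exp(params.to_numpy()),
            # CI exponents clipped to the double range: a +/-inf bound is
            # more honest than an overflow warning for near-empty levels
            "or_ci_low": np.exp(np.clip((params - 1.96 * bse).to_numpy(), -709, 709)),
            "or_ci_high": np.exp(np.clip((params + 1.96 * bse).to_numpy(), -709, 709)),
            "identified": identified.to_numpy(),
        }
    )
    table["is_genotype"] = table["term"] == "genotype"
    return table


def genotype_effect(table: pd.DataFrame) -> pd.Series:
    """The protective-allele dosage row of a model table."""
    return table.loc[table["is_genotype"]].iloc[0]
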