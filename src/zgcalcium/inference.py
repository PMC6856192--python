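"""Hierarchical genotype comparison and phenotype formulas.

Cells recorded from the same animal are not independent; treating them as
such (pseudoreplication) inflates false-positive rates.  Per-cell
activity metrics are therefore compared between genotypes with Gaussian
linear mixed models carrying a random intercept per animal, and the
genotype effect is tested by a likelihood-ratio test (LRT) against the
model omitting genotype: chi2 = 2 (logL_full - logL_reduced), referred to
a chi-squared distribution with df equal to the fixed-parameter
difference.  All models entering an LRT are fitted by maximum likelihood
(not REML), since REML log-likelihoods of models with different fixed
effects are not comparable.

Also here: the two small phenotype formulas — relative gene expression as
2^(-ddCt) fold change against a reference group, and the per-animal
aldosterone:renin ratio (ARR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

logger = logging.getLogger("zgcalcium")

__all__ = [
    "LmmSpec",
    "FittedLmm",
    "LmmComparison",
    "fit_lmm",
    "lrt_genotype",
    "compare_conditions",
    "ddct_fold_change",
    "aldosterone_renin_ratio",
]


@dataclass(frozen=True)
class LmmSpec:
    """Specification of one Gaussian linear mixed model.

    response
        Column holding the (numeric) response metric.
    fixed_effects
        Covariate columns; categorical columns are expanded to treatment
        contrasts.  Empty list = intercept-only.
    random_intercepts
        Grouping columns, one independent random intercept each
        (default: animal).
    """

    response: str
    fixed_effects: tuple[str, ...] = ("genotype",)
    random_intercepts: tuple[str, ...] = ("animal_id",)

    def __post_init__(self):
        if not self.random_intercepts:
            raise ValueError("at least one random-intercept factor is required")

    def formula(self) -> str:
        rhs = " + ".join(self.fixed_effects) if self.fixed_effects else "1"
        return f"{self.response} ~ {rhs}"

    def without(self, effect: str) -> "LmmSpec":
        """The nested model omitting one fixed effect (for the LRT)."""
        if effect not in self.fixed_effects:
            raise ValueError(f"{effect!r} is not a fixed effect of this model")
        return LmmSpec(
            self.response,
            tuple(f for f in self.fixed_effects if f != effect),
            self.random_intercepts,
        )


@dataclass
class FittedLmm:
    """A fitted mixed model: what the LRT and reports need."""

    spec: LmmSpec
    loglik: float
    n_obs: int
    k_fixed: int
    fixed_effects: pd.Series
    fixed_se: pd.Series
    random_variances: dict[str, float]
    residual_variance: float
    converged: bool


def fit_lmm(data: pd.DataFrame, spec: LmmSpec) -> FittedLmm:
    """Fit a Gaussian LMM with independent random intercepts, by ML.

    One grouping factor uses the standard random-intercept
    parameterisation; several are fitted as independent variance
    components on a single group (crossed random intercepts, as in the
    telemetry blood-pressure design with animal and time-of-day).
    Non-convergence is reported on the result, never silently ignored.
    """
    data = data.copy()
    for col in (spec.response, *spec.fixed_effects, *spec.random_intercepts):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    if not pd.api.types.is_numeric_dtype(data[spec.response]):
        raise ValueError(f"response {spec.response!r} must be numeric")
    for g in spec.random_intercepts:
        if data[g].nunique() < 2:
            raise ValueError(f"grouping factor {g!r} has fewer than 2 levels")

    formula = spec.formula()
    if len(spec.random_intercepts) == 1:
        model = smf.mixedlm(formula, data, groups=data[spec.random_intercepts[0]])
    else:
        data["_one_group"] = 1
        vc = {g: f"0 + C({g})" for g in spec.random_intercepts}
        model = smf.mixedlm(formula, data, groups=data["_one_group"], vc_formula=vc)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance estimates are expected
        res = model.fit(reml=False)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        logger.warning("mixed model did not converge: %s", formula)

    k_fe = int(res.k_fe)
    fe_names = res.model.exog_names
    if len(spec.random_intercepts) == 1:
        rv = {spec.random_intercepts[0]: float(np.atleast_2d(res.cov_re)[0, 0])}
    else:
        rv = {g: float(res.vcomp[i]) for i, g in enumerate(spec.random_intercepts)}
    return FittedLmm(
        spec=spec,
        loglik=float(res.llf),
        n_obs=int(res.nobs),
        k_fixed=k_fe,
        fixed_effects=res.params[fe_names[:k_fe]] if k_fe else pd.Series(dtype=float),
        fixed_se=res.bse[fe_names[:k_fe]] if k_fe else pd.Series(dtype=float),
        random_variances=rv,
        residual_variance=float(res.scale),
        converged=converged,
    )


@dataclass
class LmmComparison:
    """Likelihood-ratio comparison of a full vs. a reduced mixed model."""

    loglik_full: float
    loglik_reduced: float
    chi2: float
    df: int
    p_value: float
    fixed_effects: pd.Series
    fixed_se: pd.Series
    random_variances: dict[str, float]
    converged: bool


def lrt_genotype(full: FittedLmm, reduced: FittedLmm) -> LmmComparison:
    """LRT of the fixed effect dropped between two nested ML fits.

    chi2 = 2 (logL_full - logL_reduced), clipped at 0 against optimizer
    noise; p is the upper tail of chi2 with df = fixed-parameter
    difference.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError(
            f"models fitted on different rows ({full.n_obs} vs {reduced.n_obs})"
        )
    df = full.k_fixed - reduced.k_fixed
    if df < 1:
        raise ValueError("reduced model is not nested in the full model (df < 1)")
    if set(reduced.spec.fixed_effects) - set(full.spec.fixed_effects):
        raise ValueError("reduced model has fixed effects absent from the full model")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, df))
    return LmmComparison(
        loglik_full=full.loglik,
        loglik_reduced=reduced.loglik,
        chi2=chi2,
        df=df,
        p_value=p,
        fixed_effects=full.fixed_effects,
        fixed_se=full.fixed_se,
        random_variances=full.random_variances,
        converged=full.converged and reduced.converged,
    )


def genotype_lrt(
    data: pd.DataFrame,
    response: str,
    fixed_effects: tuple[str, ...] = ("genotype",),
    random_intercepts: tuple[str, ...] = ("animal_id",),
    tested_effect: str = "genotype",
) -> LmmComparison:
    """Convenience wrapper: fit full and reduced models and run the LRT."""
    spec = LmmSpec(response, tuple(fixed_effects), tuple(random_intercepts))
    full = fit_lmm(data, spec)
    reduced = fit_lmm(data, spec.without(tested_effect))
    return lrt_genotype(full, reduced)


def compare_conditions(
    summaries: pd.DataFrame,
    metric: str = "spikes_per_s",
    conditions: list[str] | None = None,
    random_intercepts: tuple[str, ...] = ("animal_id",),
) -> pd.DataFrame:
    """Per-condition genotype LRT on a cell x epoch summary table.

    Returns one row per condition with group Ns, means +- SD, chi2, df
    and p.  Conditions where the metric is identically zero in both
    genotypes (e.g. no-AT-II epochs with essentially no spikes) are
    flagged ``not tested`` rather than fitted.
    """
    if metric not in summaries.columns:
        raise ValueError(f"metric {metric!r} not in summary table")
    if conditions is None:
        conditions = list(pd.unique(summaries["condition"]))
    genotypes = sorted(pd.unique(summaries["genotype"]))
    if len(genotypes) != 2:
        raise ValueError(f"need exactly 2 genotypes, found {genotypes}")
    rows = []
    for cond in conditions:
        sub = summaries[summaries["condition"] == cond].dropna(subset=[metric])
        row = {"metric": metric, "condition": cond}
        for g in genotypes:
            vals = sub.loc[sub["genotype"] == g, metric]
            row[f"n_{g}"] = int(len(vals))
            row[f"mean_{g}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"sd_{g}"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        testable = (
            all(row[f"n_{g}"] > 0 for g in genotypes)
            and np.nanstd(sub[metric].to_numpy(float)) > 0
        )
        if not testable:
            row.update(chi2=np.nan, df=np.nan, p_value=np.nan, tested=False)
        else:
            cmp_ = genotype_lrt(sub, metric, random_intercepts=random_intercepts)
            row.update(chi2=cmp_.chi2, df=cmp_.df, p_value=cmp_.p_value, tested=True)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phenotype formulas
# ---------------------------------------------------------------------------

def ddct_fold_change(records: pd.DataFrame, reference_group: str = "WT") -> pd.DataFrame:
    """Relative expression per animal: fold change = 2^(-ddCt).

    dCt = ct_target - ct_housekeeping per animal; ddCt = dCt minus the
    reference-group mean dCt.  Lower target Ct (more template) gives fold
    change > 1; the reference group's geometric-mean fold change is
    exactly 1 by construction.
    """
    for col in ("genotype", "ct_target", "ct_housekeeping"):
        if col not in records.columns:
            raise ValueError(f"column {col!r} missing from phenotype records")
    if records[["ct_target", "ct_housekeeping"]].isna().any().any():
        raise ValueError("missing Ct values in phenotype records")
    ref = records[records["genotype"] == reference_group]
    if len(ref) == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    out = records.copy()
    out["delta_ct"] = out["ct_target"] - out["ct_housekeeping"]
    ref_mean = float(out.loc[out["genotype"] == reference_group, "delta_ct"].mean())
    out["delta_delta_ct"] = out["delta_ct"] - ref_mean
    out["fold_change"] = 2.0 ** (-out["delta_delta_ct"])
    return out


def aldosterone_renin_ratio(records: pd.DataFrame) -> pd.DataFrame:
    """Per-animal ARR = aldosterone / PRC (pg ml^-1 per ng ml^-1 h^-1).

    Group summaries of ARR must average the per-animal ratios, never
    divide group means — the two differ on heterogeneous data.
    """
    for col in ("aldosterone", "prc"):
        if col not in records.columns:
            raise ValueError(f"column {col!r} missing from phenotype records")
    if (records["prc"] <= 0).any():
        bad = records.loc[records["prc"] <= 0].index[0]
        raise ValueError(f"nonpositive PRC for record {bad}; ARR undefined")
    out = records.copy()
    out["arr"] = out["aldosterone"] / out["prc"]
    return out
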