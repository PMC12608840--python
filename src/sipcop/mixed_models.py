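"""Linear mixed-effects models of the SIP-CoP relationship.

Proportional pressure is regressed on CoP magnitude (centered on its grand
mean) with lean direction -- and, where present, cushion, starting position,
and participant type -- as categorical fixed effects, participant as the
grouping factor, and random-effects structures of increasing richness:

    (1)                          random intercept only
    (1 + CoP)                    + per-participant CoP slope
    (1 + CoP + PR + CoP:PR)      + per-participant direction offsets and
                                   direction-specific CoP slopes
    maximal CoP interactions     + per-participant slopes for every other
                                   CoP interaction present

Numerical fitting is delegated to statsmodels' MixedLM with REML; this
module's own work is design construction (treatment coding with baselines
forward / air / backrest / AB), centering, AIC/BIC bookkeeping across
structures, confidence-interval assembly, and slope composition.  AIC/BIC
are computed from the restricted log-likelihood as -2 llf + {2, ln n} k with
k counting fixed effects, covariance parameters, and the residual variance
(statsmodels leaves them undefined under REML).  Reported degrees of freedom
are the large-sample residual approximation n - k_fe; p-values are the
routine's Wald tests.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import (
    MissingTermError,
    SingleLevelFactorError,
    ValidationError,
)

REQUIRED_COLUMNS = (
    "participant", "group", "cushion", "start_position", "direction",
    "cop_mag", "prop_pressure",
)

BASELINES = {
    "direction": "forward",
    "cushion": "air",
    "start_position": "backrest",
    "group": "AB",
}

FACTOR_LEVELS = {
    "direction": ("forward", "left", "right"),
    "cushion": ("air", "foam", "own"),
    "start_position": ("backrest", "situp"),
    "group": ("AB", "MWU"),
}

#: Random-effects structures, by the label of the per-participant formula.
STRUCTURES = ("(1)", "(1 + CoP)", "(1 + CoP + PR + CoP:PR)", "maximal")

_WALD_Z = 1.959963984540054  # 97.5th normal percentile, 95% CIs


def validate_dataset(data: pd.DataFrame) -> pd.DataFrame:
    """Check an LMM dataset's columns, vocabularies, and invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValidationError(f"LMM dataset missing columns: {missing}")
    if data["participant"].nunique() < 2:
        raise ValidationError("LMM dataset needs at least 2 participants")
    if (data["cop_mag"] < 0).any():
        raise ValidationError("cop_mag must be nonnegative")
    for col, levels in FACTOR_LEVELS.items():
        bad = set(data[col].unique()) - set(levels)
        if bad:
            raise ValidationError(f"unknown {col} level(s): {sorted(bad)}")
    return data


@dataclass
class LmmSpec:
    """A ready-to-fit model specification.

    ``exog`` holds named design columns (Intercept, cop, treatment dummies,
    and cop x dummy interactions); ``re_columns`` maps each random-effects
    structure label to the subset of those columns given random slopes.
    """

    endog: pd.Series
    exog: pd.DataFrame
    groups: pd.Series
    re_columns: dict
    cop_mean: float
    data_hash: str
    description: str


@dataclass
class LmmResult:
    """Fixed-effects table plus information criteria for one fitted model.

    ``effects`` is indexed by term name with columns estimate, std_error,
    df, t, p, ci_low, ci_high.
    """

    effects: pd.DataFrame
    aic: float
    bic: float
    structure: str
    n_obs: int
    converged: bool = True
    data_hash: str = ""

    def __post_init__(self) -> None:
        bad = self.effects[
            (self.effects["ci_low"] > self.effects["estimate"])
            | (self.effects["estimate"] > self.effects["ci_high"])
        ]
        if len(bad):
            raise ValidationError(f"CI does not bracket estimate for {list(bad.index)}")

    @classmethod
    def from_effects_table(
        cls, estimates: dict, structure: str = "external", n_obs: int = 0
    ) -> "LmmResult":
        """Build a result from a plain {term: estimate} mapping (e.g. a
        published fixed-effects table) for slope composition and thresholds."""
        eff = pd.DataFrame(
            {
                "estimate": pd.Series(estimates, dtype=float),
                "std_error": np.nan,
                "df": np.nan,
                "t": np.nan,
                "p": np.nan,
            }
        )
        eff["ci_low"] = eff["estimate"]
        eff["ci_high"] = eff["estimate"]
        return cls(
            effects=eff, aic=np.nan, bic=np.nan, structure=structure, n_obs=n_obs
        )


def _dummy_name(col: str, level: str) -> str:
    short = {"direction": "dir", "cushion": "cushion", "start_position": "position",
             "group": "type"}[col]
    return f"{short}_{level}"


def build_design(
    data: pd.DataFrame,
    center_cop: bool = True,
    include_cushion: Optional[bool] = None,
    include_position: Optional[bool] = None,
    include_type: bool = False,
) -> LmmSpec:
    """Construct the fixed-effects design and random-structure column sets.

    CoP magnitude is centered on its grand mean when ``center_cop`` is set.
    Factors use treatment coding against the baselines forward / air /
    backrest / AB.  Direction is always included; cushion and starting
    position are included automatically when more than one level is observed
    (or on request), each with its CoP interaction; participant type is
    opt-in.  Requesting a factor observed at a single level raises
    :class:`SingleLevelFactorError`.
    """
    data = validate_dataset(data)
    n = len(data)
    cop_mean = float(data["cop_mag"].mean()) if center_cop else 0.0
    cop = data["cop_mag"].to_numpy() - cop_mean

    def levels_present(col: str):
        return [lv for lv in FACTOR_LEVELS[col] if lv in set(data[col])]

    factors = {"direction": True}
    for col, flag in (("cushion", include_cushion), ("start_position", include_position)):
        present = len(levels_present(col)) > 1
        if flag is True and not present:
            raise SingleLevelFactorError(f"{col} has a single observed level")
        factors[col] = present if flag is None else flag
    if include_type:
        if len(levels_present("group")) < 2:
            raise SingleLevelFactorError("group has a single observed level")
        factors["group"] = True

    if len(levels_present("direction")) < 2:
        raise SingleLevelFactorError("direction has a single observed level")

    exog = pd.DataFrame({"Intercept": np.ones(n), "cop": cop}, index=data.index)
    interactions = []
    for col, included in factors.items():
        if not included:
            continue
        for level in levels_present(col):
            if level == BASELINES[col]:
                continue
            name = _dummy_name(col, level)
            dummy = (data[col] == level).astype(float).to_numpy()
            exog[name] = dummy
            exog[f"cop_x_{name}"] = cop * dummy
            interactions.append(f"cop_x_{name}")

    dir_cols = [c for c in exog.columns if c.startswith(("dir_", "cop_x_dir_"))]
    re_columns = {
        "(1)": ["Intercept"],
        "(1 + CoP)": ["Intercept", "cop"],
        "(1 + CoP + PR + CoP:PR)": ["Intercept", "cop", *dir_cols],
        "maximal": ["Intercept", "cop", *dir_cols,
                    *[c for c in interactions if not c.startswith("cop_x_dir_")]],
    }
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(
            data[list(REQUIRED_COLUMNS)].reset_index(drop=True), index=True
        ).to_numpy().tobytes()
    ).hexdigest()[:16]
    return LmmSpec(
        endog=data["prop_pressure"].astype(float),
        exog=exog,
        groups=data["participant"],
        re_columns=re_columns,
        cop_mean=cop_mean,
        data_hash=digest,
        description="prop_pressure ~ " + " + ".join(exog.columns[1:]),
    )


def fit_lmm(spec: LmmSpec, random_structure: str = "(1 + CoP + PR + CoP:PR)") -> LmmResult:
    """Fit one REML mixed model for a given random-effects structure.

    Non-convergence is flagged on the result rather than raised, so that
    structure comparisons can still report the attempt.
    """
    if random_structure not in spec.re_columns:
        raise ValidationError(
            f"unknown random structure {random_structure!r}; "
            f"expected one of {list(spec.re_columns)}"
        )
    exog_re = spec.exog[spec.re_columns[random_structure]]
    model = MixedLM(spec.endog, spec.exog, groups=spec.groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = model.fit(reml=True, method=["lbfgs", "cg"], maxiter=500)
    n = int(model.nobs)
    k_fe = model.k_fe
    est = np.asarray(result.fe_params, dtype=float)
    se = np.asarray(result.bse_fe, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = est / se
    pvals = np.asarray(result.pvalues)[:k_fe]
    effects = pd.DataFrame(
        {
            "estimate": est,
            "std_error": se,
            "df": float(n - k_fe),
            "t": tvals,
            "p": pvals,
            "ci_low": est - _WALD_Z * se,
            "ci_high": est + _WALD_Z * se,
        },
        index=list(spec.exog.columns),
    )
    # number of estimated parameters: fixed effects + free covariance terms
    # of the random structure + the residual variance
    k_re = exog_re.shape[1]
    k = k_fe + k_re * (k_re + 1) // 2 + 1
    llf = float(result.llf)
    aic = -2.0 * llf + 2.0 * k
    bic = -2.0 * llf + np.log(n) * k
    return LmmResult(
        effects=effects,
        aic=aic,
        bic=bic,
        structure=random_structure,
        n_obs=n,
        converged=bool(result.converged),
        data_hash=spec.data_hash,
    )


def compare_models(results: Sequence[LmmResult]) -> pd.DataFrame:
    """Rank fitted structures by AIC (ascending), reporting BIC ranks too.

    All results must come from the same dataset.  Ties keep input order
    (stable sort)."""
    results = list(results)
    if len(results) < 2:
        raise ValidationError("need at least 2 results to compare")
    hashes = {r.data_hash for r in results}
    if len(hashes) > 1:
        raise ValidationError("models were fitted on different datasets")
    table = pd.DataFrame(
        {
            "structure": [r.structure for r in results],
            "aic": [r.aic for r in results],
            "bic": [r.bic for r in results],
            "converged": [r.converged for r in results],
        }
    )
    table["aic_rank"] = table["aic"].rank(method="min").astype(int)
    table["bic_rank"] = table["bic"].rank(method="min").astype(int)
    return table.sort_values("aic", kind="stable").reset_index(drop=True)


def total_slope(result: LmmResult, direction: str) -> float:
    """Compose the population SIP-CoP slope for a lean direction.

    Forward is the CoP estimate itself; lateral directions add the
    corresponding CoP x direction interaction."""
    est = result.effects["estimate"]
    if "cop" not in est.index:
        raise MissingTermError("model has no CoP term")
    if direction == "forward":
        return float(est["cop"])
    if direction in ("left", "right"):
        term = f"cop_x_dir_{direction}"
        if term not in est.index:
            raise MissingTermError(f"model has no {term} term")
        return float(est["cop"] + est[term])
    raise ValidationError(f"unknown direction {direction!r}")
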