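"""Model-based analysis of the measurement table.

One linear mixed-effects model per clinical parameter: rotation and flexion
as categorical fixed effects (reference categories R0 and F0) with their
interaction, a fixed effect for leg side, and a random intercept per
patient. Models are fitted by maximum likelihood so that likelihood-ratio
tests between nested models are valid for fixed effects; p-values from the
rotation, flexion and interaction tests are adjusted for multiple testing
across all fitted models with the Benjamini–Hochberg step-up procedure.
The conditional R² follows the Nakagawa–Schielzeth variance decomposition:
(fixed-effect variance + intercept variance) / (those + residual variance),
with the fixed-effect variance taken as the variance of the fixed linear
predictor over the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy.stats import chi2, norm
import statsmodels.formula.api as smf

from .errors import ConvergenceError, ValidationError
from .measure import PARAMETERS

_RHS_FULL = ("C(rotation_deg, Treatment(reference=0)) * "
             "C(flexion_deg, Treatment(reference=0))")
_RHS_MAIN = ("C(rotation_deg, Treatment(reference=0)) + "
             "C(flexion_deg, Treatment(reference=0))")
_RHS_ROT = "C(rotation_deg, Treatment(reference=0))"
_RHS_FLEX = "C(flexion_deg, Treatment(reference=0))"

TESTED_TERMS = ("rotation", "flexion", "interaction")


@dataclass
class LRTResult:
    """Likelihood-ratio test of one model term."""

    statistic: float
    df: int
    p_value: float
    p_adjusted: float | None = None


@dataclass
class MixedModelResult:
    """Fitted mixed model for one outcome, with LRTs and predictions."""

    outcome: str
    formula: str
    fe_params: pd.Series
    fe_bse: pd.Series
    vc_patient: float
    vc_residual: float
    llf: float
    r2_conditional: float
    converged: bool
    lrt: dict[str, LRTResult] = field(default_factory=dict)
    n_obs: int = 0
    n_groups: int = 0
    _res: object = None


@dataclass
class MixedModelSpec:
    """What to fit: outcome column plus design toggles."""

    outcome: str
    include_side: bool = True
    reml: bool = False

    def validate(self, df: pd.DataFrame) -> None:
        if self.outcome not in df.columns:
            raise ValidationError(f"outcome column '{self.outcome}' not in table")
        for col in ("rotation_deg", "flexion_deg", "patient_id"):
            if col not in df.columns:
                raise ValidationError(f"required column '{col}' not in table")
        if 0 not in df["rotation_deg"].values or 0 not in df["flexion_deg"].values:
            raise ValidationError("reference categories R0/F0 absent from the data")
        if df["patient_id"].nunique() < 2:
            raise ValidationError("mixed model needs at least 2 patients")


def _fit_ml(df: pd.DataFrame, formula: str, reml: bool = False):
    """ML fit that is robust to optimizer failures.

    Near-boundary variance components can make a single optimizer return a
    divergent (infinite) log-likelihood; try a sequence and keep the best
    finite fit.
    """
    model = smf.mixedlm(formula, df, groups=df["patient_id"])
    best = None
    for method in ("lbfgs", "bfgs", "powell", "cg"):
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=reml, method=method, maxiter=1000, disp=False)
        except Exception:
            continue
        if not np.isfinite(res.llf):
            continue
        if best is None or res.llf > best.llf + 1e-6:
            best = res
        if best is not None and best.converged:
            break
    if best is None:
        raise ConvergenceError(f"mixed model failed to fit: {formula}")
    return best


def conditional_r2(res) -> float:
    """Nakagawa–Schielzeth conditional R² of a random-intercept fit."""
    fixed = np.asarray(res.model.exog) @ np.asarray(res.fe_params)
    v_fix = float(np.var(fixed))
    v_b = float(np.asarray(res.cov_re)[0, 0])
    v_e = float(res.scale)
    return (v_fix + v_b) / (v_fix + v_b + v_e)


def fit_mixed_model(table, spec: MixedModelSpec | str) -> MixedModelResult:
    """Fit the per-parameter mixed model and run the three LRTs.

    ``table`` is a tidy measurement DataFrame (or an object with a ``.data``
    DataFrame). LRTs compare ML fits of nested models: rotation
    (main-effects model vs flexion-only), flexion (main-effects vs
    rotation-only), interaction (full vs main-effects).
    """
    if isinstance(spec, str):
        spec = MixedModelSpec(outcome=spec)
    df = table.data if hasattr(table, "data") else table
    spec.validate(df)
    side = " + C(side)" if spec.include_side and "side" in df.columns else ""

    full = _fit_ml(df, f"{spec.outcome} ~ {_RHS_FULL}{side}")
    main = _fit_ml(df, f"{spec.outcome} ~ {_RHS_MAIN}{side}")
    rot_only = _fit_ml(df, f"{spec.outcome} ~ {_RHS_ROT}{side}")
    flex_only = _fit_ml(df, f"{spec.outcome} ~ {_RHS_FLEX}{side}")

    n_rot = df["rotation_deg"].nunique()
    n_flex = df["flexion_deg"].nunique()
    tests = {
        "rotation": (main.llf - flex_only.llf, n_rot - 1),
        "flexion": (main.llf - rot_only.llf, n_flex - 1),
        "interaction": (full.llf - main.llf, (n_rot - 1) * (n_flex - 1)),
    }
    lrt = {}
    for term, (dll, dof) in tests.items():
        stat = max(2.0 * dll, 0.0)
        lrt[term] = LRTResult(statistic=stat, df=dof, p_value=float(chi2.sf(stat, dof)))

    v_b = float(np.asarray(full.cov_re)[0, 0])
    if v_b < 1e-10:
        warnings.warn(f"near-singular fit for '{spec.outcome}': patient variance ~ 0",
                      stacklevel=2)
    return MixedModelResult(
        outcome=spec.outcome,
        formula=full.model.formula,
        fe_params=full.fe_params,
        fe_bse=full.bse_fe,
        vc_patient=v_b,
        vc_residual=float(full.scale),
        llf=float(full.llf),
        r2_conditional=conditional_r2(full),
        converged=bool(full.converged),
        lrt=lrt,
        n_obs=int(full.nobs),
        n_groups=df["patient_id"].nunique(),
        _res=full,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def analyze_table(table, outcomes=PARAMETERS, bh_family: str = "global"):
    """Fit all per-parameter models and BH-adjust the LRT p-values.

    ``bh_family="global"`` adjusts the 3 x n_outcomes p-values as one family
    (the default); ``"per_model"`` adjusts within each outcome's three tests.
    Returns ``{outcome: MixedModelResult}``.
    """
    if bh_family not in ("global", "per_model"):
        raise ValidationError("bh_family must be 'global' or 'per_model'")
    results = {out: fit_mixed_model(table, out) for out in outcomes}
    if bh_family == "global":
        keys = [(o, t) for o in outcomes for t in TESTED_TERMS]
        adj = benjamini_hochberg([results[o].lrt[t].p_value for o, t in keys])
        for (o, t), a in zip(keys, adj):
            results[o].lrt[t].p_adjusted = float(a)
    else:
        for o in outcomes:
            adj = benjamini_hochberg([results[o].lrt[t].p_value for t in TESTED_TERMS])
            for t, a in zip(TESTED_TERMS, adj):
                results[o].lrt[t].p_adjusted = float(a)
    return results


def marginal_predictions(result: MixedModelResult, grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Population-level predicted value and 95% CI per (rotation, flexion) cell.

    Predictions average over the side factor with equal weights; intervals
    are delta-method Wald CIs from the fixed-effects covariance.
    """
    res = result._res
    if res is None:
        raise ValidationError("result carries no fitted model")
    df_fit = res.model.data.frame
    if grid is None:
        grid = df_fit[["rotation_deg", "flexion_deg"]].drop_duplicates().sort_values(
            ["rotation_deg", "flexion_deg"]).reset_index(drop=True)
    for col in ("rotation_deg", "flexion_deg"):
        unknown = set(grid[col]) - set(df_fit[col])
        if unknown:
            raise ValidationError(f"{col} values outside fitted levels: {sorted(unknown)}")

    sides = sorted(df_fit["side"].unique()) if "side" in df_fit.columns else [None]
    design_info = res.model.data.design_info
    fe = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:len(fe), :len(fe)]

    rows = []
    for _, cell in grid.iterrows():
        xs = []
        for s in sides:
            d = {"rotation_deg": [cell.rotation_deg], "flexion_deg": [cell.flexion_deg]}
            if s is not None:
                d["side"] = [s]
            xs.append(np.asarray(patsy.build_design_matrices(
                [design_info], pd.DataFrame(d))[0])[0])
        x = np.mean(xs, axis=0)
        pred = float(x @ fe)
        se = float(np.sqrt(x @ cov @ x))
        z = norm.ppf(0.975)
        rows.append({"rotation_deg": cell.rotation_deg, "flexion_deg": cell.flexion_deg,
                     "predicted": pred, "se": se,
                     "ci_low": pred - z * se, "ci_high": pred + z * se})
    return pd.DataFrame(rows)


def per_degree_slopes(table, params=None) -> pd.DataFrame:
    """Least-squares slope of each delta vs rotation, within each flexion level.

    Returns a DataFrame indexed by flexion level with one column per delta,
    in outcome units per degree of axial rotation.
    """
    df = table.data if hasattr(table, "data") else table
    params = params or [f"d_{p}" for p in PARAMETERS]
    rows = {}
    for f, sub in df.groupby("flexion_deg"):
        r = sub["rotation_deg"].to_numpy(dtype=float)
        rc = r - r.mean()
        denom = float(rc @ rc)
        rows[f] = {p: float(rc @ (sub[p].to_numpy(dtype=float))) / denom for p in params}
    out = pd.DataFrame(rows).T
    out.index.name = "flexion_deg"
    return out


def lrt_frame(results: dict[str, MixedModelResult]) -> pd.DataFrame:
    """Tidy frame of all LRTs (one row per outcome x term)."""
    rows = []
    for o, res in results.items():
        for t, lr in res.lrt.items():
            rows.append({"outcome": o, "term": t, "statistic": lr.statistic,
                         "df": lr.df, "p_value": lr.p_value, "p_adjusted": lr.p_adjusted})
    return pd.DataFrame(rows)


def coefficients_frame(results: dict[str, MixedModelResult]) -> pd.DataFrame:
    """Tidy frame of fixed-effect estimates and SEs for every fitted model."""
    rows = []
    for o, res in results.items():
        for name, est in res.fe_params.items():
            rows.append({"outcome": o, "term": name, "estimate": float(est),
                         "se": float(res.fe_bse[name])})
    return pd.DataFrame(rows)
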