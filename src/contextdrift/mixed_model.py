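"""Hierarchical regression of duration estimates on neural pattern distance,
controlling for naive duration estimates, with crossed participant and
interval random effects.

The target model is

    y_i = X_i (beta + s_j[i] + m_k[i]) + eps,
    s_j ~ N(0, Sigma_s),  m_k ~ N(0, Sigma_m),  eps ~ N(0, sigma)

with fixed design X = [1, NaiveEstimates, NeuralPatternDistance], subject
perturbations on all three coefficients and interval perturbations on the
intercept and distance slope (the naive covariate is a group-averaged
per-interval mean, so its slope cannot vary by interval). The response is
Box-Cox transformed with the exponent chosen by maximising the profile
likelihood of the fixed-effects-only model, and 95% intervals use the Wald
(asymptotic Gaussian) approximation.

The numeric optimiser is statsmodels' linear mixed-model routine. Subject
effects enter as correlated random coefficients; interval effects enter as
independent variance components (their intercept/slope covariance is
dropped — the first rung of the documented simplification ladder). If a fit
fails to converge or its covariance approaches singularity, the random
structure is simplified further (drop the interval slope component, then
the subject slopes) until it converges; the rung used is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "boxcox_lambda",
    "boxcox_transform",
    "assemble_model_data",
    "fit_mixed",
    "report_fixed_effects",
    "MixedModelFit",
]

FIXED_TERMS = ("Intercept", "NaiveEstimates", "NeuralPatternDistance")


def boxcox_transform(y: np.ndarray, lam: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if lam == 0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def boxcox_lambda(
    y: np.ndarray,
    X: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    shift: bool = False,
) -> float:
    """Box-Cox exponent maximising the profile likelihood of a fixed-effects
    regression (intercept-only when X is None).

    Searches a grid on [-2, 2] with step 0.01. All responses must be
    strictly positive; with ``shift=True`` a half-unit shift is applied to
    zeros (and logged via a warning) instead of raising.
    """
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        if not shift:
            raise ValueError("Box-Cox requires strictly positive responses")
        eps = 0.5
        warnings.warn(f"shifting {int((y <= 0).sum())} non-positive responses "
                      f"by {eps}", stacklevel=2)
        y = y + eps
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    else:
        X = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    if grid is None:
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    log_y_sum = np.log(y).sum()
    best_lam, best_ll = grid[0], -np.inf
    for lam in grid:
        z = boxcox_transform(y, float(lam))
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        rss = float(np.sum((z - X @ beta) ** 2))
        if rss <= 0:
            continue
        ll = -n / 2.0 * np.log(rss / n) + (lam - 1.0) * log_y_sum
        if ll > best_ll:
            best_lam, best_ll = float(lam), ll
    return best_lam


def assemble_model_data(
    estimates: pd.DataFrame,
    distances: pd.DataFrame,
    naive_mean: pd.Series,
) -> pd.DataFrame:
    """Long-format observations for the hierarchical fit.

    ``estimates`` and ``distances`` are interval x participant frames (NaN
    marks intervals a participant did not retain); ``naive_mean`` is the
    naive group's per-interval mean estimate. Covariates are standardised
    over the analysis set (stabilises the crossed fit; recorded here once).
    """
    rows = []
    for interval in estimates.index:
        for subject in estimates.columns:
            y = estimates.loc[interval, subject]
            d = distances.loc[interval, subject]
            if np.isnan(y) or np.isnan(d):
                continue
            rows.append((subject, interval, y, d, naive_mean.loc[interval]))
    data = pd.DataFrame(
        rows, columns=["subject", "interval", "estimate", "distance", "naive"]
    )
    for col in ("distance", "naive"):
        sd = data[col].std(ddof=1)
        if sd > 0:
            data[col] = (data[col] - data[col].mean()) / sd
    return data


@dataclass
class MixedModelFit:
    """Fixed effects, Wald CIs and fit provenance for one region's model."""

    beta: pd.Series
    wald_ci: pd.DataFrame  # columns lo, hi
    sigma: float
    lam: float
    ladder_rung: int
    description: str
    converged: bool
    cov_subject: np.ndarray | None = None
    vc_interval: dict = field(default_factory=dict)

    def excludes_zero(self, term: str) -> bool:
        lo, hi = self.wald_ci.loc[term]
        return bool(lo > 0 or hi < 0)


_LADDER = (
    # (re_formula, vc keys, description)
    ("1 + naive + distance",
     {"interval_intercept": "0 + C(interval)",
      "interval_distance": "0 + C(interval):distance"},
     "correlated subject effects on all coefficients; independent interval "
     "intercept and distance-slope components"),
    ("1 + naive + distance",
     {"interval_intercept": "0 + C(interval)"},
     "interval distance-slope component dropped"),
    ("1",
     {"interval_intercept": "0 + C(interval)"},
     "subject random intercept only plus interval intercept component"),
    ("1", {}, "subject random intercept only"),
)


def _singular(result) -> bool:
    try:
        cov = np.asarray(result.cov_re)
        if cov.size:
            eig = np.linalg.eigvalsh(cov)
            scale = max(result.scale, 1e-12)
            if eig.min() < 1e-8 * scale:
                return True
    except Exception:
        return True
    return False


def fit_mixed(
    data: pd.DataFrame,
    include_naive: bool = True,
    boxcox: bool = True,
) -> MixedModelFit:
    """Fit the hierarchical model to assembled observations.

    Tries the full random structure first and walks down the simplification
    ladder until the optimiser converges with a non-singular covariance.
    Raises RuntimeError with diagnostics if no rung converges.
    """
    if data["subject"].nunique() < 2 or data["interval"].nunique() < 2:
        raise ValueError("need at least 2 subjects and 2 intervals")
    data = data.copy()
    fixed_terms = ["naive", "distance"] if include_naive else ["distance"]
    if boxcox:
        X = data[fixed_terms].to_numpy()
        lam = boxcox_lambda(data["estimate"].to_numpy(), X=X, shift=True)
        data["y"] = boxcox_transform(
            np.maximum(data["estimate"].to_numpy(), 0.5), lam
        )
    else:
        lam = 1.0
        data["y"] = data["estimate"]

    fixed = "y ~ 1 + " + " + ".join(fixed_terms)
    errors = []
    boundary_fallback = None  # converged fit whose covariance sits on the boundary
    for rung, (re_formula, vc, description) in enumerate(_LADDER):
        if not include_naive:
            re_formula = re_formula.replace(" naive +", "")
        vc_formula = dict(vc)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                model = MixedLM.from_formula(
                    fixed,
                    data,
                    groups=data["subject"],
                    re_formula=re_formula,
                    vc_formula=vc_formula or None,
                )
                result = model.fit(reml=True, method=["lbfgs", "powell"])
                ci_probe = result.conf_int().loc[result.fe_params.index]
        except Exception as exc:  # noqa: BLE001 - recorded, ladder continues
            errors.append(f"rung {rung}: {exc}")
            continue
        if not result.converged or not np.isfinite(ci_probe.to_numpy()).all():
            errors.append(f"rung {rung}: non-convergence")
            continue
        if _singular(result):
            # a variance component estimated at zero: keep as fallback (the
            # boundary estimate is informative when the data carry little
            # group variability) but prefer an interior fit at a lower rung
            if boundary_fallback is None:
                boundary_fallback = (rung, description + " (boundary fit)",
                                     result)
            errors.append(f"rung {rung}: covariance on boundary")
            continue
        boundary_fallback = None
        break
    else:
        if boundary_fallback is None:
            raise RuntimeError(
                "mixed model failed to converge on any rung of the "
                "simplification ladder: " + "; ".join(errors)
            )
        rung, description, result = boundary_fallback

    params = result.fe_params
    ci = result.conf_int().loc[params.index]
    ci.columns = ["lo", "hi"]
    rename = {"Intercept": "Intercept", "naive": "NaiveEstimates",
              "distance": "NeuralPatternDistance"}
    beta = params.rename(rename)
    ci = ci.rename(index=rename)
    vc_named = {}
    for i, name in enumerate(_LADDER[rung][1]):
        if i < len(np.atleast_1d(result.vcomp)):
            vc_named[name] = float(np.atleast_1d(result.vcomp)[i])
    return MixedModelFit(
        beta=beta,
        wald_ci=ci,
        sigma=float(np.sqrt(result.scale)),
        lam=lam,
        ladder_rung=rung,
        description=description,
        converged=True,
        cov_subject=np.asarray(result.cov_re),
        vc_interval=vc_named,
    )


def report_fixed_effects(fits: dict[str, MixedModelFit]) -> pd.DataFrame:
    """Table of fixed effects and CIs over ROIs, flagging CIs excluding zero."""
    rows = []
    for roi, fit in fits.items():
        for term in fit.beta.index:
            lo, hi = fit.wald_ci.loc[term]
            rows.append(
                (roi, term, float(fit.beta[term]), float(lo), float(hi),
                 bool(lo > 0 or hi < 0), fit.ladder_rung)
            )
    return pd.DataFrame(
        rows,
        columns=["roi", "term", "beta", "ci_lo", "ci_hi", "excludes_zero",
                 "ladder_rung"],
    )
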