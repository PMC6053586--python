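"""Binomial GLMs of soaring behavior with AIC selection and model averaging.

Two logistic regressions model the probability that a flying fix is
thermal soaring (1 = thermal, 0 = other flight) or orographic soaring
(1 = orographic, 0 = other flight) from eight candidate terms: elevation
and slope (each with a quadratic companion), wind speed, the aspect-wind
angle of incidence v, hill shade hs, and temperature.  Every admissible
subset of terms is fitted (quadratics enter only alongside their linear
parent), models are ranked by AIC, and — unless one model carries an
Akaike weight above 0.9 — estimates are averaged over the set with
delta-AIC < 2 using renormalized Akaike weights.  Averaging is "full"
(zero-substitution): a term absent from a contributing model contributes
a zero coefficient, which shrinks weakly supported effects toward zero.
Unconditional standard errors follow Buckland's formula
``SE = sum_i w_i sqrt(se_i^2 + (b_i - b_bar)^2)``.

Discrimination of the final model is summarized by the area under the
ROC curve, computed by the rank (Mann-Whitney) formulation with ties
counted one half.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, ndtr
from scipy.stats import rankdata

#: Candidate model terms in the order used for reporting.
CANDIDATE_TERMS = [
    "elevation",
    "elevation2",
    "slope",
    "slope2",
    "wind_speed",
    "v",
    "hs",
    "temperature",
]

#: Quadratic terms and their linear parents (marginality constraint).
QUADRATIC_PARENTS = {"elevation2": "elevation", "slope2": "slope"}


def add_quadratic_terms(covariates: pd.DataFrame) -> pd.DataFrame:
    """Append elevation^2 / slope^2 columns (raw, unscaled)."""
    out = covariates.copy()
    if "elevation" in out.columns:
        out["elevation2"] = out["elevation"] ** 2
    if "slope" in out.columns:
        out["slope2"] = out["slope"] ** 2
    return out


def build_response(
    flying: pd.DataFrame,
    target: str,
    label_col: str = "behavior",
    terms: list[str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Binary response (target soaring mode vs other flight) + covariates.

    Perched rows must already be excluded; rows with missing covariates
    are dropped (count recorded in ``covariates.attrs['n_dropped']``).
    """
    if target not in ("thermal_soaring", "orographic_soaring"):
        raise ValueError("target must be thermal_soaring or orographic_soaring")
    if (flying[label_col] == "perched").any():
        raise ValueError("perched rows present; exclude them before modeling")
    terms = terms or CANDIDATE_TERMS
    cov = add_quadratic_terms(flying)
    needed = [t for t in terms if t in cov.columns]
    complete = ~cov[needed].isna().any(axis=1)
    if "weather_missing" in cov.columns:
        complete &= ~cov["weather_missing"]
    dropped = int((~complete).sum())
    cov = cov.loc[complete].reset_index(drop=True)
    y = (cov[label_col] == target).to_numpy(dtype=int)
    if y.sum() == 0:
        raise ValueError(f"no positive cases for target {target!r}")
    cov = cov[needed]
    cov.attrs["n_dropped"] = dropped
    return y, cov


@dataclass
class FittedGlm:
    """One fitted binomial GLM (logit link)."""

    terms: tuple[str, ...]
    params: pd.Series  # includes "intercept"
    bse: pd.Series
    llf: float
    k: int
    aic: float
    n: int
    converged: bool
    delta_aic: float = np.nan
    weight: float = np.nan

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(covariates), self.params["intercept"])
        for t in self.terms:
            eta += self.params[t] * covariates[t].to_numpy(dtype=float)
        return eta

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(covariates))


def fit_glm(
    y: np.ndarray, covariates: pd.DataFrame, terms: list[str] | tuple[str, ...]
) -> FittedGlm:
    """Maximum-likelihood logistic fit (IRLS, deviance tolerance 1e-8).

    Raises on non-convergence within 100 iterations; warns when any raw
    coefficient exceeds 15 in magnitude (a perfect-separation symptom).
    """
    terms = tuple(terms)
    X = np.column_stack(
        [np.ones(len(covariates))] + [covariates[t].to_numpy(dtype=float) for t in terms]
    )
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge for terms {terms}")
    names = ["intercept", *terms]
    params = pd.Series(res.params, index=names)
    if np.any(np.abs(params.to_numpy()) > 15.0):
        warnings.warn(
            f"possible separation: |coefficient| > 15 in model {terms}",
            RuntimeWarning,
            stacklevel=2,
        )
    return FittedGlm(
        terms=terms,
        params=params,
        bse=pd.Series(res.bse, index=names),
        llf=float(res.llf),
        k=X.shape[1],
        aic=float(-2.0 * res.llf + 2.0 * X.shape[1]),
        n=len(y),
        converged=bool(res.converged),
    )


def admissible_subsets(
    candidate_terms: list[str] | None = None, marginality: bool = True
) -> list[tuple[str, ...]]:
    """All term subsets (including the empty, intercept-only model).

    With the marginality rule, a quadratic term appears only together
    with its linear parent.
    """
    candidate_terms = candidate_terms or CANDIDATE_TERMS
    subsets = []
    for r in range(len(candidate_terms) + 1):
        for combo in itertools.combinations(candidate_terms, r):
            if marginality and any(
                q in combo and QUADRATIC_PARENTS[q] not in combo
                for q in QUADRATIC_PARENTS
                if q in candidate_terms
            ):
                continue
            subsets.append(combo)
    return subsets


def all_subsets_aic(
    y: np.ndarray,
    covariates: pd.DataFrame,
    candidate_terms: list[str] | None = None,
    marginality: bool = True,
) -> list[FittedGlm]:
    """Fit every admissible subset and rank ascending by AIC.

    Each returned fit carries its delta-AIC from the best model and its
    Akaike weight ``w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)``
    over all fitted subsets.  Subsets whose fit fails are skipped with a
    warning reporting how many were dropped.
    """
    candidate_terms = candidate_terms or [
        t for t in CANDIDATE_TERMS if t in covariates.columns
    ]
    fits: list[FittedGlm] = []
    failed: list[tuple[str, ...]] = []
    for subset in admissible_subsets(candidate_terms, marginality):
        try:
            fits.append(fit_glm(y, covariates, subset))
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failed.append(subset)
    if not fits:
        raise RuntimeError("no candidate model could be fitted")
    fits.sort(key=lambda f: f.aic)
    best = fits[0].aic
    rel = np.array([np.exp(-(f.aic - best) / 2.0) for f in fits])
    weights = rel / rel.sum()
    for f, w in zip(fits, weights):
        f.delta_aic = f.aic - best
        f.weight = float(w)
    if failed:
        warnings.warn(f"{len(failed)} candidate subsets failed to fit", RuntimeWarning)
    return fits


@dataclass
class AveragedModel:
    """Model-averaged coefficient set used for inverse-logit prediction."""

    estimates: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    weights: list[float]
    n_models: int
    delta_threshold: float
    response: str = ""

    @property
    def terms(self) -> list[str]:
        return [t for t in self.estimates.index if t != "intercept"]

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(covariates), self.estimates["intercept"])
        for t in self.terms:
            eta += self.estimates[t] * covariates[t].to_numpy(dtype=float)
        return eta

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        """Inverse-logit probability for each covariate row."""
        return expit(self.linear_predictor(covariates))

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "se": self.se,
                "z": self.z,
                "p": self.p,
                "ci_2.5": self.ci_low,
                "ci_97.5": self.ci_high,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "response": self.response,
                "delta_threshold": self.delta_threshold,
                "n_models": self.n_models,
                "weights": self.weights,
                "coefficients": {
                    t: {
                        "estimate": float(self.estimates[t]),
                        "se": float(self.se[t]),
                        "z": float(self.z[t]),
                        "p": float(self.p[t]),
                        "ci": [float(self.ci_low[t]), float(self.ci_high[t])],
                    }
                    for t in self.estimates.index
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "AveragedModel":
        obj = json.loads(text)
        coefs = obj["coefficients"]
        idx = list(coefs)
        return cls(
            estimates=pd.Series({t: coefs[t]["estimate"] for t in idx}),
            se=pd.Series({t: coefs[t]["se"] for t in idx}),
            z=pd.Series({t: coefs[t]["z"] for t in idx}),
            p=pd.Series({t: coefs[t]["p"] for t in idx}),
            ci_low=pd.Series({t: coefs[t]["ci"][0] for t in idx}),
            ci_high=pd.Series({t: coefs[t]["ci"][1] for t in idx}),
            weights=obj["weights"],
            n_models=obj["n_models"],
            delta_threshold=obj["delta_threshold"],
            response=obj.get("response", ""),
        )


def model_average(
    ranked: list[FittedGlm],
    delta_threshold: float = 2.0,
    conditional: bool = False,
    response: str = "",
) -> AveragedModel:
    """Average estimates over the delta-AIC < threshold set.

    If the top model's Akaike weight exceeds 0.9 it is returned as-is
    (no averaging).  Otherwise weights are renormalized over the
    contributing set (strict ``delta < threshold``); full averaging
    substitutes 0 for a term absent from a model, conditional averaging
    renormalizes each term's weight over only the models containing it.
    """
    if not ranked:
        raise ValueError("ranked model list is empty")
    if ranked[0].weight > 0.9:
        contributing = [ranked[0]]
        w = np.array([1.0])
    else:
        contributing = [f for f in ranked if f.delta_aic < delta_threshold]
        w = np.array([f.weight for f in contributing])
        w = w / w.sum()

    all_terms = ["intercept"] + [
        t for t in CANDIDATE_TERMS if any(t in f.terms for f in contributing)
    ]
    est, se = {}, {}
    for term in all_terms:
        betas = np.array([f.params.get(term, 0.0) for f in contributing])
        ses = np.array([f.bse.get(term, 0.0) for f in contributing])
        has = np.array([term == "intercept" or term in f.terms for f in contributing])
        if conditional and term != "intercept":
            wc = w * has
            wc = wc / wc.sum()
            beta_bar = float(wc @ betas)
            se_bar = float(wc @ np.sqrt(ses**2 + (betas - beta_bar) ** 2))
        else:
            beta_bar = float(w @ betas)
            se_bar = float(w @ np.sqrt(ses**2 + (betas - beta_bar) ** 2))
        est[term] = beta_bar
        se[term] = se_bar

    est_s = pd.Series(est)
    se_s = pd.Series(se)
    z = (est_s.abs() / se_s).replace([np.inf], np.nan)
    p = 2.0 * (1.0 - pd.Series(ndtr(z.to_numpy()), index=z.index))
    return AveragedModel(
        estimates=est_s,
        se=se_s,
        z=z,
        p=p,
        ci_low=est_s - 1.96 * se_s,
        ci_high=est_s + 1.96 * se_s,
        weights=[float(x) for x in w],
        n_models=len(contributing),
        delta_threshold=delta_threshold,
        response=response,
    )


def auc_roc(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by the Mann-Whitney rank formulation.

    AUC is the probability that a random positive outscores a random
    negative, with ties counted one half (midranks).
    """
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def ranking_table(ranked: list[FittedGlm]) -> pd.DataFrame:
    """Tabular view of an AIC ranking (one row per model)."""
    return pd.DataFrame(
        {
            "terms": [" + ".join(f.terms) if f.terms else "(intercept only)" for f in ranked],
            "k": [f.k for f in ranked],
            "logLik": [f.llf for f in ranked],
            "AIC": [f.aic for f in ranked],
            "delta_AIC": [f.delta_aic for f in ranked],
            "weight": [f.weight for f in ranked],
        }
    )
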