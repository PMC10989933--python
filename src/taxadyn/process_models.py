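"""Fitting and comparing the three taxon-dynamics models.

Three models describe the drift of the log abundance ratio
Z_i = log(X_i / X_r) of a focal taxon i against the reference taxon r:

consumer-resource (CR)
    dZ_i/dt = k0 + sum_j k1_j R_j, with k0 = -(m_i - m_r) the relative
    maintenance cost and k1_j = b_ij C_ij - b_rj C_rj the relative
    competition strength on resource j.  Fitted by ordinary least
    squares with homoscedastic Gaussian errors.

neutral
    dZ_i/dt = k0 + k2 / X_i + k3 / X_r + eps, derived from the
    Wright-Fisher diffusion with immigration by Ito's lemma, where
    k2 = (lambda_i p_i - 1)/a and k3 = -(lambda_r p_r - 1)/a.  The
    error variance is (2/X_i + 2/X_r)/(a dt) per interval, so the fit
    is weighted least squares with weights w = dt/(2/X_i + 2/X_r), and
    the mean squared weighted residual estimates 1/a.

combined
    the neutral regression plus the resource term, same weights.

All three likelihoods are evaluated on the same response values so AIC
values are comparable; the variance-scale parameter (sigma^2 or a)
counts toward the parameter total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocess import (
    AbundanceMatrix,
    RegressionDataset,
    build_regression_dataset,
    classify_abundance,
    mean_relative_abundance,
    presence_filter,
    select_reference_taxon,
)

__all__ = [
    "ModelFit",
    "NeutralParams",
    "CompetitionParams",
    "fit_consumer_resource",
    "fit_neutral",
    "fit_combined",
    "compare_models",
    "derive_neutral_params",
    "extract_competition_params",
    "fit_all",
]

MODEL_KINDS = ("neutral", "consumer_resource", "combined")


class FitError(ValueError):
    """Raised when a dataset cannot support the requested fit."""


@dataclass
class ModelFit:
    """A fitted model for one taxon, with goodness-of-fit diagnostics."""

    model_kind: str
    taxon_id: str
    k0: float
    k1: np.ndarray  # length J (empty for neutral)
    k2: float | None
    k3: float | None
    n_obs: int
    n_params: int
    r2: float
    loglik: float
    aic: float
    a_hat: float | None = None  # neutral/combined only
    sigma2_hat: float | None = None  # consumer-resource only
    weighted_residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    coef_se: np.ndarray = field(default_factory=lambda: np.empty(0))
    resource_names: list[str] = field(default_factory=list)

    def coefficients(self) -> dict[str, float]:
        out = {"k0": self.k0}
        for name, v in zip(self.resource_names, np.atleast_1d(self.k1)):
            out[f"k1[{name}]"] = float(v)
        if self.k2 is not None:
            out["k2"] = self.k2
        if self.k3 is not None:
            out["k3"] = self.k3
        return out


@dataclass
class NeutralParams:
    """Ecological parameters recovered from a neutral or combined fit."""

    taxon_id: str
    lambda_i: float
    p_i: float
    a_hat: float
    lambda_p_product: float
    neutral_compatible: bool


@dataclass
class CompetitionParams:
    """Relative competition strength of the focal taxon on one resource."""

    taxon_id: str
    resource_name: str
    k1_j: float

    @property
    def biCi_relative(self) -> float:
        return self.k1_j


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    """Raise a FitError naming a collinear column if the design is singular."""
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # find a column that is (nearly) in the span of the others
        for j in range(design.shape[1] - 1, -1, -1):
            others = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                resid = design[:, j] - others @ np.linalg.lstsq(
                    others, design[:, j], rcond=None
                )[0]
                if np.linalg.norm(resid) <= 1e-8 * max(
                    1.0, np.linalg.norm(design[:, j])
                ):
                    raise FitError(
                        f"design is rank deficient: column {names[j]!r} is "
                        "collinear with the others"
                    )
        raise FitError("design is rank deficient")


def fit_consumer_resource(ds: RegressionDataset) -> ModelFit:
    """OLS fit of dZ/dt on an intercept and the resource levels."""
    J = ds.n_resources
    if ds.n_obs < J + 3:
        raise FitError(
            f"consumer-resource fit needs >= {J + 3} intervals, got {ds.n_obs}"
        )
    design = np.column_stack([np.ones(ds.n_obs), ds.resources])
    names = ["intercept"] + [f"R[{n}]" for n in ds.resource_names]
    _check_rank(design, names)
    res = sm.OLS(ds.response, design).fit()
    resid = np.asarray(res.resid)
    rss = float(resid @ resid)
    sigma2 = rss / ds.n_obs  # ML variance estimate
    if sigma2 > 0:
        loglik = -0.5 * ds.n_obs * (np.log(2 * np.pi * sigma2) + 1.0)
    else:  # exact fit: unbounded likelihood
        loglik = np.inf
    n_params = J + 2  # intercept, J slopes, variance
    tss = float(((ds.response - ds.response.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return ModelFit(
        model_kind="consumer_resource",
        taxon_id=ds.taxon_id,
        k0=float(res.params[0]),
        k1=np.asarray(res.params[1:]),
        k2=None,
        k3=None,
        n_obs=ds.n_obs,
        n_params=n_params,
        r2=r2,
        loglik=float(loglik),
        aic=float(-2 * loglik + 2 * n_params),
        sigma2_hat=sigma2,
        weighted_residuals=resid,
        coef_se=np.asarray(res.bse),
        resource_names=list(ds.resource_names),
    )


def _wls_fit(
    ds: RegressionDataset, with_resources: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, float]:
    """Shared WLS machinery for the neutral and combined fits.

    Returns (params, se, weighted_residuals, a_hat, loglik, r2).
    """
    cols = [np.ones(ds.n_obs)]
    names = ["intercept"]
    if with_resources:
        cols.append(ds.resources)
        names += [f"R[{n}]" for n in ds.resource_names]
    cols += [ds.inv_x[:, None], ds.inv_xr[:, None]]
    names += ["1/X_i", "1/X_r"]
    design = np.column_stack(cols)
    _check_rank(design, names)

    w = ds.weights
    res = sm.WLS(ds.response, design, weights=w).fit()
    raw_resid = ds.response - design @ res.params
    wresid = np.sqrt(w) * raw_resid
    # Var(sqrt(w) * eps) = 1/a under the diffusion model
    mswr = float(np.mean(wresid**2))
    n = ds.n_obs
    if mswr > 0:
        a_hat = 1.0 / mswr
        # heteroscedastic Gaussian log-likelihood: Var(eps_k) = 1/(a w_k)
        loglik = float(
            0.5 * np.sum(np.log(a_hat * w)) - 0.5 * n * np.log(2 * np.pi)
            - 0.5 * a_hat * np.sum(w * raw_resid**2)
        )
    else:  # exact fit: unbounded likelihood
        a_hat = np.inf
        loglik = np.inf
    rss_w = float(np.sum(w * raw_resid**2))
    ybar_w = float(np.sum(w * ds.response) / np.sum(w))
    tss_w = float(np.sum(w * (ds.response - ybar_w) ** 2))
    r2 = 1.0 - rss_w / tss_w if tss_w > 0 else 1.0
    return np.asarray(res.params), np.asarray(res.bse), wresid, a_hat, loglik, r2


def fit_neutral(ds: RegressionDataset) -> ModelFit:
    """WLS fit of dZ/dt on intercept + 1/X_i + 1/X_r with diffusion weights."""
    if ds.n_obs < 5:
        raise FitError(f"neutral fit needs >= 5 intervals, got {ds.n_obs}")
    params, se, wresid, a_hat, loglik, r2 = _wls_fit(ds, with_resources=False)
    n_params = 4  # k0, k2, k3, a
    return ModelFit(
        model_kind="neutral",
        taxon_id=ds.taxon_id,
        k0=float(params[0]),
        k1=np.empty(0),
        k2=float(params[1]),
        k3=float(params[2]),
        n_obs=ds.n_obs,
        n_params=n_params,
        r2=r2,
        loglik=loglik,
        aic=float(-2 * loglik + 2 * n_params),
        a_hat=a_hat,
        weighted_residuals=wresid,
        coef_se=se,
        resource_names=[],
    )


def fit_combined(ds: RegressionDataset) -> ModelFit:
    """WLS fit with both resource and neutral (1/X) regressors."""
    J = ds.n_resources
    if ds.n_obs < J + 6:
        raise FitError(f"combined fit needs >= {J + 6} intervals, got {ds.n_obs}")
    params, se, wresid, a_hat, loglik, r2 = _wls_fit(ds, with_resources=True)
    n_params = J + 4  # k0, k1_j, k2, k3, a
    return ModelFit(
        model_kind="combined",
        taxon_id=ds.taxon_id,
        k0=float(params[0]),
        k1=np.asarray(params[1 : 1 + J]),
        k2=float(params[1 + J]),
        k3=float(params[2 + J]),
        n_obs=ds.n_obs,
        n_params=n_params,
        r2=r2,
        loglik=loglik,
        aic=float(-2 * loglik + 2 * n_params),
        a_hat=a_hat,
        weighted_residuals=wresid,
        coef_se=se,
        resource_names=list(ds.resource_names),
    )


def compare_models(fits: list[ModelFit]) -> str:
    """Best model by lowest AIC; ties broken toward fewer parameters."""
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError(f"fits computed on different observation counts: {n_obs}")
    best = min(fits, key=lambda f: (f.aic, f.n_params))
    return best.model_kind


def derive_neutral_params(fit: ModelFit, mean_abund_i: float) -> NeutralParams:
    """Recover lambda_i and p_i from the k2 coefficient.

    k2 = (lambda_i p_i - 1)/a, so lambda_i p_i = k2 a + 1; p_i is the
    taxon's mean relative abundance and lambda_i = (k2 a + 1)/p_i.  If
    the implied lambda_i p_i is non-positive the taxon is flagged as
    incompatible with the neutral parameterisation and lambda_i is
    reported as 0.
    """
    if fit.model_kind not in ("neutral", "combined"):
        raise ValueError("neutral parameters require a neutral or combined fit")
    if not 0.0 < mean_abund_i < 1.0:
        raise ValueError(f"mean abundance {mean_abund_i} not in (0, 1)")
    assert fit.a_hat is not None and fit.k2 is not None
    lam_p = fit.k2 * fit.a_hat + 1.0
    compatible = lam_p > 0
    lam = lam_p / mean_abund_i if compatible else 0.0
    return NeutralParams(
        taxon_id=fit.taxon_id,
        lambda_i=float(lam),
        p_i=float(mean_abund_i),
        a_hat=float(fit.a_hat),
        lambda_p_product=float(lam_p),
        neutral_compatible=bool(compatible),
    )


def extract_competition_params(fit: ModelFit) -> list[CompetitionParams]:
    """One record per resource with the relative competition strength k1_j."""
    if fit.model_kind not in ("consumer_resource", "combined"):
        raise ValueError(
            "competition parameters require a consumer-resource or combined fit"
        )
    return [
        CompetitionParams(taxon_id=fit.taxon_id, resource_name=name, k1_j=float(v))
        for name, v in zip(fit.resource_names, np.atleast_1d(fit.k1))
    ]


def fit_all(
    abund: AbundanceMatrix,
    resources,
    *,
    reference_id: str | None = None,
    min_points: int = 6,
    pseudo_abundance: float = 0.0,
) -> dict[str, pd.DataFrame]:
    """Fit all three models to every eligible taxon of a fitting unit.

    Returns a dict of tables:

    ``model_fits``
        one row per (taxon, model) with coefficients and goodness of fit;
    ``best_models``
        one row per taxon with the lowest-AIC model and abundance class;
    ``neutral_params``, ``competition_params``
        derived ecological parameters (neutral parameters from the
        neutral fit, competition strengths from the combined fit);
    ``skipped``
        taxa not fitted, with the reason.
    """
    if reference_id is None:
        reference_id = select_reference_taxon(abund)
    eligible = presence_filter(abund, min_points=min_points)

    fit_rows, best_rows, np_rows, cp_rows, skip_rows = [], [], [], [], []
    for taxon in abund.taxon_ids:
        if taxon == reference_id:
            skip_rows.append({"taxon_id": taxon, "reason": "reference taxon"})
            continue
        if taxon not in eligible:
            skip_rows.append(
                {"taxon_id": taxon, "reason": f"present at < {min_points} time points"}
            )
            continue
        ds = build_regression_dataset(
            abund, resources, taxon, reference_id, pseudo_abundance=pseudo_abundance
        )
        p_hat = mean_relative_abundance(abund, taxon)
        abund_class = classify_abundance(p_hat)
        fits: list[ModelFit] = []
        try:
            for fitter in (fit_neutral, fit_consumer_resource, fit_combined):
                fits.append(fitter(ds))
        except FitError as exc:
            skip_rows.append({"taxon_id": taxon, "reason": str(exc)})
            continue
        for f in fits:
            row = {
                "taxon_id": taxon,
                "model_kind": f.model_kind,
                "n_obs": f.n_obs,
                "n_params": f.n_params,
                "r2": f.r2,
                "loglik": f.loglik,
                "aic": f.aic,
                "a_hat": f.a_hat,
                "sigma2_hat": f.sigma2_hat,
            }
            row.update(f.coefficients())
            fit_rows.append(row)
        best = compare_models(fits)
        best_rows.append(
            {
                "taxon_id": taxon,
                "best_model": best,
                "abundance_class": abund_class,
                "mean_rel_abund": p_hat,
                "n_obs": ds.n_obs,
            }
        )
        neutral_fit = fits[0]
        npar = derive_neutral_params(neutral_fit, p_hat)
        np_rows.append(
            {
                "taxon_id": taxon,
                "lambda_i": npar.lambda_i,
                "p_i": npar.p_i,
                "a_hat": npar.a_hat,
                "lambda_p_product": npar.lambda_p_product,
                "neutral_compatible": npar.neutral_compatible,
            }
        )
        combined_fit = fits[2]
        for cp in extract_competition_params(combined_fit):
            cp_rows.append(
                {
                    "taxon_id": taxon,
                    "resource_name": cp.resource_name,
                    "k1_j": cp.k1_j,
                }
            )

    return {
        "model_fits": pd.DataFrame(fit_rows),
        "best_models": pd.DataFrame(best_rows),
        "neutral_params": pd.DataFrame(np_rows),
        "competition_params": pd.DataFrame(cp_rows),
        "skipped": pd.DataFrame(skip_rows, columns=["taxon_id", "reason"]),
    }
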