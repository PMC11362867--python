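"""Cross-classified random-intercept logistic regression.

The delay outcome is modelled as

    logit Pr(delayed_ij) = x_ij' beta + u_phys(i) + v_hrr(j)

with independent Gaussian random intercepts for the treating physician (NPI)
and the patient's hospital referral region - two *crossed*, non-nested
grouping factors. Exact likelihood integration over crossed effects is
infeasible, so estimation is an explicit strategy choice recorded on the
result object:

* ``"laplace"`` (default): penalized-likelihood fit at the joint mode of
  (beta, u, v) by damped Newton iterations with sparse designs, alternating
  with Laplace-EM updates of the two variance components
  (sigma_k^2 <- (||u_k||^2 + tr Cov_kk) / q_k). This is the classic
  Laplace/PQL family of GLMM strategies and scales to thousands of
  random-intercept levels.
* ``"vb"``: mean-field variational approximation (statsmodels
  ``BinomialBayesMixedGLM.fit_vb``) with a weakly-informative Gaussian
  fixed-effect prior (sd 5 on the log-odds scale). Accurate but slow once
  the physician factor has many hundreds of levels.
* ``"map"``: statsmodels' Laplace/posterior-mode fit of the same Bayesian
  model.
* ``"plain"``: ordinary logistic regression ignoring the grouping (the
  reference model when the variance components are zero).

Wald standard errors for the fixed effects are computed from the penalized
observed information of the joint (beta, u, v) problem at the fitted point,
conditioning on the estimated variance components (for ``"vb"`` this also
sidesteps the known optimism of mean-field posterior variances). Reported
effects are odds ratios with Wald 95% CIs and 2-sided p-values.

The model object follows the statsmodels pattern: construct from data
(``CrossedLogit.from_dataframe``), call :meth:`CrossedLogit.fit`, and read
estimates off the returned :class:`CrossedLogitResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import expit
from scipy.stats import norm

import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

logger = logging.getLogger(__name__)

#: reference level per categorical covariate (treatment coding)
REFERENCE_LEVELS = {
    "care_density_level": "low",
    "age_group": "66-69",
    "race_ethnicity": "White",
    "comorbidity_bin": "0",
    "deprivation_bin": "very low",
    "patient_rurality": "urban",
    "surgeon_rurality": "urban",
    "surgeon_volume_tertile": "low",
    "surgeon_supply_tertile": "low",
    "surgeon_within_hsa_tertile": "low",
    "surgeon_between_hsa_tertile": "low",
    "surgeon_gender": "man",
}

#: the full adjustment set of an analysis-row table
FULL_COVARIATES = [
    "age_group", "race_ethnicity", "comorbidity_bin", "deprivation_bin",
    "patient_rurality", "nci_affiliated", "surgeon_volume_tertile",
    "surgeon_rurality", "surgeon_supply_tertile", "surgeon_within_hsa_tertile",
    "surgeon_between_hsa_tertile", "surgeon_gender", "encounter_count",
]

EXPOSURES = ["linchpin_exposed", "care_density_level"]


class DegenerateOutcomeError(ValueError):
    """The outcome has a single observed value; the model is not identifiable."""


def _encode_column(data: pd.DataFrame, col: str) -> pd.DataFrame:
    """Treatment-coded design columns for one covariate."""
    s = data[col]
    if s.dtype == bool or np.issubdtype(s.dtype, np.number):
        return pd.DataFrame({col: s.astype(float)})
    ref = REFERENCE_LEVELS.get(col)
    levels = [l for l in pd.unique(s) if pd.notna(l)]
    if ref is None or ref not in levels:
        ref = sorted(levels)[0]
    ordered = [ref] + sorted(l for l in levels if l != ref)
    out = {}
    for level in ordered[1:]:
        out[f"{col}[{level}]"] = (s == level).astype(float)
    return pd.DataFrame(out, index=data.index)


def build_design(
    data: pd.DataFrame, fixed: list[str]
) -> tuple[np.ndarray, list[str]]:
    blocks = [pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)]
    blocks += [_encode_column(data, col) for col in fixed]
    design = pd.concat(blocks, axis=1)
    return design.to_numpy(dtype=float), list(design.columns)


def _one_hot(codes: np.ndarray, n_levels: int) -> sparse.csr_matrix:
    n = len(codes)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


class CrossedLogit:
    """Logistic model with crossed random intercepts for two grouping factors.

    Parameters
    ----------
    endog : array of 0/1 outcomes
    exog : fixed-effect design matrix (first column should be the intercept)
    groups : tuple of two label arrays (e.g. surgeon NPI, patient HRR)
    exog_names, group_names : labels for reporting
    """

    def __init__(self, endog, exog, groups, exog_names=None,
                 group_names=("npi", "hrr")):
        self.endog = np.asarray(endog, dtype=float)
        if set(np.unique(self.endog)) - {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if len(np.unique(self.endog)) < 2:
            raise DegenerateOutcomeError(
                "outcome takes a single value; logistic model is degenerate")
        self.exog = np.asarray(exog, dtype=float)
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(self.exog.shape[1])]
        self.group_names = tuple(group_names)
        self.group_levels = []
        self.group_codes = []
        for g in groups:
            codes, levels = pd.factorize(np.asarray(g), sort=True)
            if len(levels) < 2:
                raise ValueError(
                    "each random-effect factor needs at least 2 levels")
            self.group_codes.append(codes)
            self.group_levels.append(list(levels))

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str = "delayed",
        fixed: list[str] | None = None,
        groups: tuple[str, str] = ("surgeon_id", "hrr"),
        group_names: tuple[str, str] = ("npi", "hrr"),
    ) -> "CrossedLogit":
        """Build the model from an analysis-row table.

        ``fixed`` defaults to both exposures plus the full covariate set
        (columns absent from ``data`` are ignored, so reduced tables such as
        simulation output fit the same way).
        """
        if fixed is None:
            fixed = [c for c in EXPOSURES + FULL_COVARIATES if c in data.columns]
        exog, names = build_design(data, fixed)
        return cls(
            data[outcome].astype(float).to_numpy(), exog,
            (data[groups[0]].to_numpy(), data[groups[1]].to_numpy()),
            exog_names=names, group_names=group_names,
        )

    # ------------------------------------------------------------------

    def _vc_matrix(self) -> tuple[sparse.csr_matrix, np.ndarray, list[str]]:
        mats, ident, names = [], [], []
        for k, (codes, levels) in enumerate(zip(self.group_codes, self.group_levels)):
            mats.append(_one_hot(codes, len(levels)))
            ident.extend([k] * len(levels))
            names.extend(f"{self.group_names[k]}[{l}]" for l in levels)
        return sparse.hstack(mats, format="csr"), np.asarray(ident), names

    def fit(
        self,
        method: str = "laplace",
        fe_prior_sd: float = 5.0,
        vcp_prior_sd: float = 2.0,
    ) -> "CrossedLogitResults":
        """Fit and return a results object; `method` is recorded on it."""
        if method == "plain":
            return self._fit_plain()
        if method == "laplace":
            return self._fit_laplace()
        exog_vc, ident, vc_names = self._vc_matrix()
        model = BinomialBayesMixedGLM(
            self.endog, self.exog, exog_vc, ident,
            vcp_p=vcp_prior_sd, fe_p=fe_prior_sd,
            fep_names=self.exog_names,
            vcp_names=list(self.group_names), vc_names=vc_names,
        )
        converged = True
        messages: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = model.fit_vb(verbose=False) if method == "vb" else model.fit_map()
            for w in caught:
                if "converge" in str(w.message).lower():
                    converged = False
                messages.append(str(w.message))
        params = np.asarray(fit.fe_mean)
        re_means = np.asarray(fit.vc_mean)
        vc_sd = np.exp(np.asarray(fit.vcp_mean))
        bse, cov = self._wald_covariance(params, re_means, vc_sd, exog_vc, ident)
        if np.any(np.abs(params[1:]) > 10):
            converged = False
            messages.append("implausibly large coefficient; possible separation")
        return CrossedLogitResults(
            model=self, method=method, params=params, bse=bse, cov_params=cov,
            vc_sd={self.group_names[k]: float(vc_sd[k]) for k in range(len(vc_sd))},
            random_effects={
                name: dict(zip(levels, re_means[np.asarray(ident) == k]))
                for k, (name, levels) in enumerate(
                    zip(self.group_names, self.group_levels))
            },
            converged=converged, messages=messages,
        )

    def _fit_laplace(
        self,
        max_outer: int = 200,
        max_newton: int = 50,
        tol: float = 1e-8,
        sigma_tol: float = 1e-3,
        ridge: float = 1e-4,
    ) -> "CrossedLogitResults":
        """Laplace/PQL fit: damped-Newton joint mode + EM variance updates.

        Given the variance components, the penalized log-likelihood in
        (beta, u) is concave and maximized by Newton iterations with step
        halving (the objective is non-decreasing by construction). The
        variance components are then updated by the Laplace-EM step
        sigma_k^2 = (||u_k||^2 + tr Cov_kk)/q_k and the two stages alternate
        to convergence. A small ridge on the fixed effects (prior sd
        ``1/sqrt(ridge)``) keeps separated levels finite.
        """
        y = self.endog
        exog_vc, ident, _ = self._vc_matrix()
        M = sparse.hstack([sparse.csr_matrix(self.exog), exog_vc], format="csr")
        p, q = self.exog.shape[1], exog_vc.shape[1]
        n_comp = len(self.group_levels)
        sigma2 = np.full(n_comp, 0.25)
        theta = np.zeros(p + q)
        sigma_floor = 1e-6

        def precision(s2: np.ndarray) -> np.ndarray:
            prec = np.full(p + q, ridge)
            prec[p:] = 1.0 / np.maximum(s2[ident], sigma_floor)
            return prec

        def objective(th: np.ndarray, prec: np.ndarray) -> float:
            eta = M @ th
            return float(y @ eta - np.logaddexp(0.0, eta).sum()
                         - 0.5 * (prec * th * th).sum())

        converged = True
        messages: list[str] = []
        cov = None
        n_outer = 0
        trace: list[float] = []
        for outer in range(max_outer):
            n_outer = outer + 1
            prec = precision(sigma2)
            obj = objective(theta, prec)
            trace = [obj]
            for _ in range(max_newton):
                eta = M @ theta
                mu = expit(eta)
                grad = M.T @ (y - mu) - prec * theta
                H = (M.T.multiply(mu * (1.0 - mu)) @ M).toarray()
                H[np.diag_indices_from(H)] += prec
                step = np.linalg.solve(H, grad)
                scale = 1.0
                for _ in range(30):
                    cand = theta + scale * step
                    cand_obj = objective(cand, prec)
                    if cand_obj >= obj:
                        break
                    scale *= 0.5
                improved = cand_obj - obj
                theta, obj = cand, cand_obj
                trace.append(obj)
                if improved < tol * (abs(obj) + 1.0):
                    break
            cov = np.linalg.inv(H)
            u = theta[p:]
            new_sigma2 = sigma2.copy()
            diag_cov = np.diag(cov)[p:]
            for k in range(n_comp):
                mask = ident == k
                qk = int(mask.sum())
                new_sigma2[k] = (u[mask] @ u[mask] + diag_cov[mask].sum()) / qk
            delta = float(np.max(np.abs(new_sigma2 - sigma2)))
            sigma2 = new_sigma2
            if delta < sigma_tol:
                break
        else:
            converged = False
            messages.append("variance-component loop hit max iterations")

        # final information matrix at the converged point for reported SEs
        prec = precision(sigma2)
        eta = M @ theta
        mu = expit(eta)
        H = (M.T.multiply(mu * (1.0 - mu)) @ M).toarray()
        H[np.diag_indices_from(H)] += prec
        cov = np.linalg.inv(H)

        beta = theta[:p]
        if np.any(np.abs(beta[1:]) > 10):
            converged = False
            messages.append("implausibly large coefficient; possible separation")
        bse = np.sqrt(np.diag(cov)[:p])
        vc_sd = np.sqrt(np.maximum(sigma2, 0.0))
        u = theta[p:]
        return CrossedLogitResults(
            model=self, method="laplace", params=beta, bse=bse,
            cov_params=cov[:p, :p],
            vc_sd={self.group_names[k]: float(vc_sd[k]) for k in range(n_comp)},
            random_effects={
                name: dict(zip(levels, u[ident == k]))
                for k, (name, levels) in enumerate(
                    zip(self.group_names, self.group_levels))
            },
            converged=converged, messages=messages,
            diagnostics={"n_outer_iterations": n_outer,
                         "newton_objective_trace": trace},
        )

    def _fit_plain(self) -> "CrossedLogitResults":
        res = sm.GLM(self.endog, self.exog,
                     family=sm.families.Binomial()).fit()
        return CrossedLogitResults(
            model=self, method="plain",
            params=np.asarray(res.params), bse=np.asarray(res.bse),
            cov_params=np.asarray(res.cov_params()),
            vc_sd={name: 0.0 for name in self.group_names},
            random_effects={name: {} for name in self.group_names},
            converged=bool(res.converged), messages=[],
        )

    def _wald_covariance(self, beta, u, vc_sd, exog_vc, ident):
        """Fixed-effect covariance from the penalized observed information,
        conditional on the estimated variance components."""
        eta = self.exog @ beta + exog_vc @ u
        w = expit(eta) * (1.0 - expit(eta))
        M = sparse.hstack([sparse.csr_matrix(self.exog), exog_vc], format="csr")
        H = (M.T.multiply(w) @ M).toarray()
        p = self.exog.shape[1]
        prec = np.zeros(H.shape[0])
        floor = 1e-4  # guards against exactly-zero variance components
        prec[p:] = 1.0 / np.maximum(vc_sd[ident] ** 2, floor)
        H[np.diag_indices_from(H)] += prec
        cov_all = np.linalg.inv(H)
        cov_fe = cov_all[:p, :p]
        return np.sqrt(np.diag(cov_fe)), cov_fe


@dataclass
class CrossedLogitResults:
    """Estimates, uncertainties and diagnostics from a CrossedLogit fit."""

    model: CrossedLogit
    method: str
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    vc_sd: dict[str, float]
    random_effects: dict[str, dict]
    converged: bool
    messages: list[str] = dataclass_field(default_factory=list)
    diagnostics: dict = dataclass_field(default_factory=dict)

    @property
    def pvalues(self) -> np.ndarray:
        z = self.params / self.bse
        return 2.0 * norm.sf(np.abs(z))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """One row per coefficient: OR, Wald CI, p-value (intercept included)."""
        ci = self.conf_int(alpha)
        return pd.DataFrame({
            "term": self.model.exog_names,
            "log_or": self.params,
            "or": np.exp(self.params),
            "ci_low": np.exp(ci[:, 0]),
            "ci_high": np.exp(ci[:, 1]),
            "p_value": self.pvalues,
        }).set_index("term")

    def summary(self) -> str:
        lines = [
            "Cross-classified random-intercept logistic regression",
            f"  method: {self.method}    n obs: {len(self.model.endog)}"
            f"    converged: {self.converged}",
            "  random-intercept SDs: "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.vc_sd.items()),
            "",
            self.odds_ratios().round(4).to_string(),
        ]
        if self.messages:
            lines += ["", "notes:"] + [f"  - {m}" for m in self.messages]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# convenience layer over the Model/Results pair


def fit_crossed_glmm(
    rows: pd.DataFrame,
    outcome: str = "delayed",
    fixed: list[str] | None = None,
    groups: tuple[str, str] = ("surgeon_id", "hrr"),
    backend: str = "laplace",
) -> CrossedLogitResults:
    """Fit the delay model on an analysis-row table (both exposures plus all
    available covariates, crossed NPI and HRR random intercepts)."""
    model = CrossedLogit.from_dataframe(rows, outcome=outcome, fixed=fixed,
                                        groups=groups)
    return model.fit(method=backend)


def sensitivity_rerun(
    rows: pd.DataFrame,
    cutoff: int = 90,
    fixed: list[str] | None = None,
    groups: tuple[str, str] = ("surgeon_id", "hrr"),
    backend: str = "laplace",
) -> CrossedLogitResults:
    """Refit the identical model with the delay outcome re-derived at another
    cutoff (default: the 90-day sensitivity definition)."""
    if "interval_days" not in rows.columns:
        raise ValueError("rows must retain interval_days for a sensitivity rerun")
    rederived = rows.copy()
    rederived["delayed"] = rederived.interval_days > cutoff
    if rederived.delayed.nunique() < 2:
        raise DegenerateOutcomeError(
            f"cutoff {cutoff} leaves a single outcome value; model is degenerate")
    return fit_crossed_glmm(rederived, fixed=fixed, groups=groups, backend=backend)


def side_by_side(primary: CrossedLogitResults,
                 sensitivity: CrossedLogitResults) -> pd.DataFrame:
    """Primary and sensitivity odds ratios in one table."""
    a = primary.odds_ratios()[["or", "ci_low", "ci_high", "p_value"]]
    b = sensitivity.odds_ratios()[["or", "ci_low", "ci_high", "p_value"]]
    return a.join(b, lsuffix="_60d", rsuffix="_90d")
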