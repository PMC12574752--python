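"""Binary logistic regression with cluster-robust (CR1) covariance.

The survey design samples respondents within a handful of hospitals, so
standard errors must allow arbitrary within-hospital correlation of score
contributions.  The covariance used here is the cluster-level sandwich

    V = B ( sum_g s_g s_g' ) B * G/(G-1)

where B is the inverse observed information (the "bread"), s_g the sum of
per-observation scores (y_i - p_i) x_i within cluster g, and G/(G-1) the
CR1 small-sample factor.  Confidence intervals and p-values use t(G-1)
critical values, the conventional few-cluster correction; with G as small
as 3 (the study design) any cluster-robust flavor is fragile and results
should be read accordingly.

`ClusterRobustLogit` is a scikit-learn-style estimator (``fit(X, y,
groups=...)``, fitted attributes with trailing underscores); the module
functions `fit_logit_cluster` and `run_table4_battery` wrap it with the
survey-specific model specifications (three outcomes x three service
categories, awareness models without the technology-acceptance scores,
want/adoption models with them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .awag import aggregate_category
from .scoring import MissingPolicy, score_record
from .survey_io import Category, RespondentRecord, ServiceCatalog, default_catalog

__all__ = [
    "ClusterRobustLogit",
    "ModelSpec",
    "RegressionResult",
    "fit_logit_cluster",
    "run_table4_battery",
    "build_design_matrix",
    "battery_to_frame",
]

#: covariates of the awareness models; want/adoption add pu and peou
BASE_COVARIATES = (
    "sex",
    "age",
    "marital",
    "residence",
    "education",
    "income_tier",
    "srh3",
    "chronic",
    "eheals",
)
TECH_COVARIATES = ("pu", "peou")

OUTCOMES = ("awareness", "want", "adoption")


class ConvergenceWarning(UserWarning):
    pass


class ClusterRobustLogit(BaseEstimator):
    """Logistic regression with CR1 cluster-robust covariance.

    Parameters
    ----------
    alpha : float
        Two-sided level for confidence intervals (default 0.05 -> 95% CI).
    add_constant : bool
        Prepend an intercept column (default True).
    max_iter, tol : int, float
        Newton/IRLS iteration limits for the ML fit.
    separation_threshold : float
        |beta| beyond which (quasi-)separation is flagged.

    Fitted attributes
    -----------------
    params_ : pd.Series of log-odds coefficients (including ``const``)
    cov_ : pd.DataFrame, cluster-robust covariance (classical if <2 clusters)
    bse_, pvalues_, conf_int_ : inference on the log-odds scale
    odds_ratios_ : exp(params_) with exponentiated CI bounds
    n_obs_, n_clusters_, converged_, separation_ : fit metadata
    """

    def __init__(
        self,
        alpha: float = 0.05,
        add_constant: bool = True,
        max_iter: int = 100,
        tol: float = 1e-8,
        separation_threshold: float = 15.0,
    ):
        self.alpha = alpha
        self.add_constant = add_constant
        self.max_iter = max_iter
        self.tol = tol
        self.separation_threshold = separation_threshold

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def fit(self, X, y, groups=None) -> "ClusterRobustLogit":
        Xf = self._as_frame(X).reset_index(drop=True)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != Xf.shape[0]:
            raise ValueError("X and y length mismatch")
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("y must be binary 0/1")
        if uniq.size < 2:
            raise ValueError("outcome is constant")
        if self.add_constant:
            Xf = sm.add_constant(Xf, has_constant="add")
        if Xf.shape[0] <= Xf.shape[1]:
            raise ValueError("fewer complete-case rows than parameters")

        model = sm.Logit(y, Xf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(
                    disp=0, maxiter=self.max_iter, tol=self.tol, method="newton"
                )
            except np.linalg.LinAlgError:
                # singular Hessian, typically (quasi-)separation; quasi-Newton
                # still yields diverging coefficients we can flag
                res = model.fit(disp=0, maxiter=self.max_iter, method="bfgs")
        params = res.params
        converged = bool(res.mle_retvals.get("converged", True))
        separation = bool(np.any(np.abs(params.values) > self.separation_threshold))
        if separation or not converged:
            warnings.warn(
                "possible separation or non-convergence in logistic fit",
                ConvergenceWarning,
                stacklevel=2,
            )

        Xm = Xf.to_numpy()
        p = res.predict(Xf)
        W = p * (1 - p)
        info = (Xm * W.to_numpy()[:, None]).T @ Xm  # observed information
        try:
            bread = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            bread = np.linalg.pinv(info)
        scores = (y - p.to_numpy())[:, None] * Xm

        if groups is None:
            n_clusters = 0
        else:
            groups = np.asarray(groups)
            if groups.shape[0] != Xm.shape[0]:
                raise ValueError("groups length mismatch")
            n_clusters = len(np.unique(groups))

        if n_clusters >= 2:
            meat = np.zeros((Xm.shape[1], Xm.shape[1]))
            for g in np.unique(groups):
                s_g = scores[groups == g].sum(axis=0)
                meat += np.outer(s_g, s_g)
            cov = bread @ meat @ bread * n_clusters / (n_clusters - 1)
            df = n_clusters - 1
            crit = stats.t.ppf(1 - self.alpha / 2, df)
            sf = lambda z: 2 * stats.t.sf(np.abs(z), df)
        else:
            if groups is not None:
                warnings.warn(
                    "fewer than 2 clusters; falling back to classical covariance",
                    UserWarning,
                    stacklevel=2,
                )
            cov = bread
            crit = stats.norm.ppf(1 - self.alpha / 2)
            sf = lambda z: 2 * stats.norm.sf(np.abs(z))

        names = list(Xf.columns)
        bse = np.sqrt(np.diag(cov))
        zvals = params.to_numpy() / bse
        self.feature_names_in_ = np.array(names, dtype=object)
        self.params_ = pd.Series(params.to_numpy(), index=names)
        self.cov_ = pd.DataFrame(cov, index=names, columns=names)
        self.bse_ = pd.Series(bse, index=names)
        self.pvalues_ = pd.Series(sf(zvals), index=names)
        ci = np.column_stack(
            [params.to_numpy() - crit * bse, params.to_numpy() + crit * bse]
        )
        self.conf_int_ = pd.DataFrame(ci, index=names, columns=["low", "high"])
        with np.errstate(over="ignore"):  # separated fits give infinite CI bounds
            self.odds_ratios_ = pd.DataFrame(
                {
                    "odds_ratio": np.exp(params.to_numpy()),
                    "ci_low": np.exp(ci[:, 0]),
                    "ci_high": np.exp(ci[:, 1]),
                    "p_value": sf(zvals),
                },
                index=names,
            )
        self.n_obs_ = int(Xm.shape[0])
        self.n_clusters_ = int(n_clusters)
        self.converged_ = converged and not separation
        self.separation_ = separation
        self.llf_ = float(res.llf)
        self._columns = names
        return self

    def predict_proba(self, X) -> np.ndarray:
        Xf = self._as_frame(X)
        if self.add_constant:
            Xf = sm.add_constant(Xf, has_constant="add")
        eta = Xf[self._columns].to_numpy() @ self.params_.to_numpy()
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one model of the battery."""

    outcome: str
    category: str
    covariates: tuple[str, ...]
    cluster_var: str = "hospital"
    reference_levels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        has_tech = any(c in self.covariates for c in TECH_COVARIATES)
        if self.outcome == "awareness" and has_tech:
            raise ValueError("awareness models exclude pu/peou")
        if self.outcome in ("want", "adoption") and not has_tech:
            raise ValueError(f"{self.outcome} models include pu and peou")


def default_model_spec(outcome: str, category: str) -> ModelSpec:
    cov = BASE_COVARIATES if outcome == "awareness" else BASE_COVARIATES + TECH_COVARIATES
    return ModelSpec(outcome=outcome, category=category, covariates=cov)


@dataclass(frozen=True)
class RegressionResult:
    """Odds ratios with cluster-robust 95% CIs for one fitted model."""

    outcome: str
    category: str
    terms: tuple[dict, ...]  # term, level, odds_ratio, ci_low, ci_high, p_value
    n_used: int
    n_clusters: int
    converged: bool
    error: str | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(list(self.terms))
        df.insert(0, "category", self.category)
        df.insert(0, "outcome", self.outcome)
        return df


# design-matrix column -> (term, level) labels for reporting
_TERM_LABELS = {
    "const": ("intercept", ""),
    "female": ("sex", "female"),
    "age": ("age", ""),
    "unmarried": ("marital", "unmarried"),
    "rural": ("residence", "rural"),
    "education": ("education", ""),
    "income_middle": ("income", "middle"),
    "income_highest": ("income", "highest"),
    "srh_fair": ("srh", "fair"),
    "srh_positive": ("srh", "positive"),
    "chronic_yes": ("chronic", "yes"),
    "eheals": ("eheals", ""),
    "pu": ("pu", ""),
    "peou": ("peou", ""),
}

_TIER_ORDER = {"lowest": 0, "middle": 1, "highest": 2}


def build_design_matrix(
    records: Sequence[RespondentRecord],
    covariates: Sequence[str],
    *,
    reference_income: float | None = None,
    missing: MissingPolicy = "strict",
) -> pd.DataFrame:
    """Scored design matrix (without intercept) for the requested covariates.

    Categorical codes are expanded to indicators against the reference
    levels of the published models (male, married, urban, lowest income,
    negative SRH, no chronic disease); continuous covariates enter
    untransformed.  Rows with any missing covariate carry NaN and are
    dropped per-model by the caller (complete-case analysis).
    """
    cols: dict[str, list] = {c: [] for c in _expand(covariates)}
    for rec in records:
        cv = score_record(rec, reference_income=reference_income, missing=missing)
        vals = {
            "female": float(cv.sex == 2),
            "age": float(cv.age),
            "unmarried": float(cv.marital == 2),
            "rural": float(cv.residence == 2),
            "education": float(cv.education),
            "income_middle": (
                np.nan if cv.income_tier is None else float(cv.income_tier == "middle")
            ),
            "income_highest": (
                np.nan if cv.income_tier is None else float(cv.income_tier == "highest")
            ),
            "srh_fair": float(cv.srh3 == "fair"),
            "srh_positive": float(cv.srh3 == "positive"),
            "chronic_yes": float(cv.chronic == 2),
            "eheals": np.nan if cv.eheals is None else float(cv.eheals),
            "pu": np.nan if cv.pu is None else float(cv.pu),
            "peou": np.nan if cv.peou is None else float(cv.peou),
        }
        for c in cols:
            cols[c].append(vals[c])
    return pd.DataFrame(cols)


def _expand(covariates: Sequence[str]) -> list[str]:
    out: list[str] = []
    for c in covariates:
        if c == "sex":
            out.append("female")
        elif c == "marital":
            out.append("unmarried")
        elif c == "residence":
            out.append("rural")
        elif c == "income_tier":
            out += ["income_middle", "income_highest"]
        elif c == "srh3":
            out += ["srh_fair", "srh_positive"]
        elif c == "chronic":
            out.append("chronic_yes")
        elif c in ("age", "education", "eheals", "pu", "peou"):
            out.append(c)
        else:
            raise ValueError(f"unknown covariate {c!r}")
    return out


def fit_logit_cluster(
    records: Sequence[RespondentRecord],
    spec: ModelSpec,
    catalog: ServiceCatalog | None = None,
    *,
    reference_income: float | None = None,
    missing: MissingPolicy = "strict",
) -> RegressionResult:
    """Fit one model of the battery on complete cases."""
    catalog = catalog or default_catalog()
    X = build_design_matrix(
        records, spec.covariates, reference_income=reference_income, missing=missing
    )
    awa = aggregate_category(records, catalog, spec.category)
    y = pd.Series(
        [getattr(a, spec.outcome) for a in awa], dtype="float"
    )
    groups = pd.Series([getattr(r, spec.cluster_var) for r in records])

    keep = X.notna().all(axis=1) & y.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"{spec.outcome}/{spec.category}: {n_dropped} rows dropped "
            "(listwise deletion)",
            UserWarning,
            stacklevel=2,
        )
    Xk, yk, gk = X[keep], y[keep].to_numpy(), groups[keep].to_numpy()

    est = ClusterRobustLogit()
    est.fit(Xk, yk, groups=gk)
    terms = []
    for name in est.params_.index:
        term, level = _TERM_LABELS.get(name, (name, ""))
        row = est.odds_ratios_.loc[name]
        terms.append(
            {
                "term": term,
                "level": level,
                "odds_ratio": float(row["odds_ratio"]),
                "ci_low": float(row["ci_low"]),
                "ci_high": float(row["ci_high"]),
                "p_value": float(row["p_value"]),
            }
        )
    return RegressionResult(
        outcome=spec.outcome,
        category=str(getattr(spec.category, "value", spec.category)),
        terms=tuple(terms),
        n_used=est.n_obs_,
        n_clusters=est.n_clusters_,
        converged=est.converged_,
    )


def run_table4_battery(
    records: Sequence[RespondentRecord],
    catalog: ServiceCatalog | None = None,
    *,
    reference_income: float | None = None,
    missing: MissingPolicy = "strict",
) -> list[RegressionResult]:
    """Fit all nine models: three outcomes within each service category.

    Ordering is category-major (information-based awareness/want/adoption,
    then treatment-intermediary, then treatment), mirroring the published
    model numbering 1-9.  A failing model yields a placeholder result with
    the error recorded; the battery continues.
    """
    catalog = catalog or default_catalog()
    results: list[RegressionResult] = []
    for category in (
        Category.INFORMATION_BASED,
        Category.TREATMENT_INTERMEDIARY,
        Category.TREATMENT,
    ):
        for outcome in OUTCOMES:
            spec = default_model_spec(outcome, category)
            try:
                results.append(
                    fit_logit_cluster(
                        records,
                        spec,
                        catalog,
                        reference_income=reference_income,
                        missing=missing,
                    )
                )
            except Exception as exc:  # keep going past individual failures
                results.append(
                    RegressionResult(
                        outcome=outcome,
                        category=category.value,
                        terms=(),
                        n_used=0,
                        n_clusters=0,
                        converged=False,
                        error=str(exc),
                    )
                )
    return results


def battery_to_frame(results: Iterable[RegressionResult]) -> pd.DataFrame:
    """Stack battery results into one tidy table (CSV-ready)."""
    frames = [r.to_frame() for r in results if r.terms]
    if not frames:
        return pd.DataFrame(
            columns=["outcome", "category", "term", "level", "odds_ratio",
                     "ci_low", "ci_high", "p_value"]
        )
    return pd.concat(frames, ignore_index=True)
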