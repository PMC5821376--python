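"""Moderated regression of environment on outcome with a binary genetic moderator.

The core model is the crossover-interaction regression

    Y = b0 + b1*X + b2*Z + b3*X*Z + e,

where X is a continuous environment score (here: mean subjective impact of
recent life events, on the raw -3..+3 scale), Z is a binary risk-carrier
moderator and e is homoskedastic Gaussian noise.  :class:`GxEModel` builds
the design (optionally with X^2 / X^2*Z nonlinearity terms or
covariate-by-X and covariate-by-Z adjustment terms) and ``fit`` returns a
:class:`GxEResults` object carrying estimates, their covariance, simple
slopes and the downstream susceptibility indices.

X and covariates enter uncentered by default: the crossover point -b2/b3
is then expressed on the raw environment scale.  Centering is an explicit
opt-in that re-expresses the model, never a silent default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import SingularDesignError

logger = logging.getLogger("gxeds")

BASE_TERMS = ("const", "x", "z", "x:z")


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class AnalysisDataset:
    """Aligned outcome / environment / moderator (/ covariate) arrays.

    Listwise deletion is applied at assembly; the number of dropped rows
    is logged and recorded so analysed-n bookkeeping matches the data that
    actually entered the fit.
    """

    y: np.ndarray
    x: np.ndarray
    z: np.ndarray
    covariates: pd.DataFrame | None
    ids: pd.Index
    outcome_name: str = "y"
    env_name: str = "x"
    moderator_name: str = "z"
    n_dropped: int = 0

    @classmethod
    def assemble(
        cls,
        phenotypes: pd.DataFrame,
        outcome: str,
        env: str,
        moderator,
        covariates: Sequence[str] = (),
    ) -> "AnalysisDataset":
        from .genetics import ModeratorGroup

        cols = [outcome, env, *covariates]
        missing = [c for c in cols if c not in phenotypes.columns]
        if missing:
            raise KeyError(f"phenotype table lacks column(s): {missing}")
        frame = phenotypes[cols].apply(pd.to_numeric)
        if isinstance(moderator, ModeratorGroup):
            z = moderator.coding
            name = moderator.name
        elif isinstance(moderator, str):
            z = pd.to_numeric(phenotypes[moderator])
            name = moderator
        else:
            z = pd.Series(moderator, index=phenotypes.index)
            name = getattr(moderator, "name", None) or "z"
        frame = frame.join(z.rename("__z__"), how="inner")
        before = len(phenotypes)
        frame = frame.dropna()
        dropped = before - len(frame)
        if dropped:
            logger.info(
                "assemble(%s ~ %s x %s): %d of %d individuals dropped "
                "(missing data or excluded from moderator)",
                outcome, env, name, dropped, before,
            )
        cov = frame[list(covariates)] if covariates else None
        return cls(
            y=frame[outcome].to_numpy(float),
            x=frame[env].to_numpy(float),
            z=frame["__z__"].to_numpy(float),
            covariates=cov,
            ids=frame.index,
            outcome_name=outcome,
            env_name=env,
            moderator_name=name,
            n_dropped=dropped,
        )

    def __len__(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class GxEModel:
    """OLS crossover-interaction model Y = b0 + b1*X + b2*Z + b3*X*Z.

    Parameters
    ----------
    quadratic
        Add X^2 and X^2*Z terms (nonlinearity check).
    keller
        For each covariate C, add C, C*X and C*Z so the interaction term
        is tested net of covariate-by-environment and covariate-by-gene
        confounding (no three-way C*X*Z term).
    center
        Subtract the sample mean from X (and covariates) before building
        the design.  Off by default; the crossover identity -b2/b3 then
        lives on the raw X scale.
    """

    def __init__(
        self,
        y,
        x,
        z,
        covariates: pd.DataFrame | Mapping | None = None,
        *,
        quadratic: bool = False,
        keller: bool = False,
        center: bool = False,
        ids=None,
    ):
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        if not (len(y) == len(x) == len(z)):
            raise ValueError("y, x and z must have equal length")
        if np.isnan(y).any() or np.isnan(x).any() or np.isnan(z).any():
            raise ValueError("missing values must be removed before fitting")
        if not set(np.unique(z)) <= {0.0, 1.0}:
            raise ValueError("moderator z must be binary 0/1")
        if keller and covariates is None:
            raise ValueError("keller adjustment requires at least one covariate")
        if covariates is not None and not isinstance(covariates, pd.DataFrame):
            covariates = pd.DataFrame(dict(covariates))

        x_used = x - x.mean() if center else x
        exog = {"const": np.ones(len(y)), "x": x_used, "z": z, "x:z": x_used * z}
        if quadratic:
            exog["x2"] = x_used**2
            exog["x2:z"] = x_used**2 * z
        if covariates is not None:
            for name in covariates.columns:
                c = covariates[name].to_numpy(float)
                c_used = c - c.mean() if center else c
                exog[name] = c_used
                if keller:
                    exog[f"{name}:x"] = c_used * x_used
                    exog[f"{name}:z"] = c_used * z
        self.exog = pd.DataFrame(exog, index=ids if ids is not None else None)
        self.endog = y
        self.quadratic = quadratic
        self.keller = keller
        self.center = center
        if len(y) < self.exog.shape[1] + 2:
            raise ValueError(
                f"n = {len(y)} too small for {self.exog.shape[1]} parameters"
            )

    @classmethod
    def from_dataset(cls, data: AnalysisDataset, **kwargs) -> "GxEModel":
        return cls(
            data.y, data.x, data.z, covariates=data.covariates, ids=data.ids, **kwargs
        )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        outcome: str,
        env: str,
        moderator: str,
        covariates: Sequence[str] = (),
        **kwargs,
    ) -> "GxEModel":
        data = AnalysisDataset.assemble(frame, outcome, env, moderator, covariates)
        return cls.from_dataset(data, **kwargs)

    def _check_rank(self) -> None:
        mat = self.exog.to_numpy()
        rank = 0
        for j, name in enumerate(self.exog.columns):
            new_rank = np.linalg.matrix_rank(mat[:, : j + 1])
            if new_rank == rank:
                raise SingularDesignError(
                    f"design is rank deficient: column {name!r} is collinear "
                    "with the preceding columns"
                )
            rank = new_rank

    def fit(self) -> "GxEResults":
        self._check_rank()
        res = sm.OLS(self.endog, self.exog).fit()
        return GxEResults(sm_results=res, model=self)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimpleSlope:
    """Environment slope at a fixed moderator level (b1 or b1 + b3)."""

    moderator_level: int
    estimate: float
    se: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    p_value: float | None = None
    df: float | None = None


@dataclass(frozen=True)
class NonlinearityCheck:
    """Joint and individual tests of the X^2 and X^2*Z terms."""

    p_x2: float
    p_x2_z: float
    p_joint: float
    alpha: float
    detected: bool


class GxEResults:
    """Fitted interaction model: estimates, covariance, diagnostics.

    Can be built from a fitted :class:`GxEModel` or, via ``from_params``,
    directly from published coefficients (with optional covariance and
    residual df) so that crossover/PoI/simple-slope arithmetic can be
    applied to printed regression tables.
    """

    def __init__(self, *, sm_results=None, model=None, params=None, cov=None,
                 df_resid=None, nobs=None):
        self._sm = sm_results
        self.model = model
        if sm_results is not None:
            self.params = sm_results.params.copy()
            self._cov = sm_results.cov_params()
            self.df_resid = float(sm_results.df_resid)
            self.nobs = int(sm_results.nobs)
        else:
            if params is None:
                raise ValueError("either sm_results or params is required")
            if not isinstance(params, pd.Series):
                params = pd.Series(
                    np.asarray(params, float), index=list(BASE_TERMS)[: len(params)]
                )
            self.params = params
            if cov is not None:
                cov = pd.DataFrame(
                    np.asarray(cov, float), index=params.index, columns=params.index
                )
                diff = cov.to_numpy() - cov.to_numpy().T
                if np.abs(diff).max() > 1e-8:
                    raise ValueError("coefficient covariance must be symmetric")
            self._cov = cov
            self.df_resid = None if df_resid is None else float(df_resid)
            self.nobs = nobs

    @classmethod
    def from_params(cls, params, cov=None, df_resid=None, nobs=None) -> "GxEResults":
        return cls(params=params, cov=cov, df_resid=df_resid, nobs=nobs)

    # -- accessors -------------------------------------------------------
    @property
    def b(self) -> np.ndarray:
        """Coefficients (b0, b1, b2, b3) of the base interaction model."""
        return self.params.loc[list(BASE_TERMS)].to_numpy()

    def cov_params(self) -> pd.DataFrame:
        if self._cov is None:
            raise ValueError("no coefficient covariance available for this fit")
        return self._cov

    @property
    def has_cov(self) -> bool:
        return self._cov is not None

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params())), index=self.params.index
        )

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        if self._sm is not None:
            return self._sm.pvalues
        if self.df_resid is None:
            raise ValueError("residual df required for p-values")
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df_resid),
            index=self.params.index,
        )

    @property
    def rsquared(self) -> float:
        if self._sm is None:
            raise ValueError("fit statistics require a fitted model")
        return float(self._sm.rsquared)

    @property
    def rsquared_adj(self) -> float:
        if self._sm is None:
            raise ValueError("fit statistics require a fitted model")
        return float(self._sm.rsquared_adj)

    @property
    def interaction_pvalue(self) -> float:
        return float(self.pvalues["x:z"])

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = stats.t.ppf(1 - alpha / 2, self.df_resid)
        se = self.bse
        return pd.DataFrame(
            {"lower": self.params - tcrit * se, "upper": self.params + tcrit * se}
        )

    # -- derived quantities ---------------------------------------------
    def simple_slopes(self, alpha: float = 0.05) -> tuple[SimpleSlope, SimpleSlope]:
        return simple_slopes(self, alpha=alpha)

    def nonlinearity_check(self, alpha: float = 0.05) -> NonlinearityCheck:
        """Joint F-test of (X^2, X^2*Z) plus the individual t-test p-values.

        The detection flag is driven by the joint test at ``alpha``.
        """
        if "x2" not in self.params.index or "x2:z" not in self.params.index:
            raise ValueError("fit the model with quadratic=True first")
        if self._sm is None:
            raise ValueError("nonlinearity check requires a fitted model")
        p = self.pvalues
        contrast = np.zeros((2, len(self.params)))
        contrast[0, list(self.params.index).index("x2")] = 1.0
        contrast[1, list(self.params.index).index("x2:z")] = 1.0
        p_joint = float(self._sm.f_test(contrast).pvalue)
        return NonlinearityCheck(
            p_x2=float(p["x2"]),
            p_x2_z=float(p["x2:z"]),
            p_joint=p_joint,
            alpha=alpha,
            detected=p_joint < alpha,
        )

    def ds_indices(self, env, polarity=None, alpha: float = 0.05):
        """Differential-susceptibility indices for this fit (see
        :mod:`gxeds.indices`)."""
        from . import indices as _indices

        polarity = polarity if polarity is not None else _indices.OutcomePolarity()
        return _indices.compute_indices(self, env, polarity=polarity, alpha=alpha)

    def summary(self) -> str:
        lines = ["GxE moderated regression (OLS)"]
        if self.nobs is not None:
            lines.append(f"n = {self.nobs}, residual df = {self.df_resid:g}")
        if self._sm is not None:
            lines.append(
                f"R2 = {self.rsquared:.4f}, adjusted R2 = {self.rsquared_adj:.4f}"
            )
        table = pd.DataFrame({"coef": self.params})
        if self.has_cov and self.df_resid is not None:
            table["se"] = self.bse
            table["t"] = self.tvalues
            table["p"] = self.pvalues
            ci = self.conf_int()
            table["[0.025"] = ci["lower"]
            table["0.975]"] = ci["upper"]
        lines.append(table.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def fit_gxe(data: AnalysisDataset, center: bool = False) -> GxEResults:
    """Fit the base interaction model Y = b0 + b1*X + b2*Z + b3*X*Z."""
    return GxEModel.from_dataset(data, center=center).fit()


def simple_slopes(fit: GxEResults, alpha: float = 0.05):
    """Environment slopes at Z = 0 (b1) and Z = 1 (b1 + b3) with t-based CIs.

    var(b1 + b3) = var(b1) + var(b3) + 2 cov(b1, b3); intervals use the
    fitted model's residual df.
    """
    b1 = float(fit.params["x"])
    b3 = float(fit.params["x:z"])
    estimates = {0: b1, 1: b1 + b3}
    if not fit.has_cov or fit.df_resid is None:
        return tuple(
            SimpleSlope(moderator_level=lvl, estimate=est)
            for lvl, est in estimates.items()
        )
    cov = fit.cov_params()
    variances = {
        0: cov.loc["x", "x"],
        1: cov.loc["x", "x"] + cov.loc["x:z", "x:z"] + 2 * cov.loc["x", "x:z"],
    }
    df = fit.df_resid
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    out = []
    for lvl, est in estimates.items():
        se = float(np.sqrt(max(variances[lvl], 0.0)))
        p = float(2 * stats.t.sf(abs(est) / se, df)) if se > 0 else 0.0
        out.append(
            SimpleSlope(
                moderator_level=lvl,
                estimate=est,
                se=se,
                ci_lower=est - tcrit * se,
                ci_upper=est + tcrit * se,
                p_value=p,
                df=df,
            )
        )
    return tuple(out)


def fit_nonlinear_check(data: AnalysisDataset, center: bool = False) -> GxEResults:
    """Fit the interaction model augmented with X^2 and X^2*Z terms."""
    return GxEModel.from_dataset(data, quadratic=True, center=center).fit()


def fit_keller_adjusted(data: AnalysisDataset, center: bool = False) -> GxEResults:
    """Fit the interaction model with covariate, covariate*X and covariate*Z
    terms for every covariate, so the GxE term is tested net of
    covariate-by-environment and covariate-by-gene confounds."""
    if data.covariates is None or data.covariates.shape[1] == 0:
        raise ValueError("keller adjustment requires at least one covariate")
    return GxEModel.from_dataset(data, keller=True, center=center).fit()


@dataclass(frozen=True)
class GECorrelation:
    """Two-sample t-test of the environment score across moderator groups."""

    t_stat: float
    p_value: float
    df: float
    cohens_d: float
    d_ci_lower: float
    d_ci_upper: float


def ge_correlation_check(x, z, alpha: float = 0.05) -> GECorrelation:
    """Gene-environment correlation check: does X differ by carrier status?

    Pooled-variance two-sample t-test; Cohen's d = mean difference /
    pooled SD, with a normal-approximation confidence interval.
    """
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    g0, g1 = x[z == 0], x[z == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("both moderator groups need at least two observations")
    t_stat, p = stats.ttest_ind(g1, g0, equal_var=True)
    n0, n1 = len(g0), len(g1)
    df = n0 + n1 - 2
    pooled = np.sqrt(
        ((n0 - 1) * g0.var(ddof=1) + (n1 - 1) * g1.var(ddof=1)) / df
    )
    d = 0.0 if pooled == 0 else (g1.mean() - g0.mean()) / pooled
    se_d = np.sqrt((n0 + n1) / (n0 * n1) + d * d / (2 * (n0 + n1)))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return GECorrelation(
        t_stat=float(t_stat),
        p_value=float(p),
        df=float(df),
        cohens_d=float(d),
        d_ci_lower=float(d - zcrit * se_d),
        d_ci_upper=float(d + zcrit * se_d),
    )


@dataclass(frozen=True)
class NormalityTest:
    statistic: float
    p_value: float


def normality_check(x) -> NormalityTest:
    """Shapiro-Wilk normality test of the environment score (3 <= n <= 5000)."""
    x = np.asarray(x, float)
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant sample")
    stat, p = stats.shapiro(x)
    return NormalityTest(statistic=float(stat), p_value=float(p))
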