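"""Random-slope linear mixed models for longitudinal progression analysis.

`ProgressionModel` fits, by REML, the model used throughout the analysis:

    y_ij = x_ij' beta + b0_i + b1_i * u_ij + eps_ij,
    (b0_i, b1_i) ~ N(0, G) unstructured,  eps_ij ~ N(0, sigma^2),

where the random slope is on elapsed time in months for trajectory models
and on the standardized covariate for association models. `fit()` returns a
`ProgressionResults` carrying the fixed effects with Wald 95% CIs and
p-values, the random-effect covariance G, the residual variance, the
per-participant conditional means (empirical BLUPs), and the marginal and
conditional coefficients of determination (R2m/R2c) in the
Nakagawa-Schielzeth form with the random-slope (observation-averaged
z'Gz) extension.

Estimation is delegated to statsmodels' MixedLM; the outcome is internally
rescaled to unit SD for optimizer stability and all reported quantities are
back-transformed to natural units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning


class RankDeficientError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


class NotConvergedError(RuntimeError):
    """Raised when results of a non-converged fit are used."""


_OPTIMIZERS = ("lbfgs", "powell", "cg")


@dataclass
class ProgressionModel:
    """Random intercept + random slope LMM specification bound to data.

    Parameters
    ----------
    data : long-format observations; one row per measurement.
    outcome : outcome column name.
    time : elapsed-time column (months); always a fixed effect unless
        ``include_time=False`` (association models).
    groups : participant identifier column.
    extra_fixed : additional fixed-effect columns (indicators,
        interactions, standardized covariates), already constructed.
    random_slope_on : column carrying the random slope; defaults to `time`.
    """

    data: pd.DataFrame
    outcome: str
    time: str = "t_months"
    groups: str = "participant_id"
    extra_fixed: tuple[str, ...] = ()
    random_slope_on: str | None = None
    include_time: bool = True

    def __post_init__(self) -> None:
        if self.random_slope_on is None:
            self.random_slope_on = self.time
        cols = [self.outcome, self.groups, self.random_slope_on]
        if self.include_time:
            cols.append(self.time)
        cols.extend(self.extra_fixed)
        df = self.data.dropna(subset=list(dict.fromkeys(cols))).copy()
        if df[self.groups].nunique() < 2:
            raise ValueError("need at least 2 participants")
        if not (df.groupby(self.groups).size() >= 2).any():
            raise ValueError("need repeated measurements for some participant")
        self._df = df
        names = ["Intercept"]
        X = [np.ones(len(df))]
        if self.include_time:
            names.append(self.time)
            X.append(df[self.time].to_numpy(float))
        for c in self.extra_fixed:
            names.append(c)
            X.append(df[c].to_numpy(float))
        self._X = np.column_stack(X)
        self._fe_names = names
        if np.linalg.matrix_rank(self._X) < self._X.shape[1]:
            raise RankDeficientError(
                f"fixed-effect design {names} is rank deficient"
            )
        self._Z = np.column_stack(
            [np.ones(len(df)), df[self.random_slope_on].to_numpy(float)]
        )

    def fit(self, reml: bool = True) -> "ProgressionResults":
        y = self._df[self.outcome].to_numpy(float)
        s = float(np.std(y))
        if not np.isfinite(s) or s == 0.0:
            s = 1.0
        md = sm.MixedLM(
            y / s,
            self._X,
            groups=self._df[self.groups].to_numpy(),
            exog_re=self._Z,
        )
        md.data.xnames = list(self._fe_names)
        res, diagonal = self._optimize(md, reml)
        return ProgressionResults(self, res, scale_factor=s,
                                  diagonal_refit=diagonal)

    def _optimize(self, md, reml):
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            for method in _OPTIMIZERS:
                try:
                    res = md.fit(reml=reml, method=[method], maxiter=2000)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if res.converged and _psd(np.asarray(res.cov_re)):
                    return res, False
            # singular or non-converged G: retry with diagonal covariance
            free = MixedLMParams.from_components(
                fe_params=np.ones(self._X.shape[1]), cov_re=np.eye(2)
            )
            for method in _OPTIMIZERS:
                try:
                    dres = md.fit(
                        reml=reml, method=[method], maxiter=2000, free=free
                    )
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if dres.converged:
                    return dres, True
        if res is None:
            raise NotConvergedError("mixed-model optimization failed")
        return res, False  # non-converged; flagged on the results object


def _psd(a: np.ndarray, rtol: float = 1e-10) -> bool:
    w = np.linalg.eigvalsh(a)
    return bool(w.min() >= -rtol * max(w.max(), 1.0) and w.min() > 0)


class ProgressionResults:
    """Estimates, uncertainties and diagnostics of a fitted model."""

    def __init__(self, model: ProgressionModel, res, scale_factor: float,
                 diagonal_refit: bool) -> None:
        self.model = model
        self._res = res
        self._s = scale_factor
        self.diagonal_refit = diagonal_refit
        self.converged = bool(res.converged)
        k = len(model._fe_names)
        self.fe_names = list(model._fe_names)
        self.params = pd.Series(
            np.asarray(res.fe_params) * scale_factor, index=self.fe_names
        )
        self.bse = pd.Series(
            np.asarray(res.bse_fe) * scale_factor, index=self.fe_names
        )
        ci = np.asarray(res.conf_int())[:k] * scale_factor
        self.conf_int = pd.DataFrame(
            ci, index=self.fe_names, columns=["ci_low", "ci_high"]
        )
        self.pvalues = pd.Series(
            np.asarray(res.pvalues)[:k], index=self.fe_names
        )
        self.cov_re = pd.DataFrame(
            np.asarray(res.cov_re) * scale_factor**2,
            index=["intercept", "slope"],
            columns=["intercept", "slope"],
        )
        self.scale = float(res.scale) * scale_factor**2  # residual variance
        self.n_obs = len(model._df)
        self.n_groups = model._df[model.groups].nunique()

    # -- random effects & conditional means ------------------------------

    @property
    def random_effects(self) -> pd.DataFrame:
        """Empirical BLUPs of (intercept, slope) per participant."""
        self._require_converged()
        rows = {
            pid: np.asarray(be) * self._s
            for pid, be in self._res.random_effects.items()
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["b0", "b1"]
        )

    def conditional_lines(self) -> pd.DataFrame:
        """Per-participant conditional (intercept, slope) of the outcome
        against the random-slope variable.

        Only defined for pure trajectory models (no extra fixed terms).
        """
        self._require_converged()
        if self.model.extra_fixed:
            raise ValueError(
                "conditional lines are defined only for outcome ~ time models"
            )
        re = self.random_effects
        beta0 = self.params["Intercept"]
        beta1 = self.params[self.model.time] if self.model.include_time else 0.0
        return pd.DataFrame(
            {
                "intercept": beta0 + re["b0"],
                "slope": beta1 + re["b1"],
            },
            index=re.index,
        )

    def conditional_means(self, times) -> pd.DataFrame:
        """Model-implied trajectories at the given times (months)."""
        lines = self.conditional_lines()
        times = np.asarray(times, dtype=float)
        vals = lines["intercept"].to_numpy()[:, None] + np.outer(
            lines["slope"].to_numpy(), times
        )
        return pd.DataFrame(vals, index=lines.index, columns=times)

    # -- derived quantities ----------------------------------------------

    def r2(self) -> tuple[float, float]:
        """(R2m, R2c): variance explained by fixed effects alone vs fixed
        plus random effects, with the random-slope extension in which the
        random-effect variance is averaged over observations as z'Gz."""
        self._require_converged()
        var_f = float(np.var(self.model._X @ (self.params.to_numpy())))
        G = self.cov_re.to_numpy()
        Z = self.model._Z
        var_r = float(np.mean(np.einsum("ij,jk,ik->i", Z, G, Z)))
        total = var_f + var_r + self.scale
        if total <= 0:
            return float("nan"), float("nan")
        return var_f / total, (var_f + var_r) / total

    def pct_relative_change(
        self, horizon: float = 6.0, threshold: float = 0.10
    ) -> float:
        """Percent of participants whose conditional mean changed by at
        least `threshold` (relative) over `horizon` months, in the same
        direction as the population slope.

        Participants with a zero conditional baseline are excluded.
        """
        lines = self.conditional_lines()
        m0 = lines["intercept"] + lines["slope"] * 0.0
        mh = lines["intercept"] + lines["slope"] * horizon
        usable = m0 != 0
        if not usable.any():
            return float("nan")
        rel = (mh[usable] - m0[usable]) / m0[usable]
        pop_sign = np.sign(self.params[self.model.time])
        hit = (rel.abs() >= threshold) & (
            np.sign(mh[usable] - m0[usable]) == pop_sign
        )
        return float(100.0 * hit.sum() / usable.sum())

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        r2m, r2c = self.r2() if self.converged else (float("nan"),) * 2
        lines = [
            f"Random-slope LMM: {self.model.outcome} "
            f"(REML; n_obs={self.n_obs}, n_participants={self.n_groups})",
            f"converged={self.converged}"
            + ("  [diagonal G refit]" if self.diagonal_refit else ""),
            "",
            f"{'term':<22}{'estimate':>14}{'ci_low':>14}"
            f"{'ci_high':>14}{'p':>10}",
        ]
        for name in self.fe_names:
            lines.append(
                f"{name:<22}{self.params[name]:>14.4g}"
                f"{self.conf_int.loc[name, 'ci_low']:>14.4g}"
                f"{self.conf_int.loc[name, 'ci_high']:>14.4g}"
                f"{self.pvalues[name]:>10.3g}"
            )
        g = self.cov_re.to_numpy()
        corr = (
            g[0, 1] / np.sqrt(g[0, 0] * g[1, 1])
            if g[0, 0] > 0 and g[1, 1] > 0
            else float("nan")
        )
        lines += [
            "",
            f"random effects: sd(intercept)={np.sqrt(max(g[0, 0], 0)):.4g}, "
            f"sd(slope)={np.sqrt(max(g[1, 1], 0)):.4g}, corr={corr:.3f}",
            f"residual sd={np.sqrt(self.scale):.4g}",
            f"R2m={r2m:.3f}, R2c={r2c:.3f}",
        ]
        return "\n".join(lines)

    def fe_table(self) -> pd.DataFrame:
        """Tidy fixed-effect table: term, estimate, CI bounds, p-value."""
        return pd.DataFrame(
            {
                "term": self.fe_names,
                "estimate": self.params.to_numpy(),
                "ci_low": self.conf_int["ci_low"].to_numpy(),
                "ci_high": self.conf_int["ci_high"].to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )

    def _require_converged(self) -> None:
        if not self.converged:
            raise NotConvergedError(
                "model did not converge; estimates unavailable"
            )
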