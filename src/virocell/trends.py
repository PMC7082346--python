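"""Treatment x time polynomial trend models for global omics counts.

Per-sample total transcript (or protein) counts are modelled by Gaussian
least squares as

    counts ~ treatment + time + time^2 + treatment:time

with reference-level treatment contrasts. Raw counts (not a count GLM) are
modelled deliberately, to match the way these global time-course summaries
are usually analysed. Effects are tested with nested-model F statistics
(the time test pools the linear and quadratic terms), fitted curves carry
Bonferroni-corrected simultaneous confidence bands, and treatment pairs are
compared on overall level and linear time trend with Tukey's studentized
range adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin


@dataclass
class PairwiseComparison:
    pair: str
    quantity: str  # "level" | "slope"
    estimate: float
    se: float
    statistic: float
    p_adjusted: float


def _check_design(design: pd.DataFrame) -> pd.DataFrame:
    for col in ("response", "treatment", "time_min"):
        if col not in design.columns:
            raise ValueError(f"design missing column {col!r}")
    if design["time_min"].nunique() < 3:
        raise ValueError("need at least 3 distinct timepoints")
    return design


class TimeTrendModel(RegressorMixin, BaseEstimator):
    """Least-squares treatment x time trend model (sklearn-style estimator).

    Parameters
    ----------
    reference : treatment used as the contrast baseline (its effects are
        absorbed in the intercept/time terms).
    quadratic_interaction : also interact the quadratic term with treatment.

    Attributes (after ``fit``)
    --------------------------
    coef_ : named coefficient Series.
    treatments_ : treatment levels in model order (reference first).
    result_ : the underlying OLS results (covariances, residuals).
    """

    def __init__(self, reference: str = "uninfected", quadratic_interaction: bool = False):
        self.reference = reference
        self.quadratic_interaction = quadratic_interaction

    # -- design matrix ------------------------------------------------------
    def _levels(self, design: pd.DataFrame) -> list[str]:
        levels = list(pd.unique(design["treatment"]))
        if self.reference in levels:
            levels.remove(self.reference)
            levels = [self.reference] + sorted(levels)
        else:
            levels = sorted(levels)
        return levels

    def _design_matrix(self, df: pd.DataFrame, levels: list[str]) -> pd.DataFrame:
        t = df["time_min"].to_numpy(dtype=float)
        cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
        for lev in levels[1:]:
            cols[f"treatment[{lev}]"] = (df["treatment"] == lev).to_numpy(float)
        cols["time"] = t
        cols["time2"] = t**2
        for lev in levels[1:]:
            cols[f"treatment[{lev}]:time"] = cols[f"treatment[{lev}]"] * t
            if self.quadratic_interaction:
                cols[f"treatment[{lev}]:time2"] = cols[f"treatment[{lev}]"] * t**2
        return pd.DataFrame(cols, index=df.index)

    # -- fitting ------------------------------------------------------------
    def fit(self, design: pd.DataFrame, y=None):
        design = _check_design(design)
        self.design_ = design.reset_index(drop=True)
        self.treatments_ = self._levels(design)
        X = self._design_matrix(self.design_, self.treatments_)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # identify aliased columns by pivoted QR
            from scipy.linalg import qr as pivoted_qr

            _, r, piv = pivoted_qr(X.to_numpy(), pivoting=True)
            diag = np.abs(np.diag(r))
            tol = (diag.max() if diag.size else 0.0) * 1e-10
            aliased = [
                str(X.columns[piv[i]])
                for i in range(X.shape[1])
                if i >= diag.size or diag[i] <= tol
            ]
            raise ValueError(f"design matrix rank deficient; aliased: {aliased}")
        self.X_ = X
        self.result_ = sm.OLS(self.design_["response"].to_numpy(), X).fit()
        self.coef_ = pd.Series(self.result_.params, index=X.columns)
        self.df_resid_ = int(self.result_.df_resid)
        self.sigma2_ = float(self.result_.mse_resid)
        return self

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        X = self._design_matrix(design, self.treatments_)
        return X.to_numpy() @ self.coef_.to_numpy()

    # -- effect F tests -----------------------------------------------------
    def anova_effects(self) -> pd.DataFrame:
        """Sequential nested-model F tests with the full-model error.

        Terms enter in the order treatment, time (linear and quadratic
        jointly), treatment:time; each F compares consecutive nested fits:
        F = ((RSS_reduced - RSS_full_block) / ddf) / (RSS_full / df_resid).
        """
        y = self.design_["response"].to_numpy()
        blocks = [
            ("treatment", [c for c in self.X_.columns if c.startswith("treatment[") and ":" not in c]),
            ("time", ["time", "time2"]),
            ("treatment:time", [c for c in self.X_.columns if ":" in c]),
        ]
        blocks = [(n, cols) for n, cols in blocks if cols]
        rss_full = float(self.result_.ssr)
        if self.df_resid_ == 0:
            raise ValueError("zero residual degrees of freedom")
        mse = rss_full / self.df_resid_
        rows = []
        included = ["Intercept"]
        rss_prev = float(np.sum((y - y.mean()) ** 2))
        for name, cols in blocks:
            included = included + cols
            beta, rss_cur, *_ = np.linalg.lstsq(
                self.X_[included].to_numpy(), y, rcond=None
            )
            rss_cur = float(np.sum((y - self.X_[included].to_numpy() @ beta) ** 2))
            ddf = len(cols)
            fstat = ((rss_prev - rss_cur) / ddf) / mse
            p = float(stats.f.sf(fstat, ddf, self.df_resid_))
            rows.append((name, ddf, self.df_resid_, fstat, p))
            rss_prev = rss_cur
        return pd.DataFrame(
            rows, columns=["effect", "df_num", "df_den", "F", "p"]
        ).set_index("effect")

    # -- simultaneous confidence bands --------------------------------------
    def simultaneous_cis(
        self,
        grid: np.ndarray | list,
        alpha: float = 0.05,
        m_corrections: int | None = None,
    ) -> pd.DataFrame:
        """Fitted curve per treatment with Bonferroni simultaneous CIs.

        The half-width at each grid x treatment point is
        t(1 - alpha/(2 m), df_resid) * se(fitted); ``m`` defaults to the
        number of grid x treatment points. Grid points outside the observed
        time range only warn.
        """
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.design_["time_min"].min(), self.design_["time_min"].max()
        if (grid < lo).any() or (grid > hi).any():
            warnings.warn("CI grid extrapolates beyond the observed time range")
        m = m_corrections or len(grid) * len(self.treatments_)
        tcrit = stats.t.ppf(1 - alpha / (2 * m), self.df_resid_)
        cov = np.asarray(self.result_.cov_params())
        rows = []
        for trt in self.treatments_:
            df = pd.DataFrame({"treatment": trt, "time_min": grid})
            X = self._design_matrix(df, self.treatments_).to_numpy()
            fit = X @ self.coef_.to_numpy()
            se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
            for t, f, s in zip(grid, fit, se):
                rows.append((trt, t, f, f - tcrit * s, f + tcrit * s))
        return pd.DataFrame(rows, columns=["treatment", "time_min", "fit", "lo", "hi"])

    # -- Tukey pairwise comparisons ------------------------------------------
    def _contrast(self, a: str, b: str, quantity: str) -> np.ndarray:
        """Contrast vector for treatment a minus b on level or linear slope."""
        c = pd.Series(0.0, index=self.X_.columns)
        tbar = float(self.design_["time_min"].mean())
        for lev, sign in ((a, 1.0), (b, -1.0)):
            if lev == self.treatments_[0]:
                continue  # reference contributes zero to contrasts
            if quantity == "level":
                c[f"treatment[{lev}]"] += sign
                c[f"treatment[{lev}]:time"] += sign * tbar
                if self.quadratic_interaction:
                    c[f"treatment[{lev}]:time2"] += sign * tbar**2
            elif quantity == "slope":
                c[f"treatment[{lev}]:time"] += sign
                if self.quadratic_interaction:
                    c[f"treatment[{lev}]:time2"] += sign * 2 * tbar
            else:
                raise ValueError("quantity must be 'level' or 'slope'")
        return c.to_numpy()

    def tukey_pairwise(self, quantity: str = "level") -> list[PairwiseComparison]:
        """All treatment-pair contrasts with studentized-range adjusted p.

        ``quantity='level'`` compares the fitted mean response at the
        average observed time; ``'slope'`` compares linear time trends.
        With two treatments Tukey reduces to an ordinary t test.
        """
        k = len(self.treatments_)
        if k < 2:
            raise ValueError("need at least 2 treatments")
        cov = np.asarray(self.result_.cov_params())
        out = []
        for i in range(k):
            for j in range(i + 1, k):
                a, b = self.treatments_[i], self.treatments_[j]
                c = self._contrast(a, b, quantity)
                est = float(c @ self.coef_.to_numpy())
                se = float(np.sqrt(c @ cov @ c))
                tval = est / se if se > 0 else 0.0
                p = float(
                    stats.studentized_range.sf(
                        np.sqrt(2.0) * abs(tval), k, self.df_resid_
                    )
                )
                out.append(
                    PairwiseComparison(
                        pair=f"{a} - {b}",
                        quantity=quantity,
                        estimate=est,
                        se=se,
                        statistic=tval,
                        p_adjusted=min(1.0, p),
                    )
                )
        return out


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


def fit_trend_model(
    design: pd.DataFrame,
    reference: str = "uninfected",
    quadratic_interaction: bool = False,
) -> TimeTrendModel:
    """Fit the treatment x time trend model; returns the fitted estimator."""
    return TimeTrendModel(
        reference=reference, quadratic_interaction=quadratic_interaction
    ).fit(design)


def anova_effects(fit: TimeTrendModel) -> pd.DataFrame:
    return fit.anova_effects()


def simultaneous_cis(
    fit: TimeTrendModel, grid, alpha: float = 0.05, m_corrections: int | None = None
) -> pd.DataFrame:
    return fit.simultaneous_cis(grid, alpha=alpha, m_corrections=m_corrections)


def tukey_pairwise(fit: TimeTrendModel, quantity: str = "level") -> list[PairwiseComparison]:
    return fit.tukey_pairwise(quantity)
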