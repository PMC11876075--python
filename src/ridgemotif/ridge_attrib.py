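"""Ridge models of differential accessibility and motif attribution.

The per-peak log2 fold change in accessibility between two cell
populations is modeled as a linear function of binary motif presence:

    y = b0 + X beta + eps,    beta_ridge = (X'X + lambda I)^{-1} X' y

on column-centered X with an unpenalized intercept. The ridge parameter
can be fixed or chosen semi-automatically in the Cule-De Iorio manner: a
principal-components generalization of the Hoerl-Kennard-Baldwin
estimator, lambda_r = r * sigma^2_r / ||alpha_r||^2, is evaluated for
every number of components r, and the candidate minimizing exact
leave-one-out prediction error is retained. Coefficient significance
follows Cule's test: a normal reference on the ridge estimator's
asymptotic standard error.

Motif importance at a peak subset is measured by leave-one-motif-out
delta-cor: the drop in Pearson correlation between observed and
predicted log2FC on the subset when the models are refit with that
motif's column removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DifferentialTable
from .motif_catalog import PeakMotifMatrix


@dataclass
class RidgeFit:
    """A fitted ridge model for one population comparison."""

    comparison: str
    lam: float
    coefficients: pd.Series  # indexed by motif group
    intercept: float
    pvalues: pd.Series
    fitted: pd.Series  # indexed by peak id
    stderr: pd.Series = field(repr=False, default=None)
    sigma2: float = field(repr=False, default=np.nan)

    def __post_init__(self) -> None:
        p = self.pvalues.dropna()
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values outside [0,1]")


@dataclass
class DeltaCorReport:
    """Per-motif delta-cor and mean subset log2FC at one peak subset."""

    subset: str
    table: pd.DataFrame  # columns: delta_cor, subset_log2fc_mean, full_model_coefficient
    reference_log2fc: float  # mean log2FC over all subset peaks (dashed line)
    cor_full: float


@dataclass
class SignificanceCall:
    group: str
    svn_significant: bool
    svr_significant: bool
    alpha: float = 0.001

    @property
    def category(self) -> str:
        if self.svn_significant and self.svr_significant:
            return "both"
        if self.svn_significant:
            return "svn-only"
        if self.svr_significant:
            return "svr-only"
        return "neither"


def _as_frame(X: PeakMotifMatrix | pd.DataFrame) -> pd.DataFrame:
    return X.values if isinstance(X, PeakMotifMatrix) else X


def _ridge_solve(U: np.ndarray, s: np.ndarray, Vt: np.ndarray, yc: np.ndarray,
                 lam: float) -> np.ndarray:
    d = s / (s**2 + lam)
    return Vt.T @ (d * (U.T @ yc))


def _loo_error(U: np.ndarray, s: np.ndarray, yc: np.ndarray, lam: float) -> float:
    """Exact ridge leave-one-out mean squared prediction error.

    Uses the hat-diagonal identity e_loo,i = e_i / (1 - h_ii), with
    h_ii including the unpenalized intercept's 1/n contribution.
    """
    n = len(yc)
    shrink = s**2 / (s**2 + lam)
    fitted = U @ (shrink * (U.T @ yc))
    h = (U**2 @ shrink) + 1.0 / n
    resid = yc - fitted
    denom = np.clip(1.0 - h, 1e-12, None)
    return float(np.mean((resid / denom) ** 2))


def fit_ridge(
    X: PeakMotifMatrix | pd.DataFrame,
    y: pd.Series | np.ndarray,
    lam: float | str = "auto",
    comparison: str = "",
) -> RidgeFit:
    """Fit the motif-presence ridge model of per-peak log2FC.

    ``lam="auto"`` runs the semi-automatic Cule-De Iorio selection; a
    nonnegative float fixes the penalty (0 reduces to OLS and requires a
    full-rank design).
    """
    Xf = _as_frame(X)
    y = pd.Series(np.asarray(y, dtype=float), index=Xf.index) if not isinstance(y, pd.Series) else y.astype(float)
    if list(y.index) != list(Xf.index):
        y = y.reindex(Xf.index)
        if y.isna().any():
            raise ValueError("rows of X do not align with y")
    Xm = Xf.values.astype(float)
    n, p = Xm.shape
    if (Xm.std(axis=0) == 0).all():
        raise ValueError("all design columns are constant")
    col_means = Xm.mean(axis=0)
    Xc = Xm - col_means
    ybar = float(y.mean())
    yc = y.values - ybar

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0

    if isinstance(lam, str):
        if lam != "auto":
            raise ValueError(f"unknown lambda policy {lam!r}")
        lam = _cule_lambda(U, s, Vt, yc, rank)
    lam = float(lam)
    if lam < 0:
        raise ValueError("ridge parameter must be nonnegative")
    if lam == 0 and rank < p:
        raise ValueError("singular design with lambda = 0; use lambda > 0")

    beta = _ridge_solve(U, s, Vt, yc, lam) if lam > 0 else Vt.T @ ((U.T @ yc) / s)
    fitted = Xc @ beta + ybar
    resid = y.values - fitted
    df_model = float((s**2 / (s**2 + lam)).sum()) + 1.0
    sigma2 = float(resid @ resid) / max(n - df_model, 1.0)

    # Cule test: Var(beta) = sigma^2 V diag(s^2/(s^2+lam)^2) V'
    var_diag = (Vt.T**2) @ (s**2 / (s**2 + lam) ** 2)
    se = np.sqrt(sigma2 * var_diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.norm.sf(np.abs(z))

    groups = list(Xf.columns)
    return RidgeFit(
        comparison=comparison,
        lam=lam,
        coefficients=pd.Series(beta, index=groups),
        intercept=ybar - float(col_means @ beta),
        pvalues=pd.Series(pvals, index=groups),
        fitted=pd.Series(fitted, index=Xf.index),
        stderr=pd.Series(se, index=groups),
        sigma2=sigma2,
    )


def _cule_lambda(U: np.ndarray, s: np.ndarray, Vt: np.ndarray, yc: np.ndarray,
                 rank: int) -> float:
    """Semi-automatic ridge parameter: HKB generalized over PC counts.

    For each r = 1..rank, alpha_r holds the first r principal-component
    regression coefficients and sigma^2_r the residual variance of the
    r-component fit; the candidate lambda_r = r sigma^2_r / ||alpha_r||^2
    minimizing exact leave-one-out error is returned.
    """
    n = len(yc)
    uy = U.T @ yc
    alpha = np.where(s > 0, uy / np.where(s > 0, s, 1.0), 0.0)
    candidates: list[float] = []
    for r in range(1, min(rank, n - 1) + 1):
        fitted_r = U[:, :r] @ uy[:r]
        rss = float(((yc - fitted_r) ** 2).sum())
        dof = max(n - r - 1, 1)
        sigma2_r = rss / dof
        norm2 = float((alpha[:r] ** 2).sum())
        if norm2 > 0:
            candidates.append(r * sigma2_r / norm2)
    if not candidates:
        return 1.0
    errs = [_loo_error(U, s, yc, lam) for lam in candidates]
    return float(candidates[int(np.argmin(errs))])


def zeroed_out_fits(
    X: PeakMotifMatrix | pd.DataFrame,
    y: pd.Series | np.ndarray,
    lam: float | str = "auto",
    comparison: str = "",
    freeze_lambda: bool = False,
    full_fit: RidgeFit | None = None,
) -> dict[str, RidgeFit]:
    """Refit the model once per motif group with that column removed.

    By default the penalty is re-selected per reduced model under the
    same policy; ``freeze_lambda=True`` reuses the full model's value.
    """
    Xf = _as_frame(X)
    if freeze_lambda:
        if full_fit is None:
            full_fit = fit_ridge(Xf, y, lam, comparison)
        lam = full_fit.lam
    y_ser = y if isinstance(y, pd.Series) else pd.Series(np.asarray(y, float), index=Xf.index)
    out: dict[str, RidgeFit] = {}
    for col in Xf.columns:
        reduced = Xf.drop(columns=[col])
        if reduced.shape[1] == 0:
            ybar = float(y_ser.mean())
            out[col] = RidgeFit(
                comparison=comparison, lam=float(lam) if not isinstance(lam, str) else 0.0,
                coefficients=pd.Series(dtype=float), intercept=ybar,
                pvalues=pd.Series(dtype=float),
                fitted=pd.Series(ybar, index=Xf.index),
                stderr=pd.Series(dtype=float),
            )
        else:
            out[col] = fit_ridge(reduced, y_ser, lam, comparison=comparison)
    return out


def delta_cor(
    full: RidgeFit,
    zeroed: dict[str, RidgeFit],
    subset: list[str],
    y: pd.Series,
    X: PeakMotifMatrix | pd.DataFrame | None = None,
    subset_label: str = "",
) -> DeltaCorReport:
    """Leave-one-motif-out correlation drop on a peak subset.

    delta_cor(m) = cor(y_S, yhat_full_S) - cor(y_S, yhat_zeroed(m)_S)
    over subset S. Also reports, per motif, the mean observed log2FC of
    subset peaks containing that motif, and the subset-wide mean as the
    reference (the dashed line of the attribution plots).
    """
    subset = list(subset)
    if len(subset) < 3:
        raise ValueError("subset must contain at least 3 peaks")
    y_s = y.loc[subset].values
    if np.std(y_s) == 0:
        raise ValueError("zero variance of log2FC on subset; delta-cor undefined")
    f_s = full.fitted.loc[subset].values
    cor_full = float(np.corrcoef(y_s, f_s)[0, 1])
    rows = {}
    Xf = _as_frame(X) if X is not None else None
    for m, fit in zeroed.items():
        z_s = fit.fitted.loc[subset].values
        cor_z = float(np.corrcoef(y_s, z_s)[0, 1]) if np.std(z_s) > 0 else 0.0
        mean_fc = np.nan
        if Xf is not None and m in Xf.columns:
            present = Xf.loc[subset, m] == 1
            if present.any():
                mean_fc = float(y.loc[subset][present.values].mean())
        rows[m] = {
            "delta_cor": cor_full - cor_z,
            "subset_log2fc_mean": mean_fc,
            "full_model_coefficient": float(full.coefficients.get(m, np.nan)),
        }
    return DeltaCorReport(
        subset=subset_label,
        table=pd.DataFrame.from_dict(rows, orient="index"),
        reference_log2fc=float(np.mean(y_s)),
        cor_full=cor_full,
    )


def compare_models(svn: RidgeFit, svr: RidgeFit, alpha: float = 0.001) -> pd.DataFrame:
    """Paired per-motif coefficients and significance categories.

    Returns one row per shared motif group with beta and p for each model
    and the category in {neither, svn-only, svr-only, both} at strict
    p < alpha.
    """
    common = [g for g in svn.coefficients.index if g in set(svr.coefficients.index)]
    if not common:
        raise ValueError("models share no motif groups")
    calls = [
        SignificanceCall(g, bool(svn.pvalues[g] < alpha), bool(svr.pvalues[g] < alpha), alpha)
        for g in common
    ]
    return pd.DataFrame(
        {
            "group": common,
            "beta_svn": svn.coefficients.loc[common].values,
            "beta_svr": svr.coefficients.loc[common].values,
            "p_svn": svn.pvalues.loc[common].values,
            "p_svr": svr.pvalues.loc[common].values,
            "category": [c.category for c in calls],
        }
    ).set_index("group")


def shared_fc_concordance(
    diff: DifferentialTable, comparisons: tuple[str, str], alpha: float = 0.05
) -> tuple[float, int]:
    """Pearson correlation of log2FC between two comparisons on the peaks
    significantly differential (padj < alpha) in the first."""
    c1, c2 = comparisons
    mask = diff.padj(c1) < alpha
    x = diff.log2fc(c1)[mask]
    z = diff.log2fc(c2)[mask]
    if len(x) < 3:
        raise ValueError(f"only {len(x)} significant peaks in {c1}; need >= 3")
    r = float(np.corrcoef(x.values, z.values)[0, 1])
    return r, int(len(x))
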