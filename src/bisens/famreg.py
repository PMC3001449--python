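"""Per-family regression of structural divergence on sequence divergence.

The central model is the bilinear law

.. math::

    \\mathrm{RMSD} = b_0 + b_1 \\cdot \\mathrm{PNI} + b_2 \\cdot \\mathrm{SNG} + \\varepsilon

fitted by ordinary least squares within one protein family, with each
pairwise structure alignment as one observation.  The slope on PNI is the
family's *structural substitution sensitivity* (SSS): Angstrom of structural
change per percent of substituted sites.  The slope on SNG is its
*structural indel sensitivity* (SIDS): Angstrom per indel event per standard
sequence length.

Around the central fit the module provides the model-comparison machinery:
a PNI-only linear fit, a paraboloid (squared-term) extension, an additive
natural-cubic-spline surface, adjusted R-squared, adequacy ratios between
nested fits, first-order partial correlations of each predictor with RMSD,
and the variance inflation factor (VIF) of the two predictors.

The estimator :class:`SequenceStructureRegressor` follows the scikit-learn
protocol (``fit``/``predict``/``get_params``) so it composes with sklearn
pipelines and model selection; the module-level functions are thin wrappers
returning the domain dataclasses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import (
    InsufficientDataError,
    SingularFitError,
    UndefinedStatisticError,
    ValidationError,
)
from .pairstats import AlignmentStats

MODELS = ("linear_pni", "bilinear", "paraboloid", "cubic_spline")

#: families with fewer usable alignments than this are not fitted
DEFAULT_MIN_OBS = 10


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class FamilyFit:
    """Bilinear-regression output for one family."""

    family_id: str
    n_obs: int
    b0: float
    b1: float  # SSS, Angstrom per PNI percent
    b2: float  # SIDS, Angstrom per SNG unit
    se_b1: float
    se_b2: float
    p_b1: float
    p_b2: float
    R: float
    R2_adj: float
    p_model: float
    partial_r_pni: float
    partial_p_pni: float
    partial_r_sng: float
    partial_p_sng: float
    vif: float
    pni_sd: float
    mean_n_algn: float = math.nan
    mean_disulfide: float = math.nan
    gaps_per_unit_length: float = math.nan
    total_indels: float = math.nan
    note: str = ""

    @property
    def sss(self) -> float:
        return self.b1

    @property
    def sids(self) -> float:
        return self.b2


@dataclass
class ModelFit:
    """One model's fit summary, comparable across the nested family."""

    model: str
    R2: float
    R2_adj: float
    k: int  # number of independent variables (design columns less intercept)
    n: int
    fitted_values: np.ndarray = field(repr=False)
    coef: np.ndarray = field(default=None, repr=False)


@dataclass
class AdequacyResult:
    """Ratio of adjusted determination coefficients between nested fits."""

    pair: str
    r2: float


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------

def adjusted_r2(R2: float, n: int, k: int) -> float:
    """Adjust a coefficient of determination for sample size and model size.

    ``1 - (1 - R2) * (n - 1) / (n - k - 1)``; undefined when ``n <= k + 1``.
    """
    if n <= k + 1:
        raise UndefinedStatisticError(f"adjusted R2 undefined for n={n}, k={k}")
    if not 0.0 <= R2 <= 1.0 + 1e-12:
        raise ValidationError(f"R2={R2} outside [0, 1]")
    return 1.0 - (1.0 - R2) * (n - 1) / (n - k - 1)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("correlation undefined: zero-variance variable")
    return float(np.corrcoef(x, y)[0, 1])


def _partial_corr(x, y, z) -> tuple[float, float]:
    """First-order partial correlation r(x, y | z) and its two-sided p-value.

    Computed from the pairwise correlations; the p-value uses the t
    transform ``r * sqrt((n-3)/(1-r^2))`` with n - 3 degrees of freedom.
    """
    n = len(x)
    if n < 5:
        raise InsufficientDataError(f"partial correlation needs n >= 5, got {n}")
    rxy, rxz, ryz = _corr(x, y), _corr(x, z), _corr(y, z)
    if abs(ryz) >= 1.0 - 1e-12:
        # the conditioner explains the response exactly: nothing is left for
        # x to correlate with
        return 0.0, 1.0
    if abs(rxz) >= 1.0 - 1e-12:
        raise UndefinedStatisticError(
            "partial correlation undefined: predictor collinear with conditioner"
        )
    denom = math.sqrt((1 - rxz**2) * (1 - ryz**2))
    r = (rxy - rxz * ryz) / denom
    r = max(-1.0, min(1.0, r))
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), df)
    return r, float(p)


def vif_from_predictors(pni: np.ndarray, sng: np.ndarray) -> float:
    """Variance inflation factor of the two-predictor design, ``1/(1 - r^2)``.

    Returns ``inf`` when the predictors are perfectly collinear.
    """
    pni = np.asarray(pni, float)
    sng = np.asarray(sng, float)
    if len(pni) < 3:
        raise InsufficientDataError("VIF needs at least 3 observations")
    r = _corr(pni, sng)
    if abs(r) >= 1.0 - 1e-15:
        return math.inf
    return 1.0 / (1.0 - r**2)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class SequenceStructureRegressor(RegressorMixin, BaseEstimator):
    """OLS regression of structural divergence on sequence divergence.

    Parameters
    ----------
    model : {"bilinear", "linear_pni", "paraboloid", "cubic_spline"}
        Design of the mean surface.  ``bilinear`` regresses RMSD on PNI and
        SNG; ``linear_pni`` on PNI alone; ``paraboloid`` adds squared PNI
        and SNG terms; ``cubic_spline`` fits an additive natural-cubic-
        spline surface in PNI and SNG.
    spline_df : int
        Degrees of freedom per spline term (interior knots at within-family
        quantiles).
    min_obs : int
        Minimum observations required to fit.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray
        Slopes on the design columns (for ``bilinear``: ``[b1, b2]`` =
        [SSS, SIDS]).
    bse_, pvalues_ : ndarray
        Standard errors and two-sided t-test p-values of the slopes
        (t distribution with ``n - k - 1`` degrees of freedom).
    r2_, r2_adj_, r_ : float
        Determination coefficient, its size-adjusted form, and the multiple
        correlation coefficient (nonnegative root of R2).
    p_model_ : float
        Overall-fit p-value from the F test against the intercept-only model.
    vif_, partial_ : populated for the bilinear model only.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> pni = rng.uniform(20, 90, 200)
    >>> sng = rng.uniform(0, 8, 200)
    >>> rmsd = 0.5 + 0.02 * pni + 0.15 * sng + rng.normal(0, 0.1, 200)
    >>> reg = SequenceStructureRegressor().fit(np.column_stack([pni, sng]), rmsd)
    >>> reg.coef_.round(2)
    array([0.02, 0.15])
    """

    def __init__(
        self,
        model: str = "bilinear",
        spline_df: int = 4,
        min_obs: int = 4,
    ):
        self.model = model
        self.spline_df = spline_df
        self.min_obs = min_obs

    # -- design construction -------------------------------------------------
    def _design(self, X: np.ndarray):
        pni = X[:, 0]
        if self.model == "linear_pni":
            return np.column_stack([pni])
        sng = X[:, 1]
        if self.model == "bilinear":
            return np.column_stack([pni, sng])
        if self.model == "paraboloid":
            return np.column_stack([pni, sng, pni**2, sng**2])
        if self.model == "cubic_spline":
            # Natural cubic spline per predictor, knots at within-family
            # quantiles.  The raw cr() basis spans the constant, so each
            # block is centered and rotated onto its non-constant column
            # space (a sum-to-zero identifiability constraint, as in mgcv),
            # leaving exactly spline_df columns per predictor next to the
            # intercept.
            self._spline_info_ = []
            blocks = []
            for v in (pni, sng):
                dm = dmatrix(f"cr(v, df={self.spline_df + 1}) - 1", {"v": v})
                B = np.asarray(dm)
                colmeans = B.mean(axis=0)
                Bc = B - colmeans
                _, sv, Vt = np.linalg.svd(Bc, full_matrices=False)
                V = Vt[: self.spline_df].T
                self._spline_info_.append((dm.design_info, colmeans, V))
                blocks.append(Bc @ V)
            return np.hstack(blocks)
        raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")

    def _design_new(self, X: np.ndarray):
        if self.model == "cubic_spline":
            blocks = []
            for v, (dinfo, colmeans, V) in zip(
                (X[:, 0], X[:, 1]), self._spline_info_
            ):
                B = np.asarray(build_design_matrices([dinfo], {"v": v})[0])
                blocks.append((B - colmeans) @ V)
            return np.hstack(blocks)
        return self._design(X)

    # -- fitting -------------------------------------------------------------
    def fit(self, X, y):
        """Fit the model.  ``X`` has columns ``[pni, sng]`` (PNI alone is
        accepted for ``linear_pni``); ``y`` is RMSD in Angstrom."""
        X, y = check_X_y(X, y, ensure_min_samples=3)
        if X.shape[1] == 1:
            if self.model != "linear_pni":
                raise ValidationError(
                    f"model {self.model!r} needs both PNI and SNG columns"
                )
            X = np.column_stack([X[:, 0], np.zeros(len(X))])
        n = len(y)
        if n < self.min_obs:
            raise InsufficientDataError(
                f"{n} observations < min_obs={self.min_obs}"
            )
        Z = self._design(X)
        k = Z.shape[1]
        if n <= k + 1:
            raise InsufficientDataError(
                f"n={n} observations cannot support k={k} predictors"
            )
        if self.model in ("bilinear", "paraboloid"):
            # fail loudly on a collinear PNI/SNG design rather than returning
            # an arbitrary minimum-norm solution
            sd = X[:, :2].std(axis=0)
            if sd.min() > 0:
                r = _corr(X[:, 0], X[:, 1])
                if abs(r) >= 1.0 - 1e-12:
                    raise SingularFitError(
                        f"PNI and SNG perfectly collinear (r={r:.6f})",
                        predictor_correlation=r,
                    )
            elif self.model == "bilinear":
                raise SingularFitError(
                    "a predictor has zero variance", predictor_correlation=math.nan
                )

        A = np.column_stack([np.ones(n), Z])
        beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < A.shape[1]:
            raise SingularFitError(f"design matrix rank {rank} < {A.shape[1]}")
        fitted = A @ beta
        resid = y - fitted
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        if tss == 0:
            raise UndefinedStatisticError("response has zero variance")
        r2 = 1.0 - rss / tss
        r2 = min(max(r2, 0.0), 1.0)
        df_resid = n - k - 1
        sigma2 = rss / df_resid
        XtX_inv = np.linalg.inv(A.T @ A)
        bse = np.sqrt(np.diag(XtX_inv) * sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(bse > 0, beta / bse, np.inf)
        pvals = 2 * sps.t.sf(np.abs(tvals), df_resid)
        # overall F test against the intercept-only model
        if rss == 0:
            p_model = 0.0
        else:
            F = (r2 / k) / ((1 - r2) / df_resid) if r2 < 1 else math.inf
            p_model = float(sps.f.sf(F, k, df_resid))

        self.n_obs_ = n
        self.k_ = k
        self.df_resid_ = df_resid
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.bse_ = bse[1:]
        self.pvalues_ = pvals[1:]
        self.fitted_values_ = fitted
        self.r2_ = r2
        self.r2_adj_ = adjusted_r2(r2, n, k)
        self.r_ = math.sqrt(r2)
        self.p_model_ = p_model

        if self.model == "bilinear":
            pni, sng = X[:, 0], X[:, 1]
            self.vif_ = vif_from_predictors(pni, sng)
            self.partial_r_pni_, self.partial_p_pni_ = _partial_corr(pni, y, sng)
            self.partial_r_sng_, self.partial_p_sng_ = _partial_corr(sng, y, pni)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        if X.shape[1] == 1:
            X = np.column_stack([X[:, 0], np.zeros(len(X))])
        return self.intercept_ + self._design_new(X) @ self.coef_

    def model_fit(self) -> ModelFit:
        """The fit summarized for nested-model comparison."""
        check_is_fitted(self, "coef_")
        return ModelFit(
            model=self.model,
            R2=self.r2_,
            R2_adj=self.r2_adj_,
            k=self.k_,
            n=self.n_obs_,
            fitted_values=self.fitted_values_,
            coef=np.concatenate([[self.intercept_], self.coef_]),
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def _as_frame(stats) -> pd.DataFrame:
    if isinstance(stats, pd.DataFrame):
        return stats
    if len(stats) and isinstance(stats[0], AlignmentStats):
        return pd.DataFrame(
            {
                "pni": [s.pni for s in stats],
                "sng": [s.sng for s in stats],
                "rmsd": [s.rmsd for s in stats],
                "n_algn": [s.n_algn for s in stats],
                "n_gap": [s.n_gap for s in stats],
            }
        )
    return pd.DataFrame(stats)


def fit_model(stats, model: str, spline_df: int = 4) -> ModelFit:
    """Fit one of the comparison models to a family's alignment statistics."""
    df = _as_frame(stats)
    X = df[["pni", "sng"]].to_numpy(float)
    y = df["rmsd"].to_numpy(float)
    reg = SequenceStructureRegressor(model=model, spline_df=spline_df, min_obs=3)
    reg.fit(X, y)
    return reg.model_fit()


_SANCTIONED_PAIRS = {
    ("linear_pni", "bilinear"): "linear_vs_bilinear",
    ("bilinear", "paraboloid"): "bilinear_vs_paraboloid",
    ("bilinear", "cubic_spline"): "bilinear_vs_spline",
}


def adequacy(fit_small: ModelFit, fit_large: ModelFit) -> AdequacyResult:
    """Adequacy ratio of a smaller to a larger nested fit.

    ``r2 = R2_adj(small) / R2_adj(large)``; a value near 1 means the larger
    model adds nothing once its extra parameters are penalized, and values
    above 1 are legal (the larger model can lose on adjusted terms).
    """
    pair = _SANCTIONED_PAIRS.get((fit_small.model, fit_large.model))
    if pair is None:
        raise ValidationError(
            f"unsupported adequacy pair ({fit_small.model}, {fit_large.model})"
        )
    if fit_small.n != fit_large.n:
        raise ValidationError("adequacy requires fits on the same observations")
    if fit_large.R2_adj <= 0:
        raise UndefinedStatisticError(
            f"adequacy undefined: adjusted R2 of {fit_large.model} is "
            f"{fit_large.R2_adj:.4f} <= 0"
        )
    return AdequacyResult(pair=pair, r2=fit_small.R2_adj / fit_large.R2_adj)


def partial_correlations(stats) -> tuple[float, float, float, float]:
    """First-order partial correlations of each predictor with RMSD.

    Returns ``(r_pni_rmsd_given_sng, p, r_sng_rmsd_given_pni, p)``.
    """
    df = _as_frame(stats)
    pni = df["pni"].to_numpy(float)
    sng = df["sng"].to_numpy(float)
    rmsd = df["rmsd"].to_numpy(float)
    r1, p1 = _partial_corr(pni, rmsd, sng)
    r2, p2 = _partial_corr(sng, rmsd, pni)
    return r1, p1, r2, p2


def vif(stats) -> float:
    """Variance inflation factor of the family's PNI/SNG design."""
    df = _as_frame(stats)
    return vif_from_predictors(df["pni"].to_numpy(float), df["sng"].to_numpy(float))


def fit_bilinear(
    stats,
    family_id: str = "",
    min_obs: int = DEFAULT_MIN_OBS,
) -> FamilyFit:
    """Fit the bilinear law to one family and assemble the full summary.

    Requires at least ``min_obs`` alignments (default 10, the smallest
    family worth fitting); raises :class:`SingularFitError` when PNI and
    SNG are perfectly collinear.
    """
    df = _as_frame(stats)
    n = len(df)
    if n < min_obs:
        raise InsufficientDataError(
            f"family {family_id or '?'}: {n} observations < minimum {min_obs}"
        )
    X = df[["pni", "sng"]].to_numpy(float)
    y = df["rmsd"].to_numpy(float)
    reg = SequenceStructureRegressor(model="bilinear", min_obs=min_obs).fit(X, y)

    mean_n_algn = float(df["n_algn"].mean()) if "n_algn" in df else math.nan
    mean_disulfide = (
        float(df["avg_disulfide"].mean()) if "avg_disulfide" in df else math.nan
    )
    if {"n_gap", "n_algn"} <= set(df.columns):
        gaps_per_len = float((df["n_gap"] / df["n_algn"]).mean())
        total_indels = float(df["n_gap"].sum())
    else:
        gaps_per_len = total_indels = math.nan

    return FamilyFit(
        family_id=family_id,
        n_obs=n,
        b0=reg.intercept_,
        b1=float(reg.coef_[0]),
        b2=float(reg.coef_[1]),
        se_b1=float(reg.bse_[0]),
        se_b2=float(reg.bse_[1]),
        p_b1=float(reg.pvalues_[0]),
        p_b2=float(reg.pvalues_[1]),
        R=reg.r_,
        R2_adj=reg.r2_adj_,
        p_model=reg.p_model_,
        partial_r_pni=reg.partial_r_pni_,
        partial_p_pni=reg.partial_p_pni_,
        partial_r_sng=reg.partial_r_sng_,
        partial_p_sng=reg.partial_p_sng_,
        vif=reg.vif_,
        pni_sd=float(X[:, 0].std(ddof=1)),
        mean_n_algn=mean_n_algn,
        mean_disulfide=mean_disulfide,
        gaps_per_unit_length=gaps_per_len,
        total_indels=total_indels,
    )


def fit_families(
    stats_df: pd.DataFrame,
    min_obs: int = DEFAULT_MIN_OBS,
) -> pd.DataFrame:
    """Fit every family in a stacked statistics table.

    ``stats_df`` needs columns ``family_id, pni, sng, rmsd`` (plus optional
    ``n_algn, n_gap, avg_disulfide`` for the summary columns).  Families
    with too few alignments are skipped with a note; families whose SNG has
    zero variance (e.g. gapless families) fall back to the PNI-only linear
    fit, recorded in the ``note`` column, rather than aborting the cohort.
    """
    rows = []
    for fam, grp in stats_df.groupby("family_id", sort=True):
        try:
            fit = fit_bilinear(grp, family_id=str(fam), min_obs=min_obs)
        except InsufficientDataError:
            rows.append({"family_id": str(fam), "n_obs": len(grp), "note": "too_few_obs"})
            continue
        except SingularFitError:
            mf = fit_model(grp, "linear_pni")
            rows.append(
                {
                    "family_id": str(fam),
                    "n_obs": len(grp),
                    "b0": float(mf.coef[0]),
                    "b1": float(mf.coef[1]),
                    "R": math.sqrt(mf.R2),
                    "R2_adj": mf.R2_adj,
                    "note": "degenerate_sng_linear_fallback",
                }
            )
            continue
        row = {f.name: getattr(fit, f.name) for f in dc_fields(fit)}
        rows.append(row)
    out = pd.DataFrame(rows)
    if "note" in out.columns:
        out["note"] = out["note"].fillna("")
    return out


def adequacy_by_family(
    stats_df: pd.DataFrame,
    min_obs: int = DEFAULT_MIN_OBS,
    spline_df: int = 4,
) -> pd.DataFrame:
    """Adequacy ratios of the three sanctioned model pairs, per family.

    Families that cannot support the largest model's degrees of freedom, or
    whose larger-model adjusted R2 is nonpositive, get a flagged row and
    are meant to be excluded from cohort medians.
    """
    rows = []
    for fam, grp in stats_df.groupby("family_id", sort=True):
        if len(grp) < max(min_obs, 2 * spline_df + 2):
            rows.append({"family_id": str(fam), "pair": "all", "r2": math.nan,
                         "flag": "too_few_obs"})
            continue
        try:
            fits = {m: fit_model(grp, m, spline_df=spline_df) for m in MODELS}
            for small, large in (
                ("linear_pni", "bilinear"),
                ("bilinear", "paraboloid"),
                ("bilinear", "cubic_spline"),
            ):
                res = adequacy(fits[small], fits[large])
                rows.append({"family_id": str(fam), "pair": res.pair, "r2": res.r2,
                             "flag": ""})
        except (UndefinedStatisticError, SingularFitError, InsufficientDataError) as exc:
            rows.append({"family_id": str(fam), "pair": "all", "r2": math.nan,
                         "flag": type(exc).__name__})
    return pd.DataFrame(rows)
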