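"""Covariate-adjusted differential expression with moderated t-statistics.

Per feature, expression is regressed on an intercept, a two-group contrast
indicator and the adjustment covariates (age, gender, optional extras) by
ordinary least squares.  The per-feature residual variances are then
shrunk toward a common prior estimated by empirical Bayes: the gene-wise
variances are modelled as scaled inverse-chi-square draws with prior
degrees of freedom d0 and prior scale s0^2, estimated by matching the mean
and variance of log(sigma_hat^2) to the log scaled-F distribution.  The
moderated t-statistic uses the posterior variance

    s_tilde_g^2 = (d0 * s0^2 + d_g * sigma_hat_g^2) / (d0 + d_g)

with d0 + d_g degrees of freedom.  Significance is called either on
Benjamini-Hochberg adjusted p-values (default, alpha = 0.01) or on nominal
p-values for low-powered validation cohorts.

The module exposes both the individual operations and a statsmodels-style
:class:`DifferentialExpression` model whose :meth:`~DifferentialExpression.fit`
returns a :class:`DEResults` with the DEG table and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionDataset, FeatureAnnotation, SampleInfo

__all__ = [
    "DesignMatrix",
    "GeneModelFit",
    "ModerationParams",
    "build_design",
    "fit_gene_models",
    "eb_moderate",
    "bh_adjust",
    "call_degs",
    "DifferentialExpression",
    "DEResults",
]


@dataclass
class DesignMatrix:
    """Sample x term design for a two-group contrast."""

    matrix: np.ndarray
    terms: list[str]
    sample_ids: list[str]
    contrast: tuple[str, str]

    @property
    def contrast_index(self) -> int:
        return self.terms.index("group")


@dataclass
class GeneModelFit:
    """Per-feature least-squares results for the contrast coefficient."""

    feature_ids: list[str]
    coef: np.ndarray          # contrast coefficient, log2 units
    sigma2: np.ndarray        # residual variance RSS / d
    df_resid: float           # d_g = n - rank(design)
    v_unscaled: float         # unscaled variance of the contrast coefficient


@dataclass
class ModerationParams:
    """Empirical-Bayes moderation output."""

    feature_ids: list[str]
    coef: np.ndarray
    d0: float
    s0_sq: float
    s_tilde_sq: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_total: float


def build_design(
    info: list[SampleInfo],
    contrast: tuple[str, str],
    covariates: list[str] = ["age", "gender"],
) -> tuple[DesignMatrix, list[SampleInfo]]:
    """Design matrix for a pairwise group contrast.

    Only samples in the two contrast groups are retained; the ``group``
    indicator is 1 for the first-named group.  Covariate columns that are
    constant in the selected samples (e.g. gender in an all-female subset)
    are dropped with a warning.
    """
    g1, g2 = contrast
    if g1 == g2:
        raise ValueError("contrast groups must differ")
    selected = [s for s in info if s.group in (g1, g2)]
    for g in contrast:
        if not any(s.group == g for s in selected):
            raise ValueError(f"contrast group {g!r} has no samples")
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(selected)),
        "group": np.array([1.0 if s.group == g1 else 0.0 for s in selected]),
    }
    for name in covariates:
        if name == "age":
            cols[name] = np.array([s.age for s in selected])
        elif name == "gender":
            cols[name] = np.array([s.gender_indicator for s in selected])
        else:
            cols[name] = np.array([s.extra_covariates[name] for s in selected])
    for name in list(cols):
        if name in ("intercept", "group"):
            continue
        if np.ptp(cols[name]) == 0.0:
            warnings.warn(f"covariate {name!r} is constant; dropping it from the design", stacklevel=2)
            del cols[name]
    X = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after constant-column removal")
    return (
        DesignMatrix(matrix=X, terms=list(cols), sample_ids=[s.sample_id for s in selected], contrast=(g1, g2)),
        selected,
    )


def fit_gene_models(ds: ExpressionDataset, design: DesignMatrix) -> GeneModelFit:
    """Least-squares fit of every feature on the design matrix."""
    sub = ds.subset_samples(design.sample_ids)
    X = design.matrix
    n, k = X.shape
    d = n - k
    if d <= 0:
        raise ValueError("no residual degrees of freedom (n <= rank of design)")
    pinv = np.linalg.pinv(X)
    B = sub.matrix @ pinv.T
    resid = sub.matrix - B @ X.T
    rss = (resid ** 2).sum(axis=1)
    sigma2 = rss / d
    j = design.contrast_index
    xtx_inv = np.linalg.inv(X.T @ X)
    return GeneModelFit(
        feature_ids=list(sub.feature_ids),
        coef=B[:, j],
        sigma2=sigma2,
        df_resid=float(d),
        v_unscaled=float(xtx_inv[j, j]),
    )


def _trigamma_inverse(x: float, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < tol:
            break
    return float(y)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log sigma_hat^2.

    Under the hierarchical model, sigma_hat^2 / s0^2 follows a scaled F
    distribution; matching the mean and variance of log(sigma_hat^2)
    (via digamma/trigamma identities) gives d0 from a trigamma equation
    and s0^2 from the corrected mean.  If the observed variance of
    log(sigma_hat^2) falls at or below the value implied by d0 = infinity,
    the prior df is infinite and all variances are shrunk fully to s0^2.
    """
    ok = sigma2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive residual variances")
    z = np.log(sigma2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # at or below the pure-sampling variance of log(sigma_hat^2): the
        # prior is effectively a point mass, pool fully
        d0 = np.inf
        s0_sq = float(np.mean(sigma2[ok]))
    return float(d0), float(s0_sq)


def eb_moderate(fits: GeneModelFit, prior_df: float | None = None) -> ModerationParams:
    """Shrink gene-wise variances and compute moderated t and p.

    ``prior_df`` overrides the estimated d0 (0 recovers ordinary t-tests;
    infinity pools fully).  Features with zero residual variance are
    excluded from hyperparameter estimation but still moderated.
    """
    G = len(fits.feature_ids)
    if G < 2:
        raise ValueError("need at least 2 features")
    if G < 10:
        warnings.warn("fewer than 10 features: hyperparameter estimates will be unstable", stacklevel=2)
    d = fits.df_resid
    if prior_df is None:
        d0, s0_sq = estimate_prior(fits.sigma2, d)
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_prior(fits.sigma2, d) if d0 != 0 else (None, float(np.mean(fits.sigma2)))
    if np.isinf(d0):
        s_tilde_sq = np.full(G, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s_tilde_sq = fits.sigma2.copy()
        df_total = d
    else:
        s_tilde_sq = (d0 * s0_sq + d * fits.sigma2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s_tilde_sq * fits.v_unscaled)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fits.coef / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModerationParams(
        feature_ids=list(fits.feature_ids),
        coef=fits.coef.copy(),
        d0=float(d0),
        s0_sq=float(s0_sq),
        s_tilde_sq=s_tilde_sq,
        t=t,
        p=p,
        df_total=float(df_total),
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    mod: ModerationParams,
    mode: str = "bh",
    alpha: float = 0.01,
    annotation: list[FeatureAnnotation] | None = None,
) -> pd.DataFrame:
    """Assemble the DEG table and flag significance.

    ``bh`` mode flags BH.pval < alpha; ``nominal`` mode flags p < alpha
    (the fallback used when no feature survives multiple testing).
    FC = 2^logFC, so FC < 1 marks down-regulation.
    """
    if mode not in ("bh", "nominal"):
        raise ValueError(f"unknown significance mode {mode!r}")
    bh = bh_adjust(mod.p)
    gene_of = {a.feature_id: a.gene_id for a in annotation} if annotation else {}
    direction = np.where(mod.coef > 0, "up", "down")
    significant = (bh < alpha) if mode == "bh" else (mod.p < alpha)
    return pd.DataFrame(
        {
            "feature_id": mod.feature_ids,
            "gene_id": [gene_of.get(f, "") for f in mod.feature_ids],
            "logFC": mod.coef,
            "FC": 2.0 ** mod.coef,
            "t": mod.t,
            "p": mod.p,
            "BH.pval": bh,
            "direction": direction,
            "significant": significant,
        }
    )


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"feature_id": str, "gene_id": str})


class DifferentialExpression:
    """Moderated differential-expression model for one group contrast.

    Parameters
    ----------
    dataset : ExpressionDataset
        log2 expression (already normalised / batch-adjusted).
    sample_info : list of SampleInfo
        Metadata covering the dataset's samples.
    contrast : (str, str)
        Groups to compare; the coefficient is first minus second.
    covariates : list of str
        Adjustment covariates (default age and gender).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        sample_info: list[SampleInfo],
        contrast: tuple[str, str] = ("AD", "CTL"),
        covariates: list[str] = ["age", "gender"],
        annotation: list[FeatureAnnotation] | None = None,
    ) -> None:
        self.dataset = dataset
        self.sample_info = sample_info
        self.contrast = tuple(contrast)
        self.covariates = list(covariates)
        self.annotation = annotation
        by_id = {s.sample_id: s for s in sample_info}
        missing = [s for s in dataset.sample_ids if s not in by_id]
        if missing:
            raise ValueError(f"metadata missing for sample(s): {missing[:5]}")
        in_ds = set(dataset.sample_ids)
        self.design, self._selected = build_design(
            [by_id[s] for s in dataset.sample_ids if s in in_ds], self.contrast, self.covariates
        )

    def fit(self, mode: str = "bh", alpha: float = 0.01, prior_df: float | None = None) -> "DEResults":
        fits = fit_gene_models(self.dataset, self.design)
        mod = eb_moderate(fits, prior_df=prior_df)
        table = call_degs(mod, mode=mode, alpha=alpha, annotation=self.annotation)
        return DEResults(model=self, fits=fits, moderation=mod, table=table, mode=mode, alpha=alpha)


@dataclass
class DEResults:
    """Fitted differential-expression results."""

    model: DifferentialExpression
    fits: GeneModelFit
    moderation: ModerationParams
    table: pd.DataFrame
    mode: str
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def significant_features(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "feature_id"])

    def top(self, n: int = 20) -> pd.DataFrame:
        return self.table.sort_values("p").head(n)

    def summary(self) -> str:
        g1, g2 = self.model.contrast
        up = int((self.table["significant"] & (self.table["direction"] == "up")).sum())
        down = self.n_significant - up
        lines = [
            "Differential expression (moderated t)",
            "=" * 46,
            f"Contrast:        {g1} vs {g2}",
            f"Covariates:      {', '.join(self.model.covariates) or 'none'}",
            f"Samples:         {len(self.model.design.sample_ids)}",
            f"Features:        {len(self.table)}",
            f"Residual df:     {self.fits.df_resid:.0f}",
            f"Prior df (d0):   {self.moderation.d0:.4g}",
            f"Prior var (s0^2):{self.moderation.s0_sq: .4g}",
            f"Significance:    {self.mode} < {self.alpha:g}",
            f"Significant:     {self.n_significant} ({up} up, {down} down)",
        ]
        return "\n".join(lines)
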