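"""Cohort merging, covariate residualisation, and probeset-to-gene collapsing.

The biomarker workflow starts from two already-normalised cohorts measured
on overlapping probesets.  This module

* drops features without a gene annotation,
* merges two cohorts on their common features with an explicit, logged
  batch-adjustment method (per-batch mean centering by default, or a
  ComBat-style empirical-Bayes location/scale adjustment),
* removes age and gender effects feature-by-feature with a Huber robust
  regression and centres/scales the residuals to mean 0, sd 1 (the input
  the machine-learning stage trains on), and
* collapses probeset-level differential-expression tables to unique genes
  (representative probeset = smallest unadjusted p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, FeatureAnnotation, SampleInfo

HUBER_C = 1.345            # 95%-efficiency Huber tuning constant
MAD_SCALE = 1.4826         # consistency factor for the Gaussian
MAX_IRLS_ITER = 50
IRLS_TOL = 1e-8


@dataclass
class MergedDataset:
    """Merged expression data plus per-sample batch labels."""

    dataset: ExpressionDataset
    batch_labels: list[str]
    method: str

    def __post_init__(self) -> None:
        if len(self.batch_labels) != self.dataset.n_samples:
            raise ValueError("batch labels must align with samples")


@dataclass
class ResidualMatrix:
    """Centred/scaled residuals with per-feature fit diagnostics."""

    matrix: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    converged: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    iterations: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    constant: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.feature_ids, columns=self.sample_ids)

    def to_tsv(self, path, labels: list[str] | None = None) -> None:
        """Write features x samples residuals as TSV; an optional label row
        (e.g. diagnosis per sample) is appended for ML hand-off files."""
        df = self.to_frame()
        df.index.name = "feature_id"
        if labels is not None:
            if len(labels) != len(self.sample_ids):
                raise ValueError("labels must align with samples")
            df = pd.concat([df, pd.DataFrame([labels], index=["label"], columns=self.sample_ids)])
        df.to_csv(path, sep="\t")


def filter_annotated(ds: ExpressionDataset, annotation: list[FeatureAnnotation]) -> ExpressionDataset:
    """Keep only features whose annotation has a non-empty gene id.

    Features missing from the annotation table are treated as unannotated.
    Order is preserved.  An empty result is allowed (with a warning).
    """
    annotated = {a.feature_id for a in annotation if a.gene_id}
    keep = [f for f in ds.feature_ids if f in annotated]
    if not keep:
        warnings.warn("no annotated features remain after filtering", stacklevel=2)
        return ExpressionDataset(np.empty((0, ds.n_samples)), [], list(ds.sample_ids), ds.dataset_label)
    return ds.subset_features(keep)


def _batch_mean_center(matrix: np.ndarray, batch_idx: list[np.ndarray]) -> np.ndarray:
    out = matrix.copy()
    for idx in batch_idx:
        out[:, idx] -= out[:, idx].mean(axis=1, keepdims=True)
    return out


def _eb_location_scale(matrix: np.ndarray, batch_idx: list[np.ndarray]) -> np.ndarray:
    """ComBat-style parametric empirical-Bayes location/scale adjustment.

    Features are standardised against the grand mean and pooled variance;
    per-batch location (gamma) and scale (delta^2) parameters are then
    shrunk toward across-feature priors (normal for gamma, inverse-gamma
    for delta^2, both fit by moments) via the usual EB fixed-point
    iteration before the batch effect is removed.
    """
    G = matrix.shape[0]
    n_b = np.array([len(idx) for idx in batch_idx])
    n = n_b.sum()
    B = len(batch_idx)
    mu_gb = np.stack([matrix[:, idx].mean(axis=1) for idx in batch_idx], axis=1)  # G x B
    grand = mu_gb @ (n_b / n)
    pooled = np.zeros(G)
    for b, idx in enumerate(batch_idx):
        pooled += ((matrix[:, idx] - grand[:, None]) ** 2).sum(axis=1)
    pooled /= n
    pooled = np.maximum(pooled, 1e-12)
    s = np.sqrt(pooled)
    z = (matrix - grand[:, None]) / s[:, None]

    out = np.empty_like(z)
    for b, idx in enumerate(batch_idx):
        zb = z[:, idx]
        gamma_hat = zb.mean(axis=1)
        delta2_hat = zb.var(axis=1, ddof=1) if len(idx) > 1 else np.ones(G)
        # moment-matched priors across features
        g_bar, t2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        d_bar, s2 = delta2_hat.mean(), delta2_hat.var(ddof=1)
        lam = (d_bar * d_bar + 2.0 * s2) / s2 if s2 > 0 else np.inf
        theta = (d_bar ** 3 + d_bar * s2) / s2 if s2 > 0 else d_bar
        m = len(idx)
        gamma_star, delta2_star = gamma_hat.copy(), delta2_hat.copy()
        for _ in range(100):
            if np.isfinite(lam) and t2 > 0:
                g_new = (m * t2 * gamma_hat + delta2_star * g_bar) / (m * t2 + delta2_star)
            else:
                g_new = np.full(G, g_bar) if t2 == 0 else gamma_hat
            ssq = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            if np.isfinite(lam):
                d_new = (theta + 0.5 * ssq) / (m / 2.0 + lam - 1.0)
            else:
                d_new = delta2_hat
            if max(np.abs(g_new - gamma_star).max(), np.abs(d_new - delta2_star).max()) < 1e-6:
                gamma_star, delta2_star = g_new, d_new
                break
            gamma_star, delta2_star = g_new, d_new
        out[:, idx] = (zb - gamma_star[:, None]) / np.sqrt(np.maximum(delta2_star, 1e-12))[:, None]
    return out * s[:, None] + grand[:, None]


def merge_datasets(
    ds_a: ExpressionDataset,
    ds_b: ExpressionDataset,
    method: str = "batch_mean_center",
) -> MergedDataset:
    """Merge two cohorts on their common features, removing batch effects.

    ``batch_mean_center`` subtracts each feature's per-batch mean;
    ``eb_location_scale`` additionally shrinks per-batch feature variances
    toward a pooled prior (ComBat-style) before standardising.
    """
    if method not in ("batch_mean_center", "eb_location_scale"):
        raise ValueError(f"unknown merge method {method!r}")
    common = [f for f in ds_a.feature_ids if f in set(ds_b.feature_ids)]
    if len(common) < 2:
        raise ValueError("fewer than 2 common features between datasets")
    dup = set(ds_a.sample_ids) & set(ds_b.sample_ids)
    if dup:
        raise ValueError(f"duplicated sample id(s) across datasets: {sorted(dup)[:5]}")
    sub_a, sub_b = ds_a.subset_features(common), ds_b.subset_features(common)
    matrix = np.hstack([sub_a.matrix, sub_b.matrix])
    n_a = sub_a.n_samples
    batch_idx = [np.arange(n_a), np.arange(n_a, n_a + sub_b.n_samples)]
    if method == "batch_mean_center":
        adjusted = _batch_mean_center(matrix, batch_idx)
    else:
        adjusted = _eb_location_scale(matrix, batch_idx)
    label_a = ds_a.dataset_label or "batchA"
    label_b = ds_b.dataset_label or "batchB"
    merged = ExpressionDataset(
        adjusted, common, sub_a.sample_ids + sub_b.sample_ids, dataset_label="merged"
    )
    return MergedDataset(
        dataset=merged,
        batch_labels=[label_a] * n_a + [label_b] * sub_b.n_samples,
        method=method,
    )


def _covariate_matrix(info: list[SampleInfo], covariates: list[str]) -> np.ndarray:
    cols = [np.ones(len(info))]
    for name in covariates:
        if name == "age":
            cols.append(np.array([s.age for s in info]))
        elif name == "gender":
            cols.append(np.array([s.gender_indicator for s in info]))
        else:
            try:
                cols.append(np.array([s.extra_covariates[name] for s in info]))
            except KeyError as exc:
                raise ValueError(f"covariate {name!r} missing for sample {exc.args[0]!r}") from None
    return np.column_stack(cols)


def huber_residualize(
    ds: ExpressionDataset,
    info: list[SampleInfo],
    covariates: list[str] = ["age", "gender"],
) -> ResidualMatrix:
    """Remove covariate effects per feature by Huber M-estimation, then
    centre and scale the residuals to mean 0, sd 1.

    Per feature the linear model expression ~ intercept + covariates is fit
    by IRLS with the Huber psi (c = 1.345 in residual-scale units), the
    scale re-estimated each iteration as 1.4826 * median(|residual|), at
    most 50 iterations, convergence when the largest coefficient change
    drops below 1e-8.  Non-converging features fall back to the
    least-squares fit (flagged, with a warning); constant features get
    all-zero residuals and are flagged so downstream stages can drop them.
    """
    order = {s.sample_id: s for s in info}
    missing = [s for s in ds.sample_ids if s not in order]
    if missing:
        raise ValueError(f"sample metadata missing for: {missing[:5]}")
    recs = [order[s] for s in ds.sample_ids]
    X = _covariate_matrix(recs, list(covariates))
    n, k = X.shape
    if n <= k:
        raise ValueError("need more samples than covariates + intercept")
    Y = ds.matrix
    G = Y.shape[0]

    constant = Y.std(axis=1) == 0.0
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T  # G x k, OLS start
    beta_ols = beta.copy()
    active = ~constant
    iterations = np.zeros(G, dtype=int)
    converged = constant.copy()  # constant features trivially "done"
    for it in range(1, MAX_IRLS_ITER + 1):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        resid = Y[idx] - beta[idx] @ X.T
        scale = MAD_SCALE * np.median(np.abs(resid), axis=1)
        scale = np.maximum(scale, 1e-12)
        u = np.abs(resid) / (HUBER_C * scale[:, None])
        w = np.minimum(1.0, 1.0 / np.maximum(u, 1e-300))
        A = np.einsum("ni,gn,nj->gij", X, w, X)
        b = np.einsum("ni,gn->gi", X, w * Y[idx])
        new_beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        delta = np.abs(new_beta - beta[idx]).max(axis=1)
        beta[idx] = new_beta
        iterations[idx] = it
        done = delta < IRLS_TOL
        converged[idx[done]] = True
        active[idx[done]] = False
    if active.any():
        warnings.warn(
            f"{int(active.sum())} feature(s) did not converge in {MAX_IRLS_ITER} IRLS "
            "iterations; falling back to least squares",
            stacklevel=2,
        )
        beta[active] = beta_ols[active]

    resid = Y - beta @ X.T
    resid[constant] = 0.0
    centred = resid - resid.mean(axis=1, keepdims=True)
    sd = centred.std(axis=1, ddof=1)
    nz = (~constant) & (sd > 0)
    centred[nz] /= sd[nz, None]
    return ResidualMatrix(
        matrix=centred,
        feature_ids=list(ds.feature_ids),
        sample_ids=list(ds.sample_ids),
        converged=converged,
        iterations=iterations,
        constant=constant,
    )


def collapse_to_genes(table: pd.DataFrame, annotation: list[FeatureAnnotation]) -> pd.DataFrame:
    """Collapse a probeset-level DEG table to unique genes.

    Representative probeset = smallest unadjusted p per gene; a gene is
    significant iff any of its probesets is; direction comes from the
    representative.  Every feature in the table must be annotated.
    """
    gene_of = {a.feature_id: a.gene_id for a in annotation if a.gene_id}
    unannot = [f for f in table["feature_id"] if f not in gene_of]
    if unannot:
        raise ValueError(f"unannotated feature(s) in DEG table: {unannot[:5]}")
    tab = table.copy()
    tab["gene_id"] = [gene_of[f] for f in tab["feature_id"]]
    rows = []
    for gid, grp in tab.groupby("gene_id", sort=False):
        rep = grp.loc[grp["p"].idxmin()].copy()
        rep["significant"] = bool(grp["significant"].any())
        rows.append(rep)
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out
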