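"""Biomarker panel discovery: repeated-CV LASSO selection plus a voting ensemble.

The procedure mirrors blood-transcriptomic biomarker practice:

1. Starting from the full residualised feature pool, an L1-penalised
   logistic regression is tuned by stratified 5-fold cross-validation
   (penalty chosen to maximise mean out-of-fold ROC AUC over a geometric
   grid of 100 lambda values spanning 4 decades below lambda_max), and the
   whole tuning is repeated many times with fresh fold assignments.  Each
   repeat contributes one candidate feature set: the nonzero-coefficient
   support of the refit at the chosen penalty.
2. A panel is selected among the candidates by best CV AUC (or highest
   selection frequency), skipping candidates with fewer than two features
   in favour of the next-ranked candidate.
3. Three classifiers are trained on the panel - an RBF-kernel SVM (C = 1,
   kernel width 1/(p * Var(X))), a 500-tree random forest (sqrt(p)
   features per split), and an L2 (ridge) logistic regression with CV-tuned
   penalty and a training-derived decision cutoff - and combined by
   majority vote.
4. Performance is reported as per-model ROC AUC (rank statistic, ties
   counted half), the vote AUC (arithmetic mean of the three AUCs), AUPR,
   and vote accuracy / sensitivity / specificity with an exact binomial CI.

The cross-dataset protocol residualises two cohorts independently, trains
on one and tests on the other, then swaps, and also reports the fraction
of MCI samples the AD-vs-CTL models call AD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatypes import ExpressionDataset, SampleInfo
from .preprocess import huber_residualize

__all__ = [
    "auc_score",
    "aupr_score",
    "optimal_cutoff",
    "CandidatePanel",
    "BiomarkerPanel",
    "cv_lasso_select",
    "select_panel",
    "EnsembleModel",
    "train_ensemble",
    "predict_vote",
    "EvaluationReport",
    "evaluate",
    "vote_auc",
    "cross_dataset_protocol",
    "PanelDiscovery",
    "PanelDiscoveryResults",
]

N_LAMBDA = 100
LAMBDA_DECADES = 4.0
RIDGE_C_GRID = np.geomspace(1e-3, 1e3, 13)


# ---------------------------------------------------------------------------
# metrics


def auc_score(scores, labels) -> float:
    """ROC AUC as the rank (Mann-Whitney) statistic; ties count half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def aupr_score(scores, labels) -> float:
    """Area under the precision-recall curve by step-wise integration.

    Thresholds descend through the unique scores; the area accumulates
    precision * (recall step), the standard average-precision estimator.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPR undefined: no positive labels")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate only at threshold boundaries (last index of each tied block)
    boundary = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[boundary], fp[boundary]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum(precision * (recall - prev_recall)))


def optimal_cutoff(scores, labels) -> tuple[float, bool]:
    """Training-derived decision cutoff for a score-based classifier.

    Candidate cutoffs are the midpoints between adjacent sorted unique
    scores; a sample is called positive when score >= cutoff.  The cutoff
    maximising accuracy wins; ties break by larger Youden's J
    (sensitivity + specificity - 1), then by the smaller cutoff.  Constant
    scores return that value with the degenerate flag set.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0]), True
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best = None
    for cut in mids:
        pred = scores >= cut
        tp = int((pred & (labels == 1)).sum())
        tn = int((~pred & (labels == 0)).sum())
        acc = (tp + tn) / len(labels)
        j = tp / n_pos + tn / n_neg - 1.0
        key = (acc, j, -cut)
        if best is None or key > best[0]:
            best = (key, float(cut))
    return best[1], False


def score_average_auc(scores_per_model: dict, labels) -> float:
    """Alternative aggregation: AUC of the mean of the three model scores
    (each rank-normalised first so the scales are commensurate).  Not the
    default — the reported vote AUC averages the AUCs, not the scores."""
    mats = [stats.rankdata(np.asarray(s, dtype=float)) for s in scores_per_model.values()]
    return auc_score(np.mean(mats, axis=0), labels)


def vote_auc(aucs) -> float:
    """Vote AUC: the arithmetic mean of the three per-model AUCs, at 3 dp."""
    aucs = tuple(float(a) for a in aucs)
    if len(aucs) != 3:
        raise ValueError("vote_auc expects exactly three AUC values")
    if any(not 0.0 <= a <= 1.0 for a in aucs):
        raise ValueError("AUC values must lie in [0, 1]")
    return round(sum(aucs) / 3.0, 3)


# ---------------------------------------------------------------------------
# LASSO feature selection


@dataclass
class CandidatePanel:
    """One candidate feature set aggregated over LASSO repeats."""

    features: frozenset[str]
    cv_auc: float          # mean CV AUC over the repeats selecting this set
    frequency: int         # number of repeats selecting exactly this set
    lam: float             # penalty that produced it (first occurrence)

    @property
    def size(self) -> int:
        return len(self.features)


@dataclass
class BiomarkerPanel:
    """The selected panel with its selection provenance."""

    features: list[str]
    rule: str
    cv_auc: float
    frequency: int
    seed: int


def _lambda_grid(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    ybar = y.mean()
    lam_max = np.abs(X.T @ (y - ybar)).max() / len(y)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 10 ** (-LAMBDA_DECADES), N_LAMBDA)


def _l1_fit(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    C = 1.0 / (len(y) * lam)
    clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=C, max_iter=1000, tol=1e-4)
    clf.fit(X, y)
    return clf


def cv_lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
) -> list[CandidatePanel]:
    """Repeated cross-validated LASSO logistic feature selection.

    Per repeat: stratified ``folds``-fold assignment; the lambda grid is
    scored by mean out-of-fold AUC; the model is refit on the full
    training data at the winning lambda and its nonzero-coefficient
    support recorded.  Identical supports are aggregated with a selection
    frequency and mean CV AUC.  Candidates are returned sorted by
    frequency, descending.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(y) < 2 * folds:
        raise ValueError("need at least 2 samples per fold")
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature column(s)", stacklevel=2)
        X = X[:, keep]
        feature_ids = [f for f, k in zip(feature_ids, keep) if k]
    grid = _lambda_grid(X, y)
    agg: dict[frozenset, dict] = {}
    child_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(child_seeds[r]))
        fold_aucs = np.zeros((folds, len(grid)))
        for fi, (tr, te) in enumerate(skf.split(X, y)):
            for li, lam in enumerate(grid):
                clf = _l1_fit(X[tr], y[tr], lam)
                fold_aucs[fi, li] = auc_score(clf.decision_function(X[te]), y[te])
        mean_auc = fold_aucs.mean(axis=0)
        best_li = int(np.argmax(mean_auc))  # ties -> largest lambda (sparser)
        clf = _l1_fit(X, y, grid[best_li])
        support = frozenset(np.array(feature_ids)[np.abs(clf.coef_[0]) > 0])
        rec = agg.setdefault(support, {"aucs": [], "lam": float(grid[best_li])})
        rec["aucs"].append(float(mean_auc[best_li]))
    candidates = [
        CandidatePanel(
            features=fs,
            cv_auc=float(np.mean(rec["aucs"])),
            frequency=len(rec["aucs"]),
            lam=rec["lam"],
        )
        for fs, rec in agg.items()
    ]
    candidates.sort(key=lambda c: (-c.frequency, -c.cv_auc, c.size))
    return candidates


def select_panel(candidates: list[CandidatePanel], rule: str = "best_auc", seed: int = 0) -> BiomarkerPanel:
    """Choose the biomarker panel from the candidate list.

    ``best_auc`` ranks by mean CV AUC (ties: higher frequency, then
    smaller panel); ``most_frequent`` ranks by selection frequency (ties:
    higher AUC).  Candidates with fewer than two features are skipped in
    favour of the next-ranked candidate of size >= 2 (the sub-optimal-AUC
    fallback).
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if rule == "best_auc":
        ranked = sorted(candidates, key=lambda c: (-c.cv_auc, -c.frequency, c.size))
    elif rule == "most_frequent":
        ranked = sorted(candidates, key=lambda c: (-c.frequency, -c.cv_auc, c.size))
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    for cand in ranked:
        if cand.size >= 2:
            return BiomarkerPanel(
                features=sorted(cand.features),
                rule=rule,
                cv_auc=cand.cv_auc,
                frequency=cand.frequency,
                seed=seed,
            )
    raise ValueError("no candidate panel with at least two features")


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class EnsembleModel:
    """SVM + random-forest + ridge-logistic triple with a voting rule."""

    svm: SVC
    rf: RandomForestClassifier
    ridge: LogisticRegression
    ridge_cutoff: float
    panel: list[str]
    seed: int
    ridge_c: float
    cutoff_degenerate: bool = False


def train_ensemble(
    X_panel: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    panel: list[str] | None = None,
    class_weight: str | None = None,
) -> EnsembleModel:
    """Train the three classifiers on the panel columns.

    SVM: RBF kernel, C = 1, kernel width 1/(p * Var(X)).  RF: 500 trees,
    sqrt(p) candidate features per split.  Ridge logistic: L2 penalty
    chosen by stratified 5-fold CV AUC on training over a geometric C
    grid; its decision cutoff comes from :func:`optimal_cutoff` on the
    training scores.  ``class_weight='balanced'`` enables inverse-
    frequency weighting for imbalanced cohorts (off by default).
    """
    X = np.asarray(X_panel, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if panel is None:
        panel = [f"f{i}" for i in range(X.shape[1])]
    svm = SVC(kernel="rbf", C=1.0, gamma="scale", class_weight=class_weight, random_state=seed)
    svm.fit(X, y)
    rf = RandomForestClassifier(
        n_estimators=500, max_features="sqrt", class_weight=class_weight, random_state=seed
    )
    rf.fit(X, y)

    n_splits = min(5, np.bincount(y).min())
    best_c, best_auc = RIDGE_C_GRID[len(RIDGE_C_GRID) // 2], -np.inf
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**31))
        splits = list(skf.split(X, y))
        for C in RIDGE_C_GRID:
            aucs = []
            for tr, te in splits:
                clf = LogisticRegression(C=C, max_iter=2000, class_weight=class_weight)
                clf.fit(X[tr], y[tr])
                aucs.append(auc_score(clf.decision_function(X[te]), y[te]))
            m = float(np.mean(aucs))
            if m > best_auc:
                best_auc, best_c = m, C
    ridge = LogisticRegression(C=best_c, max_iter=2000, class_weight=class_weight)
    ridge.fit(X, y)
    cutoff, degenerate = optimal_cutoff(ridge.predict_proba(X)[:, 1], y)
    return EnsembleModel(
        svm=svm,
        rf=rf,
        ridge=ridge,
        ridge_cutoff=float(cutoff),
        panel=list(panel),
        seed=seed,
        ridge_c=float(best_c),
        cutoff_degenerate=degenerate,
    )


def predict_vote(model: EnsembleModel, X: np.ndarray) -> dict:
    """Per-sample model labels, majority-vote label and model scores.

    The ridge label applies the trained cutoff to its probability; SVM and
    RF use their native predictions.  Three voters means no ties.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.panel):
        raise ValueError(
            f"expected {len(model.panel)} panel column(s), got {X.shape[1]}"
        )
    svm_score = model.svm.decision_function(X)
    rf_score = model.rf.predict_proba(X)[:, 1]
    ridge_score = model.ridge.predict_proba(X)[:, 1]
    labels = {
        "svm": model.svm.predict(X).astype(int),
        "rf": model.rf.predict(X).astype(int),
        "ridge": (ridge_score >= model.ridge_cutoff).astype(int),
    }
    votes = (labels["svm"] + labels["rf"] + labels["ridge"] >= 2).astype(int)
    return {
        "labels": labels,
        "vote": votes,
        "scores": {"svm": svm_score, "rf": rf_score, "ridge": ridge_score},
    }


@dataclass
class EvaluationReport:
    """Test-set performance of the ensemble."""

    auc: dict[str, float]
    vote_auc: float
    aupr: dict[str, float]
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    confusion: dict[str, int]
    n: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "vote_auc": self.vote_auc,
            "aupr": self.aupr,
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": self.confusion,
            "n": self.n,
        }


def evaluate(scores_per_model: dict[str, np.ndarray], labels, vote_labels) -> EvaluationReport:
    """Compute AUC / AUPR per model plus vote-label metrics.

    The vote AUC is the arithmetic mean of the three per-model AUCs; the
    accuracy CI is the exact Clopper-Pearson interval on correct / n.
    """
    labels = np.asarray(labels, dtype=int)
    vote_labels = np.asarray(vote_labels, dtype=int)
    if len(labels) != len(vote_labels):
        raise ValueError("labels and vote labels must align")
    aucs = {m: auc_score(s, labels) for m, s in scores_per_model.items()}
    auprs = {m: aupr_score(s, labels) for m, s in scores_per_model.items()}
    tp = int(((vote_labels == 1) & (labels == 1)).sum())
    tn = int(((vote_labels == 0) & (labels == 0)).sum())
    fp = int(((vote_labels == 1) & (labels == 0)).sum())
    fn = int(((vote_labels == 0) & (labels == 1)).sum())
    n = len(labels)
    correct = tp + tn
    ci = stats.binomtest(correct, n).proportion_ci(confidence_level=0.95, method="exact")
    return EvaluationReport(
        auc=aucs,
        vote_auc=vote_auc([aucs[m] for m in ("svm", "rf", "ridge")]) if set(aucs) >= {"svm", "rf", "ridge"} else round(float(np.mean(list(aucs.values()))), 3),
        aupr=auprs,
        accuracy=correct / n,
        accuracy_ci=(float(ci.low), float(ci.high)),
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        n=n,
    )


# ---------------------------------------------------------------------------
# cross-dataset protocol


def _residual_xy(
    ds: ExpressionDataset,
    info: list[SampleInfo],
    covariates: list[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Residualise a dataset and split samples into AD/CTL (labelled) and MCI."""
    res = huber_residualize(ds, info, covariates=covariates)
    keep = ~res.constant
    matrix = res.matrix[keep]
    features = [f for f, k in zip(res.feature_ids, keep) if k]
    by_id = {s.sample_id: s for s in info}
    groups = np.array([by_id[s].group for s in res.sample_ids])
    X = matrix.T  # samples x features
    return X, groups, np.array(res.sample_ids), features


def cross_dataset_protocol(
    ds_a: ExpressionDataset,
    info_a: list[SampleInfo],
    ds_b: ExpressionDataset,
    info_b: list[SampleInfo],
    seed: int = 0,
    folds: int = 5,
    repeats: int = 100,
    rule: str = "best_auc",
    covariates: list[str] = ["age", "gender"],
    class_weight: str | None = None,
) -> dict:
    """Train-on-one / test-on-the-other panel discovery, both directions.

    Each dataset is residualised independently on its own covariates;
    panel selection and ensemble training happen on the training cohort
    only.  Reports include, per direction, the selected panel, the test
    :class:`EvaluationReport`, and (when MCI samples exist in the test
    cohort) the fraction of MCI samples the AD-vs-CTL vote calls AD.
    """
    common = [f for f in ds_a.feature_ids if f in set(ds_b.feature_ids)]
    if not common:
        raise ValueError("no common features between datasets")
    sub_a, sub_b = ds_a.subset_features(common), ds_b.subset_features(common)
    Xa, grp_a, _, feats_a = _residual_xy(sub_a, info_a, covariates)
    Xb, grp_b, _, feats_b = _residual_xy(sub_b, info_b, covariates)
    shared = [f for f in feats_a if f in set(feats_b)]
    ia = {f: i for i, f in enumerate(feats_a)}
    ib = {f: i for i, f in enumerate(feats_b)}
    Xa = Xa[:, [ia[f] for f in shared]]
    Xb = Xb[:, [ib[f] for f in shared]]

    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    out: dict = {"features": shared, "seed": seed, "rule": rule}
    for direction, (Xtr, gtr, Xte, gte, s) in {
        "a_to_b": (Xa, grp_a, Xb, grp_b, int(seeds[0])),
        "b_to_a": (Xb, grp_b, Xa, grp_a, int(seeds[1])),
    }.items():
        tr_mask = np.isin(gtr, ("AD", "CTL"))
        te_mask = np.isin(gte, ("AD", "CTL"))
        ytr = (gtr[tr_mask] == "AD").astype(int)
        yte = (gte[te_mask] == "AD").astype(int)
        candidates = cv_lasso_select(Xtr[tr_mask], ytr, shared, folds=folds, repeats=repeats, seed=s)
        panel = select_panel(candidates, rule=rule, seed=s)
        cols = [shared.index(f) for f in panel.features]
        model = train_ensemble(Xtr[tr_mask][:, cols], ytr, seed=s, panel=panel.features, class_weight=class_weight)
        pred = predict_vote(model, Xte[te_mask][:, cols])
        report = evaluate(pred["scores"], yte, pred["vote"])
        mci_mask = gte == "MCI"
        mci_rate = None
        if mci_mask.any():
            mci_pred = predict_vote(model, Xte[mci_mask][:, cols])
            mci_rate = float(mci_pred["vote"].mean())
        out[direction] = {
            "panel": panel,
            "candidates": candidates,
            "model": model,
            "report": report,
            "mci_as_ad_rate": mci_rate,
        }
    return out


class PanelDiscovery:
    """Cross-dataset biomarker-panel discovery model.

    Wraps the full protocol (independent residualisation, repeated-CV
    LASSO selection, voting-ensemble training, swap-and-repeat) behind a
    Model/Results interface.
    """

    def __init__(
        self,
        ds_a: ExpressionDataset,
        info_a: list[SampleInfo],
        ds_b: ExpressionDataset,
        info_b: list[SampleInfo],
        covariates: list[str] = ["age", "gender"],
        folds: int = 5,
        repeats: int = 100,
        rule: str = "best_auc",
        class_weight: str | None = None,
    ) -> None:
        self.ds_a, self.info_a = ds_a, info_a
        self.ds_b, self.info_b = ds_b, info_b
        self.covariates = list(covariates)
        self.folds, self.repeats, self.rule = folds, repeats, rule
        self.class_weight = class_weight

    def fit(self, seed: int = 0) -> "PanelDiscoveryResults":
        raw = cross_dataset_protocol(
            self.ds_a,
            self.info_a,
            self.ds_b,
            self.info_b,
            seed=seed,
            folds=self.folds,
            repeats=self.repeats,
            rule=self.rule,
            covariates=self.covariates,
            class_weight=self.class_weight,
        )
        return PanelDiscoveryResults(model=self, protocol=raw, seed=seed)


@dataclass
class PanelDiscoveryResults:
    """Both-direction panels, trained ensembles and test reports."""

    model: PanelDiscovery
    protocol: dict
    seed: int

    def panel(self, direction: str = "a_to_b") -> BiomarkerPanel:
        return self.protocol[direction]["panel"]

    def report(self, direction: str = "a_to_b") -> EvaluationReport:
        return self.protocol[direction]["report"]

    def mci_as_ad_rate(self, direction: str = "a_to_b") -> float | None:
        return self.protocol[direction]["mci_as_ad_rate"]

    def summary(self) -> str:
        lines = ["Biomarker panel discovery (LASSO + SVM/RF/ridge vote)", "=" * 56]
        for direction in ("a_to_b", "b_to_a"):
            d = self.protocol[direction]
            r: EvaluationReport = d["report"]
            p: BiomarkerPanel = d["panel"]
            lines += [
                f"[{direction}] panel ({len(p.features)}): {', '.join(p.features)}",
                f"  selection: rule={p.rule}, CV AUC={p.cv_auc:.3f}, frequency={p.frequency}",
                f"  test AUC: svm={r.auc['svm']:.3f} rf={r.auc['rf']:.3f} ridge={r.auc['ridge']:.3f}"
                f" | vote AUC={r.vote_auc:.3f}",
                f"  accuracy={r.accuracy:.3f} (95% CI {r.accuracy_ci[0]:.3f}-{r.accuracy_ci[1]:.3f})"
                f" sens={r.sensitivity:.3f} spec={r.specificity:.3f}",
            ]
            if d["mci_as_ad_rate"] is not None:
                lines.append(f"  MCI predicted as AD: {d['mci_as_ad_rate']:.1%}")
        return "\n".join(lines)
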