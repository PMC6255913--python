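"""Synthetic two-cohort expression data with known ground truth.

The generator emulates the statistical structure of a two-cohort blood
microarray study of Alzheimer's disease: log2-scale expression for three
diagnosis groups (AD, MCI, CTL) in two batches, with

* a planted fraction of differentially expressed features whose AD effect
  is a random log2 shift and whose MCI effect is a scaled version of the
  AD effect on the same features (optionally direction-flipped for a
  configurable fraction, controlling cross-status concordance),
* age and gender covariate effects on a subset of features,
* an additive per-dataset (batch) offset per feature,
* heteroskedastic per-feature noise with variances drawn from a scaled
  inverse-chi-square prior (so empirical-Bayes variance moderation has a
  well-specified recovery target), and
* a small planted discriminative panel whose features separate AD from
  CTL by a known standardized effect size.

Everything planted is recorded in :class:`SyntheticTruth`, which
round-trips through JSON so recovery tests never need to re-run the
generator.  All randomness flows from one integer seed through fixed
sub-streams, so identical configurations give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .datatypes import ExpressionDataset, GeneSetCollection, SampleInfo

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_cohorts",
    "generate_overlap_lists",
    "generate_genesets",
    "planted_bayes_auc",
]


@dataclass
class SimConfig:
    """Configuration of the two-cohort simulator.

    Defaults mirror the study conditions the simulator emulates: group
    sizes (143/77/104 and 102/65/78 for AD/MCI/CTL in the two cohorts),
    small log2 effects on a planted DEG fraction, MCI effects 1.2x the AD
    effects on the same features, and a four-feature discriminative panel.
    """

    n_per_group: tuple[tuple[int, int, int], tuple[int, int, int]] = ((143, 77, 104), (102, 65, 78))
    n_features: int = 4000
    deg_fraction: float = 0.2
    deg_effect_range: tuple[float, float] = (0.1, 0.5)
    mci_attenuation: float = 1.2
    concordance_target: float = 1.0
    panel_features: int = 4
    panel_effect: float = 1.0
    age_mean: float = 75.0
    age_sd: float = 7.0
    age_slope_fraction: float = 0.3
    age_slope_range: tuple[float, float] = (0.01, 0.05)
    gender_offset_range: tuple[float, float] = (0.1, 0.3)
    batch_offset_sd: float = 0.5
    d0_true: float = 4.0
    s0_true_sq: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ValueError("deg_fraction must lie in [0, 1]")
        if not 0.0 <= self.concordance_target <= 1.0:
            raise ValueError("concordance_target must lie in [0, 1]")
        if not 0.0 <= self.age_slope_fraction <= 1.0:
            raise ValueError("age_slope_fraction must lie in [0, 1]")
        if self.n_features < self.panel_features:
            raise ValueError("n_features must be >= panel_features")
        for name in ("age_sd", "batch_offset_sd", "panel_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.mci_attenuation <= 2.0:
            raise ValueError("mci_attenuation must lie in (0, 2]")
        if self.d0_true <= 0 or self.s0_true_sq <= 0:
            raise ValueError("variance prior parameters must be positive")


@dataclass
class SyntheticTruth:
    """Full record of every planted quantity; JSON round-trippable."""

    deg_effects_ad: dict[str, float]
    deg_effects_mci: dict[str, float]
    panel_effects: dict[str, float]
    panel_deg_overlap: list[str]
    age_slopes: dict[str, float]
    gender_offsets: dict[str, float]
    batch_offsets: dict[str, dict[str, float]]
    noise_variances: dict[str, float]
    config: dict = field(default_factory=dict)

    @property
    def deg_features(self) -> set[str]:
        return set(self.deg_effects_ad)

    @property
    def panel_feature_ids(self) -> list[str]:
        return list(self.panel_effects)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def _substream(seed: int, offset: int) -> np.random.Generator:
    """Deterministic sub-stream: one global seed, fixed integer offsets."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(offset,)))


def generate_cohorts(
    config: SimConfig,
) -> tuple[tuple[ExpressionDataset, ExpressionDataset], tuple[list[SampleInfo], list[SampleInfo]], SyntheticTruth]:
    """Simulate two cohorts plus the ground truth describing them.

    Expression for feature g, sample i of dataset d:

        y_gi = baseline_g + effect_g(group_i) + slope_g * (age_i - age_mean)
               + offset_g * female_i + batch_gd + N(0, sigma_g)

    with sigma_g^2 ~ s0^2 * d0 / chi2(d0).  Panel features get an extra
    separation of panel_effect * sigma_g added to AD samples (and
    mci_attenuation times that to MCI samples).
    """
    cfg = config
    G = cfg.n_features
    n_deg = int(round(cfg.deg_fraction * G))
    if n_deg < 1:
        raise ValueError("deg_fraction * n_features must be >= 1")
    feature_ids = [f"g{i:05d}" for i in range(G)]

    rng_feat = _substream(cfg.seed, 0)
    baseline = rng_feat.uniform(6.0, 10.0, size=G)
    sigma2 = cfg.s0_true_sq * cfg.d0_true / rng_feat.chisquare(cfg.d0_true, size=G)
    sigma = np.sqrt(sigma2)

    deg_idx = rng_feat.choice(G, size=n_deg, replace=False)
    delta_ad = np.zeros(G)
    mag = rng_feat.uniform(cfg.deg_effect_range[0], cfg.deg_effect_range[1], size=n_deg)
    sign = rng_feat.choice([-1.0, 1.0], size=n_deg)
    delta_ad[deg_idx] = mag * sign
    delta_mci = cfg.mci_attenuation * delta_ad
    n_flip = int(round((1.0 - cfg.concordance_target) * n_deg))
    if n_flip > 0:
        flip = rng_feat.choice(deg_idx, size=n_flip, replace=False)
        delta_mci[flip] *= -1.0

    n_cov = int(round(cfg.age_slope_fraction * G))
    age_slope = np.zeros(G)
    gender_offset = np.zeros(G)
    if n_cov > 0:
        cov_idx = rng_feat.choice(G, size=n_cov, replace=False)
        age_slope[cov_idx] = rng_feat.uniform(*cfg.age_slope_range, size=n_cov) * rng_feat.choice(
            [-1.0, 1.0], size=n_cov
        )
        gender_offset[cov_idx] = rng_feat.uniform(*cfg.gender_offset_range, size=n_cov) * rng_feat.choice(
            [-1.0, 1.0], size=n_cov
        )

    panel_idx = rng_feat.choice(G, size=cfg.panel_features, replace=False)
    panel_delta = cfg.panel_effect * sigma[panel_idx]

    batch_offsets = {}
    datasets: list[ExpressionDataset] = []
    infos: list[list[SampleInfo]] = []
    labels = ("sim60", "sim61")
    for d, (label, counts) in enumerate(zip(labels, cfg.n_per_group)):
        rng_b = _substream(cfg.seed, 1 + d)
        batch = rng_b.normal(0.0, cfg.batch_offset_sd, size=G)
        batch_offsets[label] = batch
        n_ad, n_mci, n_ctl = counts
        n = n_ad + n_mci + n_ctl
        groups = np.array(["AD"] * n_ad + ["MCI"] * n_mci + ["CTL"] * n_ctl)
        age = np.clip(rng_b.normal(cfg.age_mean, cfg.age_sd, size=n), 40.0, 100.0)
        female = rng_b.integers(0, 2, size=n).astype(float)

        effect = np.zeros((G, n))
        effect[:, groups == "AD"] += delta_ad[:, None]
        effect[:, groups == "MCI"] += delta_mci[:, None]
        is_ad = groups == "AD"
        is_mci = groups == "MCI"
        effect[np.ix_(panel_idx, np.where(is_ad)[0])] += panel_delta[:, None]
        effect[np.ix_(panel_idx, np.where(is_mci)[0])] += cfg.mci_attenuation * panel_delta[:, None]

        noise = rng_b.normal(0.0, 1.0, size=(G, n)) * sigma[:, None]
        matrix = (
            baseline[:, None]
            + effect
            + age_slope[:, None] * (age[None, :] - cfg.age_mean)
            + gender_offset[:, None] * female[None, :]
            + batch[:, None]
            + noise
        )
        sample_ids = [f"{label}_s{i:04d}" for i in range(n)]
        datasets.append(ExpressionDataset(matrix, feature_ids, sample_ids, dataset_label=label))
        infos.append(
            [
                SampleInfo(
                    sample_id=sid,
                    group=g,
                    age=float(a),
                    gender="F" if f > 0.5 else "M",
                )
                for sid, g, a, f in zip(sample_ids, groups, age, female)
            ]
        )

    deg_ids = [feature_ids[i] for i in deg_idx]
    panel_ids = [feature_ids[i] for i in panel_idx]
    truth = SyntheticTruth(
        deg_effects_ad={fid: float(delta_ad[i]) for fid, i in zip(deg_ids, deg_idx)},
        deg_effects_mci={fid: float(delta_mci[i]) for fid, i in zip(deg_ids, deg_idx)},
        panel_effects={fid: float(d) for fid, d in zip(panel_ids, cfg.panel_effect * np.ones(cfg.panel_features))},
        panel_deg_overlap=sorted(set(panel_ids) & set(deg_ids)),
        age_slopes={feature_ids[i]: float(age_slope[i]) for i in np.nonzero(age_slope)[0]},
        gender_offsets={feature_ids[i]: float(gender_offset[i]) for i in np.nonzero(gender_offset)[0]},
        batch_offsets={lab: {fid: float(v) for fid, v in zip(feature_ids, off)} for lab, off in batch_offsets.items()},
        noise_variances={fid: float(v) for fid, v in zip(feature_ids, sigma2)},
        config=json.loads(json.dumps(asdict(cfg))),  # JSON-normalised (tuples -> lists)
    )
    return (datasets[0], datasets[1]), (infos[0], infos[1]), truth


def expected_overlap(n_universe: int, n_list_a: int, n_list_b: int, target_or: float) -> float:
    """Expected 2x2 overlap count a solving the fixed-margin odds-ratio
    equation  a*d / (b*c) = target_or  with b = nA-a, c = nB-a,
    d = N-nA-nB+a  (quadratic in a; the feasible root is returned)."""
    N, nA, nB, psi = n_universe, n_list_a, n_list_b, float(target_or)
    if psi <= 0:
        raise ValueError("target_or must be positive")
    lo, hi = max(0.0, nA + nB - N), float(min(nA, nB))
    if psi == 1.0:
        a = nA * nB / N
    else:
        A = psi - 1.0
        B = (psi - 1.0) * (nA + nB) + N
        C = psi * nA * nB
        disc = B * B - 4.0 * A * C
        if disc < 0:
            raise ValueError("infeasible margins for the requested odds ratio")
        a = (B - np.sqrt(disc)) / (2.0 * A)
        if not (lo - 1e-9 <= a <= hi + 1e-9):
            a = (B + np.sqrt(disc)) / (2.0 * A)
    if not (lo - 1e-9 <= a <= hi + 1e-9):
        raise ValueError("infeasible margins for the requested odds ratio")
    return float(a)


def generate_overlap_lists(
    n_universe: int,
    n_list_a: int,
    n_list_b: int,
    target_or: float,
    concordance: float,
    seed: int,
) -> tuple[dict[str, int], dict[str, int], dict]:
    """Draw two DEG-style id lists (with regulation directions) whose 2x2
    overlap against a common universe realises a target odds ratio, and
    whose overlapping members share direction for a target fraction.

    Returns (listA, listB, truth) where each list maps feature id -> +1/-1
    direction and truth records the realised 2x2 counts.
    """
    if n_list_a > n_universe or n_list_b > n_universe:
        raise ValueError("list sizes must not exceed the universe")
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must lie in [0, 1]")
    a = int(round(expected_overlap(n_universe, n_list_a, n_list_b, target_or)))
    a = max(max(0, n_list_a + n_list_b - n_universe), min(a, min(n_list_a, n_list_b)))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10,)))
    ids = np.array([f"u{i:06d}" for i in range(n_universe)])
    perm = rng.permutation(n_universe)
    a_ids = ids[perm[:n_list_a]]
    overlap_ids = a_ids[rng.choice(n_list_a, size=a, replace=False)] if a > 0 else np.array([], dtype=ids.dtype)
    outside = ids[perm[n_list_a:]]
    b_only = outside[rng.choice(len(outside), size=n_list_b - a, replace=False)] if n_list_b - a > 0 else np.array([], dtype=ids.dtype)

    dir_a = {fid: int(d) for fid, d in zip(a_ids, rng.choice([-1, 1], size=n_list_a))}
    n_same = int(round(concordance * a))
    same_mask = np.zeros(a, dtype=bool)
    if a > 0:
        same_mask[rng.choice(a, size=n_same, replace=False)] = True
    dir_b: dict[str, int] = {}
    for fid, same in zip(overlap_ids, same_mask):
        dir_b[fid] = dir_a[fid] if same else -dir_a[fid]
    for fid, d in zip(b_only, rng.choice([-1, 1], size=len(b_only))):
        dir_b[fid] = int(d)

    truth = {
        "a": a,
        "b": n_list_a - a,
        "c": n_list_b - a,
        "d": n_universe - n_list_a - n_list_b + a,
        "target_or": float(target_or),
        "concordance_target": float(concordance),
        "n_same_direction": n_same,
        "universe_ids": [str(i) for i in ids],
    }
    return dir_a, dir_b, truth


def generate_genesets(
    n_genes: int,
    n_sets: int,
    set_size_range: tuple[int, int],
    planted: list[tuple[int, float]],
    deg_list: list[str] | set[str],
    seed: int,
) -> tuple[GeneSetCollection, dict]:
    """Build a gene-set collection over the universe g000000..g{n_genes-1}.

    Non-planted sets sample members uniformly from the universe; a planted
    set (set_index, fold) draws each member from the DEG list with
    probability fold * |DEG|/n_genes, overrepresenting DEG members by that
    fold relative to background.
    """
    universe = np.array([f"g{i:05d}" for i in range(n_genes)])
    deg = np.array(sorted(set(deg_list)))
    non_deg = np.array(sorted(set(universe) - set(deg)))
    if deg.size and not set(deg) <= set(universe):
        raise ValueError("deg_list contains ids outside the gene universe")
    q = deg.size / n_genes
    planted_map = dict(planted)
    for idx in planted_map:
        if not 0 <= idx < n_sets:
            raise ValueError(f"planted set index {idx} out of range")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(20,)))
    lo, hi = set_size_range
    sets: dict[str, list[str]] = {}
    truth: dict[str, dict] = {}
    for i in range(n_sets):
        m = int(rng.integers(lo, hi + 1))
        name = f"S{i:03d}"
        fold = float(planted_map.get(i, 1.0))
        p1 = fold * q
        if p1 > 1.0:
            raise ValueError(f"fold {fold} infeasible: fold * deg fraction exceeds 1")
        if fold != 1.0:
            k = int(rng.binomial(m, p1))
            if k > deg.size or m - k > non_deg.size:
                raise ValueError(f"fold {fold} infeasible for set size {m}")
            members = np.concatenate(
                [
                    rng.choice(deg, size=k, replace=False),
                    rng.choice(non_deg, size=m - k, replace=False),
                ]
            )
        else:
            members = rng.choice(universe, size=m, replace=False)
        sets[name] = [str(x) for x in members]
        truth[name] = {"size": m, "fold": fold, "n_deg_members": int(np.isin(members, deg).sum())}
    return GeneSetCollection(sets=sets), {"sets": truth, "universe_size": n_genes, "n_deg": int(deg.size)}


def recovery_config(seed: int = 0, panel_features: int = 4, panel_effect: float = 1.0) -> SimConfig:
    """Panel-recovery study conditions: the planted panel is the only
    group signal (DEG effects zeroed), G = 1000 features, 125 AD + 125 CTL
    per cohort, covariate and batch structure left in place so the
    residualisation stage still has work to do."""
    return SimConfig(
        n_per_group=((125, 0, 125), (125, 0, 125)),
        n_features=1000,
        deg_fraction=0.01,
        deg_effect_range=(0.0, 0.0),
        panel_features=panel_features,
        panel_effect=panel_effect,
        seed=seed,
    )


def planted_bayes_auc(delta: float) -> float:
    """Optimal (Bayes) AUC for one equal-variance Gaussian feature whose
    class means differ by ``delta`` standard deviations: Phi(delta/sqrt(2))."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    return float(norm.cdf(delta / np.sqrt(2.0)))
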