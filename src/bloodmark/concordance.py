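"""Cross-tissue overlap statistics for DEG lists.

Given differential-expression tables from two tissues (or disease stages),
this module quantifies

* enrichment of one DEG list in another via the 2x2 Fisher exact test,
  reporting the conditional-MLE odds ratio with a 95% CI,
* direction concordance of the overlapping DEGs via an exact two-sided
  sign (binomial) test against 0.5,
* per-region overlap ratio tables (fraction of a region's DEGs that are
  also blood DEGs, rounded half-up to 2 decimals),
* enrichment of DEGs among genes whose expression correlates with a
  neuropathological trait (|r| above a threshold), and
* gene-set overrepresentation (upper-tail hypergeometric with BH
  correction across the collection, significant at BH < 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .datatypes import GeneSetCollection
from .dge import bh_adjust

EXACT_CI_MAX_MARGIN = 200  # exact conditional CI up to this min margin, Woolf beyond


@dataclass
class ContingencyTable:
    """2x2 overlap counts over a common universe."""

    a: int  # in both lists
    b: int  # list A only
    c: int  # list B only
    d: int  # neither
    label_a: str = "A"
    label_b: str = "B"
    label_universe: str = "universe"

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class EnrichmentStat:
    """Fisher-exact enrichment result."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    degenerate: bool = False


@dataclass
class ConcordanceResult:
    """Direction-concordance (sign test) result."""

    n_overlap: int
    n_same_direction: int
    proportion: float
    p: float
    defined: bool = True


def build_contingency(
    list_a: set[str],
    list_b: set[str],
    universe: set[str],
    label_a: str = "A",
    label_b: str = "B",
    label_universe: str = "universe",
) -> ContingencyTable:
    """Cross-tabulate membership of two id sets over a universe."""
    list_a, list_b, universe = set(list_a), set(list_b), set(universe)
    stray = (list_a | list_b) - universe
    if stray:
        raise ValueError(f"ids outside the universe: {sorted(stray)[:5]}")
    a = len(list_a & list_b)
    return ContingencyTable(
        a=a,
        b=len(list_a) - a,
        c=len(list_b) - a,
        d=len(universe) - len(list_a | list_b),
        label_a=label_a,
        label_b=label_b,
        label_universe=label_universe,
    )


def fisher_pvalue(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (minimum-likelihood rule): the sum of
    hypergeometric probabilities, at the observed margins, of every table
    no more probable than the observed one."""
    arr = table.as_array()
    return float(min(stats.fisher_exact(arr, alternative="two-sided")[1], 1.0))


def fisher_enrichment(table: ContingencyTable) -> EnrichmentStat:
    """Fisher exact test with conditional-MLE odds ratio and 95% CI.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins that are no more probable than the observed one.
    The CI is the exact conditional interval when the smallest margin is
    at most 200 and no cell is zero; large tables use the Woolf log-OR
    normal approximation, and a zero cell forces the Woolf interval with
    a 0.5 continuity correction (flagged).
    """
    arr = table.as_array()
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return EnrichmentStat(np.nan, np.nan, np.nan, 1.0, method="degenerate-margin", degenerate=True)
    p = fisher_pvalue(table)
    res = _odds_ratio(arr, kind="conditional")
    or_mle = float(res.statistic)
    min_margin = int(min(row.min(), col.min()))
    zero_cell = bool((arr == 0).any())
    if zero_cell or min_margin > EXACT_CI_MAX_MARGIN:
        cc = 0.5 if zero_cell else 0.0
        a, b, c, d = (arr + cc).ravel()
        log_or = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo, hi = float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se))
        method = "woolf" + ("-cc" if zero_cell else "")
    else:
        ci = res.confidence_interval(confidence_level=0.95)
        lo, hi, method = float(ci.low), float(ci.high), "exact-conditional"
    return EnrichmentStat(odds_ratio=or_mle, ci_low=lo, ci_high=hi, p=min(p, 1.0), method=method, degenerate=zero_cell)


def direction_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame) -> ConcordanceResult:
    """Sign-test of regulation-direction agreement among shared DEGs.

    The overlap is the set of features significant in both tables; the
    two-sided exact binomial test compares the same-direction count
    against Binomial(n_overlap, 0.5).
    """
    sig_a = table_a.loc[table_a["significant"]].set_index("feature_id")["direction"]
    sig_b = table_b.loc[table_b["significant"]].set_index("feature_id")["direction"]
    shared = sig_a.index.intersection(sig_b.index)
    n = len(shared)
    if n == 0:
        return ConcordanceResult(0, 0, np.nan, np.nan, defined=False)
    same = int((sig_a.loc[shared] == sig_b.loc[shared]).sum())
    p = float(stats.binomtest(same, n, 0.5, alternative="two-sided").pvalue)
    return ConcordanceResult(n_overlap=n, n_same_direction=same, proportion=same / n, p=p)


def round_ratio(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Half-up rounded ratio, matching printed-table precision."""
    if denominator == 0:
        return 0.0
    q = Decimal(numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def overlap_percentage(k: int, n: int, decimals: int = 1) -> float:
    """Overlap proportion expressed as a half-up rounded percentage."""
    if n == 0:
        return 0.0
    q = Decimal(k) * 100 / Decimal(n)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def overlap_ratio_table(
    region_tables: dict[str, pd.DataFrame],
    blood_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-region overlap of significant genes with a blood DEG table.

    One row per region: the region's up/down/all DEG counts, the counts of
    those DEGs also significant in blood, and the 2-decimal overlap ratio
    (overlap_all / region_all).  Rows are sorted by ratio, descending.
    """
    blood_sig = set(blood_table.loc[blood_table["significant"], "feature_id"])
    rows = []
    for region, tab in region_tables.items():
        sig = tab.loc[tab["significant"]]
        up = sig.loc[sig["direction"] == "up", "feature_id"]
        down = sig.loc[sig["direction"] == "down", "feature_id"]
        ov_up = sum(f in blood_sig for f in up)
        ov_down = sum(f in blood_sig for f in down)
        rows.append(
            {
                "region": region,
                "region_up": len(up),
                "region_down": len(down),
                "region_all": len(sig),
                "overlap_up": ov_up,
                "overlap_down": ov_down,
                "overlap_all": ov_up + ov_down,
                "ratio": round_ratio(ov_up + ov_down, len(sig)),
            }
        )
    return pd.DataFrame(rows).sort_values("ratio", ascending=False, kind="stable").reset_index(drop=True)


def trait_association(
    gene_corrs: dict[str, float],
    deg_list: set[str],
    universe: set[str],
    threshold: float = 0.5,
) -> EnrichmentStat:
    """Enrichment of DEGs among trait-correlated genes (|r| > threshold)."""
    r = np.array(list(gene_corrs.values()), dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    flagged = {g for g, v in gene_corrs.items() if abs(v) > threshold}
    table = build_contingency(set(deg_list), flagged, set(universe), label_a="DEG", label_b="trait-correlated")
    return fisher_enrichment(table)


def ora(
    deg_list: set[str],
    universe: set[str],
    collection: GeneSetCollection,
    direction_label: str = "all",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Gene-set overrepresentation by the upper-tail hypergeometric test.

    Set sizes count only in-universe members; p = P(X >= k) for
    X ~ Hypergeom(N, m, n) with N the universe size, m the in-universe set
    size and n the DEG count.  BH correction runs across all tested sets;
    a set is significant at BH < 0.01.  Sets with no in-universe member
    are skipped with a warning.
    """
    deg_list, universe = set(deg_list), set(universe)
    stray = deg_list - universe
    if stray:
        raise ValueError(f"DEG ids outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(deg_list)
    rows = []
    for name in collection.names():
        members = set(collection[name]) & universe
        m = len(members)
        if m == 0:
            warnings.warn(f"gene set {name!r} has no members in the universe; skipping", stacklevel=2)
            continue
        k = len(members & deg_list)
        p = float(stats.hypergeom.sf(k - 1, N, m, n))
        rows.append(
            {
                "set": name,
                "set_size": m,
                "hits": k,
                "n_deg": n,
                "universe": N,
                "ratio": f"{k}/{m}",
                "p": min(p, 1.0),
                "direction": direction_label,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["BH.pval"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["BH.pval"] < alpha
    return out
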