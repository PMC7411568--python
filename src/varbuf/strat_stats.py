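"""Gene stratification, regulatory indices and enrichment statistics.

Genes are stratified by promoter architecture and expression variation into
three classes: *broad* (broad-promoter genes), and narrow-promoter genes
split at the median variation of the narrow group into *narrow_low* and
*narrow_high*. Two rank-average indices summarize regulatory complexity:
the broad index (promoter-proximal DHS conditions, TF peaks, TF motifs) and
the narrow index (distal DHSs, miRNA motifs, Pol II pausing).

Enrichment uses Fisher's exact test with the conditional-MLE odds ratio
(the noncentral-hypergeometric convention) and Benjamini-Hochberg adjustment
across a declared test family; effect sizes use Cohen's d with a Wilcoxon
rank (Mann-Whitney) test for significance.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

from .util import rng

__all__ = [
    "BROAD_INDEX_FEATURES",
    "NARROW_INDEX_FEATURES",
    "EffectSize",
    "stratify_genes",
    "rank_average_index",
    "regulatory_indices",
    "fisher_test",
    "fisher_enrichment",
    "cohens_d",
    "association_measures",
    "bh_adjust",
]

BROAD_INDEX_FEATURES = (
    "num_dhs_conditions.prox",
    "num_tf_peaks.prox",
    "num_tf_motifs.prox",
)
NARROW_INDEX_FEATURES = ("num_dhs_any.dist", "num_mirna", "pausing_index")


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

def stratify_genes(
    promoter_calls: pd.DataFrame, resid_cv: pd.Series
) -> pd.DataFrame:
    """Three-way stratification: broad / narrow_low / narrow_high.

    Broad genes come straight from the promoter call; narrow genes split at
    the median resid_cv *of narrow genes* (<= median -> narrow_low; a gene
    exactly at the median goes to narrow_low). Thresholds are recorded in
    ``attrs``.
    """
    genes = promoter_calls.index.intersection(resid_cv.dropna().index)
    calls = promoter_calls.loc[genes, "promoter_class"]
    v = resid_cv.loc[genes]
    narrow = calls == "narrow"
    if not narrow.any():
        raise ValueError("no narrow-promoter genes to split")
    cut = float(v[narrow].median())
    strata = pd.Series("broad", index=genes, dtype=object)
    strata[narrow & (v <= cut)] = "narrow_low"
    strata[narrow & (v > cut)] = "narrow_high"
    out = pd.DataFrame({"stratum": strata, "resid_cv": v})
    out.attrs["narrow_median_cut"] = cut
    return out


# ---------------------------------------------------------------------------
# Rank-average indices
# ---------------------------------------------------------------------------

def rank_average_index(
    features: pd.DataFrame, columns: Sequence[str], seed: int = 0
) -> pd.Series:
    """Normalized rank-average of the named feature columns.

    Each column is converted to ranks 1..n ascending with ties broken
    uniformly at random (seeded per column name), normalized by n, and the
    index is the simple mean of the normalized ranks (in (0, 1]).
    """
    missing = [c for c in columns if c not in features.columns]
    if missing:
        raise ValueError(f"missing index component features: {missing}")
    n = len(features)
    parts = []
    for c in columns:
        tie = rng(seed, "ties", c).random(n)
        order = np.lexsort((tie, features[c].to_numpy(dtype=float)))
        ranks = np.empty(n)
        ranks[order] = np.arange(1, n + 1)
        parts.append(ranks / n)
    return pd.Series(np.mean(parts, axis=0), index=features.index)


def regulatory_indices(features: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Broad and narrow regulatory indices with the standard component sets."""
    return pd.DataFrame(
        {
            "broad_index": rank_average_index(features, BROAD_INDEX_FEATURES, seed),
            "narrow_index": rank_average_index(features, NARROW_INDEX_FEATURES, seed),
        }
    )


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def fisher_test(member_a: pd.Series, member_b: pd.Series) -> dict:
    """Conditional-MLE odds ratio + two-sided exact p for two memberships.

    Also reports the sample (cross-product) odds ratio for transparency.
    Tables with an empty margin are flagged undefined (NaN OR and p).
    """
    a = np.asarray(member_a, dtype=bool)
    b = np.asarray(member_b, dtype=bool)
    t11 = int(np.sum(a & b))
    t10 = int(np.sum(a & ~b))
    t01 = int(np.sum(~a & b))
    t00 = int(np.sum(~a & ~b))
    table = np.array([[t11, t10], [t01, t00]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return {
            "table": table, "odds_ratio": np.nan, "sample_odds_ratio": np.nan,
            "p_value": np.nan, "undefined": True,
        }
    res = _odds_ratio(table, kind="conditional")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_or = (t11 * t00) / (t10 * t01) if t10 * t01 > 0 else np.inf
    return {
        "table": table,
        "odds_ratio": float(res.statistic),
        "sample_odds_ratio": float(sample_or),
        "p_value": float(p),
        "undefined": False,
    }


def fisher_enrichment(
    comparisons: Mapping[str, tuple[pd.Series, pd.Series]],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Fisher tests over a declared family with BH adjustment.

    ``comparisons`` maps comparison id -> (membership_a, membership_b);
    the family size for BH is the number of comparisons.
    """
    rows = []
    for cid, (a, b) in comparisons.items():
        r = fisher_test(a, b)
        rows.append(
            {
                "comparison": cid,
                "odds_ratio": r["odds_ratio"],
                "sample_odds_ratio": r["sample_odds_ratio"],
                "p_value": r["p_value"],
                "undefined": r["undefined"],
            }
        )
    out = pd.DataFrame(rows).set_index("comparison")
    ok = out["p_value"].notna()
    adj = pd.Series(np.nan, index=out.index)
    if ok.any():
        adj[ok] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out["p_adjusted"] = adj
    out["significant"] = out["p_adjusted"] < alpha
    out["family_size"] = len(out)
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Effect sizes & association
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EffectSize:
    """Cohen's d (group1 - group2, pooled SD) with a rank-test p-value."""

    d: float
    p_value: float
    n1: int
    n2: int


def cohens_d(x: Sequence[float], y: Sequence[float]) -> EffectSize:
    """Standardized mean difference with a two-sided Wilcoxon rank test.

    ``d = (mean_x - mean_y) / s_pooled`` with the classical pooled variance;
    positive d means group x has the larger mean. The rank test is exact for
    small groups and a continuity-corrected normal approximation above n=50.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    nx, ny = len(x), len(y)
    s2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if s2 <= 0:
        raise ValueError("zero pooled standard deviation")
    d = (x.mean() - y.mean()) / np.sqrt(s2)
    method = "exact" if max(nx, ny) <= 50 else "asymptotic"
    try:
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    except ValueError:  # exact method refuses ties
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic").pvalue)
    return EffectSize(float(d), p, nx, ny)


def association_measures(a: Sequence, b: Sequence, kind: str) -> float:
    """Standard association coefficients.

    ``spearman``/``pearson`` for continuous pairs; ``point_biserial`` is
    Pearson with one 0/1-coded variable; ``phi`` is Pearson on two 0/1
    vectors. Constant vectors give NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return float("nan")
    if kind == "spearman":
        return float(sps.spearmanr(a, b).statistic)
    if kind == "pearson":
        return float(sps.pearsonr(a, b).statistic)
    if kind in ("point_biserial", "phi"):
        binaries = [b] if kind == "point_biserial" else [a, b]
        for v in binaries:
            if not set(np.unique(v)) <= {0.0, 1.0}:
                raise ValueError(f"{kind} requires 0/1 coding")
        return float(sps.pearsonr(a, b).statistic)
    raise ValueError("kind must be spearman, pearson, point_biserial or phi")
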