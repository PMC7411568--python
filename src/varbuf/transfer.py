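"""Cross-prediction of differential expression from expression variation.

A gene's variation across individuals is interpreted as its propensity to
respond to any perturbation. Two analyses quantify the link:

* per-study effect sizes (Cohen's d of resid_cv, DE vs non-DE genes), with
  the share of studies exceeding a minimal effect cut-off, and variation
  stratified by how many studies call a gene DE;
* the transfer protocol: a random-forest classifier trained to separate the
  top 30% from the bottom 30% of genes by expression variation (on genes
  outside the test set) is scored by ROC AUC at telling DE from non-DE
  genes on a held-out, class-balanced test set; ten rounds of random test
  sampling are summarized by the median AUC.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .strat_stats import EffectSize, cohens_d
from .util import child_seed, rng

__all__ = [
    "DEStudySet",
    "TransferResult",
    "auc_score",
    "de_effect_scan",
    "de_count_strata",
    "transfer_protocol",
]


@dataclasses.dataclass
class DEStudySet:
    """One study's DE call set (union over conditions) and gene universe."""

    study: str
    de_genes: set
    universe: set

    def __post_init__(self):
        if not self.de_genes <= self.universe:
            raise ValueError("DE genes must be a subset of the universe")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> list["DEStudySet"]:
        """Build study sets from a long (study, gene_id, is_de) table."""
        out = []
        for study, grp in df.groupby("study"):
            out.append(
                cls(
                    study=str(study),
                    de_genes=set(grp.loc[grp["is_de"].astype(bool), "gene_id"]),
                    universe=set(grp["gene_id"]),
                )
            )
        return out


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    Tied scores receive average ranks, so the AUC is the probability that a
    random positive outranks a random negative (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


# ---------------------------------------------------------------------------
# Effect-size scans
# ---------------------------------------------------------------------------

def de_effect_scan(
    resid_cv: pd.Series,
    studies: Sequence[DEStudySet],
    d_threshold: float = 0.2,
    min_de: int = 10,
) -> pd.DataFrame:
    """Per-study Cohen's d of variation, DE vs non-DE genes.

    Positive d means DE genes are more variable. Studies with fewer than
    ``min_de`` DE genes inside the variation universe are skipped. The share
    of analysed studies with d above ``d_threshold`` is in ``attrs``.
    """
    values = resid_cv.dropna()
    rows = []
    for st in studies:
        uni = values.index.intersection(list(st.universe))
        de = uni.intersection(list(st.de_genes))
        non = uni.difference(de)
        if len(de) < min_de:
            rows.append({"study": st.study, "skipped": True, "d": np.nan,
                         "p_value": np.nan, "n_de": len(de), "n_non_de": len(non)})
            continue
        eff = cohens_d(values[de], values[non])
        rows.append({"study": st.study, "skipped": False, "d": eff.d,
                     "p_value": eff.p_value, "n_de": eff.n1, "n_non_de": eff.n2})
    out = pd.DataFrame(rows).set_index("study")
    analysed = out[~out["skipped"]]
    out.attrs["share_d_above_threshold"] = (
        float((analysed["d"] > d_threshold).mean()) if len(analysed) else np.nan
    )
    return out


def de_count_strata(
    studies: Sequence[DEStudySet],
    resid_cv: pd.Series,
    bin_edges: Sequence[float] = (0, 10, np.inf),
) -> pd.DataFrame:
    """Variation of genes grouped by the number of studies calling them DE.

    ``bin_edges`` define right-closed count bins (default: 0-10 vs >10).
    Each bin row carries its median variation and Cohen's d versus the first
    bin; a single non-empty bin is flagged degenerate.
    """
    values = resid_cv.dropna()
    count = pd.Series(0, index=values.index)
    for st in studies:
        hits = values.index.intersection(list(st.de_genes))
        count[hits] += 1
    bins = pd.cut(count, bins=list(bin_edges), right=True, include_lowest=True)
    rows = []
    ref_values = None
    for interval in bins.cat.categories:
        members = values[bins == interval]
        row = {
            "bin": str(interval),
            "n_genes": len(members),
            "median_resid_cv": float(members.median()) if len(members) else np.nan,
            "d_vs_first": np.nan,
            "p_value": np.nan,
        }
        if len(members) >= 2:
            if ref_values is None:
                ref_values = members
            else:
                eff = cohens_d(members, ref_values)
                row["d_vs_first"] = eff.d
                row["p_value"] = eff.p_value
        rows.append(row)
    out = pd.DataFrame(rows).set_index("bin")
    out.attrs["gene_counts"] = count
    out.attrs["degenerate"] = int((out["n_genes"] > 0).sum()) < 2
    return out


# ---------------------------------------------------------------------------
# Transfer protocol
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TransferResult:
    aucs: list[float]
    composition: pd.DataFrame  # per-round train/test sizes

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs))


def transfer_protocol(
    features: pd.DataFrame,
    resid_cv: pd.Series,
    de_labels: pd.Series,
    top_frac: float = 0.3,
    rounds: int = 10,
    seed: int = 0,
    gene_subset: str = "all",
    narrow_mask: pd.Series | None = None,
    trees: int = 500,
    min_class: int = 20,
) -> TransferResult:
    """Variation-to-DE transfer classification.

    Per round: the test set is a random 50% of DE genes plus an equal-size
    sample of non-DE genes (without replacement). From the remaining genes
    (optionally narrow-promoter only), the top and bottom ``top_frac`` by
    resid_cv become the training classes (1 = variable, 0 = stable; ties at
    the cut resolved by gene-id order). A random forest (500 trees) is
    trained on the variation classes and its P(class 1) scores the test
    genes; the AUC of DE vs non-DE is recorded. Train/test gene sets are
    asserted disjoint every round.

    ``de_labels`` may contain NaN for genes outside the labelled universe
    (e.g. middle genes of a prior ranking); those genes never enter the test
    set but may be used for training.
    """
    genes = features.index.intersection(resid_cv.dropna().index)
    feats = features.loc[genes]
    v = resid_cv.loc[genes]
    labels = de_labels.reindex(genes)
    de_ids = labels.index[labels == 1]
    non_ids = labels.index[labels == 0]
    if len(de_ids) < min_class or len(non_ids) < min_class:
        raise ValueError("need at least %d genes in each DE class" % min_class)
    if gene_subset not in ("all", "narrow"):
        raise ValueError("gene_subset must be 'all' or 'narrow'")
    if gene_subset == "narrow" and narrow_mask is None:
        raise ValueError("narrow subset requires narrow_mask")

    aucs = []
    comp = []
    for rd in range(rounds):
        gen = rng(seed, "round", rd)
        n_test_de = len(de_ids) // 2
        test_de = pd.Index(gen.choice(de_ids, size=n_test_de, replace=False))
        pool_non = non_ids
        n_test_non = min(n_test_de, len(pool_non))
        test_non = pd.Index(gen.choice(pool_non, size=n_test_non, replace=False))
        test_ids = test_de.union(test_non)

        train_pool = genes.difference(test_ids)
        if gene_subset == "narrow":
            mask = narrow_mask.reindex(train_pool).fillna(False).astype(bool)
            train_pool = train_pool[mask]
        ranked = v.loc[train_pool].sort_values(
            kind="mergesort"
        )  # stable: ties by gene order
        k = int(np.floor(top_frac * len(ranked)))
        if k < 5:
            raise ValueError("training pool too small")
        bottom = ranked.index[:k]
        top = ranked.index[-k:]
        train_ids = bottom.union(top)
        overlap = train_ids.intersection(test_ids)
        assert len(overlap) == 0, "train/test overlap: protocol bug"

        y_train = pd.Series(0, index=train_ids)
        y_train[top] = 1
        clf = RandomForestClassifier(
            n_estimators=trees,
            max_features="sqrt",
            random_state=child_seed(seed, "clf", rd),
            n_jobs=1,
        )
        clf.fit(feats.loc[train_ids], y_train)
        scores = clf.predict_proba(feats.loc[test_ids])[:, 1]
        y_test = labels.loc[test_ids].astype(int)
        aucs.append(auc_score(scores, y_test))
        comp.append(
            {
                "round": rd,
                "n_train": len(train_ids),
                "n_test_de": len(test_de),
                "n_test_non_de": len(test_non),
            }
        )
    return TransferResult(aucs, pd.DataFrame(comp).set_index("round"))
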