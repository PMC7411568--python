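"""Expression-variation statistics.

The central quantity is the *residual coefficient of variation* (``resid_cv``):
per-gene CV of normalized counts across individuals, corrected for its strong
dependence on expression level by taking residuals from a LOESS (local linear)
regression of log2 CV on log2 median expression. Genes above/below the fitted
trend are more/less variable than expected at their expression level.

The module covers the full measurement pipeline:

* median-of-ratios size-factor normalization,
* per-gene summaries (median, CV),
* the ordered filtering ladder (zero median, top/bottom 5%, developmentally
  decreasing genes, missing features),
* LOESS-residual variation for CV and the alternative spread statistics
  (sd, MAD, IQR),
* robustness analyses: sample-subsetting stability and the neighbouring-gene
  correlation structure (distance bins x TAD co-membership).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .util import geometric_mean, rng

__all__ = [
    "CountMatrix",
    "normalize_counts",
    "summarize_expression",
    "filter_genes",
    "residual_variation",
    "expression_summary",
    "subsample_stability",
    "neighbor_pair_correlation",
    "VARIATION_METRICS",
]

VARIATION_METRICS = ("cv", "sd", "mad", "iqr")


@dataclasses.dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample metadata.

    ``counts`` is indexed by gene id with one column per sample id;
    ``samples`` is indexed by sample id and may carry line/tissue, timepoint
    and batch columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame | None = None

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("gene and sample ids must be unique")
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.samples is None:
            self.samples = pd.DataFrame(index=c.columns)
        elif not self.samples.index.equals(c.columns):
            self.samples = self.samples.reindex(c.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_counts(counts: CountMatrix | pd.DataFrame):
    """Median-of-ratios size factors and the normalized matrix.

    Reference genes are those with nonzero counts in every sample. Each
    sample's factor is the median over reference genes of the ratio of its
    count to the gene's geometric mean across samples; factors are rescaled
    to geometric mean 1 (conventional; absolute scale is arbitrary).

    Returns ``(size_factors, normalized)`` with ``size_factors`` a Series per
    sample and ``normalized = counts / size_factors``.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if mat.shape[1] < 2:
        raise ValueError("normalization requires at least 2 samples")
    arr = mat.to_numpy(dtype=float)
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "median-of-ratios reference set is empty"
        )
    ref_arr = arr[ref]
    geo = geometric_mean(ref_arr, axis=1)
    ratios = ref_arr / geo[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / geometric_mean(factors)
    sf = pd.Series(factors, index=mat.columns, name="size_factor")
    normalized = mat / sf
    return sf, normalized


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_expression(normalized: pd.DataFrame, timepoint=None) -> pd.DataFrame:
    """Per-gene median and coefficient of variation of normalized counts.

    CV is the sample standard deviation (``ddof=1``) divided by the mean.
    Genes with zero mean get CV = NaN and ``cv_undefined = True``.
    """
    if normalized.shape[1] < 3:
        raise ValueError("need at least 3 samples to summarize variation")
    arr = normalized.to_numpy(dtype=float)
    med = np.median(arr, axis=1)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    out = pd.DataFrame(
        {
            "median": med,
            "mean": mean,
            "sd": sd,
            "cv": cv,
            "mad": sps.median_abs_deviation(arr, axis=1),
            "iqr": sps.iqr(arr, axis=1),
            "cv_undefined": mean <= 0,
        },
        index=normalized.index,
    )
    if timepoint is not None:
        out["timepoint"] = timepoint
    return out


# ---------------------------------------------------------------------------
# Filtering ladder
# ---------------------------------------------------------------------------

#: documented rule order; `filter_genes` applies exactly this sequence.
FILTER_ORDER = ("zero_median", "top5", "bottom5", "decreasing", "missing_features")


def filter_genes(
    summaries: Mapping[object, pd.DataFrame],
    focal,
    early=None,
    pct: float = 0.05,
    feature_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the filtering ladder; returns per-gene boolean flags + ``retained``.

    Rules, in order, each applied to the genes surviving the previous one:

    1. ``zero_median`` -- zero median normalized expression at the focal
       timepoint (non-expressed genes);
    2. ``top5``/``bottom5`` -- top and bottom ``pct`` by median expression at
       the focal timepoint (outlier-prone extremes). Cut sizes are
       ``floor(pct * n_remaining)``; ties are resolved deterministically by
       rank on (median, gene id);
    3. ``decreasing`` -- median(focal) < median(early), flagging genes whose
       expression decays between the early and focal stages (maternal
       transcripts); skipped when ``early`` is None;
    4. ``missing_features`` -- genes with non-imputable missing values in the
       feature table; skipped when no table is given.
    """
    if focal not in summaries:
        raise KeyError(f"no summary for focal timepoint {focal!r}")
    s_focal = summaries[focal]
    genes = s_focal.index
    flags = pd.DataFrame(False, index=genes, columns=list(FILTER_ORDER))

    alive = s_focal["median"] > 0
    flags["zero_median"] = ~alive

    med = s_focal["median"]
    order = pd.DataFrame({"median": med[alive]}).sort_index()
    order["_rank"] = order["median"].rank(method="first")  # gene-id order breaks ties
    n = int(alive.sum())
    k = int(np.floor(pct * n))
    if k > 0:
        bottom_ids = order.nsmallest(k, "_rank").index
        top_ids = order.nlargest(k, "_rank").index
        flags.loc[bottom_ids, "bottom5"] = True
        flags.loc[top_ids, "top5"] = True
        alive = alive & ~flags["top5"] & ~flags["bottom5"]

    if early is not None:
        if early not in summaries:
            raise KeyError(f"no summary for early timepoint {early!r}")
        med_early = summaries[early]["median"].reindex(genes)
        dec = (med < med_early) & alive
        flags["decreasing"] = dec.fillna(False)
        alive = alive & ~flags["decreasing"]

    if feature_table is not None:
        ft = feature_table.reindex(genes[alive])
        missing = ft.isna().any(axis=1)
        flags.loc[missing[missing].index, "missing_features"] = True
        alive = alive & ~flags["missing_features"]

    flags["retained"] = alive
    if not alive.any():
        raise ValueError("filtering ladder removed every gene")
    return flags


# ---------------------------------------------------------------------------
# LOESS residual variation
# ---------------------------------------------------------------------------

def _loess_fit(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Degree-1 LOESS fit of y on x evaluated at x; duplicate x averaged first."""
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size < 2:
        return np.full_like(x, y.mean())
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    fit = lowess(uy, ux, frac=span, it=0, return_sorted=False)
    return np.interp(x, ux, fit)


def residual_variation(
    log2_median: pd.Series,
    statistic: pd.Series,
    metric: str = "cv",
    span: float = 0.75,
    degree: int = 1,
    log_response: bool = True,
) -> pd.Series:
    """LOESS residuals of a spread statistic against log2 median expression.

    By default the response is log2-transformed (log-log fit); residuals are
    in log2 units. Genes whose statistic is zero or undefined get NaN.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if degree != 1:
        raise ValueError("only degree-1 (local linear) LOESS is supported")
    if metric not in VARIATION_METRICS:
        raise ValueError(f"metric must be one of {VARIATION_METRICS}")
    x = np.asarray(log2_median, dtype=float)
    y = np.asarray(statistic, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if log_response:
        ok &= y > 0
    if ok.sum() < 50:
        raise ValueError("residual variation requires at least 50 genes")
    resp = np.log2(y[ok]) if log_response else y[ok]
    fit = _loess_fit(x[ok], resp, span)
    out = np.full(x.shape, np.nan)
    resid = resp - fit
    out[ok] = resid - resid.mean()  # centered: exactly mean-free over the gene set
    return pd.Series(out, index=log2_median.index, name=f"resid_{metric}")


def expression_summary(
    normalized: pd.DataFrame,
    span: float = 0.75,
    log_response: bool = True,
) -> pd.DataFrame:
    """Full per-gene summary on a (final, filtered) gene set.

    Residual measures are re-fit on exactly the genes given, per the protocol
    of recomputing variation on the final set after filtering.
    """
    s = summarize_expression(normalized)
    with np.errstate(divide="ignore"):
        s["log2_median"] = np.log2(s["median"])
    for metric in VARIATION_METRICS:
        s[f"resid_{metric}"] = residual_variation(
            s["log2_median"], s[metric], metric=metric, span=span,
            log_response=log_response,
        )
    return s


# ---------------------------------------------------------------------------
# Robustness: subsampling
# ---------------------------------------------------------------------------

def subsample_stability(
    counts: CountMatrix,
    subset_sizes: Sequence[int],
    reps: int = 100,
    seed: int = 0,
    span: float = 0.75,
    genes: Iterable | None = None,
) -> pd.DataFrame:
    """Stability of resid_cv under random sample subsetting.

    For each subset size and repetition, ``resid_cv`` is recomputed from
    scratch on the subset (renormalization and LOESS re-fit included) and
    correlated (Pearson) with the full-data values. Returns one record per
    (size, rep) plus the per-size mean/sd via ``groupby``.
    """
    n = counts.n_samples
    for size in subset_sizes:
        if size < 3:
            raise ValueError("subset size must be at least 3")
        if size > n:
            raise ValueError(f"subset size {size} exceeds {n} samples")
    _, norm_full = normalize_counts(counts)
    if genes is not None:
        norm_full = norm_full.loc[list(genes)]
    full = expression_summary(norm_full, span=span)["resid_cv"]
    gen = rng(seed, "subsample")
    records = []
    for size in subset_sizes:
        for rep in range(reps):
            cols = counts.counts.columns[np.sort(gen.choice(n, size=size, replace=False))]
            sub = CountMatrix(counts.counts[cols])
            _, norm_sub = normalize_counts(sub)
            if genes is not None:
                norm_sub = norm_sub.loc[list(genes)]
            sub_resid = expression_summary(norm_sub, span=span)["resid_cv"]
            both = pd.concat([full, sub_resid], axis=1, keys=["full", "sub"]).dropna()
            r = float(np.corrcoef(both["full"], both["sub"])[0, 1])
            records.append({"size": size, "rep": rep, "pearson_r": r})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Robustness: neighbouring genes
# ---------------------------------------------------------------------------

def _assign_tads(annotation: pd.DataFrame, tads: pd.DataFrame) -> pd.Series:
    """TAD id per gene, assigned by TSS coordinate; NaN outside any TAD."""
    out = pd.Series(np.nan, index=annotation.index, dtype=object)
    for contig, tad_c in tads.groupby("contig"):
        genes_c = annotation[annotation["contig"] == contig]
        if genes_c.empty:
            continue
        starts = tad_c["start"].to_numpy()
        ends = tad_c["end"].to_numpy()
        ids = tad_c.index.to_numpy()
        pos = genes_c["tss"].to_numpy() - 1  # 0-based
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        out.loc[genes_c.index[inside]] = ids[idx[inside]]
    return out


def neighbor_pair_correlation(
    values: pd.Series,
    annotation: pd.DataFrame,
    tads: pd.DataFrame,
    max_dist: int = 100_000,
    n_bins: int = 5,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Spearman correlation of a per-gene value between neighbouring genes.

    All same-contig gene pairs with TSS-to-TSS distance below ``max_dist``
    (each pair once, ordered by coordinate) are binned into ``n_bins``
    distance quantiles and split by same/different TAD (TSS assignment).
    Cells with fewer than ``min_pairs`` pairs report NaN.
    """
    ann = annotation.loc[annotation.index.intersection(values.dropna().index)]
    tad_of = _assign_tads(ann, tads)
    pairs = []
    for contig, grp in ann.groupby("contig"):
        g = grp.sort_values("tss")
        tss = g["tss"].to_numpy()
        ids = g.index.to_numpy()
        for i in range(len(g)):
            j = i + 1
            while j < len(g) and tss[j] - tss[i] < max_dist:
                pairs.append((ids[i], ids[j], tss[j] - tss[i]))
                j += 1
    if not pairs:
        raise ValueError("no gene pairs under max_dist")
    pdf = pd.DataFrame(pairs, columns=["gene1", "gene2", "dist"])
    t1 = tad_of.reindex(pdf["gene1"]).to_numpy()
    t2 = tad_of.reindex(pdf["gene2"]).to_numpy()
    pdf["same_tad"] = (t1 == t2) & pd.notna(t1) & pd.notna(t2)
    pdf["dist_bin"] = pd.qcut(pdf["dist"], n_bins, labels=False, duplicates="drop")
    v1 = values.reindex(pdf["gene1"]).to_numpy()
    v2 = values.reindex(pdf["gene2"]).to_numpy()
    rows = []
    for (b, same), grp in pdf.groupby(["dist_bin", "same_tad"]):
        if len(grp) < min_pairs:
            rho, p = np.nan, np.nan
        else:
            rho, p = sps.spearmanr(v1[grp.index], v2[grp.index])
        rows.append(
            {
                "dist_bin": b,
                "same_tad": same,
                "n_pairs": len(grp),
                "median_dist": float(grp["dist"].median()),
                "spearman_rho": rho,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
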