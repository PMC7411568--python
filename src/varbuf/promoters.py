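"""Promoter architecture from TSS tag distributions.

A promoter's *shape* summarizes how spread out transcription initiation is.
Two routes are implemented:

* the shape-index route: ``SI = 2 + sum_i p_i log2 p_i`` over tag positions
  (2 minus the Shannon entropy in bits of the tag distribution); a single
  initiation site gives SI = 2, a uniform spread over L sites gives
  ``2 - log2 L``. Promoters are broad iff SI is strictly below a threshold
  (default -1);
* the width route: inter-percentile (5-95%) width of the tag cluster, with
  the broad/narrow boundary found by fitting a two-component mixture
  (gamma on transformed widths, or Gaussian on shape indices) by EM and
  taking the density crossing point between the component means.

Upstream steps: power-law normalization of tag counts (rank-preserving map
onto a reference law) and single-linkage clustering of tag positions
(distclu-style, max gap 20 bp, per contig/strand/dataset).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from .util import rng

__all__ = [
    "PromoterCluster",
    "MixtureFit",
    "power_law_normalize",
    "cluster_tss",
    "shape_index",
    "interpercentile_width",
    "fit_two_component_mixture",
    "classify_gene_promoters",
]


@dataclasses.dataclass
class PromoterCluster:
    """A TSS tag cluster on one strand of one contig."""

    contig: str
    strand: str
    positions: np.ndarray  # 1-based, ascending
    counts: np.ndarray
    dataset: str = ""

    def __post_init__(self):
        order = np.argsort(self.positions)
        self.positions = np.asarray(self.positions)[order]
        self.counts = np.asarray(self.counts, dtype=float)[order]

    @property
    def total_signal(self) -> float:
        return float(self.counts.sum())

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1])

    @property
    def span(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Power-law normalization
# ---------------------------------------------------------------------------

def power_law_normalize(
    tags: pd.DataFrame,
    fit_range: tuple[float, float] = (5, 1000),
    ref_slope: float = -1.25,
    ref_total: float = 1e6,
    count_floor: float = 5.0,
) -> pd.DataFrame:
    """Map tag counts onto a reference power law, preserving rank order.

    The reverse-cumulative count R(c) (number of tag positions with count
    >= c) of CAGE-like data follows an approximate power law; the slope is
    fit by least squares on log-log within ``fit_range`` (reported in
    ``attrs['fitted_slope']``). Each tag count is then replaced by the count
    the reference law (``R(c) = ref_total * c**ref_slope``) assigns to its
    own reverse-cumulative rank. Tags with normalized count below
    ``count_floor`` are dropped afterwards.
    """
    counts = tags["count"].to_numpy(dtype=float)
    values, val_counts = np.unique(counts, return_counts=True)
    # reverse cumulative: number of tags with count >= v
    rev = val_counts[::-1].cumsum()[::-1]
    in_range = (values >= fit_range[0]) & (values <= fit_range[1])
    if in_range.sum() < 3:
        raise ValueError("fewer than 3 distinct tag-count values in fit_range")
    slope, intercept = np.polyfit(
        np.log10(values[in_range]), np.log10(rev[in_range]), 1
    )
    rev_of = dict(zip(values, rev.astype(float)))
    r = np.array([rev_of[c] for c in counts])
    normalized = (r / ref_total) ** (1.0 / ref_slope)
    out = tags.copy()
    out["count"] = normalized
    out = out[out["count"] >= count_floor].reset_index(drop=True)
    out.attrs["fitted_slope"] = float(slope)
    out.attrs["fitted_intercept"] = float(intercept)
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_tss(
    tags: pd.DataFrame,
    max_dist: int = 20,
    min_cluster_signal: float = 0.0,
) -> list[PromoterCluster]:
    """Single-linkage chaining of tag positions into clusters.

    Positions on the same contig, strand and dataset that are at most
    ``max_dist`` apart are chained into one cluster; clusters never span
    contigs or strands. Clusters with total signal below
    ``min_cluster_signal`` are dropped.
    """
    clusters: list[PromoterCluster] = []
    keys = ["contig", "strand"] + (["dataset"] if "dataset" in tags.columns else [])
    for key, grp in tags.groupby(keys, sort=True):
        g = grp.sort_values("pos")
        pos = g["pos"].to_numpy()
        cnt = g["count"].to_numpy(dtype=float)
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_dist) + 1
        for chunk_pos, chunk_cnt in zip(np.split(pos, breaks), np.split(cnt, breaks)):
            if chunk_cnt.sum() < min_cluster_signal:
                continue
            contig, strand = key[0], key[1]
            ds = key[2] if len(keys) == 3 else ""
            clusters.append(PromoterCluster(contig, strand, chunk_pos, chunk_cnt, ds))
    return clusters


# ---------------------------------------------------------------------------
# Shape metrics
# ---------------------------------------------------------------------------

def shape_index(cluster: PromoterCluster) -> float:
    """``SI = 2 + sum p_i log2 p_i`` over positions with at least one tag."""
    c = cluster.counts[cluster.counts > 0]
    total = c.sum()
    if total <= 0:
        raise ValueError("empty cluster has no shape index")
    p = c / total
    return float(2.0 + np.sum(p * np.log2(p)))


def interpercentile_width(
    cluster: PromoterCluster, lo: float = 0.05, hi: float = 0.95
) -> int:
    """Width between the positions where the cumulative tag fraction first
    reaches ``lo`` and ``hi`` (inclusive, in bp). Positions are taken in
    ascending coordinate order regardless of strand."""
    total = cluster.counts.sum()
    if total <= 0:
        raise ValueError("empty cluster has no width")
    cum = np.cumsum(cluster.counts) / total
    p_lo = cluster.positions[np.searchsorted(cum, lo)]
    p_hi = cluster.positions[np.searchsorted(cum, hi)]
    return int(p_hi - p_lo + 1)


# ---------------------------------------------------------------------------
# Two-component mixtures
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MixtureFit:
    family: str
    weights: np.ndarray
    params: list  # per component: (mean, sd) or (shape, scale)
    log_likelihood: float
    n_iter: int
    separation_threshold: float
    loglik_path: np.ndarray
    responsibilities: np.ndarray | None = None

    @property
    def component_means(self) -> np.ndarray:
        if self.family == "gaussian":
            return np.array([p[0] for p in self.params])
        return np.array([p[0] * p[1] for p in self.params])

    def component_pdf(self, x: np.ndarray, k: int) -> np.ndarray:
        if self.family == "gaussian":
            return sps.norm.pdf(x, *self.params[k])
        return sps.gamma.pdf(x, self.params[k][0], scale=self.params[k][1])


def _gamma_wmle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted gamma MLE: Newton on log(k) - digamma(k) = log(m) - mlog."""
    wsum = w.sum()
    m = (w * x).sum() / wsum
    mlog = (w * np.log(x)).sum() / wsum
    s = np.log(m) - mlog
    s = max(s, 1e-10)
    k = (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)  # Minka's closed-form init
    for _ in range(50):
        num = np.log(k) - special.digamma(k) - s
        den = 1.0 / k - special.polygamma(1, k)
        step = num / den
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2
        if abs(k_new - k) < 1e-12 * k:
            k = k_new
            break
        k = k_new
    return float(k), float(m / k)


def fit_two_component_mixture(
    values: Sequence[float],
    family: str = "gaussian",
    transform=None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    restarts: int = 5,
) -> MixtureFit:
    """Two-component mixture by EM with a separation threshold.

    ``transform`` (e.g. ``lambda w: (w - 1) / 10`` for promoter widths before
    a gamma fit) is applied first. The threshold is the crossing point of the
    weight-scaled component densities, root-found in the open interval
    between the component means; if they do not cross there, the midpoint of
    the means is used with a warning. The log-likelihood is asserted
    non-decreasing at every EM step.
    """
    x = np.asarray(values, dtype=float)
    if transform is not None:
        x = np.asarray([transform(v) for v in x], dtype=float)
    if x.size < 50:
        raise ValueError("mixture fit requires at least 50 values")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: all values identical")
    if family not in ("gaussian", "gamma"):
        raise ValueError("family must be 'gaussian' or 'gamma'")
    if family == "gamma" and np.any(x <= 0):
        raise ValueError("gamma mixture requires positive values after transform")

    gen = rng(seed, "mixture")
    best: MixtureFit | None = None
    errors = []
    for restart in range(restarts):
        try:
            fit = _em_once(x, family, gen, tol, max_iter)
        except (FloatingPointError, ValueError, np.linalg.LinAlgError) as e:  # retry
            errors.append(str(e))
            continue
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if best is None:
        raise RuntimeError(
            f"EM failed to converge in all {restarts} restarts: {errors}"
        )
    best.separation_threshold = _separation_threshold(best)
    return best


def _em_once(x, family, gen, tol, max_iter) -> MixtureFit:
    n = x.size
    # init: split around a jittered quantile
    q = gen.uniform(0.3, 0.7)
    cut = np.quantile(x, q)
    z = x > cut
    if z.sum() < 2 or (~z).sum() < 2:
        z = x > np.median(x)
    w = np.array([(~z).mean(), z.mean()])
    params = []
    for mask in (~z, z):
        xm = x[mask]
        if family == "gaussian":
            params.append((xm.mean(), max(xm.std(), 1e-6)))
        else:
            params.append(_gamma_wmle(xm, np.ones(xm.size)))
    loglik_path = []
    prev = -np.inf
    resp = None
    for it in range(1, max_iter + 1):
        comp = np.empty((n, 2))
        for k in range(2):
            if family == "gaussian":
                comp[:, k] = sps.norm.logpdf(x, *params[k])
            else:
                comp[:, k] = sps.gamma.logpdf(x, params[k][0], scale=params[k][1])
        comp += np.log(np.maximum(w, 1e-300))
        m = comp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(comp - m).sum(axis=1))
        ll = float(lse.sum())
        assert ll >= prev - 1e-8 * max(1.0, abs(prev)), "EM log-likelihood decreased"
        loglik_path.append(ll)
        resp = np.exp(comp - lse[:, None])
        if ll - prev < tol * max(1.0, abs(ll)) and it > 1:
            prev = ll
            break
        prev = ll
        # M-step
        w = resp.mean(axis=0)
        new_params = []
        for k in range(2):
            rk = resp[:, k]
            if rk.sum() < 1e-8:
                raise ValueError("component collapsed")
            if family == "gaussian":
                mu = (rk * x).sum() / rk.sum()
                sd = np.sqrt((rk * (x - mu) ** 2).sum() / rk.sum())
                new_params.append((mu, max(sd, 1e-8)))
            else:
                new_params.append(_gamma_wmle(x, rk))
        params = new_params
    else:
        raise ValueError("EM did not converge within max_iter")
    # order components by mean
    fit = MixtureFit(family, w, params, prev, len(loglik_path), np.nan,
                     np.asarray(loglik_path), resp)
    order = np.argsort(fit.component_means)
    fit.weights = fit.weights[order]
    fit.params = [fit.params[k] for k in order]
    if resp is not None:
        fit.responsibilities = resp[:, order]
    return fit


def _separation_threshold(fit: MixtureFit) -> float:
    m1, m2 = fit.component_means
    lo, hi = sorted((m1, m2))
    if not np.isfinite(lo) or not np.isfinite(hi) or np.isclose(lo, hi):
        return float((lo + hi) / 2)

    def g(x):
        x = np.atleast_1d(x)
        d = (np.log(np.maximum(fit.weights[0] * fit.component_pdf(x, 0), 1e-300))
             - np.log(np.maximum(fit.weights[1] * fit.component_pdf(x, 1), 1e-300)))
        return d[0]

    eps = 1e-6 * (hi - lo)
    a, b = lo + eps, hi - eps
    ga, gb = g(a), g(b)
    if ga * gb > 0:
        warnings.warn(
            "mixture densities do not cross between component means; "
            "using the midpoint", RuntimeWarning,
        )
        return float((lo + hi) / 2)
    return float(optimize.brentq(g, a, b, xtol=1e-10 * max(1.0, hi - lo)))


# ---------------------------------------------------------------------------
# Gene-level classification
# ---------------------------------------------------------------------------

def _assign_clusters(
    clusters: list[PromoterCluster],
    annotation: pd.DataFrame,
    upstream: int,
    downstream: int,
) -> pd.DataFrame:
    """Assign clusters to genes by overlap with core-promoter windows.

    A cluster is assigned when its span overlaps the strand-aware window
    [-upstream, +downstream] around the gene TSS (1-based, inclusive).
    Returns one row per (gene, cluster) with shape metrics precomputed.
    """
    rows = []
    for ci, cl in enumerate(clusters):
        si = shape_index(cl)
        width = interpercentile_width(cl)
        rows.append((ci, cl.contig, cl.strand, cl.start, cl.end,
                     cl.total_signal, si, width, cl.dataset))
    cdf = pd.DataFrame(
        rows,
        columns=["cluster", "contig", "strand", "start", "end",
                 "signal", "shape_index", "width", "dataset"],
    )
    frames = []
    for (contig, strand), cgrp in cdf.groupby(["contig", "strand"]):
        genes = annotation[
            (annotation["contig"] == contig) & (annotation["strand"] == strand)
        ]
        if genes.empty:
            continue
        tss = genes["tss"].to_numpy()
        if strand == "+":
            w_lo, w_hi = tss - upstream, tss + downstream
        else:
            w_lo, w_hi = tss - downstream, tss + upstream
        cs = cgrp["start"].to_numpy()
        ce = cgrp["end"].to_numpy()
        gi, ci = np.nonzero(
            (cs[None, :] <= w_hi[:, None]) & (ce[None, :] >= w_lo[:, None])
        )
        if gi.size == 0:
            continue
        block = cgrp.iloc[ci].reset_index(drop=True)
        block.insert(0, "gene_id", genes.index.to_numpy()[gi])
        frames.append(block)
    if not frames:
        return pd.DataFrame(
            columns=["gene_id", "cluster", "contig", "strand", "start", "end",
                     "signal", "shape_index", "width", "dataset"]
        )
    return pd.concat(frames, ignore_index=True)


def classify_gene_promoters(
    clusters: list[PromoterCluster],
    annotation: pd.DataFrame,
    route: str = "fly_SI",
    si_threshold: float = -1.0,
    width_threshold: float | None = None,
    upstream: int = 300,
    downstream: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene promoter call from assigned clusters.

    ``fly_SI`` route: the major (highest-signal) cluster's shape index
    decides the class: broad iff SI < ``si_threshold`` (strictly below; SI
    exactly at the threshold is narrow). ``alt_shape`` is 1 when any
    alternative cluster's class differs from the major one.

    ``human_width`` route: per-dataset (tissue) classes from the
    inter-percentile width against ``width_threshold`` (fit one with
    :func:`fit_two_component_mixture` on ``(width - 1) / 10`` if not given);
    aggregates ``mean_promoter_width`` and ``percent_of_broad`` over
    datasets with signal.

    Genes without any passing cluster are absent from the result (class
    missing, not narrow/broad by default).
    """
    assigned = _assign_clusters(clusters, annotation, upstream, downstream)
    if assigned.empty:
        return pd.DataFrame(
            columns=["shape_index", "width", "promoter_class", "alt_shape"]
        )
    if route == "fly_SI":
        rows = {}
        for gene, grp in assigned.groupby("gene_id"):
            grp = grp.sort_values(["signal", "start"], ascending=[False, True])
            major = grp.iloc[0]
            cls = "broad" if major["shape_index"] < si_threshold else "narrow"
            alt = 0
            for _, r in grp.iloc[1:].iterrows():
                alt_cls = "broad" if r["shape_index"] < si_threshold else "narrow"
                if alt_cls != cls:
                    alt = 1
            rows[gene] = {
                "shape_index": major["shape_index"],
                "width": major["width"],
                "promoter_class": cls,
                "alt_shape": alt,
                "n_clusters": len(grp),
            }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")
    if route == "human_width":
        if width_threshold is None:
            fit = fit_two_component_mixture(
                assigned["width"].to_numpy(),
                family="gamma",
                transform=lambda w: (w - 1) / 10 + 1e-9,
                seed=seed,
            )
            width_threshold = fit.separation_threshold * 10 + 1
        rows = {}
        for gene, grp in assigned.groupby("gene_id"):
            per_ds = grp.sort_values(["signal", "start"], ascending=[False, True])
            per_ds = per_ds.groupby("dataset").first()
            classes = per_ds["width"] > width_threshold  # broad = wide
            rows[gene] = {
                "mean_promoter_width": float(per_ds["width"].mean()),
                "percent_of_broad": float(classes.mean()),
                "promoter_class": "broad" if classes.mean() > 0.5 else "narrow",
                "n_tissues_with_signal": len(per_ds),
                "width_threshold": width_threshold,
            }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")
    raise ValueError("route must be 'fly_SI' or 'human_width'")
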