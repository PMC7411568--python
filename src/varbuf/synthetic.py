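"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a population expression study: negative-binomial
counts for a panel of inbred lines with gene-specific dispersion driven by
genomically encoded features, CAGE-like TSS tag distributions (narrow vs
broad initiation), condition-labelled interval tracks consistent with the
feature table, and differential-expression labels whose probability is a
logistic function of the true residual dispersion. Full ground truth is
recorded so every downstream stage can be tested for parameter recovery.

Model
-----
Counts are NB with variance ``mu + alpha * mu**2``. The log dispersion is

    ln alpha_g = a0 + a1 * ln mu_g + r_g

where ``r_g`` (the *true residual dispersion*) is a centered linear
combination of standardized causal feature values plus Gaussian noise:
``r_g = sum_k beta_k * z_gk + eps_g - mean(.)``. Decoy features are drawn
from the same marginal families but carry no effect. Because ``alpha``
decreases with ``mu`` (``a1 < 0``) the binned CV-vs-median curve decreases,
matching the empirical mean-CV relationship.

All randomness flows from ``SimConfig.seed`` through named sub-streams
(one per operation), so stages regenerate independently and byte-identically.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .util import rng
from .variation import CountMatrix

__all__ = [
    "FeatureSpec",
    "SimConfig",
    "SimData",
    "default_feature_spec",
    "simulate_counts",
    "simulate_gene_features",
    "simulate_tss_tags",
    "simulate_de_labels",
    "simulate_all",
    "DHS_CONDITIONS",
]


@dataclasses.dataclass(frozen=True)
class FeatureSpec:
    """One simulated gene feature.

    ``kind``: "binary" (param = prevalence), "count" (param = Poisson rate,
    optionally capped), "continuous" (param = lognormal sigma; 0 -> standard
    normal). ``beta`` is the effect on log-dispersion per SD of the feature;
    0 marks a decoy. ``cap`` bounds count features (e.g. 19 DHS conditions).
    ``track`` marks features materialized as interval tracks.
    """

    name: str
    kind: str
    param: float
    beta: float = 0.0
    cap: int | None = None
    track: str | None = None

    @property
    def causal(self) -> bool:
        return self.beta != 0.0


def default_feature_spec() -> list[FeatureSpec]:
    """10 causal features + 90 decoys (9:1), causal effects fixed once.

    The causal set mirrors the regulatory-complexity axes of the analysis:
    promoter-proximal accessibility/occupancy (negative effects: more
    regulation, less variation), distal accessibility, post-transcriptional
    repression (miRNA), Pol II pausing, housekeeping status and broad
    initiation (negative), and TATA-box / 3'UTR variant load (positive).
    """
    causal = [
        FeatureSpec("num_dhs_conditions.prox", "count", 6.0, -0.30, cap=19, track="dhs_prox"),
        FeatureSpec("num_tf_peaks.prox", "count", 8.0, -0.20, cap=40, track="tf_prox"),
        FeatureSpec("num_tf_motifs.prox", "count", 10.0, -0.15, cap=60, track="motif_prox"),
        FeatureSpec("num_dhs_any.dist", "count", 5.0, -0.20, cap=30, track="dhs_dist"),
        FeatureSpec("num_mirna", "count", 20.0, -0.25),
        FeatureSpec("pausing_index", "continuous", 1.0, -0.25),
        FeatureSpec("tata_box", "binary", 0.15, 0.35),
        FeatureSpec("is_housekeeping", "binary", 0.20, -0.30),
        FeatureSpec("broad_promoter", "binary", -1.0, -0.30),  # param unused; frac_broad
        FeatureSpec("utr3_variant_index", "continuous", 0.5, 0.15),
    ]
    decoys = []
    for i in range(90):
        kind = ("binary", "count", "continuous")[i % 3]
        param = {"binary": 0.2, "count": 5.0, "continuous": 0.0}[kind]
        decoys.append(FeatureSpec(f"decoy_{i:03d}", kind, param, 0.0))
    return causal + decoys


#: 19-condition open-chromatin vocabulary: whole embryo (WE) at five
#: timepoints, three sorted tissues at four timepoints (the 12 "sorted"
#: conditions defining ubiquitous accessibility), and two 6-8 h extras.
def _dhs_conditions() -> pd.DataFrame:
    rows = []
    times = ["2-4h", "4-6h", "6-8h", "8-10h", "10-12h"]
    early = {"2-4h", "4-6h", "6-8h"}
    for t in times:
        rows.append(("WE_" + t, "WE", t))
    for tissue in ["meso", "neuro", "dn"]:
        for t in times[1:]:
            rows.append((f"{tissue}_{t}", "tissue", t))
    rows.append(("vm_pos_6-8h", "tissue", "6-8h"))
    rows.append(("vm_neg_6-8h", "tissue", "6-8h"))
    df = pd.DataFrame(rows, columns=["condition", "tissue_group", "time_group"])
    df["time_class"] = np.where(df["time_group"].isin(early), "early", "late")
    df["sorted12"] = df["condition"].str.match(r"(meso|neuro|dn)_")
    return df.set_index("condition")


DHS_CONDITIONS = _dhs_conditions()


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the generator (defaults = default study design)."""

    n_genes: int = 4000
    n_samples: int = 75
    n_timepoints: int = 3
    seed: int = 0
    mean_log_mu: float = 4.0
    mean_log_sigma: float = 1.5
    disp_baseline: tuple[float, float] = (-0.5, -0.25)  # (a0, a1) on ln scale
    feature_spec: Sequence[FeatureSpec] = dataclasses.field(
        default_factory=default_feature_spec
    )
    disp_noise_sd: float = 0.25
    frac_broad: float = 0.4
    decay_frac: float = 0.4
    de_coupling: tuple[float, float] = (-1.0, 2.0)  # (gamma0, gamma1)
    size_factor_sd: float = 0.1
    min_promoter_tags: int = 50

    def __post_init__(self):
        if min(self.n_genes, self.n_samples, self.n_timepoints) <= 0:
            raise ValueError("n_genes, n_samples and n_timepoints must be positive")
        if not 0 <= self.frac_broad <= 1:
            raise ValueError("frac_broad must be in [0, 1]")
        if not 0 <= self.decay_frac <= 1:
            raise ValueError("decay_frac must be in [0, 1]")
        names = [f.name for f in self.feature_spec]
        if len(names) != len(set(names)):
            raise ValueError("feature names collide")

    @property
    def timepoints(self) -> list[str]:
        return [f"t{i}" for i in range(self.n_timepoints)]

    @property
    def focal_timepoint(self) -> str:
        return self.timepoints[-1]

    @property
    def early_timepoint(self) -> str:
        return self.timepoints[0]


# ---------------------------------------------------------------------------
# Counts + truth
# ---------------------------------------------------------------------------

def _draw_feature(spec: FeatureSpec, n: int, gen: np.random.Generator) -> np.ndarray:
    if spec.kind == "binary":
        return gen.binomial(1, spec.param, size=n).astype(float)
    if spec.kind == "count":
        x = gen.poisson(spec.param, size=n).astype(float)
        if spec.cap is not None:
            x = np.minimum(x, spec.cap)
        return x
    if spec.kind == "continuous":
        if spec.param > 0:
            return gen.lognormal(0.0, spec.param, size=n)
        return gen.normal(0.0, 1.0, size=n)
    raise ValueError(f"unknown feature kind {spec.kind!r}")


def _nb_counts(mean: np.ndarray, alpha: np.ndarray, gen: np.random.Generator) -> np.ndarray:
    """NB(mean, dispersion alpha) with var = mean + alpha*mean^2; Poisson limit."""
    out = np.empty_like(mean)
    tiny = alpha < 1e-8
    if tiny.any():
        out[tiny] = gen.poisson(mean[tiny])
    big = ~tiny
    if big.any():
        size = 1.0 / alpha[big]
        p = size / (size + mean[big])
        out[big] = gen.negative_binomial(size, p)
    return out


def simulate_counts(config: SimConfig):
    """Draw per-timepoint count matrices and the ground-truth table.

    Returns ``(counts, truth)`` where ``counts`` maps timepoint ->
    :class:`CountMatrix` and ``truth`` is a per-gene DataFrame with true
    means, dispersion, residual dispersion, feature values and flags.
    """
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    gen_mean = rng(config.seed, "means")
    mu = gen_mean.lognormal(config.mean_log_mu, config.mean_log_sigma, config.n_genes)

    cols: dict[str, np.ndarray] = {}
    gen_feat = rng(config.seed, "features")
    is_broad = gen_feat.random(config.n_genes) < config.frac_broad
    zsum = np.zeros(config.n_genes)
    for spec in config.feature_spec:
        if spec.name == "broad_promoter":
            vals = is_broad.astype(float)
        else:
            vals = _draw_feature(spec, config.n_genes, rng(config.seed, "feature", spec.name))
        cols[spec.name] = vals
        if spec.causal:
            sd = vals.std()
            z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
            zsum += spec.beta * z
    eps = rng(config.seed, "disp_noise").normal(0.0, config.disp_noise_sd, config.n_genes)
    r = zsum + eps
    r -= r.mean()  # zero-mean residual dispersion by construction

    a0, a1 = config.disp_baseline
    log_alpha = a0 + a1 * np.log(mu) + r
    alpha = np.exp(log_alpha)

    # decay genes lose expression towards the focal stage (maternal-like);
    # the rest drift mildly upwards (zygotic activation), so the
    # decreasing-gene filter targets the decay class rather than noise
    gen_decay = rng(config.seed, "decay")
    decays = gen_decay.random(config.n_genes) < config.decay_frac
    decay_factor = np.where(
        decays,
        gen_decay.uniform(0.2, 0.8, config.n_genes),
        gen_decay.uniform(1.1, 1.5, config.n_genes),
    )

    cols["true_dispersion"] = alpha
    cols["true_residual_dispersion"] = r
    cols["is_broad"] = is_broad
    cols["is_decay"] = decays
    cols["decay_factor"] = decay_factor

    counts: dict[str, CountMatrix] = {}
    T = config.n_timepoints
    for ti, tp in enumerate(config.timepoints):
        frac = ti / (T - 1) if T > 1 else 1.0
        mu_t = mu * decay_factor**frac
        cols[f"true_mean_{tp}"] = mu_t
        sf = rng(config.seed, "sizefactors", tp).lognormal(
            0.0, config.size_factor_sd, config.n_samples
        )
        gen_c = rng(config.seed, "counts", tp)
        mean_mat = mu_t[:, None] * sf[None, :]
        alpha_mat = np.broadcast_to(alpha[:, None], mean_mat.shape)
        arr = _nb_counts(np.ascontiguousarray(mean_mat, dtype=float),
                         np.ascontiguousarray(alpha_mat, dtype=float), gen_c)
        sample_ids = [f"line{j:03d}_{tp}" for j in range(config.n_samples)]
        cm = pd.DataFrame(arr.astype(np.int64),
                          index=pd.Index(genes, name="gene_id"),
                          columns=sample_ids)
        meta = pd.DataFrame(
            {
                "line": [f"line{j:03d}" for j in range(config.n_samples)],
                "timepoint": tp,
                "batch": "b0",
                "true_size_factor": sf,
            },
            index=cm.columns,
        )
        counts[tp] = CountMatrix(cm, meta)
    truth = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return counts, truth


# ---------------------------------------------------------------------------
# Annotation, tracks and the emitted feature table
# ---------------------------------------------------------------------------

_CONTIGS = ["chr2L", "chr2R", "chr3L", "chr3R", "chrX"]
_GENE_SPACING = 30_000  # > 2x the 10 kb distal window: no track leakage
_PROX_BP = 500
_DIST_BP = 10_000


def simulate_gene_features(config: SimConfig, truth: pd.DataFrame):
    """Materialize annotation, TADs and interval tracks consistent with truth.

    Track-derived feature counts (proximal DHS conditions, TF peaks, motifs,
    distal DHSs) are placed as intervals inside each gene's windows so that
    the feature-assembly rules recover the emitted values exactly. Genes are
    spaced 30 kb apart on five contigs; TADs partition each contig.

    Returns ``(feature_table, tracks, annotation, tads)``; also attaches
    contig/tss/strand columns to ``truth`` (in place) for later stages.
    """
    gen = rng(config.seed, "geometry")
    genes = truth.index
    n = len(genes)
    contigs = np.array([_CONTIGS[i % len(_CONTIGS)] for i in range(n)])
    pos_on_contig = np.array([i // len(_CONTIGS) for i in range(n)])
    tss = 50_000 + pos_on_contig * _GENE_SPACING  # 1-based
    strand = np.where(gen.random(n) < 0.5, "+", "-")
    span = gen.integers(1_000, 8_000, n)
    start = np.where(strand == "+", tss, tss - span)
    end = np.where(strand == "+", tss + span, tss)
    utr_w = np.maximum(50, gen.lognormal(5.5, 0.8, n).astype(int))

    annotation = pd.DataFrame(
        {
            "contig": contigs,
            "strand": strand,
            "tss": tss,
            "start": start,
            "end": end,
            "utr3_width": utr_w,
            "arm": contigs,
        },
        index=genes,
    )
    truth["contig"] = contigs
    truth["tss"] = tss
    truth["strand"] = strand

    # TAD partition per contig
    tad_rows = []
    gen_tad = rng(config.seed, "tads")
    for contig in _CONTIGS:
        c_tss = annotation.loc[annotation["contig"] == contig, "tss"]
        if c_tss.empty:
            continue
        limit = int(c_tss.max()) + 60_000
        pos = 0
        k = 0
        while pos < limit:
            size = int(gen_tad.integers(50_000, 150_000))
            tad_rows.append((f"{contig}_tad{k:03d}", contig, pos, min(pos + size, limit)))
            pos += size
            k += 1
    tads = pd.DataFrame(tad_rows, columns=["tad_id", "contig", "start", "end"]).set_index(
        "tad_id"
    )

    # interval tracks (0-based half-open), placed strictly inside windows
    track_specs = {f.track: f for f in config.feature_spec if f.track}
    tracks: dict[str, pd.DataFrame] = {}
    conds = DHS_CONDITIONS.index.to_numpy()
    gen_trk = rng(config.seed, "tracks")

    dhs_rows = []
    for g, contig, t in zip(genes, contigs, tss):
        t0 = int(t) - 1
        if "dhs_prox" in track_specs:
            c = int(truth.at[g, "num_dhs_conditions.prox"])
            chosen = gen_trk.choice(conds, size=c, replace=False) if c else []
            for j, cond in enumerate(chosen):
                s = t0 - 400 + (j % 8) * 90
                dhs_rows.append((contig, s, s + 60, cond))
        if "dhs_dist" in track_specs:
            d = int(truth.at[g, "num_dhs_any.dist"])
            for j in range(d):
                s = t0 + 600 + j * 250
                cond = conds[int(gen_trk.integers(len(conds)))]
                dhs_rows.append((contig, s, s + 120, cond))
    tracks["dhs"] = pd.DataFrame(dhs_rows, columns=["contig", "start", "end", "condition"])

    if "tf_prox" in track_specs:
        tf_rows = []
        for g, contig, t in zip(genes, contigs, tss):
            t0 = int(t) - 1
            k = int(truth.at[g, "num_tf_peaks.prox"])
            for j in range(k):
                s = t0 - 450 + (j % 12) * 70
                tf_rows.append((contig, s, s + 40, f"TF_{j:03d}"))
        tracks["tf_peaks"] = pd.DataFrame(
            tf_rows, columns=["contig", "start", "end", "condition"]
        )

    if "motif_prox" in track_specs:
        mt_rows = []
        for g, contig, t in zip(genes, contigs, tss):
            t0 = int(t) - 1
            k = int(truth.at[g, "num_tf_motifs.prox"])
            for j in range(k):
                s = t0 - 480 + (j % 24) * 40
                mt_rows.append((contig, s, s + 10, f"MOTIF_{j:03d}"))
        tracks["tf_motifs"] = pd.DataFrame(
            mt_rows, columns=["contig", "start", "end", "condition"]
        )

    feat_cols = [f.name for f in config.feature_spec]
    feature_table = truth[feat_cols].copy()
    meta = pd.DataFrame(
        {
            "feature": feat_cols,
            "kind": [f.kind for f in config.feature_spec],
            "causal": [f.causal for f in config.feature_spec],
            "beta": [f.beta for f in config.feature_spec],
            "track": [f.track or "" for f in config.feature_spec],
        }
    ).set_index("feature")
    feature_table.attrs["meta"] = meta
    return feature_table, tracks, annotation, tads


# ---------------------------------------------------------------------------
# TSS tags
# ---------------------------------------------------------------------------

def simulate_tss_tags(config: SimConfig, truth: pd.DataFrame, dataset: str = "embryo"):
    """CTSS-style tag counts: narrow genes over 1-5 adjacent positions, broad
    genes spread over 40-100 positions (Dirichlet weights keep broad promoters
    high-entropy so the shape-index threshold separates the classes)."""
    if "tss" not in truth.columns:
        raise ValueError("truth lacks coordinates; run simulate_gene_features first")
    gen = rng(config.seed, "tss_tags")
    rows = []
    for g, row in truth.iterrows():
        broad = bool(row["is_broad"])
        L = int(gen.integers(40, 101)) if broad else int(gen.integers(1, 6))
        total = config.min_promoter_tags + int(gen.poisson(150))
        w = gen.dirichlet(np.full(L, 1.5 if broad else 0.8))
        counts = gen.multinomial(total, w)
        base = int(row["tss"])
        for i, c in enumerate(counts):
            if c > 0:
                rows.append((row["contig"], base + i, row["strand"], int(c), dataset, g))
    return pd.DataFrame(
        rows, columns=["contig", "pos", "strand", "count", "dataset", "gene_id"]
    )


# ---------------------------------------------------------------------------
# DE labels
# ---------------------------------------------------------------------------

def simulate_de_labels(
    truth: pd.DataFrame,
    de_coupling: tuple[float, float],
    n_studies: int,
    seed: int,
) -> pd.DataFrame:
    """Per-study DE labels: P(DE) = logistic(gamma0 + gamma1 * r_g).

    Labels are independent across studies given ``r_g``. Returns a long
    DataFrame (study, gene_id, is_de); ``de_prob`` is attached to ``truth``.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    g0, g1 = de_coupling
    r = truth["true_residual_dispersion"].to_numpy()
    prob = expit(g0 + g1 * r)
    truth["de_prob"] = prob
    gen = rng(seed, "de_labels")
    frames = []
    for s in range(n_studies):
        lab = gen.random(len(r)) < prob
        frames.append(
            pd.DataFrame(
                {"study": f"study{s:02d}", "gene_id": truth.index, "is_de": lab}
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclasses.dataclass
class SimData:
    """Bundle of everything one simulation produces."""

    config: SimConfig
    counts: dict
    truth: pd.DataFrame
    features: pd.DataFrame
    tracks: dict
    annotation: pd.DataFrame
    tads: pd.DataFrame
    tss_tags: pd.DataFrame
    de_studies: pd.DataFrame


def simulate_all(config: SimConfig, n_studies: int = 5) -> SimData:
    """Run the four generator operations in order."""
    counts, truth = simulate_counts(config)
    features, tracks, annotation, tads = simulate_gene_features(config, truth)
    tags = simulate_tss_tags(config, truth)
    de = simulate_de_labels(truth, config.de_coupling, n_studies, config.seed)
    return SimData(config, counts, truth, features, tracks, annotation, tads, tags, de)
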