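"""Stage wiring, configuration, fixtures and end-to-end runs.

A pipeline run executes the stages in dependency order on one synthetic (or
user-supplied) dataset: simulate -> variation -> promshape -> features ->
strata -> model -> transfer. Every stage writes plain-text TSV outputs with
a header comment recording package version, seed and parameters, and the
run produces a machine-readable ``report.json``. The report is fully
deterministic for a fixed config and seed (timings go to the log, not the
report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import assemble_feature_table, count_track_overlaps, make_tss_windows, _distal_windows
from .model import boruta_select, permutation_null, rf_regression_cv
from .promoters import classify_gene_promoters, cluster_tss
from .strat_stats import regulatory_indices, stratify_genes
from .synthetic import SimConfig, simulate_all
from .transfer import DEStudySet, de_effect_scan, transfer_protocol
from .util import child_seed
from .variation import expression_summary, filter_genes, normalize_counts, summarize_expression

log = logging.getLogger("varbuf")

STAGES = ("simulate", "variation", "promshape", "features", "strata", "model", "transfer")

#: reduced-size end-to-end profile used by `varbuf run` by default
DEFAULT_PIPELINE_CONFIG: dict = {
    "stages": list(STAGES),
    "sim": {"n_genes": 1200, "n_samples": 40, "n_timepoints": 2},
    "n_studies": 5,
    "variation": {"span": 0.75, "metric": "cv", "pct": 0.05},
    "model": {"boruta_trees": 60, "boruta_max_runs": 60, "rf_trees": 200},
    "transfer": {"rounds": 5, "trees": 200, "top_frac": 0.3},
}


def _write_tsv(df: pd.DataFrame, path: Path, seed, params: dict | None = None,
               index_label: str | None = None):
    header = f"# varbuf {__version__} seed={seed}"
    if params:
        header += " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_tsv(path) -> pd.DataFrame:
    """Read a varbuf TSV (skipping header comments), first column as index."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_bed(df: pd.DataFrame, path: Path, name_col: str = "condition",
              score_col: str | None = None):
    """0-based half-open intervals as BED (name = condition/label)."""
    out = pd.DataFrame(
        {
            "chrom": df["contig"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": df[name_col] if name_col in df.columns else ".",
            "score": df[score_col] if score_col and score_col in df.columns else 0,
        }
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "contig", 1: "start", 2: "end", 3: "condition", 4: "score"})
    return df


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def validate_config(config: dict) -> dict:
    cfg = {**DEFAULT_PIPELINE_CONFIG, **(config or {})}
    unknown = [s for s in cfg["stages"] if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}; valid stages: {list(STAGES)}")
    # dependency closure: every stage needs everything before it
    order = [s for s in STAGES if s in cfg["stages"]]
    for i, s in enumerate(order):
        need = STAGES[: STAGES.index(s)]
        missing = [d for d in need if d not in order]
        if missing:
            raise ValueError(f"stage {s!r} requires earlier stage(s) {missing}")
    cfg["stages"] = order
    return cfg


def run_pipeline(config: dict | None, seed: int, outdir) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    cfg = validate_config(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": seed, "stages": cfg["stages"]}
    t_start = time.time()

    sim_cfg = SimConfig(seed=seed, **cfg["sim"])
    data = simulate_all(sim_cfg, n_studies=cfg["n_studies"])
    focal, early = sim_cfg.focal_timepoint, sim_cfg.early_timepoint
    _write_tsv(data.counts[focal].counts, outdir / "counts.tsv", seed,
               index_label="gene_id")
    _write_tsv(data.truth, outdir / "truth.tsv", seed, index_label="gene_id")
    _write_tsv(data.annotation, outdir / "annotation.tsv", seed, index_label="gene_id")
    _write_tsv(data.tss_tags.set_index("contig"), outdir / "ctss.tsv", seed)
    for name, trk in data.tracks.items():
        write_bed(trk, outdir / f"track_{name}.bed")
    report["simulate"] = {
        "n_genes": sim_cfg.n_genes,
        "n_samples": sim_cfg.n_samples,
        "n_timepoints": sim_cfg.n_timepoints,
    }
    log.info("simulate done (%.1fs)", time.time() - t_start)
    if "variation" not in cfg["stages"]:
        return _finish(report, outdir)

    vp = cfg["variation"]
    summaries = {}
    norms = {}
    for tp, cm in data.counts.items():
        _, norm = normalize_counts(cm)
        norms[tp] = norm
        summaries[tp] = summarize_expression(norm, tp)
    flags = filter_genes(summaries, focal, early, pct=vp.get("pct", 0.05))
    retained = flags.index[flags["retained"]]
    summary = expression_summary(norms[focal].loc[retained], span=vp.get("span", 0.75))
    _write_tsv(summary.join(flags), outdir / "expression_summary.tsv", seed,
               params=vp, index_label="gene_id")
    resid = summary["resid_cv"].dropna()
    truth_r = data.truth["true_residual_dispersion"]
    from scipy.stats import spearmanr

    report["variation"] = {
        "filter_counts": {c: int(flags[c].sum()) for c in flags.columns},
        "n_retained": int(len(retained)),
        "spearman_vs_truth": round(float(
            spearmanr(resid, truth_r.loc[resid.index]).statistic), 6),
    }
    if "promshape" not in cfg["stages"]:
        return _finish(report, outdir)

    clusters = cluster_tss(data.tss_tags, max_dist=20, min_cluster_signal=10)
    calls = classify_gene_promoters(clusters, data.annotation, route="fly_SI")
    _write_tsv(calls, outdir / "promoter_calls.tsv", seed, index_label="gene_id")
    truth_broad = data.truth["is_broad"].reindex(calls.index)
    acc = float(((calls["promoter_class"] == "broad") == truth_broad).mean())
    report["promshape"] = {
        "n_genes_called": int(len(calls)),
        "broad_fraction": round(float((calls["promoter_class"] == "broad").mean()), 6),
        "accuracy_vs_truth": round(acc, 6),
    }
    if "features" not in cfg["stages"]:
        return _finish(report, outdir)

    prox = make_tss_windows(data.annotation, 500, 500)
    dist = _distal_windows(data.annotation)
    recomputed = pd.DataFrame(index=data.annotation.index)
    recomputed["num_dhs_conditions.prox"] = count_track_overlaps(
        data.tracks["dhs"], prox, "conditions")
    recomputed["num_dhs_any.dist"] = count_track_overlaps(
        data.tracks["dhs"], dist, "count")
    if "tf_peaks" in data.tracks:
        recomputed["num_tf_peaks.prox"] = count_track_overlaps(
            data.tracks["tf_peaks"], prox, "conditions")
    if "tf_motifs" in data.tracks:
        recomputed["num_tf_motifs.prox"] = count_track_overlaps(
            data.tracks["tf_motifs"], prox, "conditions")
    scalar_cols = [c for c in data.features.columns if c not in recomputed.columns]
    table, meta, dropped = assemble_feature_table(
        {"tracks": recomputed, "scalars": data.features[scalar_cols]},
    )
    mismatch = int(
        (table[recomputed.columns] != data.features[recomputed.columns]).sum().sum()
    )
    _write_tsv(table, outdir / "features.tsv", seed, index_label="gene_id")
    _write_tsv(meta, outdir / "feature_meta.tsv", seed)
    report["features"] = {
        "n_features": int(table.shape[1]),
        "n_genes": int(table.shape[0]),
        "n_dropped": int(len(dropped)),
        "track_roundtrip_mismatches": mismatch,
    }
    if "strata" not in cfg["stages"]:
        return _finish(report, outdir)

    strata = stratify_genes(calls, resid)
    indices = regulatory_indices(table, seed=child_seed(seed, "indices"))
    _write_tsv(strata, outdir / "strata.tsv", seed, index_label="gene_id")
    _write_tsv(indices, outdir / "indices.tsv", seed, index_label="gene_id")
    report["strata"] = {
        "counts": {k: int(v) for k, v in
                   strata["stratum"].value_counts().sort_index().items()},
        "narrow_median_cut": round(float(strata.attrs["narrow_median_cut"]), 6),
    }
    if "model" not in cfg["stages"]:
        return _finish(report, outdir)

    mp = cfg["model"]
    model_genes = resid.index.intersection(table.index)
    meta_tbl = data.features.attrs["meta"]
    model_cols = list(meta_tbl.index)  # causal + decoys
    Xm = table.loc[model_genes, model_cols]
    ym = resid.loc[model_genes]
    bres = boruta_select(
        Xm, ym, n_trees=mp.get("boruta_trees", 100),
        max_runs=mp.get("boruta_max_runs", 100), seed=child_seed(seed, "boruta"),
    )
    _write_tsv(bres.table, outdir / "boruta.tsv", seed)
    selected = bres.confirmed or list(
        meta_tbl.index[meta_tbl["causal"]])  # fallback for tiny demo runs
    ev = rf_regression_cv(Xm[selected], ym, trees=mp.get("rf_trees", 500),
                          seed=child_seed(seed, "rf"))
    null = permutation_null(Xm[selected], ym, seed=child_seed(seed, "null"),
                            trees=mp.get("rf_trees", 500))
    eval_df = pd.DataFrame(
        [
            {"model": "resid_cv", "r2_pooled": ev.r2_pooled, "r2_mean": ev.r2_mean,
             "r2_sd": ev.r2_sd, "n": ev.n},
            {"model": "permuted", "r2_pooled": null.r2_pooled, "r2_mean": null.r2_mean,
             "r2_sd": null.r2_sd, "n": null.n},
        ]
    ).set_index("model")
    _write_tsv(eval_df, outdir / "eval.tsv", seed, params=mp)
    causal = set(meta_tbl.index[meta_tbl["causal"]])
    report["model"] = {
        "n_confirmed": len(bres.confirmed),
        "n_causal_confirmed": len(causal & set(bres.confirmed)),
        "n_decoy_confirmed": len(set(bres.confirmed) - causal),
        "boruta_runs": bres.runs,
        "r2_pooled": round(ev.r2_pooled, 6),
        "r2_null": round(null.r2_pooled, 6),
        "selected": sorted(selected),
    }
    if "transfer" not in cfg["stages"]:
        return _finish(report, outdir)

    tp_cfg = cfg["transfer"]
    studies = DEStudySet.from_long(data.de_studies)
    scan = de_effect_scan(resid, studies)
    # transfer target: one study's DE set (union over many coupled studies
    # saturates towards all-DE)
    first = studies[0]
    de_first = pd.Series(0, index=model_genes)
    de_first[de_first.index.isin(first.de_genes)] = 1
    tr = transfer_protocol(
        Xm[selected], ym, de_first, rounds=tp_cfg.get("rounds", 10),
        trees=tp_cfg.get("trees", 500), top_frac=tp_cfg.get("top_frac", 0.3),
        seed=child_seed(seed, "transfer"),
    )
    _write_tsv(
        pd.DataFrame({"auc": tr.aucs}).rename_axis("round"),
        outdir / "transfer.tsv", seed, params=tp_cfg,
    )
    _write_tsv(scan, outdir / "de_effects.tsv", seed)
    report["transfer"] = {
        "median_auc": round(tr.median_auc, 6),
        "aucs": [round(a, 6) for a in tr.aucs],
        "share_studies_d_above_0.2": round(
            float(scan.attrs["share_d_above_threshold"]), 6),
    }
    return _finish(report, outdir)


def _finish(report: dict, outdir: Path) -> dict:
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("report written to %s", path)
    return report


# ---------------------------------------------------------------------------
# Fixture registry
# ---------------------------------------------------------------------------

def _fixture_filter_ladder() -> dict:
    """20 genes, two timepoints, 5 identical samples each (factors all 1).

    Focal medians 0..19; pct=0.1 cuts one gene at each extreme after the
    zero-median rule; g05 and g10 decrease from the early timepoint.
    Expected retained: g02..g18 minus {g05, g10}.
    """
    genes = [f"g{i:02d}" for i in range(20)]
    focal_vals = np.arange(20)
    early_vals = focal_vals.copy()
    early_vals[5] = 10  # g05: 10 -> 5, decreasing
    early_vals[10] = 15  # g10: 15 -> 10, decreasing
    focal = pd.DataFrame(
        np.repeat(focal_vals[:, None], 5, axis=1),
        index=genes, columns=[f"s{j}_late" for j in range(5)],
    )
    early = pd.DataFrame(
        np.repeat(early_vals[:, None], 5, axis=1),
        index=genes, columns=[f"s{j}_early" for j in range(5)],
    )
    retained = [f"g{i:02d}" for i in range(2, 19) if i not in (5, 10)]
    return {
        "counts_late.tsv": focal,
        "counts_early.tsv": early,
        "expected_retained.tsv": pd.DataFrame({"gene_id": retained}).set_index("gene_id"),
        "params": {"pct": 0.1},
    }


def _fixture_overlap_enum() -> dict:
    """7 intervals across 3 conditions vs 2 genes; hand-enumerated counts."""
    track = pd.DataFrame(
        {
            "contig": ["chr1"] * 6 + ["chr2"],
            "start": [450, 499, 1499, 1500, 5400, 4400, 100],
            "end": [499, 520, 1600, 1600, 5600, 4500, 200],
            "condition": ["condA", "condA", "condB", "condB", "condC", "condA", "condB"],
        }
    )
    ann = pd.DataFrame(
        {"contig": ["chr1", "chr1"], "strand": ["+", "+"], "tss": [1000, 5000]},
        index=["gene1", "gene2"],
    )
    expected = pd.DataFrame(
        {"count": [2, 2], "conditions": [2, 2]}, index=["gene1", "gene2"]
    ).rename_axis("gene_id")
    return {"track.bed": track, "annotation.tsv": ann, "expected_counts.tsv": expected,
            "params": {"upstream": 500, "downstream": 500}}


def _fixture_rank_index() -> dict:
    """4 genes, tie-free feature triples; hand-computed normalized ranks."""
    feats = pd.DataFrame(
        {
            "num_dhs_conditions.prox": [1, 2, 3, 4],
            "num_tf_peaks.prox": [4, 3, 2, 1],
            "num_tf_motifs.prox": [1, 3, 2, 4],
            "num_dhs_any.dist": [1, 2, 3, 4],
            "num_mirna": [1, 2, 3, 4],
            "pausing_index": [1.0, 2.0, 3.0, 4.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    expected = pd.DataFrame(
        {
            "broad_index": [0.5, 2 / 3, 0.5833333333333334, 0.75],
            "narrow_index": [0.25, 0.5, 0.75, 1.0],
        },
        index=["g1", "g2", "g3", "g4"],
    ).rename_axis("gene_id")
    return {"features.tsv": feats, "expected_indices.tsv": expected, "params": {}}


def _fixture_auc_tie() -> dict:
    """Tied-score AUC case: scores (0.1, 0.4, 0.4, 0.8) vs labels (0,0,1,1)."""
    df = pd.DataFrame({"score": [0.1, 0.4, 0.4, 0.8], "label": [0, 0, 1, 1]})
    expected = pd.DataFrame({"auc": [0.875]})
    return {"scores.tsv": df, "expected_auc.tsv": expected, "params": {}}


FIXTURES = {
    "filter_ladder": _fixture_filter_ladder,
    "overlap_enum": _fixture_overlap_enum,
    "rank_index": _fixture_rank_index,
    "auc_tie": _fixture_auc_tie,
}


def generate_fixture(name: str, outdir=None) -> dict:
    """Build a registered hand-built fixture; optionally write its files."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; registry: {sorted(FIXTURES)}")
    data = FIXTURES[name]()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for fname, obj in data.items():
            if isinstance(obj, pd.DataFrame):
                if fname.endswith(".bed"):
                    write_bed(obj, outdir / fname)
                else:
                    obj.to_csv(outdir / fname, sep="\t")
        with open(outdir / "params.json", "w") as fh:
            json.dump(data.get("params", {}), fh, sort_keys=True)
    return data
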