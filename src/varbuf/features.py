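"""Gene x feature table assembly from annotation, interval tracks and scalars.

Coordinate conventions: intervals are 0-based half-open internally (BED
read as-is); the annotation's TSS column is 1-based and converted on use.
Overlap requires at least one shared base pair. Strand-aware windows mirror
on the minus strand, so symmetric windows are strand-independent.

Feature classes follow the analysis's seven groups (Genetics, Gene type,
Gene body, TSS, 3'UTR, Distal regulators, Gene context). Missing values in
imputable presence/count features are zero-filled during assembly; genes
missing non-imputable features are dropped and reported.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "make_tss_windows",
    "count_track_overlaps",
    "dhs_condition_summaries",
    "gc_content",
    "utr3_variant_index",
    "genomic_context_features",
    "aggregate_tissue_features",
    "assemble_feature_table",
    "PROX_BP",
    "DIST_BP",
]

PROX_BP = 500
DIST_BP = 10_000


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def make_tss_windows(
    annotation: pd.DataFrame, upstream: int, downstream: int
) -> pd.DataFrame:
    """Strand-aware [-upstream, +downstream] windows around the 1-based TSS.

    Emitted 0-based half-open: a + strand gene with TSS t covers 1-based
    ``t-upstream .. t+downstream``, i.e. ``[t-1-upstream, t+downstream)``;
    minus-strand windows are mirrored. Windows running off the contig start
    are clipped (logged).
    """
    tss = annotation["tss"].to_numpy(dtype=np.int64)
    plus = (annotation["strand"] == "+").to_numpy()
    start = np.where(plus, tss - 1 - upstream, tss - 1 - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    clipped = start < 0
    if clipped.any():
        log.warning("clipped %d windows at contig start", int(clipped.sum()))
        start = np.maximum(start, 0)
    return pd.DataFrame(
        {"contig": annotation["contig"].to_numpy(), "start": start, "end": end},
        index=annotation.index,
    )


# ---------------------------------------------------------------------------
# Overlap engine
# ---------------------------------------------------------------------------

def _overlap_counts_1d(
    istart: np.ndarray, iend: np.ndarray, wstart: np.ndarray, wend: np.ndarray
) -> np.ndarray:
    """Per-window count of intervals with >= 1 bp intersection.

    Intervals [s,e) and window [ws,we) overlap iff s < we and e > ws;
    count = N - #(e <= ws) - #(s >= we) via sorted endpoint arrays.
    """
    s_sorted = np.sort(istart)
    e_sorted = np.sort(iend)
    n = len(istart)
    left_out = np.searchsorted(e_sorted, wstart, side="right")
    right_out = n - np.searchsorted(s_sorted, wend, side="left")
    return n - left_out - right_out


def count_track_overlaps(
    track: pd.DataFrame,
    windows: pd.DataFrame,
    mode: str = "count",
    label_col: str = "condition",
) -> pd.Series:
    """Overlap summary of a track against per-gene windows.

    ``mode``:
      * ``count`` -- number of intervals overlapping each window;
      * ``presence`` -- 0/1 any overlap;
      * ``conditions`` -- number of distinct ``label_col`` values with at
        least one overlapping interval.

    ``windows`` may contain several rows per gene id (e.g. the two distal
    flanks); counts are summed per gene for ``count`` and distinct-union'd
    for ``conditions``. Track intervals on contigs absent from the windows
    are skipped with a warning.
    """
    if mode not in ("count", "presence", "conditions"):
        raise ValueError("mode must be count, presence or conditions")
    known = set(windows["contig"].unique())
    unknown = set(track["contig"].unique()) - known
    if unknown:
        warnings.warn(
            f"track contigs not in windows, skipped: {sorted(unknown)}", RuntimeWarning
        )
        track = track[track["contig"].isin(known)]

    genes = windows.index.unique()
    if mode in ("count", "presence"):
        total = pd.Series(0, index=genes, dtype=np.int64)
        for contig, wgrp in windows.groupby("contig"):
            t = track[track["contig"] == contig]
            if t.empty:
                continue
            c = _overlap_counts_1d(
                t["start"].to_numpy(), t["end"].to_numpy(),
                wgrp["start"].to_numpy(), wgrp["end"].to_numpy(),
            )
            total = total.add(pd.Series(c, index=wgrp.index).groupby(level=0).sum(),
                              fill_value=0)
        total = total.astype(np.int64)
        return (total > 0).astype(np.int64) if mode == "presence" else total

    # conditions: distinct labels with >= 1 overlap
    present = pd.DataFrame(False, index=genes, columns=sorted(track[label_col].unique()))
    for (contig, label), tgrp in track.groupby(["contig", label_col]):
        wgrp = windows[windows["contig"] == contig]
        if wgrp.empty:
            continue
        c = _overlap_counts_1d(
            tgrp["start"].to_numpy(), tgrp["end"].to_numpy(),
            wgrp["start"].to_numpy(), wgrp["end"].to_numpy(),
        )
        hit = pd.Series(c, index=wgrp.index).groupby(level=0).sum() > 0
        present.loc[hit[hit].index, label] = True
    return present.sum(axis=1).astype(np.int64)


def _distal_windows(annotation: pd.DataFrame, prox: int = PROX_BP,
                    dist: int = DIST_BP) -> pd.DataFrame:
    """Two flanks per gene covering (prox, dist] on both sides of the TSS,
    with the proximal window subtracted exactly (disjoint partition)."""
    tss0 = annotation["tss"].to_numpy(dtype=np.int64) - 1
    left = pd.DataFrame(
        {
            "contig": annotation["contig"].to_numpy(),
            "start": np.maximum(tss0 - dist, 0),
            "end": np.maximum(tss0 - prox, 0),
        },
        index=annotation.index,
    )
    right = pd.DataFrame(
        {
            "contig": annotation["contig"].to_numpy(),
            "start": tss0 + 1 + prox,
            "end": tss0 + 1 + dist,
        },
        index=annotation.index,
    )
    return pd.concat([left, right])


# ---------------------------------------------------------------------------
# DHS condition summaries
# ---------------------------------------------------------------------------

def _profiles_for(
    track: pd.DataFrame, windows: pd.DataFrame, vocab: pd.DataFrame, suffix: str
) -> pd.DataFrame:
    genes = windows.index.unique()
    required = {"tissue_group", "time_class", "sorted12"}
    if not required <= set(vocab.columns):
        raise ValueError("condition vocabulary must declare tissue/time attributes")
    cond_hits = pd.DataFrame(False, index=genes, columns=vocab.index)
    for (contig, cond), tgrp in track.groupby(["contig", "condition"]):
        if cond not in vocab.index:
            raise ValueError(f"condition {cond!r} missing from vocabulary")
        wgrp = windows[windows["contig"] == contig]
        if wgrp.empty:
            continue
        c = _overlap_counts_1d(
            tgrp["start"].to_numpy(), tgrp["end"].to_numpy(),
            wgrp["start"].to_numpy(), wgrp["end"].to_numpy(),
        )
        hit = pd.Series(c, index=wgrp.index).groupby(level=0).sum() > 0
        cond_hits.loc[hit[hit].index, cond] = True

    early = cond_hits[vocab.index[vocab["time_class"] == "early"]].any(axis=1)
    late = cond_hits[vocab.index[vocab["time_class"] == "late"]].any(axis=1)
    we = cond_hits[vocab.index[vocab["tissue_group"] == "WE"]].any(axis=1)
    tis = cond_hits[vocab.index[vocab["tissue_group"] == "tissue"]].any(axis=1)
    sorted12 = vocab.index[vocab["sorted12"]]

    def profile(a, b, names):
        out = pd.Series("none", index=genes, dtype=object)
        out[a & ~b] = names[0]
        out[~a & b] = names[1]
        out[a & b] = names[2]
        return out

    return pd.DataFrame(
        {
            f"num_dhs_conditions.{suffix}": cond_hits.sum(axis=1).astype(np.int64),
            f"dhs_time_profile.{suffix}": profile(early, late, ["early_only", "late_only", "both"]),
            f"dhs_tissue_profile.{suffix}": profile(tis, we, ["tissues_only", "WE_only", "both"]),
            f"dhs_ubiq.{suffix}": cond_hits[sorted12].all(axis=1).astype(np.int64),
            f"num_dhs_any.{suffix}": count_track_overlaps(track, windows, "count"),
        }
    )


def dhs_condition_summaries(
    dhs_track: pd.DataFrame,
    annotation: pd.DataFrame,
    vocabulary: pd.DataFrame,
    prox: int = PROX_BP,
    dist: int = DIST_BP,
) -> pd.DataFrame:
    """Open-chromatin condition features per gene, proximal and distal.

    Proximal window: +-``prox`` of the TSS. Distal: (``prox``, ``dist``] on
    both sides, proximal region excluded exactly. The vocabulary declares
    per-condition tissue/time attributes and the 12 sorted-tissue conditions
    whose joint presence defines a ubiquitous DHS.
    """
    prox_w = make_tss_windows(annotation, prox, prox)
    dist_w = _distal_windows(annotation, prox, dist)
    out = pd.concat(
        [
            _profiles_for(dhs_track, prox_w, vocabulary, "prox"),
            _profiles_for(dhs_track, dist_w, vocabulary, "dist"),
        ],
        axis=1,
    )
    return out


# ---------------------------------------------------------------------------
# Scalar features
# ---------------------------------------------------------------------------

def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N bases excluded from the denominator."""
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def utr3_variant_index(
    n_variants: int, allele_freqs: Sequence[float], utr_width: float
) -> float:
    """(number of 3'UTR variants x mean allele frequency) / 3'UTR width."""
    if utr_width <= 0:
        raise ValueError("utr_width must be positive")
    if n_variants == 0:
        return 0.0
    if len(allele_freqs) != n_variants:
        raise ValueError("allele_freqs length must equal n_variants")
    return n_variants * float(np.mean(allele_freqs)) / utr_width


def genomic_context_features(
    annotation: pd.DataFrame,
    tads: pd.DataFrame,
    prox_bp: int = 1_000,
    dist_bp: int = 20_000,
) -> pd.DataFrame:
    """Gene-density and TAD-context features.

    ``num_genes.prox``/``.dist``: genes (self excluded) with TSS within
    +-1 kb / +-20 kb. TAD assignment by TSS; ``dist_to_tad_border`` is the
    minimum distance from the TSS to either boundary; genes outside all TADs
    get NaN TAD features.
    """
    out = pd.DataFrame(index=annotation.index)
    out["num_genes.prox"] = 0
    out["num_genes.dist"] = 0
    for contig, grp in annotation.groupby("contig"):
        tss = np.sort(grp["tss"].to_numpy())
        mine = grp["tss"].to_numpy()
        for col, radius in (("num_genes.prox", prox_bp), ("num_genes.dist", dist_bp)):
            lo = np.searchsorted(tss, mine - radius, side="left")
            hi = np.searchsorted(tss, mine + radius, side="right")
            out.loc[grp.index, col] = hi - lo - 1  # exclude self
    tad_id = pd.Series(pd.NA, index=annotation.index, dtype=object)
    border = pd.Series(np.nan, index=annotation.index)
    size = pd.Series(np.nan, index=annotation.index)
    for contig, tgrp in tads.groupby("contig"):
        genes_c = annotation[annotation["contig"] == contig]
        if genes_c.empty:
            continue
        starts = tgrp["start"].to_numpy()
        ends = tgrp["end"].to_numpy()
        ids = tgrp.index.to_numpy()
        pos = genes_c["tss"].to_numpy() - 1
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        sel = genes_c.index[ok]
        tad_id.loc[sel] = ids[idx[ok]]
        border.loc[sel] = np.minimum(pos[ok] - starts[idx[ok]], ends[idx[ok]] - pos[ok])
        size.loc[sel] = ends[idx[ok]] - starts[idx[ok]]
    out["tad_id"] = tad_id
    out["dist_to_tad_border"] = border
    out["tad_size"] = size
    return out


def aggregate_tissue_features(
    per_tissue: pd.DataFrame, mode: str = "mean"
) -> pd.Series:
    """Aggregate per-tissue values over tissues where the gene has a value.

    ``mean`` averages non-missing values; ``share_positive`` / ``share_broad``
    report the fraction of non-missing values that are truthy.
    """
    if mode == "mean":
        return per_tissue.mean(axis=1, skipna=True)
    if mode in ("share_positive", "share_broad"):
        return (per_tissue > 0).sum(axis=1) / per_tissue.notna().sum(axis=1)
    raise ValueError("mode must be mean, share_positive or share_broad")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_feature_table(
    blocks: Mapping[str, pd.DataFrame],
    classes: Mapping[str, str] | None = None,
    imputable: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Join feature blocks into one gene x feature table.

    ``blocks`` maps block name -> DataFrame indexed by gene id. Duplicate
    feature names across blocks raise. Features in ``imputable`` (motif/peak
    presence and counts, where absence genuinely means zero) are zero-filled;
    genes with missing values in any other feature are dropped and listed in
    the returned report.

    Returns ``(table, feature_meta, dropped_report)``.
    """
    all_cols: list[str] = []
    for name, df in blocks.items():
        for c in df.columns:
            if c in all_cols:
                raise ValueError(f"duplicate feature name {c!r} (block {name!r})")
            all_cols.append(c)
    genes = pd.Index(sorted(set().union(*[set(df.index) for df in blocks.values()])))
    table = pd.concat([df.reindex(genes) for df in blocks.values()], axis=1)
    meta_rows = []
    for name, df in blocks.items():
        for c in df.columns:
            meta_rows.append(
                {
                    "feature": c,
                    "block": name,
                    "feature_class": (classes or {}).get(c, (classes or {}).get(name, "")),
                    "dtype": str(table[c].dtype),
                    "imputable": c in imputable,
                }
            )
    meta = pd.DataFrame(meta_rows).set_index("feature")
    for c in imputable:
        if c in table.columns:
            table[c] = table[c].fillna(0)
    missing = table.isna().any(axis=1)
    dropped = pd.DataFrame(
        {
            "gene_id": genes[missing],
            "missing_features": [
                ",".join(table.columns[table.loc[g].isna()]) for g in genes[missing]
            ],
        }
    )
    table = table.loc[~missing]
    assert not table.isna().any().any()
    return table, meta, dropped
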