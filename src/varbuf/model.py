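"""Boruta feature selection and random-forest prediction of expression
variation / level, with cross-validated and stratified evaluation.

Boruta is implemented from first principles: each run appends *shadow*
features (independent column permutations of every active real feature),
fits a bagged regression forest, and scores every feature by the Z-score of
its out-of-bag permutation importance (mean decrease in accuracy across
trees divided by its standard deviation). A real feature scores a *hit* when
its Z exceeds the best shadow's Z. Accumulated hits are tested against a
Binomial(runs, 1/2) null (two-sided, Bonferroni-corrected by default over
the real features, p = 0.01): significantly more hits than chance confirms
a feature, significantly fewer rejects it (rejected features and their
shadows leave the forest). After ``max_runs`` undecided features are
tentative; tentative resolution compares each feature's median importance
history to the median shadow maximum.

The forest used inside Boruta is our own bagging of sklearn decision trees
so per-tree out-of-bag sets are explicit; prediction/evaluation forests use
sklearn's RandomForestRegressor directly (num trees 500, mtry = sqrt p).

Internally Boruta orders columns canonically by feature name and derives
per-feature permutation streams from the feature names, so decisions are
invariant to the column order of the input table.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .util import child_seed, rng

__all__ = [
    "BorutaResult",
    "ModelEval",
    "boruta_select",
    "rf_regression_cv",
    "permutation_null",
    "stratified_evaluation",
]


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BorutaResult:
    """Per-feature Boruta decisions and importance history."""

    table: pd.DataFrame  # decision, hits, runs_used, median_importance
    shadow_max_history: np.ndarray
    runs: int

    @property
    def confirmed(self) -> list[str]:
        return list(self.table.index[self.table["decision"] == "confirmed"])

    @property
    def rejected(self) -> list[str]:
        return list(self.table.index[self.table["decision"] == "rejected"])

    @property
    def tentative(self) -> list[str]:
        return list(self.table.index[self.table["decision"] == "tentative"])


def _oob_importance_z(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    gen: np.random.Generator,
    max_oob: int = 256,
) -> np.ndarray:
    """Z-score (mean/sd over trees) of OOB permutation importance per column.

    Importance of a column in one tree = increase in OOB MSE after permuting
    that column. Columns a tree never sees contribute 0 for that tree.
    ``max_oob`` caps the OOB rows used per tree (a uniform subsample) purely
    for speed; the Z-score still averages over all trees.
    """
    n, p = X.shape
    imps = np.zeros((n_trees, p))
    mtry = max(1, int(np.sqrt(p)))
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for t in range(n_trees):
        boot = gen.integers(0, n, size=n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[boot] = False
        oob = np.flatnonzero(oob_mask)
        if oob.size < 5:
            continue
        if oob.size > max_oob:
            oob = gen.choice(oob, size=max_oob, replace=False)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=5,
            random_state=int(gen.integers(2**31 - 1)),
        )
        tree.fit(X32[boot], y[boot], check_input=False)
        Xo = X32[oob]
        yo = y[oob]
        base = np.mean((tree.predict(Xo, check_input=False) - yo) ** 2)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        perm = gen.permutation(oob.size)
        Xp = Xo.copy()
        for k in used:
            saved = Xp[:, k].copy()
            Xp[:, k] = Xo[perm, k]
            imps[t, k] = np.mean((tree.predict(Xp, check_input=False) - yo) ** 2) - base
            Xp[:, k] = saved
    mean = imps.mean(axis=0)
    sd = imps.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, mean / sd, 0.0)
    return z


def boruta_select(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    p: float = 0.01,
    max_runs: int = 500,
    n_trees: int = 100,
    seed: int = 0,
    bonferroni: bool = True,
    min_runs: int = 5,
) -> BorutaResult:
    """All-relevant feature selection against shadow features."""
    if X.shape[1] < 2:
        raise ValueError("Boruta requires at least 2 features")
    if X.isna().any().any():
        raise ValueError("Boruta requires a complete feature table")
    y = np.asarray(y, dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("constant response")

    names = sorted(X.columns)  # canonical order: decisions ignore input order
    Xs = X[names].to_numpy(dtype=float)
    n, n_feat = Xs.shape
    alpha = p / n_feat if bonferroni else p

    decision = pd.Series("tentative", index=pd.Index(names, name="feature"))
    hits = pd.Series(0, index=decision.index)
    runs_used = pd.Series(0, index=decision.index)
    history: dict[str, list[float]] = {f: [] for f in names}
    shadow_max_hist: list[float] = []

    active = list(names)
    run = 0
    while run < max_runs and any(decision[f] == "tentative" for f in active):
        run += 1
        cols = [f for f in active if decision[f] != "rejected"]
        idx = [names.index(f) for f in cols]
        Xa = Xs[:, idx]
        # shadows: per-feature named streams so column order cannot matter.
        # At least 5 shadows are always kept (extra permuted copies of the
        # remaining features), so the max-shadow reference never collapses
        # to a single competitor late in the run.
        shadow_cols = list(cols)
        k = 0
        while len(shadow_cols) < 5:
            shadow_cols.append(cols[k % len(cols)])
            k += 1
        shadows = np.empty((n, len(shadow_cols)))
        for j, f in enumerate(shadow_cols):
            g = rng(seed, "shadow", run, f, j)
            shadows[:, j] = Xs[g.permutation(n), names.index(f)]
        Xrun = np.hstack([Xa, shadows])
        gen = rng(seed, "forest", run)
        z = _oob_importance_z(Xrun, y, n_trees, gen)
        z_real = z[: len(cols)]
        z_shadow_max = z[len(cols):].max()
        shadow_max_hist.append(float(z_shadow_max))
        for f, zf in zip(cols, z_real):
            history[f].append(float(zf))
            if decision[f] == "tentative":
                runs_used[f] += 1
                if zf > z_shadow_max:
                    hits[f] += 1
        if run < min_runs:
            continue
        for f in cols:
            if decision[f] != "tentative":
                continue
            h, r = hits[f], runs_used[f]
            if sps.binom.sf(h - 1, r, 0.5) < alpha:
                decision[f] = "confirmed"
            elif sps.binom.cdf(h, r, 0.5) < alpha:
                decision[f] = "rejected"
        active = [f for f in active if decision[f] != "rejected"]

    med_imp = pd.Series({f: (np.median(v) if v else np.nan) for f, v in history.items()})
    med_shadow = float(np.median(shadow_max_hist)) if shadow_max_hist else np.nan
    tentative_resolution = pd.Series("", index=decision.index)
    for f in names:
        if decision[f] == "tentative":
            tentative_resolution[f] = (
                "confirmed" if med_imp[f] > med_shadow else "rejected"
            )
    table = pd.DataFrame(
        {
            "decision": decision,
            "hits": hits,
            "runs_used": runs_used,
            "median_importance": med_imp,
            "tentative_resolution": tentative_resolution,
        }
    )
    return BorutaResult(table, np.asarray(shadow_max_hist), run)


# ---------------------------------------------------------------------------
# Random-forest evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelEval:
    """Cross-validated forest performance for one target/grouping."""

    target: str
    group: str
    r2_pooled: float
    r2_folds: list[float]
    n: int
    oof_pred: np.ndarray | None = None
    train_r2: float | None = None

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.r2_folds))

    @property
    def r2_sd(self) -> float:
        return float(np.std(self.r2_folds, ddof=1)) if len(self.r2_folds) > 1 else 0.0


def _r2(y, pred) -> float:
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1 - ss_res / ss_tot)


def rf_regression_cv(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    folds: int = 5,
    trees: int = 500,
    seed: int = 0,
    target: str = "y",
    group: str = "all",
) -> ModelEval:
    """Out-of-fold random-forest R^2 (pooled headline + per-fold mean/sd)."""
    y = np.asarray(y, dtype=float)
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
    if len(y) < 50:
        raise ValueError("need at least 50 observations")
    if np.allclose(y, y[0]):
        raise ValueError("constant response: R^2 undefined")
    kf = KFold(n_splits=folds, shuffle=True, random_state=child_seed(seed, "folds"))
    oof = np.full(len(y), np.nan)
    fold_r2 = []
    train_r2s = []
    for fi, (tr, te) in enumerate(kf.split(Xa)):
        if len(te) < 2:
            raise ValueError("fold with fewer than 2 observations")
        rf = RandomForestRegressor(
            n_estimators=trees,
            max_features="sqrt",
            min_samples_leaf=5,
            random_state=child_seed(seed, "rf", fi),
            n_jobs=1,
        )
        rf.fit(Xa[tr], y[tr])
        oof[te] = rf.predict(Xa[te])
        fold_r2.append(_r2(y[te], oof[te]))
        train_r2s.append(_r2(y[tr], rf.predict(Xa[tr])))
    return ModelEval(
        target=target,
        group=group,
        r2_pooled=_r2(y, oof),
        r2_folds=fold_r2,
        n=len(y),
        oof_pred=oof,
        train_r2=float(np.mean(train_r2s)),
    )


def permutation_null(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    seed: int = 0,
    folds: int = 5,
    trees: int = 500,
    permutation: np.ndarray | None = None,
) -> ModelEval:
    """Full CV on a label permutation (the chance-performance baseline).

    ``permutation`` overrides the random draw (identity array reproduces
    :func:`rf_regression_cv` exactly; used as a test hook).
    """
    y = np.asarray(y, dtype=float)
    if permutation is None:
        permutation = rng(seed, "perm").permutation(len(y))
    ev = rf_regression_cv(
        X, y[permutation], folds=folds, trees=trees, seed=seed,
        target="permuted", group="permuted",
    )
    return ev


def stratified_evaluation(
    X: pd.DataFrame,
    y: pd.Series,
    grouping: pd.Series,
    design: str = "quantile",
    n_bins: int = 5,
    min_genes: int = 50,
    folds: int = 5,
    trees: int = 500,
    seed: int = 0,
) -> list[ModelEval]:
    """Robustness designs: per-bin CV or chromosome holdout.

    ``design='quantile'``: ``grouping`` is a continuous per-gene variable
    (expression level, promoter shape index, expression change); genes are
    cut into ``n_bins`` quantile bins and a model is cross-validated within
    each bin. ``design='holdout'``: ``grouping`` is categorical (chromosome
    arm); for each level a model trains on all other levels and is scored on
    the held-out one. The feature set is fixed by the caller (pass the
    full-model Boruta selection). Bins with fewer than ``min_genes`` genes
    are skipped with a warning entry (r2 NaN).
    """
    grouping = grouping.reindex(X.index)
    evals: list[ModelEval] = []
    if design == "quantile":
        bins = pd.qcut(grouping, n_bins, labels=False, duplicates="drop")
        for b in sorted(bins.dropna().unique()):
            mask = (bins == b).to_numpy()
            label = f"bin{int(b)}"
            if mask.sum() < min_genes:
                evals.append(ModelEval("y", label, np.nan, [], int(mask.sum())))
                continue
            evals.append(
                rf_regression_cv(
                    X[mask], y[mask], folds=folds, trees=trees,
                    seed=child_seed(seed, "bin", int(b)), group=label,
                )
            )
        return evals
    if design == "holdout":
        for level in sorted(grouping.dropna().unique()):
            te = (grouping == level).to_numpy()
            tr = ~te
            if te.sum() < min_genes or tr.sum() < min_genes:
                evals.append(ModelEval("y", str(level), np.nan, [], int(te.sum())))
                continue
            rf = RandomForestRegressor(
                n_estimators=trees,
                max_features="sqrt",
                min_samples_leaf=5,
                random_state=child_seed(seed, "holdout", str(level)),
                n_jobs=1,
            )
            ya = np.asarray(y, dtype=float)
            rf.fit(X[tr], ya[tr])
            r2 = _r2(ya[te], rf.predict(X[te]))
            evals.append(ModelEval("y", str(level), r2, [r2], int(te.sum())))
        return evals
    raise ValueError("design must be 'quantile' or 'holdout'")
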