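"""Shared fixtures: one default-scale simulation reused across the suite."""

import dataclasses
import warnings

import pandas as pd
import pytest
from hypothesis import settings

import varbuf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning)


@dataclasses.dataclass
class Bundle:
    """Default simulation plus the full variation pipeline applied to it."""

    cfg: varbuf.SimConfig
    data: varbuf.SimData
    norms: dict
    summaries: dict
    flags: pd.DataFrame
    retained: pd.Index
    summary: pd.DataFrame  # expression_summary on the final gene set
    resid: pd.Series
    causal: list


def _build_bundle(cfg: varbuf.SimConfig, n_studies: int) -> Bundle:
    data = varbuf.simulate_all(cfg, n_studies=n_studies)
    norms, summaries = {}, {}
    for tp, cm in data.counts.items():
        _, norm = varbuf.normalize_counts(cm)
        norms[tp] = norm
        summaries[tp] = varbuf.summarize_expression(norm, tp)
    flags = varbuf.filter_genes(summaries, cfg.focal_timepoint, cfg.early_timepoint)
    retained = flags.index[flags["retained"]]
    summary = varbuf.expression_summary(norms[cfg.focal_timepoint].loc[retained])
    resid = summary["resid_cv"].dropna()
    meta = data.features.attrs["meta"]
    causal = list(meta.index[meta["causal"]])
    return Bundle(cfg, data, norms, summaries, flags, retained, summary, resid, causal)


@pytest.fixture(scope="session")
def default_bundle() -> Bundle:
    """Full default study design: 4,000 genes x 75 samples, 50 DE studies."""
    return _build_bundle(varbuf.SimConfig(seed=1), n_studies=50)


@pytest.fixture(scope="session")
def small_bundle() -> Bundle:
    """Reduced design for cheaper structural tests: 1,200 genes x 40 samples."""
    return _build_bundle(
        varbuf.SimConfig(n_genes=1200, n_samples=40, n_timepoints=2, seed=3),
        n_studies=5,
    )
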