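"""Shared fixtures: the default labelled dataset and one pipeline run.

The expensive artifacts (fragment-level simulation, end-to-end pipeline) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from tripeak.patternmatch import SimRefConfig, simulate_reference
from tripeak.pipeline import PipelineConfig, run_pipeline
from tripeak.synthetic_data import default_config, generate_dataset

#: pipeline settings used for every fixture run: alpha and d are the study
#: defaults; the motif-discovery set size is the desk-scale analogue of
#: selecting ~200 high-quality regions out of tens of thousands.
FIXTURE_PIPELINE = dict(d=250, alpha=0.5, n_high_quality=12, seed=1)


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    ds = generate_dataset(default_config(seed=1))
    paths = ds.write(tmp_path_factory.mktemp("fixture"))
    return ds, paths


@pytest.fixture(scope="session")
def pipeline_run(default_dataset, tmp_path_factory):
    ds, paths = default_dataset
    outdir = tmp_path_factory.mktemp("pipeline_out")
    result = run_pipeline(
        paths["tags"],
        paths["genome"],
        PipelineConfig(**FIXTURE_PIPELINE),
        fasta_path=paths["fasta"],
        outdir=outdir,
    )
    return ds, paths, result, outdir


@pytest.fixture(scope="session")
def reference_pattern():
    return simulate_reference(SimRefConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
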