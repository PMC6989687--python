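"""Shared fixtures: one default synthetic dataset run through the pipeline.

The default-configuration dataset (78 pass-QC cells with a 10-cell
haematopoietic minority, 25 planted markers) is expensive enough to share,
so it is generated once per session together with the downstream QC,
classification and marker-scan products.
"""

from __future__ import annotations

import numpy as np
import pytest

from ehtmark import (
    MarkerPanel,
    SimulationConfig,
    annotate_components,
    compute_qc,
    filter_cells,
    fit_gmm2,
    generate_dataset,
    log_transform,
    marker_pca,
    rescale_tpm_excluding_spikeins,
    scan_all,
)

FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """(ExpressionMatrix, ReadCountTable, GroundTruth) under the default config."""
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def classified(default_dataset):
    """Full chain QC -> rescale -> log -> PCA -> GMM -> labels on the fixture."""
    matrix, reads, truth = default_dataset
    filtered = filter_cells(matrix, compute_qc(matrix, reads))
    logm = log_transform(rescale_tpm_excluding_spikeins(filtered))
    panel = MarkerPanel()
    pca = marker_pca(logm, panel)
    fit = fit_gmm2(pca.scores, seed=FIXTURE_SEED)
    labels = annotate_components(fit, logm, panel)
    return {
        "truth": truth,
        "filtered": filtered,
        "log_matrix": logm,
        "pca": pca,
        "fit": fit,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def marker_table(classified):
    return scan_all(classified["log_matrix"], classified["labels"])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
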