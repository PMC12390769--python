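"""Shared fixtures: small study-shaped synthetic datasets."""

from __future__ import annotations

import dataclasses

import pytest

from proteoconnect import preprocess as pp
from proteoconnect import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.GeneratorConfig:
    """Scaled-down study layout: 26 ROI groups x 6 donors, 200 proteins."""
    return sd.GeneratorConfig(seed=7, n_proteins=200, n_donors=6,
                              n_subjects=8, n_timepoints=120)


@pytest.fixture(scope="session")
def proteome(small_config):
    return sd.generate_proteome(small_config)


@pytest.fixture(scope="session")
def corrected(proteome):
    m, meta, _ = proteome
    return pp.remove_batch_effect(pp.normalize_log2_median(m), meta)


@pytest.fixture(scope="session")
def connectome_data(small_config, proteome):
    _, _, gt = proteome
    sim = sd.similarity_from_groundtruth(gt)
    return sd.generate_connectome(small_config, sim, gt)


@pytest.fixture(scope="session")
def left_geometry():
    geom = sd.generate_roi_geometry(13, seed=3).hemisphere_subset("L")
    return dataclasses.replace(
        geom, labels=tuple(l.rsplit("_", 1)[0] for l in geom.labels))
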