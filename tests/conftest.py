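"""Shared fixtures: small synthetic studies and hand-built matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from orthotime.containers import TimeCourseMatrix
from orthotime.simulate import SimConfig, generate_experiment

FIVE_SHAPES = ("down", "up", "peak:2", "peak:5", "peak:8")


def make_matrix(rows: dict[str, list[float]], days, n_replicates=1,
                species="test") -> TimeCourseMatrix:
    """Build a TimeCourseMatrix from per-probe replicate-mean profiles.

    Each profile value is replicated identically across replicates, so the
    replicate mean equals the given profile.
    """
    days = tuple(float(d) for d in days)
    columns = pd.MultiIndex.from_product(
        [days, range(1, n_replicates + 1)], names=["day", "replicate"]
    )
    data = {
        probe: np.repeat(vals, n_replicates) for probe, vals in rows.items()
    }
    values = pd.DataFrame.from_dict(data, orient="index", columns=columns)
    values.index.name = "probe_id"
    return TimeCourseMatrix(species, days, n_replicates, values)


def five_shape_config(**overrides) -> SimConfig:
    """Study config with five well-separated regulated shape templates."""
    base = dict(
        n_genes=150,
        n_clusters=5,
        cluster_shapes=FIVE_SHAPES,
        conserved_fraction=1.0,
        noise_sd=0.2,
        presence_absent_fraction=0.0,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    """A small mixed study: conserved + divergent clusters, silent genes."""
    cfg = SimConfig(
        n_genes=180,
        n_clusters=6,
        conserved_fraction=0.7,
        noise_sd=0.2,
        presence_absent_fraction=0.2,
        seed=11,
    )
    out = generate_experiment(cfg)
    keys = (
        "human", "mouse", "map_h", "map_m", "pairs", "calls_h", "calls_m",
        "truth",
    )
    return dict(zip(keys, out), config=cfg)
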