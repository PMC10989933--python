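"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from taxadyn.data_io import CountTable, ResourceSeries
from taxadyn.preprocess import RegressionDataset


def brute_force_wls(design: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least squares by explicit normal equations.

    Independent of the fitting path under test: builds X' W X and
    X' W y element by element and solves with a plain inverse.
    """
    n, p = design.shape
    xtx = np.zeros((p, p))
    xty = np.zeros(p)
    for k in range(n):
        for i in range(p):
            xty[i] += design[k, i] * w[k] * y[k]
            for j in range(p):
                xtx[i, j] += design[k, i] * w[k] * design[k, j]
    return np.linalg.solve(xtx, xty)


def make_dataset(
    *,
    response: np.ndarray,
    inv_x: np.ndarray,
    inv_xr: np.ndarray,
    resources: np.ndarray | None = None,
    dt: np.ndarray | None = None,
    taxon_id: str = "taxonA",
    reference_id: str = "ref",
) -> RegressionDataset:
    """Assemble a RegressionDataset directly from arrays (weights recomputed)."""
    n = len(response)
    if resources is None:
        resources = np.ones((n, 1))
    resources = np.asarray(resources, dtype=float).reshape(n, -1)
    if dt is None:
        dt = np.ones(n)
    dt = np.asarray(dt, dtype=float)
    weights = dt / (2.0 * inv_x + 2.0 * inv_xr)
    return RegressionDataset(
        taxon_id=taxon_id,
        reference_id=reference_id,
        resource_names=[f"res{j}" for j in range(resources.shape[1])],
        response=np.asarray(response, dtype=float),
        resources=resources,
        inv_x=np.asarray(inv_x, dtype=float),
        inv_xr=np.asarray(inv_xr, dtype=float),
        dt=dt,
        weights=weights,
        replicate_ids=np.array(["R1"] * n, dtype=object),
        days=np.arange(n, dtype=float),
    )


def synthetic_design(rng: np.random.Generator, n: int, J: int = 1):
    """Random but well-conditioned regressors for fitter tests."""
    inv_x = 1.0 / rng.uniform(0.02, 0.4, n)
    inv_xr = 1.0 / rng.uniform(0.2, 0.5, n)
    resources = rng.uniform(1.0, 3.0, (n, J))
    dt = rng.uniform(0.5, 2.0, n)
    return inv_x, inv_xr, resources, dt


@pytest.fixture
def toy_count_table() -> CountTable:
    """3 taxa x 4 samples over two replicates."""
    counts = np.array(
        [
            [10, 20, 30, 40],
            [5, 5, 0, 10],
            [85, 75, 70, 50],
        ]
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "replicate_id": ["R1", "R1", "R2", "R2"],
            "day": [0.0, 10.0, 0.0, 10.0],
            "group": ["control"] * 4,
        }
    ).set_index("sample_id")
    return CountTable(
        taxon_ids=["A", "B", "C"],
        sample_ids=["s1", "s2", "s3", "s4"],
        counts=counts,
        metadata=meta,
    )


@pytest.fixture
def toy_resources() -> list[ResourceSeries]:
    return [
        ResourceSeries(
            replicate_id=rep,
            resource_names=["VS"],
            days=np.array([0.0, 10.0]),
            values=np.array([[2.0], [2.5]]),
        )
        for rep in ("R1", "R2")
    ]
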