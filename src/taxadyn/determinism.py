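"""Determinism of taxon and community dynamics.

The combined model writes the log-ratio dynamics as
dZ = mu dtau + sigma dW.  Determinism is defined as the inverse
coefficient of variation |mu| / sigma of the abundance change: large
values mean the deterministic drift (immigration restoring force plus
resource-driven growth differences) dominates demographic noise.

For a combined fit the taxon determinism at a time point is

    |k0 + sum_j k1_j R_j + k2 / X_i + k3 / X_r| * sqrt(a / (2/X_i + 2/X_r))

on the real-time scale (default).  The alternative scaled-time
convention multiplies by a / sqrt(2/X_i + 2/X_r) instead, differing by
a factor sqrt(a); it is selectable via ``time_scale='tau'``.

Community determinism at a time point is the mean over taxa with a
defined value, either unweighted or weighted by relative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import AbundanceMatrix
from .process_models import ModelFit

__all__ = [
    "taxon_determinism",
    "community_determinism",
    "determinism_table",
    "CommunityDeterminism",
]


@dataclass
class CommunityDeterminism:
    """Aggregated determinism of co-occurring taxa at one time point."""

    day: float
    unweighted: float
    weighted: float
    n_taxa: int


def taxon_determinism(
    fit: ModelFit,
    X_i,
    X_r,
    R,
    a_hat: float | None = None,
    *,
    time_scale: str = "t",
):
    """Determinism of one taxon at given abundances and resource levels.

    Parameters are broadcast: ``X_i``, ``X_r`` may be scalars or arrays
    over time, ``R`` has shape (..., J).  Points where the focal or
    reference abundance is zero are returned as NaN (undefined there).
    """
    if fit.model_kind != "combined":
        raise ValueError("determinism is defined from the combined fit")
    if a_hat is None:
        a_hat = fit.a_hat
    if a_hat is None or a_hat <= 0:
        raise ValueError("a_hat must be positive")
    X_i = np.asarray(X_i, dtype=float)
    X_r = np.asarray(X_r, dtype=float)
    R = np.asarray(R, dtype=float)
    if R.ndim == X_i.ndim:  # single resource supplied without trailing axis
        R = R[..., None] if len(fit.k1) == 1 else R
    with np.errstate(divide="ignore", invalid="ignore"):
        drift = (
            fit.k0
            + R @ np.atleast_1d(fit.k1)
            + fit.k2 / X_i
            + fit.k3 / X_r
        )
        noise_sq = 2.0 / X_i + 2.0 / X_r
        if time_scale == "t":
            value = np.abs(drift) * np.sqrt(a_hat / noise_sq)
        elif time_scale == "tau":
            value = np.abs(drift) * a_hat / np.sqrt(noise_sq)
        else:
            raise ValueError(f"unknown time_scale {time_scale!r}")
    value = np.where((X_i > 0) & (X_r > 0), value, np.nan)
    return value if value.ndim else float(value)


def community_determinism(
    values,
    abundances,
    *,
    day: float = np.nan,
) -> CommunityDeterminism:
    """Aggregate taxon determinism values at one time point.

    The unweighted mean is the plain arithmetic mean; the weighted mean
    uses each taxon's relative abundance at that time point as weight,
    renormalised over the contributing (non-NaN) taxa.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(abundances, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError("no taxa with defined determinism at this time point")
    v, w = v[ok], w[ok]
    unweighted = float(v.mean())
    weighted = float(np.sum(w * v) / np.sum(w)) if w.sum() > 0 else unweighted
    return CommunityDeterminism(
        day=float(day), unweighted=unweighted, weighted=weighted, n_taxa=int(ok.sum())
    )


def determinism_table(
    abund: AbundanceMatrix,
    resources,
    combined_fits: dict[str, ModelFit],
    reference_id: str,
    *,
    time_scale: str = "t",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon and community determinism over all samples.

    ``combined_fits`` maps taxon_id -> combined ModelFit.  Returns
    (taxon-level table, community-level table); taxa absent at a time
    point contribute nothing there.
    """
    from .data_io import ResourceSeries

    if isinstance(resources, ResourceSeries):
        resources = {resources.replicate_id: resources}
    elif isinstance(resources, list):
        resources = {r.replicate_id: r for r in resources}

    r_idx = abund.index_of(reference_id)
    taxon_rows = []
    for rep, (days, X) in abund.replicates.items():
        R = resources[rep].at(days)
        for taxon, fit in combined_fits.items():
            i = abund.index_of(taxon)
            vals = taxon_determinism(
                fit, X[i], X[r_idx], R, time_scale=time_scale
            )
            for d, v, x in zip(days, np.atleast_1d(vals), X[i]):
                if np.isfinite(v):
                    taxon_rows.append(
                        {
                            "replicate_id": rep,
                            "taxon_id": taxon,
                            "day": d,
                            "determinism": v,
                            "rel_abund": x,
                        }
                    )
    taxa_df = pd.DataFrame(
        taxon_rows,
        columns=["replicate_id", "taxon_id", "day", "determinism", "rel_abund"],
    )
    comm_rows = []
    if not taxa_df.empty:
        for (rep, day), sub in taxa_df.groupby(["replicate_id", "day"]):
            cd = community_determinism(
                sub["determinism"].to_numpy(), sub["rel_abund"].to_numpy(), day=day
            )
            comm_rows.append(
                {
                    "replicate_id": rep,
                    "day": cd.day,
                    "unweighted": cd.unweighted,
                    "weighted": cd.weighted,
                    "n_taxa": cd.n_taxa,
                }
            )
    comm_df = pd.DataFrame(
        comm_rows, columns=["replicate_id", "day", "unweighted", "weighted", "n_taxa"]
    )
    return taxa_df, comm_df
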