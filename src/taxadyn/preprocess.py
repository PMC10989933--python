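"""From counts to regression-ready datasets.

The process models are fitted to finite differences of the log abundance
ratio Z_i = log(X_i / X_r) between a focal taxon i and a fixed reference
taxon r.  This module computes relative abundances, selects the
reference taxon, classifies taxa by mean abundance, applies the
presence filter, assembles per-taxon interval observations (response
dZ/dt, regressors, weights) and pools replicate series.

Conventions
-----------
Regressors and weights are evaluated at the *left* endpoint of each
interval (the non-anticipating Euler/Ito discretisation).  Intervals at
which either the focal or the reference taxon has a zero count are
dropped, since the log ratio is undefined there; an optional pseudocount
can be supplied for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import CountTable, ResourceSeries

__all__ = [
    "AbundanceMatrix",
    "RegressionDataset",
    "relative_abundances",
    "select_reference_taxon",
    "classify_abundance",
    "presence_filter",
    "build_regression_dataset",
    "combine_replicates",
    "mean_relative_abundance",
]

#: Abundance-class boundaries on mean relative abundance (fractions).
RARE_MAX = 1e-4  # 0.01 %
ABUNDANT_MIN = 1e-3  # 0.1 %


@dataclass
class AbundanceMatrix:
    """Relative abundances X_i(t) per replicate.

    ``replicates`` maps replicate_id -> (days, X) where X is a
    taxa x time matrix of fractions and each column sums to one.
    """

    taxon_ids: list[str]
    replicates: dict[str, tuple[np.ndarray, np.ndarray]]
    group: str = ""

    def __post_init__(self) -> None:
        for rep, (days, X) in self.replicates.items():
            if X.shape != (len(self.taxon_ids), len(days)):
                raise ValueError(f"shape mismatch in replicate {rep!r}")
            sums = X.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"columns of replicate {rep!r} do not sum to 1")
            if (X < 0).any():
                raise ValueError(f"negative abundance in replicate {rep!r}")

    def index_of(self, taxon_id: str) -> int:
        return self.taxon_ids.index(taxon_id)


@dataclass
class RegressionDataset:
    """Interval observations for one focal taxon against the reference.

    Each observation corresponds to one consecutive sample pair within a
    single replicate at which both focal and reference taxa are present.
    Fields are parallel arrays of length ``n_obs``:

    response
        (Z_{k+1} - Z_k) / dt, per day.
    resources
        resource levels R_j at the left endpoint, shape (n_obs, J).
    inv_x, inv_xr
        1/X_i and 1/X_r at the left endpoint.
    dt
        interval length in days.
    weights
        dt / (2/X_i + 2/X_r), the WLS weights of the neutral and
        combined fits.
    """

    taxon_id: str
    reference_id: str
    resource_names: list[str]
    response: np.ndarray
    resources: np.ndarray
    inv_x: np.ndarray
    inv_xr: np.ndarray
    dt: np.ndarray
    weights: np.ndarray
    replicate_ids: np.ndarray
    days: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.response)

    @property
    def n_resources(self) -> int:
        return self.resources.shape[1]

    def sufficient_for(self, n_params: int) -> bool:
        """At least n_params + 2 usable intervals (>= 2 residual d.o.f.)."""
        return self.n_obs >= n_params + 2


def relative_abundances(table: CountTable) -> AbundanceMatrix:
    """Convert a count table to per-replicate relative-abundance series."""
    table = table.sort_samples()
    meta = table.metadata.loc[table.sample_ids]
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    X_all = table.counts / totals.astype(float)
    replicates: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for rep in table.replicates():
        mask = (meta["replicate_id"] == rep).to_numpy()
        days = meta["day"].to_numpy(dtype=float)[mask]
        replicates[str(rep)] = (days, X_all[:, mask])
    group = ""
    if "group" in meta.columns and meta["group"].nunique() == 1:
        group = str(meta["group"].iloc[0])
    return AbundanceMatrix(
        taxon_ids=list(table.taxon_ids), replicates=replicates, group=group
    )


def select_reference_taxon(abund: AbundanceMatrix) -> str:
    """Pick the reference taxon: top occupancy, then top mean abundance.

    The reference must be present (abundance > 0) in every sample of
    every replicate, since all log ratios are taken against it.
    """
    X = np.hstack([Xr for _, Xr in abund.replicates.values()])
    occupancy = (X > 0).mean(axis=1)
    mean_abund = X.mean(axis=1)
    if occupancy.max() < 1.0:
        raise ValueError(
            "no taxon is present in every sample; choose a reference "
            "taxon manually via configuration"
        )
    # lexicographic: occupancy first, mean abundance as tie-break
    order = np.lexsort((mean_abund, occupancy))
    return abund.taxon_ids[int(order[-1])]


def classify_abundance(mean_rel_abund: float) -> str:
    """Classify a taxon by mean relative abundance.

    rare: < 0.01 %; moderate: 0.01 % to 0.1 % (closed interval);
    abundant: > 0.1 %.
    """
    if not 0.0 <= mean_rel_abund <= 1.0:
        raise ValueError(f"mean relative abundance {mean_rel_abund} not in [0, 1]")
    if mean_rel_abund < RARE_MAX:
        return "rare"
    if mean_rel_abund <= ABUNDANT_MIN:
        return "moderate"
    return "abundant"


def mean_relative_abundance(abund: AbundanceMatrix, taxon_id: str) -> float:
    """Mean of X_i over all samples of the fitting unit, zeros included."""
    i = abund.index_of(taxon_id)
    X = np.hstack([Xr[i] for _, Xr in abund.replicates.values()])
    return float(X.mean())


def presence_filter(abund: AbundanceMatrix, min_points: int = 6) -> list[str]:
    """Taxa present (abundance > 0) at >= min_points time points overall."""
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    X = np.hstack([Xr for _, Xr in abund.replicates.values()])
    presence = (X > 0).sum(axis=1)
    return [t for t, n in zip(abund.taxon_ids, presence) if n >= min_points]


def build_regression_dataset(
    abund: AbundanceMatrix,
    resources: ResourceSeries | list[ResourceSeries] | dict[str, ResourceSeries],
    taxon_id: str,
    reference_id: str,
    *,
    pseudo_abundance: float = 0.0,
) -> RegressionDataset:
    """Assemble interval observations for one focal taxon.

    For each consecutive sample pair within a replicate at which both
    the focal and the reference taxon are present, one observation is
    produced with response (Z_{k+1} - Z_k)/dt and regressors evaluated
    at the left endpoint.  ``pseudo_abundance`` > 0 substitutes that
    floor for zero abundances instead of dropping the interval.
    """
    if isinstance(resources, ResourceSeries):
        resources = {resources.replicate_id: resources}
    elif isinstance(resources, list):
        resources = {r.replicate_id: r for r in resources}

    i = abund.index_of(taxon_id)
    r = abund.index_of(reference_id)
    if i == r:
        raise ValueError("focal taxon cannot be the reference taxon")

    rows: list[tuple] = []
    resource_names: list[str] | None = None
    for rep, (days, X) in abund.replicates.items():
        if rep not in resources:
            raise KeyError(f"no resource series for replicate {rep!r}")
        series = resources[rep]
        if resource_names is None:
            resource_names = list(series.resource_names)
        R = series.at(days)  # (time, J)
        xi = X[i].astype(float).copy()
        xr = X[r].astype(float).copy()
        if pseudo_abundance > 0:
            xi[xi == 0] = pseudo_abundance
            xr[xr == 0] = pseudo_abundance
        for k in range(len(days) - 1):
            if min(xi[k], xi[k + 1], xr[k], xr[k + 1]) <= 0:
                continue
            dt = days[k + 1] - days[k]
            z0 = np.log(xi[k] / xr[k])
            z1 = np.log(xi[k + 1] / xr[k + 1])
            w = dt / (2.0 / xi[k] + 2.0 / xr[k])
            rows.append(
                ((z1 - z0) / dt, R[k], 1.0 / xi[k], 1.0 / xr[k], dt, w, rep, days[k])
            )

    if resource_names is None:
        resource_names = []
    n = len(rows)
    J = len(resource_names)
    return RegressionDataset(
        taxon_id=taxon_id,
        reference_id=reference_id,
        resource_names=resource_names,
        response=np.array([row[0] for row in rows], dtype=float),
        resources=(
            np.array([row[1] for row in rows], dtype=float).reshape(n, J)
            if n
            else np.empty((0, J))
        ),
        inv_x=np.array([row[2] for row in rows], dtype=float),
        inv_xr=np.array([row[3] for row in rows], dtype=float),
        dt=np.array([row[4] for row in rows], dtype=float),
        weights=np.array([row[5] for row in rows], dtype=float),
        replicate_ids=np.array([row[6] for row in rows], dtype=object),
        days=np.array([row[7] for row in rows], dtype=float),
    )


def combine_replicates(datasets: list[RegressionDataset]) -> RegressionDataset:
    """Pool interval observations from replicate series of one taxon.

    Observations are concatenated; differences are never taken across
    replicate boundaries (each input dataset already respects them).
    """
    if not datasets:
        raise ValueError("no datasets to combine")
    first = datasets[0]
    for ds in datasets[1:]:
        if ds.taxon_id != first.taxon_id or ds.reference_id != first.reference_id:
            raise ValueError(
                "cannot combine datasets with different taxon or reference ids"
            )
        if ds.resource_names != first.resource_names:
            raise ValueError("cannot combine datasets with different resources")
    return RegressionDataset(
        taxon_id=first.taxon_id,
        reference_id=first.reference_id,
        resource_names=first.resource_names,
        response=np.concatenate([d.response for d in datasets]),
        resources=np.vstack([d.resources for d in datasets]),
        inv_x=np.concatenate([d.inv_x for d in datasets]),
        inv_xr=np.concatenate([d.inv_xr for d in datasets]),
        dt=np.concatenate([d.dt for d in datasets]),
        weights=np.concatenate([d.weights for d in datasets]),
        replicate_ids=np.concatenate([d.replicate_ids for d in datasets]),
        days=np.concatenate([d.days for d in datasets]),
    )
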