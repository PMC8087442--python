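"""Group-representative connectome construction.

The template manifold is computed from a group connectome built from the
template cohort.  Two aggregation schemes are provided: distance-dependent
thresholding, which bins edges by inter-parcel distance (intra- and
inter-hemispheric pools handled separately) and keeps the most consistently
observed edges in every bin, so long-range connections survive; and
consistency thresholding, which averages the stack and drops the edges with
the highest across-subject coefficient of variation (drop fraction 0 reduces
to simple averaging).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import Connectome
from .parcellation import ParcelTable


@dataclass
class GroupConnectome:
    connectome: Connectome
    method: str  # distance_dependent | consistency | simple_average
    params: dict


def log_transform(conn: Connectome) -> Connectome:
    """Elementwise w -> ln(1 + w); errors on double application."""
    if conn.log_transformed:
        raise ValueError("connectome is already log-transformed")
    if (conn.weights < 0).any():
        raise ValueError("log transform requires nonnegative weights")
    return Connectome(weights=np.log1p(conn.weights),
                      parcel_ids=conn.parcel_ids, log_transformed=True)


def _stack(conns: list[Connectome]) -> np.ndarray:
    if len(conns) == 0:
        raise ValueError("need at least one connectome")
    shapes = {c.weights.shape for c in conns}
    if len(shapes) != 1:
        raise ValueError("connectomes have mismatched sizes")
    flags = {c.log_transformed for c in conns}
    if len(flags) != 1:
        raise ValueError("mixed log-transform state in stack")
    return np.stack([c.weights for c in conns])


def distance_dependent_group(conns: list[Connectome], parcels: ParcelTable,
                             n_bins: int = 10) -> GroupConnectome:
    """Distance-binned consensus connectome (long-range preserving).

    Target edge count is the mean per-subject nonzero edge count.  Edges are
    pooled by hemisphere relation (intra vs inter), each pool's distances are
    split into ``n_bins`` equal-frequency bins, and within every bin the edges
    with the highest across-subject occurrence (ties: mean weight, then edge
    index) fill the bin's proportional share of the target.  A retained
    edge's weight is its mean over the subjects in which it occurs.
    """
    if len(conns) < 2:
        raise ValueError("distance-dependent consensus needs >= 2 subjects")
    stack = _stack(conns)
    n = stack.shape[1]
    cids = parcels.cortical_ids
    if n != len(cids):
        raise ValueError("connectomes must cover the cortical parcels only")
    iu = np.triu_indices(n, k=1)
    present = stack[:, iu[0], iu[1]] > 0  # subjects x edges
    occ = present.sum(axis=0)
    if occ.sum() == 0:
        raise ValueError("all connectomes are empty")
    with np.errstate(invalid="ignore"):
        mean_w = np.where(occ > 0, stack[:, iu[0], iu[1]].sum(axis=0) / np.maximum(occ, 1), 0.0)
    target = int(round(present.sum(axis=1).mean()))

    hemi = parcels.table.set_index("parcel_id").loc[cids, "hemisphere"].to_numpy()
    d = parcels.great_circle_distances()[iu]
    intra = hemi[iu[0]] == hemi[iu[1]]

    keep = np.zeros(len(occ), dtype=bool)
    n_subjects = stack.shape[0]
    for pool_mask in (intra, ~intra):
        idx = np.flatnonzero(pool_mask & (occ > 0))
        if len(idx) == 0:
            continue
        # equal-frequency distance bins over the pool's observed edges;
        # each bin keeps as many edges as the average subject has in it
        order = idx[np.argsort(d[idx], kind="stable")]
        bins = np.array_split(order, min(n_bins, len(order)))
        for b in bins:
            share = int(round(occ[b].sum() / n_subjects))
            share = min(max(share, 0), len(b))
            if share <= 0:
                continue
            rank = sorted(b, key=lambda e: (-occ[e], -mean_w[e], e))
            keep[rank[:share]] = True

    w = np.zeros((n, n))
    w[iu[0][keep], iu[1][keep]] = mean_w[keep]
    w = w + w.T
    out = Connectome(weights=w, parcel_ids=conns[0].parcel_ids,
                     log_transformed=conns[0].log_transformed)
    return GroupConnectome(connectome=out, method="distance_dependent",
                           params=dict(n_bins=n_bins, target_edges=target))


def consistency_group(conns: list[Connectome],
                      drop_fraction: float = 0.0) -> GroupConnectome:
    """Average connectome with the most variable edges removed.

    The ``drop_fraction`` of nonzero edges with the highest across-subject
    coefficient of variation (SD/mean over all subjects) is zeroed;
    drop_fraction 0 is plain averaging.
    """
    if not (0 <= drop_fraction < 1):
        raise ValueError("drop_fraction must be in [0, 1)")
    stack = _stack(conns)
    if drop_fraction > 0 and len(conns) < 2:
        raise ValueError("coefficient of variation undefined for one subject")
    mean = stack.mean(axis=0)
    np.fill_diagonal(mean, 0.0)
    if drop_fraction > 0:
        sd = stack.std(axis=0, ddof=0)
        iu = np.triu_indices(mean.shape[0], k=1)
        nz = np.flatnonzero(mean[iu] > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean[iu][nz] > 0, sd[iu][nz] / mean[iu][nz], 0.0)
        n_drop = int(round(drop_fraction * len(nz)))
        if n_drop > 0:
            # highest CV first; ties broken by edge index for determinism
            order = sorted(range(len(nz)), key=lambda k: (-cv[k], nz[k]))
            drop = nz[np.array(order[:n_drop])]
            mean[iu[0][drop], iu[1][drop]] = 0.0
            mean[iu[1][drop], iu[0][drop]] = 0.0
    out = Connectome(weights=mean, parcel_ids=conns[0].parcel_ids,
                     log_transformed=conns[0].log_transformed)
    method = "simple_average" if drop_fraction == 0 else "consistency"
    return GroupConnectome(connectome=out, method=method,
                           params=dict(drop_fraction=drop_fraction))
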