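"""Sample-sample association networks from shared prognosis-associated
specificity clusters, with label assortativity to quantify separation."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .motifs import SpecificityCluster

__all__ = [
    "membership_matrix",
    "build_network",
    "prognosis_assortativity",
]

DEFAULT_R_THRESHOLD = 0.60


def membership_matrix(
    clusters: Sequence[SpecificityCluster],
    patients: Sequence[str],
) -> pd.DataFrame:
    """Binary patient x cluster matrix: 1 iff the patient contributes at
    least one member peptide to the cluster.  All-zero rows are kept."""
    if not clusters:
        raise ValidationError("membership_matrix: no clusters")
    patients = sorted(patients)
    data = {}
    for cluster in clusters:
        carriers = {pid for pid, _ in cluster.members}
        data[cluster.cluster_id] = [int(p in carriers) for p in patients]
    return pd.DataFrame(data, index=patients)


def build_network(
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | None = None,
    r_threshold: float = DEFAULT_R_THRESHOLD,
) -> nx.Graph:
    """Undirected network over patients: an edge wherever the Pearson
    correlation of two membership rows reaches ``r_threshold``.

    Constant rows have undefined correlation and are excluded (noted via
    a warning when present).
    """
    if matrix.shape[0] < 2:
        raise ValidationError("build_network needs >= 2 patients")
    rows = matrix.to_numpy(dtype=float)
    keep = rows.std(axis=1) > 0
    if not keep.any():
        warnings.warn("all membership rows constant; empty network",
                      stacklevel=2)
        keep = np.zeros(len(rows), dtype=bool)
    elif not keep.all():
        dropped = list(matrix.index[~keep])
        warnings.warn(f"constant membership rows excluded: {dropped}",
                      stacklevel=2)
    g = nx.Graph()
    for pid in matrix.index:
        g.add_node(pid, prognosis=(labels or {}).get(pid, ""))
    kept_idx = np.flatnonzero(keep)
    if len(kept_idx) >= 2:
        sub = rows[kept_idx]
        corr = np.corrcoef(sub)
        for ii in range(len(kept_idx)):
            for jj in range(ii + 1, len(kept_idx)):
                r = float(corr[ii, jj])
                if r >= r_threshold:
                    g.add_edge(matrix.index[kept_idx[ii]],
                               matrix.index[kept_idx[jj]], r=r)
    return g


def prognosis_assortativity(network: nx.Graph,
                            attribute: str = "prognosis") -> float:
    """Label assortativity over edges: 1 when every edge joins
    same-label nodes, negative for predominantly cross-label edges.

    A network whose edges all share a single label value is maximally
    assortative by convention (the normalisation degenerates to 0/0).
    """
    if network.number_of_edges() == 0:
        raise ValidationError("prognosis_assortativity: network has no edges")
    labels = sorted({network.nodes[n][attribute]
                     for edge in network.edges for n in edge})
    if len(labels) == 1:
        return 1.0
    idx = {lab: i for i, lab in enumerate(labels)}
    e = np.zeros((len(labels), len(labels)))
    for a, b in network.edges:
        i, j = idx[network.nodes[a][attribute]], idx[network.nodes[b][attribute]]
        e[i, j] += 1
        e[j, i] += 1
    e /= e.sum()
    a_marg = e.sum(axis=1)
    trace = np.trace(e)
    expected = float(a_marg @ a_marg)
    if expected == 1.0:
        return 1.0
    return float((trace - expected) / (1.0 - expected))
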