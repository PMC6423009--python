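"""Molecular subtyping by consensus NMF of the event-CCF matrix.

Patients are clustered on the matrix of CCFs of the prognosis-associated
events (rows: events, columns: samples; 0 when an event is absent).  NMF
with Kullback-Leibler multiplicative updates (Brunet-style) is run from many
random initializations; each run assigns samples to their dominant basis
component, the consensus matrix records how often two samples co-cluster,
and the final k-group assignment comes from hierarchical clustering of the
consensus.  The number of subgroups is chosen by the cophenetic rule over
k = 2..6: the first k whose cophenetic coefficient exceeds that of k+1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "SubtypeAssignment",
    "RankSelectionReport",
    "build_ccf_matrix",
    "nmf_subtype",
    "cophenetic_coefficient",
    "choose_k_by_cophenetic",
    "select_rank",
]


@dataclass
class SubtypeAssignment:
    sample_id: str
    cluster: str
    membership_weights: np.ndarray  # nonnegative, sums to 1; cluster == argmax


@dataclass
class RankSelectionReport:
    k_values: list[int]
    cophenetic: dict[int, float]
    chosen_k: int


def build_ccf_matrix(calls: pd.DataFrame, selected_events, sample_ids=None) -> pd.DataFrame:
    """Events x samples CCF matrix; absent events are encoded as 0.

    ``calls`` needs columns sample_id, event_id, ccf.  Samples without any
    selected event are retained as zero columns when listed in
    ``sample_ids``.
    """
    sel = calls[calls["event_id"].isin(selected_events)]
    if ((sel["ccf"] < 0) | (sel["ccf"] > 1)).any():
        raise ValueError("CCF outside [0,1] in calls")
    if sample_ids is None:
        sample_ids = sorted(calls["sample_id"].unique())
    mat = pd.DataFrame(0.0, index=list(selected_events), columns=list(sample_ids))
    for r in sel.itertuples(index=False):
        if r.sample_id in mat.columns:
            mat.loc[r.event_id, r.sample_id] = r.ccf
    return mat


def _nmf_kl(V, k, rng, max_iter=500, tol=1e-6):
    """Brunet multiplicative updates for the KL-divergence NMF objective."""
    p, n = V.shape
    W = rng.uniform(0.1, 1.0, size=(p, k))
    H = rng.uniform(0.1, 1.0, size=(k, n))
    eps = 1e-12
    prev = np.inf
    for it in range(max_iter):
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + eps)
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + eps)
        if it % 10 == 0:
            WH = W @ H + eps
            div = float((V * np.log((V + eps) / WH) - V + WH).sum())
            if np.isfinite(prev) and prev - div <= tol * max(abs(prev), 1e-30):
                break
            prev = div
    return W, H


def nmf_subtype(
    matrix: pd.DataFrame,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[list[SubtypeAssignment], pd.DataFrame]:
    """Consensus NMF subtyping of the CCF matrix into ``k`` clusters.

    Returns per-sample assignments (cluster plus membership weights derived
    from the consensus matrix) and the symmetric consensus matrix itself.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = matrix.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    V = matrix.to_numpy(dtype=float)
    if (V < 0).any():
        raise ValueError("matrix must be nonnegative")
    rng = np.random.default_rng(seed)
    consensus = np.zeros((n, n))
    for _ in range(n_runs):
        _, H = _nmf_kl(V + 1e-9, k, rng, max_iter=max_iter)
        labels = H.argmax(axis=0)
        same = labels[:, None] == labels[None, :]
        consensus += same
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)
    cons = pd.DataFrame(consensus, index=matrix.columns, columns=matrix.columns)

    groups = _consensus_groups(consensus, k)
    # membership weight of sample i for cluster c: mean consensus with c's members
    weights = np.zeros((n, k))
    for c in range(k):
        members = np.flatnonzero(groups == c)
        weights[:, c] = consensus[:, members].mean(axis=1)
    rowsum = weights.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    weights = weights / rowsum
    labels = weights.argmax(axis=1)  # ties resolve to the lowest cluster index
    assignments = [
        SubtypeAssignment(
            sample_id=str(s),
            cluster=f"C{labels[i] + 1}",
            membership_weights=weights[i],
        )
        for i, s in enumerate(matrix.columns)
    ]
    return assignments, cons


def _consensus_groups(consensus: np.ndarray, k: int) -> np.ndarray:
    """Cut the average-linkage dendrogram of 1-consensus into k groups."""
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1


def cophenetic_coefficient(consensus: pd.DataFrame) -> float:
    """Correlation between consensus dissimilarities and cophenetic distances."""
    c = consensus.to_numpy(dtype=float)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    y = squareform(d, checks=False)
    Z = hierarchy.linkage(y, method="average")
    coef, _ = hierarchy.cophenet(Z, y)
    return float(coef)


def choose_k_by_cophenetic(cophenetic: dict[int, float]) -> tuple[int, bool]:
    """The k before the first strict decrease of the cophenetic coefficient.

    Returns (chosen_k, decreased); when the coefficient never decreases the
    largest k is returned with decreased=False (callers warn).
    """
    ks = sorted(cophenetic)
    for a, b in zip(ks, ks[1:]):
        if cophenetic[a] > cophenetic[b]:
            return a, True
    return ks[-1], False


def select_rank(
    matrix: pd.DataFrame,
    k_range=range(2, 7),
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 500,
) -> RankSelectionReport:
    """Cophenetic rank selection over ``k_range`` (default 2..6).

    The chosen k is the smallest k whose cophenetic coefficient strictly
    exceeds that of k+1 (the k before the first decrease); if the
    coefficient never decreases the largest k is returned with a warning.
    """
    ks = sorted(k_range)
    if len(ks) < 2:
        raise ValueError("k_range must contain at least two values")
    coph: dict[int, float] = {}
    for i, k in enumerate(ks):
        _, cons = nmf_subtype(matrix, k, n_runs=n_runs, seed=seed + i, max_iter=max_iter)
        coph[k] = cophenetic_coefficient(cons)
    chosen, decreased = choose_k_by_cophenetic(coph)
    if not decreased:
        warnings.warn("cophenetic coefficient never decreased; returning max k")
    return RankSelectionReport(k_values=ks, cophenetic=coph, chosen_k=chosen)
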