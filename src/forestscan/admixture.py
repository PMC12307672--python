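"""Relatedness, PCA and rule-based selection on admixture profiles.

An admixture profile is a sample's vector of K ancestry proportions (a
row of a Q-matrix, summing to 1). The relatedness of two samples is the
overlap of their profiles, r(A, B) = sum_k min(q_Ak, q_Bk) — the
intersection of two probability vectors, equal to 1 minus half their L1
distance, so 1 - r is a proper metric. PCA on the raw proportions gives
a low-dimensional view of population structure; thresholding a single
ancestry component gives a simple rule-based group classifier.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


def read_qmatrix(path: str | Path, tol: float = 1e-6) -> pd.DataFrame:
    """Read a Q-matrix CSV (``sample, q1..qK``) of ancestry proportions.

    Rows off unit sum by more than ``tol`` are renormalized with a
    warning; negative entries are rejected.
    """
    df = pd.read_csv(path, index_col=0)
    Q = df.to_numpy(float)
    if (Q < 0).any():
        raise ValueError(f"{path}: negative ancestry proportions")
    sums = Q.sum(axis=1)
    off = np.abs(sums - 1.0) > tol
    if off.any():
        logger.warning("%s: renormalized %d rows with sum != 1", path, int(off.sum()))
        Q = Q / sums[:, None]
    return pd.DataFrame(Q, index=df.index, columns=df.columns)


def _check_profiles(profiles: pd.DataFrame) -> np.ndarray:
    Q = profiles.to_numpy(float)
    if Q.ndim != 2 or Q.shape[1] < 2:
        raise ValueError("profiles must be an n x K table with K >= 2")
    if (Q < -1e-12).any():
        raise ValueError("ancestry proportions must be nonnegative")
    if np.abs(Q.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("profile rows must sum to 1 (load via read_qmatrix)")
    return Q


def pairwise_relatedness(profiles: pd.DataFrame) -> pd.DataFrame:
    """Overlap relatedness r(A, B) = sum_k min(q_Ak, q_Bk) for all pairs.

    Returns a symmetric DataFrame with unit diagonal, values in [0, 1].
    """
    Q = _check_profiles(profiles)
    r = np.minimum(Q[:, None, :], Q[None, :, :]).sum(axis=-1)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=profiles.index, columns=profiles.index)


def relatedness_to_distance(relatedness: pd.DataFrame) -> pd.DataFrame:
    """Distance view d = 1 - r (half the L1 distance between profiles)."""
    return 1.0 - relatedness


def admixture_pca(
    profiles: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean-centred PCA of the n x K proportion matrix.

    Components are sign-fixed so each one's largest-magnitude loading is
    positive, making coordinates deterministic. Returns (coordinates,
    explained variance). Proportions share a unit, so no per-column
    scaling is applied.
    """
    Q = _check_profiles(profiles)
    if Q.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    n_components = min(n_components, min(Q.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(Q)
    for c in range(coords.shape[1]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] *= -1
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=profiles.index, columns=cols),
        pca.explained_variance_.copy(),
    )


def select_by_ancestry(
    profiles: pd.DataFrame, component: int, min_fraction: float
) -> pd.DataFrame:
    """Samples whose proportion of one ancestry is at least ``min_fraction``.

    ``component`` is the 0-based ancestry index. The returned table
    carries the per-sample proportion for audit, sorted descending.
    """
    Q = _check_profiles(profiles)
    if not 0 <= component < Q.shape[1]:
        raise ValueError(f"ancestry component {component} out of range")
    qk = Q[:, component]
    keep = qk >= min_fraction
    out = pd.DataFrame(
        {"sample": profiles.index[keep], "fraction": qk[keep]}
    ).sort_values("fraction", ascending=False)
    return out.reset_index(drop=True)


def profile_similarity_rank(profiles: pd.DataFrame, query: str) -> pd.DataFrame:
    """All samples ranked by descending relatedness to ``query``.

    The query itself ranks first with r = 1; useful for spotting
    duplicates and near-duplicates.
    """
    if query not in profiles.index:
        raise KeyError(f"query sample {query!r} not in profiles")
    r = pairwise_relatedness(profiles)[query]
    out = pd.DataFrame({"sample": r.index, "relatedness": r.values})
    out = out.sort_values(
        ["relatedness", "sample"], ascending=[False, True], kind="stable"
    )
    return out.reset_index(drop=True)
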