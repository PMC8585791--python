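"""Pre/post matrix comparison in the contralesional hemisphere.

The core statistic is the 2-D correlation coefficient between two equally
sized matrices A (pre-operative) and B (post-operative),

    c = sum_mn (A_mn - mean(A)) (B_mn - mean(B))
        / sqrt( sum_mn (A_mn - mean(A))^2 * sum_mn (B_mn - mean(B))^2 ),

i.e. the Pearson correlation of corresponding entries.  In the default
``full`` mode the double sum runs over every entry, including the unit
diagonal and both (duplicated) triangles of the symmetric matrix — the
literal definition.  ``offdiag`` mode, provided as a sensitivity option,
restricts the sums to off-diagonal entries, since a shared constant diagonal
inflates the similarity of two correlation matrices.

A subject is scored by truncating both whole-brain matrices to the
contralesional hemisphere, computing c on the full hemispheric matrix and on
each resting-state-network principal submatrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .atlas import ANALYZED_NETWORKS, ROITable, network_abbreviation
from .connectivity import ConnectivityMatrix
from .errors import UndefinedCoefficientError, ValidationError

#: Pseudo-network name for the full hemispheric comparison.
HEMISPHERE = "hemisphere"

#: Ordered network abbreviations used for per-network scores.
NETWORK_ORDER: tuple[str, ...] = tuple(abbr for abbr, _ in ANALYZED_NETWORKS)


@dataclass(frozen=True)
class PairScore:
    """2-D correlation of one subject's pre/post matrices for one network."""

    subject_id: str
    network: str
    c: float


def truncate_contralesional(matrix: ConnectivityMatrix,
                            indices: Sequence[int]) -> ConnectivityMatrix:
    """Principal submatrix on the given (ordered) contralesional indices."""
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValidationError("empty index sequence")
    if idx.min() < 0 or idx.max() >= matrix.n:
        raise ValidationError(
            f"index out of range for a {matrix.n} x {matrix.n} matrix"
        )
    values = matrix.values[np.ix_(idx, idx)]
    roi_ids = tuple(matrix.roi_ids[i] for i in idx)
    return ConnectivityMatrix(values=values, roi_ids=roi_ids,
                              n_frames_used=matrix.n_frames_used)


def build_partition(table: ROITable, indices: Sequence[int],
                    min_size: int = 3) -> dict[str, np.ndarray]:
    """Map each analyzed network to its positions within the hemispheric matrix.

    ``indices`` are the contralesional canonical-order indices; the returned
    positions index rows/columns of the *truncated* matrix.  Networks with
    fewer than ``min_size`` ROIs in the hemisphere are omitted: a 1 x 1
    submatrix has nothing to correlate, and a 2 x 2 correlation submatrix has
    a single distinct off-diagonal value, so its full-mode 2-D correlation is
    identically 1 regardless of the data.  ROIs of the three
    excluded communities and unlabeled ROIs receive no per-network entry but
    remain part of the hemisphere-level comparison.
    """
    labels = table.networks
    partition: dict[str, np.ndarray] = {}
    for abbr, name in ANALYZED_NETWORKS:
        pos = np.array(
            [p for p, i in enumerate(indices) if labels[i] == name], dtype=int
        )
        if pos.size >= min_size:
            partition[abbr] = pos
    return partition


def network_submatrix(hemi: ConnectivityMatrix,
                      partition: Mapping[str, np.ndarray],
                      network: str) -> ConnectivityMatrix:
    """Principal submatrix of the hemispheric matrix for one network."""
    key = network_abbreviation(network) if network not in partition else network
    if key not in partition:
        raise ValidationError(
            f"network {network!r} not in partition "
            f"(available: {sorted(partition)})"
        )
    return truncate_contralesional(hemi, partition[key])


def corr2(A, B, mode: str = "full") -> float:
    """2-D correlation coefficient between two equally sized matrices.

    ``mode="full"`` (default) sums over all entries; ``mode="offdiag"``
    excludes the diagonal.  The result lies in [-1, 1] by Cauchy-Schwarz.
    Raises :class:`UndefinedCoefficientError` when either matrix is constant
    over the summed region.
    """
    a = np.asarray(A.values if isinstance(A, ConnectivityMatrix) else A, dtype=float)
    b = np.asarray(B.values if isinstance(B, ConnectivityMatrix) else B, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValidationError("corr2 operands must be 2-D matrices")
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < 2:
        raise ValidationError("corr2 needs matrices of dimension >= 2")
    if mode == "full":
        av, bv = a.ravel(), b.ravel()
    elif mode == "offdiag":
        mask = ~np.eye(a.shape[0], a.shape[1], dtype=bool)
        av, bv = a[mask], b[mask]
    else:
        raise ValidationError(f"mode must be 'full' or 'offdiag', got {mode!r}")
    da = av - av.mean()
    db = bv - bv.mean()
    denom = np.sqrt(np.sum(da**2) * np.sum(db**2))
    if denom == 0 or not np.isfinite(denom):
        raise UndefinedCoefficientError(
            "2-D correlation undefined: a matrix is constant over the summed "
            f"region (mode={mode!r})"
        )
    return float(np.clip(np.sum(da * db) / denom, -1.0, 1.0))


def score_subject(
    subject_id: str,
    pre: ConnectivityMatrix,
    post: ConnectivityMatrix,
    indices: Sequence[int],
    partition: Mapping[str, np.ndarray],
    mode: str = "full",
) -> list[PairScore]:
    """All pair scores for one subject: hemisphere first, then each network.

    Both whole-brain matrices are truncated to the contralesional indices;
    one score is emitted for the full hemispheric comparison and one per
    network in the partition.
    """
    if pre.roi_ids != post.roi_ids:
        raise ValidationError(
            f"subject {subject_id!r}: pre and post matrices have different "
            "ROI orders"
        )
    hemi_pre = truncate_contralesional(pre, indices)
    hemi_post = truncate_contralesional(post, indices)
    scores = [PairScore(subject_id, HEMISPHERE,
                        corr2(hemi_pre, hemi_post, mode=mode))]
    for network in NETWORK_ORDER:
        if network not in partition:
            continue
        sub_pre = network_submatrix(hemi_pre, partition, network)
        sub_post = network_submatrix(hemi_post, partition, network)
        scores.append(PairScore(subject_id, network,
                                corr2(sub_pre, sub_post, mode=mode)))
    return scores
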