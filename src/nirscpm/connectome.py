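"""Resting-state functional connectivity features.

Each channel is a node; the connectivity between two channels is the Pearson
correlation of their band-limited hemodynamic time courses over the full
retained recording. For n channels this yields a symmetric n x n matrix
with unit diagonal and E = n(n-1)/2 unique edges, vectorized in a fixed
row-major upper-triangle order (i < j, 0-based internally; channel labels in
outputs are 1-based). Raw Pearson coefficients are used as features — no
Fisher z-transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .optics import HemoSeries


def n_edges(n_channels: int) -> int:
    return n_channels * (n_channels - 1) // 2


def edge_indices(n_channels: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (row-major) channel index pairs defining the edge order."""
    return np.triu_indices(n_channels, k=1)


def edge_table(n_channels: int) -> pd.DataFrame:
    """Edge id -> (1-based channel i, channel j) lookup in canonical order."""
    iu, ju = edge_indices(n_channels)
    return pd.DataFrame(
        {"edge_id": np.arange(iu.size), "chan_i": iu + 1, "chan_j": ju + 1}
    )


def matrix_to_edges(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise InputError(f"expected a square matrix, got shape {matrix.shape}")
    iu, ju = edge_indices(matrix.shape[0])
    return matrix[iu, ju].copy()


def edges_to_matrix(edges: np.ndarray, n_channels: int, diagonal: float = 1.0) -> np.ndarray:
    edges = np.asarray(edges)
    if edges.size != n_edges(n_channels):
        raise InputError(
            f"edge vector of length {edges.size} does not match "
            f"{n_channels} channels (expected {n_edges(n_channels)})"
        )
    m = np.full((n_channels, n_channels), diagonal, dtype=float)
    iu, ju = edge_indices(n_channels)
    m[iu, ju] = edges
    m[ju, iu] = edges
    return m


@dataclass
class ConnectivityFeatures:
    """Per-participant RSFC matrix and its canonical edge vectorization."""

    participant_id: str
    matrix: np.ndarray
    edges: np.ndarray
    chromophore: str = "HbO"

    def validate(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InputError("connectivity matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise InputError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise InputError("connectivity diagonal must be 1")
        if np.any(np.abs(m) > 1 + 1e-9):
            raise InputError("correlations must lie in [-1, 1]")
        if self.edges.size != n_edges(m.shape[0]):
            raise InputError("edge vector length inconsistent with matrix size")


def _pairwise_complete_corr(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pearson correlation per pair over samples where *both* channels are
    unflagged. Means and variances are recomputed on each pair's common
    support (unlike masked-array corrcoef, which normalizes per channel)."""
    n = data.shape[0]
    good = ~mask
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            keep = good[i] & good[j]
            if keep.sum() < 3:
                raise InputError(
                    f"channels {i + 1} and {j + 1}: fewer than 3 jointly "
                    "unflagged samples; correlation undefined"
                )
            xi, xj = data[i, keep], data[j, keep]
            if xi.std() == 0 or xj.std() == 0:
                raise InputError(
                    f"channels {i + 1} and {j + 1}: constant on the jointly "
                    "unflagged samples"
                )
            corr[i, j] = corr[j, i] = np.corrcoef(xi, xj)[0, 1]
    return corr


def rsfc_matrix(
    series: HemoSeries, chromophore: str = "HbO", use_mask: bool = True
) -> ConnectivityFeatures:
    """Pearson correlation between every pair of channel time courses.

    If the series carries artifact flags and ``use_mask`` is set, flagged
    samples are excluded pairwise-complete: each pair's correlation uses the
    time points at which both channels are unflagged.
    """
    series.validate()
    data = series.chromophore(chromophore)
    n, T = data.shape
    if T < 3:
        raise InputError("need at least 3 time points for correlation")
    sd = data.std(axis=1)
    scale = np.abs(data).max(axis=1) + 1.0
    constant = np.flatnonzero(sd <= 1e-12 * scale)
    if constant.size:
        labels = ", ".join(str(c + 1) for c in constant)
        raise InputError(f"constant channel(s) {labels}: correlation undefined")
    if use_mask and np.any(series.artifact_mask):
        corr = _pairwise_complete_corr(data, np.asarray(series.artifact_mask, bool))
    else:
        corr = np.corrcoef(data)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    feats = ConnectivityFeatures(
        participant_id=series.participant_id,
        matrix=corr,
        edges=matrix_to_edges(corr),
        chromophore=chromophore,
    )
    feats.validate()
    return feats


@dataclass
class CohortDataset:
    """Aligned cohort feature matrix (N x E) with phenotype scores."""

    X: np.ndarray
    state: np.ndarray
    trait: np.ndarray
    participant_ids: list[str]
    n_channels: int
    channel_meta: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def validate(self) -> None:
        N = self.X.shape[0]
        if len(self.participant_ids) != N:
            raise InputError("participant id list does not match feature rows")
        if self.state.shape != (N,) or self.trait.shape != (N,):
            raise InputError("score vectors must have one entry per participant")
        if not (np.all(np.isfinite(self.state)) and np.all(np.isfinite(self.trait))):
            raise InputError("missing or non-finite phenotype scores")
        if self.X.shape[1] != n_edges(self.n_channels):
            raise InputError("feature columns inconsistent with channel count")


def assemble_cohort(
    features: list[ConnectivityFeatures],
    phenotypes: pd.DataFrame,
    channel_meta: pd.DataFrame | None = None,
    provenance: dict | None = None,
) -> CohortDataset:
    """Join per-participant edge vectors with phenotype scores.

    ``phenotypes`` needs columns participant_id, state, trait. Participants
    are ordered by sorted id, so input order never matters.
    """
    required = {"participant_id", "state", "trait"}
    if not required.issubset(phenotypes.columns):
        raise InputError(f"phenotype table must have columns {sorted(required)}")
    ids = [f.participant_id for f in features]
    if len(set(ids)) != len(ids):
        raise InputError("duplicated participant ids in features")
    pheno_ids = phenotypes["participant_id"].astype(str)
    if pheno_ids.duplicated().any():
        raise InputError("duplicated participant ids in phenotype table")
    pheno = phenotypes.assign(participant_id=pheno_ids).set_index("participant_id")
    missing = set(ids) - set(pheno.index)
    extra = set(pheno.index) - set(ids)
    if missing or extra:
        raise InputError(
            f"feature/phenotype id mismatch: missing scores for {sorted(missing)}, "
            f"scores without features for {sorted(extra)}"
        )
    by_id = {f.participant_id: f for f in features}
    order = sorted(ids)
    n_chan = int(round((1 + np.sqrt(1 + 8 * features[0].edges.size)) / 2))
    X = np.vstack([by_id[i].edges for i in order])
    ds = CohortDataset(
        X=X,
        state=pheno.loc[order, "state"].to_numpy(dtype=float),
        trait=pheno.loc[order, "trait"].to_numpy(dtype=float),
        participant_ids=order,
        n_channels=n_chan,
        channel_meta=channel_meta,
        provenance=provenance or {},
    )
    ds.validate()
    return ds
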