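"""Probe ("DIC") displacement fields and k-nearest-neighbor interpolation.

A stereo-DIC system reports 3-component displacements at a few thousand probe
points on the lung surface at each inflation stage.  These points do not
coincide with FE nodes, so a k-nearest-neighbor interpolator (k = 5,
unweighted mean) maps displacement fields between the two point sets; its
accuracy is reported as the 10-fold cross-validated coefficient of
determination.  The same neighbor map is exposed as a sparse linear operator
``W`` (rows = query points, 1/k at the neighbor columns) so the calibration
objective and its adjoint load can be written as ``W u_sim - u_exp``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ProbeField",
    "InterpolatorModel",
    "CVReport",
    "fit_interpolator",
    "cross_validate",
    "interpolation_matrix",
    "read_probe_csv",
    "write_probe_csv",
    "write_operator_triplets",
]


@dataclass
class ProbeField:
    """Probe reference coordinates and measured displacements per stage.

    ``coords``: (n_probes, 3) mm; ``u_exp``: (n_stages, n_probes, 3) mm;
    ``stage_ids``: identifiers (default 0..n_stages-1).
    """

    coords: np.ndarray
    u_exp: np.ndarray
    stage_ids: list = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.u_exp = np.asarray(self.u_exp, float)
        if self.u_exp.ndim == 2:
            self.u_exp = self.u_exp[None]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_probes, 3)")
        if self.u_exp.shape[1:] != self.coords.shape:
            raise ValueError("u_exp must be (n_stages, n_probes, 3)")
        if self.stage_ids is None:
            self.stage_ids = list(range(len(self.u_exp)))
        if len(self.stage_ids) != len(self.u_exp):
            raise ValueError("stage_ids length must match u_exp stages")
        if len(self.coords) > 1:
            nn = NearestNeighbors(n_neighbors=2).fit(self.coords)
            d, _ = nn.kneighbors(self.coords)
            if np.any(d[:, 1] < 1e-9):
                raise ValueError("duplicate probe coordinates (within 1e-9 mm)")

    @property
    def n_probes(self) -> int:
        return len(self.coords)

    @property
    def n_stages(self) -> int:
        return len(self.u_exp)


@dataclass
class InterpolatorModel:
    """Fitted kNN displacement interpolator over probe coordinates."""

    k: int
    coords: np.ndarray
    u_tables: np.ndarray          # (n_stages, n_probes, 3)
    stage_ids: list
    _nn: NearestNeighbors = field(repr=False, default=None)

    def predict(self, query_coords, stage) -> np.ndarray:
        """Unweighted mean displacement of the k nearest probes per query."""
        if stage not in self.stage_ids:
            raise KeyError(f"unknown stage {stage!r}")
        si = self.stage_ids.index(stage)
        q = np.atleast_2d(np.asarray(query_coords, float))
        _, idx = self._nn.kneighbors(q)
        return self.u_tables[si][idx].mean(axis=1)

    def neighbor_matrix(self, query_coords) -> sp.csr_matrix:
        """Sparse (n_query, n_probes) operator with 1/k entries."""
        return interpolation_matrix(self.coords, query_coords, self.k, nn=self._nn)


def fit_interpolator(probe_field: ProbeField, k: int = 5) -> InterpolatorModel:
    """Build the spatial index over probe reference coordinates."""
    if not 1 <= k <= probe_field.n_probes:
        raise ValueError(f"k must lie in [1, {probe_field.n_probes}]")
    nn = NearestNeighbors(n_neighbors=k).fit(probe_field.coords)
    return InterpolatorModel(
        k=k,
        coords=probe_field.coords,
        u_tables=probe_field.u_exp,
        stage_ids=list(probe_field.stage_ids),
        _nn=nn,
    )


def interpolation_matrix(data_coords, query_coords, k: int = 5, nn=None) -> sp.csr_matrix:
    """Sparse kNN-mean operator W: (values at data points) -> (at queries).

    Applied per displacement component: ``u_query = W @ u_data``.  Rows carry
    1/k at the k nearest data columns; neighbor order (and distance ties)
    follow the index ordering of the fitted spatial tree, so the operator is
    deterministic for a fixed data ordering.
    """
    data_coords = np.asarray(data_coords, float)
    query_coords = np.atleast_2d(np.asarray(query_coords, float))
    if nn is None:
        nn = NearestNeighbors(n_neighbors=k).fit(data_coords)
    _, idx = nn.kneighbors(query_coords)
    nq = len(query_coords)
    rows = np.repeat(np.arange(nq), k)
    vals = np.full(nq * k, 1.0 / k)
    return sp.csr_matrix(
        (vals, (rows, idx.ravel())), shape=(nq, len(data_coords))
    )


@dataclass
class CVReport:
    """Per-fold, per-component determination coefficients and their mean."""

    scores: np.ndarray            # (folds, n_stages, 3), NaN where undefined
    mean_accuracy: float
    k: int
    folds: int


def cross_validate(
    probe_field: ProbeField, folds: int = 10, k: int = 5, seed: int = 0
) -> CVReport:
    """Held-out R^2 of the kNN interpolator, averaged over folds/components.

    Folds partition the probes (shuffled, seeded).  A zero-variance target
    component within a fold yields an undefined score: it is excluded from
    the mean with a warning.
    """
    if probe_field.n_probes < folds:
        raise ValueError("need at least as many probes as folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    n_st = probe_field.n_stages
    scores = np.full((folds, n_st, 3), np.nan)
    for fi, (tr, te) in enumerate(kf.split(probe_field.coords)):
        nn = NearestNeighbors(n_neighbors=min(k, len(tr))).fit(
            probe_field.coords[tr]
        )
        _, idx = nn.kneighbors(probe_field.coords[te])
        for si in range(n_st):
            pred = probe_field.u_exp[si][tr][idx].mean(axis=1)
            true = probe_field.u_exp[si][te]
            for c in range(3):
                if np.var(true[:, c]) == 0:
                    warnings.warn(
                        f"fold {fi}, stage {si}, component {c}: zero-variance "
                        "target, score undefined and excluded"
                    )
                    continue
                scores[fi, si, c] = r2_score(true[:, c], pred[:, c])
    mean_acc = float(np.nanmean(scores))
    return CVReport(scores=scores, mean_accuracy=mean_acc, k=k, folds=folds)


def write_operator_triplets(W: sp.spmatrix, path) -> None:
    """Dump a sparse operator as (row, col, value) triplets for inspection."""
    coo = sp.coo_matrix(W)
    pd.DataFrame(
        {"row": coo.row, "col": coo.col, "value": coo.data}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CSV I/O  (columns: probe_id, x, y, z, stage, ux, uy, uz)


def write_probe_csv(field: ProbeField, path) -> None:
    frames = []
    for si, sid in enumerate(field.stage_ids):
        df = pd.DataFrame(
            {
                "probe_id": np.arange(field.n_probes),
                "x": field.coords[:, 0],
                "y": field.coords[:, 1],
                "z": field.coords[:, 2],
                "stage": sid,
                "ux": field.u_exp[si, :, 0],
                "uy": field.u_exp[si, :, 1],
                "uz": field.u_exp[si, :, 2],
            }
        )
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False, float_format="%.12g")


def read_probe_csv(path) -> ProbeField:
    df = pd.read_csv(path)
    need = {"probe_id", "x", "y", "z", "stage", "ux", "uy", "uz"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"probe CSV missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError("probe CSV contains no rows")
    stages = sorted(df["stage"].unique())
    first = df[df["stage"] == stages[0]].sort_values("probe_id")
    coords = first[["x", "y", "z"]].to_numpy()
    u = np.empty((len(stages), len(first), 3))
    for si, s in enumerate(stages):
        sub = df[df["stage"] == s].sort_values("probe_id")
        if len(sub) != len(first):
            raise ValueError(f"stage {s} has a different probe count")
        u[si] = sub[["ux", "uy", "uz"]].to_numpy()
    return ProbeField(coords=coords, u_exp=u, stage_ids=stages)
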