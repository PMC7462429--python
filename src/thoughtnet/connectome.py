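"""Signed, fully connected functional connectomes.

A connectome here is the symmetric matrix of pairwise Pearson correlations
between regional (ROI) activity time series, with a zero diagonal and no
thresholding: both positive and negative weights are kept, because the
balance between correlated and anticorrelated links is itself an object of
analysis downstream (see :mod:`thoughtnet.metrics`).

Raw Pearson r values are analyzed directly; an optional Fisher z-transform
is available for sensitivity runs but is not part of the default pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance for symmetry validation, |A - A.T| elementwise
SYMMETRY_TOL = 1e-12
#: numerical slack allowed past the [-1, 1] correlation range
RANGE_TOL = 1e-9


@dataclass
class Connectome:
    """Symmetric signed weighted matrix of inter-node correlations.

    Parameters
    ----------
    weights
        Square ``(N, N)`` array with values in ``[-1, 1]``, zero diagonal.
    subject_id
        Identifier of the subject the matrix belongs to.
    component_nodes
        Set when the connectome has been masked to a suprathreshold
        component; the sorted node ids of that component. ``None`` for a
        full (unmasked) connectome.
    """

    weights: np.ndarray
    subject_id: str = ""
    component_nodes: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectome must be square, got shape {w.shape}")
        if not np.isfinite(w).all():
            raise ValueError("connectome contains non-finite values")
        asym = np.abs(w - w.T).max() if w.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"connectome asymmetric: max |A - A.T| = {asym:g}")
        out = np.abs(w).max() if w.size else 0.0
        if out > 1.0 + RANGE_TOL:
            raise ValueError(f"weight out of [-1, 1]: max |w| = {out:g}")
        if w.size and np.abs(np.diagonal(w)).max() > RANGE_TOL:
            raise ValueError("connectome diagonal must be zero")
        # exact symmetrization / clipping of numerical dust
        w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def build_connectome(timeseries: np.ndarray | pd.DataFrame,
                     subject_id: str = "",
                     fisher_z: bool = False) -> Connectome:
    """Pairwise Pearson correlation of ROI time series columns.

    Parameters
    ----------
    timeseries
        ``(timepoints, nodes)`` array of BOLD-like signals; at least 10
        timepoints are required.
    fisher_z
        If true, apply ``arctanh`` to the off-diagonal correlations
        (sensitivity option; weights then leave the [-1, 1] range and the
        result is returned as a plain array-backed connectome with
        validation on the r scale skipped).

    Raises
    ------
    ValueError
        On NaNs in the input or constant (zero-variance) columns; the
        error message lists the offending node ids.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be 2-D (timepoints x nodes)")
    if ts.shape[0] < 10:
        raise ValueError(f"need >= 10 timepoints, got {ts.shape[0]}")
    if not np.isfinite(ts).all():
        raise ValueError("time series contains NaN or infinite values")
    sd = ts.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant (zero-variance) node columns: {constant.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    if fisher_z:
        iu = np.triu_indices_from(r, k=1)
        z = np.zeros_like(r)
        z[iu] = np.arctanh(np.clip(r[iu], -1 + 1e-15, 1 - 1e-15))
        z = z + z.T
        c = Connectome.__new__(Connectome)
        c.weights, c.subject_id, c.component_nodes = z, subject_id, None
        return c
    return Connectome(r, subject_id=subject_id)


def mean_connectivity(connectome: Connectome | np.ndarray) -> float:
    """Mean signed weight over the strict upper triangle (each edge once)."""
    w = connectome.weights if isinstance(connectome, Connectome) else np.asarray(connectome)
    iu = np.triu_indices(w.shape[0], k=1)
    return float(w[iu].mean())


def as_stack(connectomes) -> np.ndarray:
    """Stack a list of :class:`Connectome` (or arrays) into ``(n, N, N)``."""
    mats = [c.weights if isinstance(c, Connectome) else np.asarray(c, float)
            for c in connectomes]
    return np.stack(mats, axis=0)


def write_connectome(connectome: Connectome, path, labels=None) -> None:
    """Write a square TSV with a header row of node labels.

    The float format keeps 17 significant digits so that a write/read
    round trip is lossless for float64 weights.
    """
    w = connectome.weights
    if labels is None:
        labels = [f"ROI_{i:04d}" for i in range(w.shape[0])]
    pd.DataFrame(w, columns=list(labels)).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_connectome(path, subject_id: str = "") -> Connectome:
    """Read a square TSV connectome, validating symmetry and range."""
    df = pd.read_csv(path, sep="\t")
    w = df.to_numpy(dtype=float)
    if w.shape[0] != w.shape[1]:
        raise ValueError(
            f"{path}: non-square connectome ({w.shape[0]} rows x {w.shape[1]} columns)")
    asym = np.abs(w - w.T).max()
    if asym > 1e-10:
        ij = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
        raise ValueError(f"{path}: asymmetric at {ij}: |A - A.T| = {asym:g}")
    if np.abs(w).max() > 1.0 + RANGE_TOL:
        raise ValueError(f"{path}: weight out of [-1, 1] (max |w| = {np.abs(w).max():g})")
    np.fill_diagonal(w, 0.0)
    return Connectome((w + w.T) / 2.0, subject_id=subject_id)
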