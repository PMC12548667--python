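"""Weighted Fisher-z connectivity matrices with explicit missing-value rules.

A connectome here is a node x node matrix of Fisher-z transformed Pearson
correlations with three masking conventions applied in order:

1. the diagonal is missing (NaN);
2. nodes with < 50% voxel coverage have their whole row and column set missing;
3. negative correlations are set missing (analysis restricted to positive
   edges), so no finite entry of a stored connectome is negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import Parcellation

#: correlations at or above this magnitude are clipped before atanh
_CLIP = 1.0 - 1e-7


@dataclass
class Connectome:
    """Symmetric N x N Fisher-z matrix with NaN missing-value semantics."""

    z: np.ndarray
    node_ids: tuple[str, ...]
    atlas_name: str = ""
    subject_id: str = ""
    session: int = 0
    group: str = ""
    variant: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.node_ids)
        if self.z.shape != (n, n):
            raise ValueError("matrix shape does not match node list")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def included(self) -> np.ndarray:
        """Boolean mask of nodes with at least one finite off-diagonal entry."""
        finite = np.isfinite(self.z)
        np.fill_diagonal(finite, False)
        return finite.any(axis=1)


def correlate(signals: np.ndarray) -> np.ndarray:
    """Pearson correlation across nodes (columns), diagonal set missing.

    Zero-variance nodes get fully missing rows/columns (with a warning).
    """
    signals = np.asarray(signals, dtype=float)
    t, n = signals.shape
    if t < 3:
        raise ValueError("need at least 3 time points")
    sd = signals.std(axis=0)
    degenerate = sd == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance node(s) set to missing",
            stacklevel=2,
        )
        signals = signals.copy()
        signals[:, degenerate] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(signals, rowvar=False)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, np.nan)
    return r


def apply_coverage_rule(matrix: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Blank rows/columns of nodes with strictly less than 50% coverage."""
    out = np.asarray(matrix, dtype=float).copy()
    low = parcellation.coverage < 0.5
    out[low, :] = np.nan
    out[:, low] = np.nan
    return out


def censor_negatives(matrix: np.ndarray) -> np.ndarray:
    """Set strictly negative entries missing; zero and positive unchanged."""
    out = np.asarray(matrix, dtype=float).copy()
    with np.errstate(invalid="ignore"):
        out[out < 0] = np.nan
    return out


def fisher_z(matrix: np.ndarray) -> np.ndarray:
    """Elementwise atanh on finite entries; r = +-1 clipped with a warning."""
    r = np.asarray(matrix, dtype=float)
    with np.errstate(invalid="ignore"):
        extreme = np.abs(r) >= 1.0
    if np.any(extreme & np.isfinite(r)):
        warnings.warn(
            "correlations at |r| = 1 clipped before Fisher transform "
            "(degenerate duplicate nodes?)",
            stacklevel=2,
        )
    return np.arctanh(np.clip(r, -_CLIP, _CLIP))


def build_connectome(
    signals: np.ndarray,
    parcellation: Parcellation,
    censor_negative: bool = True,
    **provenance: str | int,
) -> Connectome:
    """correlate -> coverage rule -> negative censoring -> Fisher z.

    ``censor_negative=False`` skips stage 3 (used e.g. when an unbiased edge
    distribution is required); the stored matrix may then hold negative z.
    """
    r = correlate(signals)
    r = apply_coverage_rule(r, parcellation)
    if censor_negative:
        r = censor_negatives(r)
    z = fisher_z(r)
    return Connectome(
        z=z,
        node_ids=parcellation.node_ids,
        atlas_name=parcellation.atlas_name,
        **provenance,  # type: ignore[arg-type]
    )


def negative_edge_fraction(pre_censor_matrix: np.ndarray) -> float:
    """Fraction of strictly negative finite upper-triangle entries.

    Input is the correlation matrix *before* negative censoring.
    """
    m = np.asarray(pre_censor_matrix, dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    vals = m[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite upper-triangle entries")
    return float(np.mean(vals < 0))
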