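"""Fisher-z functional connectivity and its hemispheric block partition.

The subject-level connectome is the Pearson correlation matrix of the
cleaned regional time series, Fisher z-transformed, with a zero diagonal
(arctanh(1) is undefined and self-connections carry no information).
Given a homotopic parcellation it is cut into four pair-indexed blocks:

* ``LL``, ``RR`` — intra-hemispheric connectivity (symmetric),
* ``LR``, ``RL`` — inter-hemispheric connectivity, with ``LR == RL.T``
  exactly since both are cut from one symmetric matrix.

Row ``i`` of ``LL`` and row ``i`` of ``RR`` refer to homotopic regions,
which is what makes the downstream asymmetry index a plain elementwise
difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parcellation import Parcellation

_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class FCMatrix:
    """Region x region Fisher-z connectivity, region order fixed."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("FC matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric within 1e-10")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValueError("FC matrix diagonal must be zero")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class HemiBlocks:
    """The four pair-indexed hemispheric FC blocks of one subject."""

    LL: np.ndarray
    RR: np.ndarray
    LR: np.ndarray
    RL: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.LL, self.RR, self.LR, self.RL)}
        if len(shapes) != 1:
            raise ValueError(f"blocks must share one shape, got {shapes}")

    @property
    def n_pairs(self) -> int:
        return self.LL.shape[0]

    def swap_hemispheres(self) -> "HemiBlocks":
        """Relabel L<->R: swaps LL<->RR and LR<->RL."""
        return HemiBlocks(LL=self.RR, RR=self.LL, LR=self.RL, RL=self.LR)


def compute_fc(ts: np.ndarray) -> FCMatrix:
    """Fisher-z FC from a timepoints x regions matrix.

    Correlations are clipped to ``+/-(1 - 1e-7)`` before arctanh so that
    perfectly (anti)correlated series stay finite; the diagonal is zeroed.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be 2-D (timepoints x regions)")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 timepoints to estimate FC")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance region(s) at column(s) {dead.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -_CLIP, _CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # remove numerical asymmetry from corrcoef
    return FCMatrix(values=z)


def partition_fc(fc: FCMatrix, parcellation: Parcellation) -> HemiBlocks:
    """Cut an FC matrix into the four pair-indexed hemispheric blocks."""
    if fc.n_regions != parcellation.n_regions:
        raise ValueError(
            f"FC has {fc.n_regions} regions, parcellation has "
            f"{parcellation.n_regions}"
        )
    li = parcellation.hemisphere_indices("L")
    ri = parcellation.hemisphere_indices("R")
    v = fc.values
    return HemiBlocks(
        LL=v[np.ix_(li, li)],
        RR=v[np.ix_(ri, ri)],
        LR=v[np.ix_(li, ri)],
        RL=v[np.ix_(ri, li)],
    )


def reassemble_fc(blocks: HemiBlocks, parcellation: Parcellation) -> FCMatrix:
    """Inverse of :func:`partition_fc` (exact round trip)."""
    n = parcellation.n_regions
    li = parcellation.hemisphere_indices("L")
    ri = parcellation.hemisphere_indices("R")
    v = np.zeros((n, n))
    v[np.ix_(li, li)] = blocks.LL
    v[np.ix_(ri, ri)] = blocks.RR
    v[np.ix_(li, ri)] = blocks.LR
    v[np.ix_(ri, li)] = blocks.RL
    return FCMatrix(values=v)
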