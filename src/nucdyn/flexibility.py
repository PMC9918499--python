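"""Root-mean-square fluctuation (RMSF) analysis.

RMSF of an atom is the square root of its mean squared deviation from its
own time-averaged position, computed on a core-superposed ensemble — the
standard per-atom flexibility measure.  Results from the two chain copies
and independent runs are aggregated per residue position as mean +/- SE
(sd/sqrt(n)), matching the n = copies x runs error convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Ensemble
from .model import NucleosomeSystem

__all__ = ["RmsfResult", "rmsf", "chain_core_rmsf", "aggregate_rmsf"]


@dataclass
class RmsfResult:
    """Per-position RMSF (Angstrom) for one selection."""

    positions: np.ndarray  # residue indices (or atom indices)
    values: np.ndarray
    selection: str
    n: int = 1
    se: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("RMSF must be >= 0")


def rmsf(ensemble: Ensemble, selection: np.ndarray) -> np.ndarray:
    """Per-atom RMSF about the time-averaged position."""
    if not ensemble.superposed:
        raise ValueError("RMSF needs a superposed ensemble")
    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = np.asarray(selection, dtype=int)
    X = ensemble.coordinates[:, sel, :]
    mean = X.mean(axis=0)
    d2 = np.sum((X - mean[None]) ** 2, axis=2)
    return np.sqrt(d2.mean(axis=0))


def chain_core_rmsf(ensemble: Ensemble, system: NucleosomeSystem,
                    variant: str, copy_index: int,
                    core_only: bool = True) -> RmsfResult:
    """C-alpha RMSF of one histone chain's globular core (tails excluded by
    default), indexed by residue."""
    k = system.chain_index(variant, copy_index)
    ch = system.chains[k]
    mask = (system.atom_chain == k) & np.array(
        [n == "CA" for n in system.atom_name])
    if core_only:
        core = np.zeros(system.n_atoms, dtype=bool)
        for lo, hi in ch.core_annotations.values():
            core |= (system.atom_resid >= lo) & (system.atom_resid <= hi)
        mask &= core
    sel = np.flatnonzero(mask)
    if len(sel) == 0:
        raise ValueError(f"no C-alpha atoms for {variant}:{copy_index}")
    order = np.argsort(system.atom_resid[sel])
    sel = sel[order]
    values = rmsf(ensemble, sel)
    return RmsfResult(positions=system.atom_resid[sel], values=values,
                      selection=f"{variant}:{copy_index}:core")


def aggregate_rmsf(results: list[RmsfResult]) -> RmsfResult:
    """Mean +/- SE per residue position over copies x runs.

    All inputs must share the residue grid; the output is order-invariant.
    """
    if len(results) < 2:
        raise ValueError("need at least two RMSF series to aggregate")
    grid = results[0].positions
    for r in results[1:]:
        if len(r.positions) != len(grid) or np.any(r.positions != grid):
            raise ValueError("residue grids do not match")
    stack = np.stack([r.values for r in results])
    n = len(results)
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(n)
    return RmsfResult(positions=grid, values=mean, se=se, n=n,
                      selection=f"mean of {n}: {results[0].selection}")
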