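"""Per-frame DNA observables: base-pair centers, unwrapped-bp counting,
radius of gyration, gaping distance and the 2D nucleosome-plane projection.

A base pair counts as *unwrapped* when its center deviates more than a
threshold (7 A by default) from the corresponding bp in the reference
structure, after superposition on the histone core.  Counting is anchored at
the DNA ends: on each side the longest contiguous displaced run starting at
the outermost core bp is counted, so isolated interior excursions are not
unwrapping.  Linker bp never count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import UNWRAP_THRESHOLD
from .io import Ensemble
from .model import CORE_HALF_SPAN, NucleosomeSystem

__all__ = ["UnwrapSeries", "GapingSeries", "bp_center", "bp_centers",
           "count_unwrapped", "unwrap_series", "radius_of_gyration",
           "rg_series", "gaping_distance", "gaping_series", "project_dna_2d"]


@dataclass
class UnwrapSeries:
    """Per-frame unwrapped-bp counts for the two DNA sides."""

    entry: np.ndarray
    exit: np.ndarray
    run_id: str
    threshold: float

    def __post_init__(self):
        if len(self.entry) != len(self.exit):
            raise ValueError("entry/exit length mismatch")
        for side in (self.entry, self.exit):
            if np.any(side < 0) or np.any(side > CORE_HALF_SPAN):
                raise ValueError("side counts must lie in 0..73")

    @property
    def total(self) -> np.ndarray:
        return self.entry + self.exit

    def __len__(self) -> int:
        return len(self.entry)


@dataclass
class GapingSeries:
    """Per-frame gyre-separation distances (Angstrom)."""

    distance: np.ndarray
    run_id: str
    shl_pair: tuple[int, int]
    window_bp: int

    def __post_init__(self):
        if np.any(self.distance <= 0):
            raise ValueError("gaping distances must be positive")

    def __len__(self) -> int:
        return len(self.distance)


def bp_center(frame_coordinates: np.ndarray, system: NucleosomeSystem,
              bp_index: int) -> np.ndarray:
    """Center of one base pair: the mean of its center-defining atoms (the
    two paired C1' atoms for all-atom systems; the bead itself for
    pseudo-atom systems)."""
    idx = system.bp_center_atoms(bp_index)
    return np.asarray(frame_coordinates)[idx].mean(axis=0)


def bp_centers(coordinates: np.ndarray, system: NucleosomeSystem,
               bp_indices=None) -> np.ndarray:
    """bp centers for one frame (n_bp, 3) or a whole stack (n_frames, n_bp, 3)."""
    if bp_indices is None:
        bp_indices = system.dna.bp_index
    cols = [system.bp_center_atoms(int(b)) for b in bp_indices]
    X = np.asarray(coordinates)
    out = np.stack([X[..., idx, :].mean(axis=-2) for idx in cols], axis=-2)
    return out


def _end_run_lengths(displaced: np.ndarray) -> np.ndarray:
    """Length of the leading contiguous True run along the last axis."""
    n = displaced.shape[-1]
    first_false = np.argmax(~displaced, axis=-1)
    all_true = displaced.all(axis=-1)
    return np.where(all_true, n, first_false)


def count_unwrapped(frame_coordinates: np.ndarray, system: NucleosomeSystem,
                    threshold: float = UNWRAP_THRESHOLD,
                    superposed: bool = True) -> tuple[int, int]:
    """(entry, exit) unwrapped-bp counts for one core-superposed frame."""
    if not superposed:
        raise ValueError("count_unwrapped needs a frame superposed on the "
                         "histone core; displacement is undefined otherwise")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    core = np.arange(-CORE_HALF_SPAN, CORE_HALF_SPAN + 1)
    cur = bp_centers(frame_coordinates, system, core)
    ref = bp_centers(system.reference_coordinates, system, core)
    disp = np.linalg.norm(cur - ref, axis=-1) > threshold
    entry = int(_end_run_lengths(disp[:CORE_HALF_SPAN]))          # -73 inward
    exit_ = int(_end_run_lengths(disp[:CORE_HALF_SPAN:-1]))       # +73 inward
    return entry, exit_


def unwrap_series(ensemble: Ensemble, system: NucleosomeSystem,
                  threshold: float = UNWRAP_THRESHOLD) -> UnwrapSeries:
    """Vectorized :func:`count_unwrapped` over an ensemble."""
    if not ensemble.superposed:
        raise ValueError("superpose the ensemble on the histone core first")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    core = np.arange(-CORE_HALF_SPAN, CORE_HALF_SPAN + 1)
    cur = bp_centers(ensemble.coordinates, system, core)
    ref = bp_centers(system.reference_coordinates, system, core)
    disp = np.linalg.norm(cur - ref[None], axis=-1) > threshold
    entry = _end_run_lengths(disp[:, :CORE_HALF_SPAN])
    exit_ = _end_run_lengths(disp[:, :CORE_HALF_SPAN:-1])
    return UnwrapSeries(entry=entry, exit=exit_, run_id=ensemble.run_id,
                        threshold=threshold)


def radius_of_gyration(coordinates: np.ndarray, selection: np.ndarray,
                       masses: np.ndarray | None = None,
                       mass_weighted: bool = True) -> float:
    """Rg = sqrt(sum w_i |r_i - rbar|^2 / sum w_i) over a selection."""
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValueError("empty selection")
    X = np.asarray(coordinates)[selection]
    if mass_weighted and masses is not None:
        w = np.asarray(masses, dtype=float)[selection]
    else:
        w = np.ones(len(selection))
    com = (w[:, None] * X).sum(axis=0) / w.sum()
    d2 = np.sum((X - com) ** 2, axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def rg_series(ensemble: Ensemble, system: NucleosomeSystem,
              selection: np.ndarray | None = None,
              mass_weighted: bool = True) -> np.ndarray:
    """Per-frame DNA (or custom-selection) radius of gyration."""
    if selection is None:
        selection = system.dna_atoms()
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValueError("empty selection")
    X = ensemble.coordinates[:, selection, :]
    w = (system.atom_mass[selection] if mass_weighted
         else np.ones(len(selection)))
    w = w / w.sum()
    com = np.einsum("j,fjc->fc", w, X)
    d2 = np.sum((X - com[:, None, :]) ** 2, axis=2)
    return np.sqrt(np.einsum("j,fj->f", w, d2))


def _gape_windows(system: NucleosomeSystem, shl_pair, window_bp):
    wins = []
    for n in shl_pair:
        c = int(round(10.3 * n))
        lo, hi = c - window_bp, c + window_bp
        if lo < -CORE_HALF_SPAN or hi > CORE_HALF_SPAN:
            raise ValueError(f"SHL {n} window {lo}..{hi} leaves the core")
        wins.append(np.arange(lo, hi + 1))
    return wins


def gaping_distance(frame_coordinates: np.ndarray, system: NucleosomeSystem,
                    shl_pair: tuple[int, int] = (-4, 4),
                    window_bp: int = 2) -> float:
    """Distance between the unweighted bp-center centroids of the two SHL
    windows (default SHL -4 and +4, +/-2 bp)."""
    wa, wb = _gape_windows(system, shl_pair, window_bp)
    ca = bp_centers(frame_coordinates, system, wa).mean(axis=-2)
    cb = bp_centers(frame_coordinates, system, wb).mean(axis=-2)
    return float(np.linalg.norm(ca - cb))


def gaping_series(ensemble: Ensemble, system: NucleosomeSystem,
                  shl_pair: tuple[int, int] = (-4, 4),
                  window_bp: int = 2) -> GapingSeries:
    wa, wb = _gape_windows(system, shl_pair, window_bp)
    ca = bp_centers(ensemble.coordinates, system, wa).mean(axis=-2)
    cb = bp_centers(ensemble.coordinates, system, wb).mean(axis=-2)
    d = np.linalg.norm(ca - cb, axis=-1)
    return GapingSeries(distance=d, run_id=ensemble.run_id,
                        shl_pair=tuple(shl_pair), window_bp=window_bp)


def _fit_cylinder_axis(points: np.ndarray) -> np.ndarray:
    """Axis direction of the best-fit cylinder through a point cloud.

    Minimizes the spread of point-to-axis distances; exact for an ideal
    superhelix (where principal-component normals are biased by the pitch
    and the partial turn)."""
    from scipy.optimize import least_squares

    m = points.mean(axis=0)
    v = points - m
    a0 = np.cross(v[:-1], v[1:]).sum(axis=0)
    a0 = a0 / np.linalg.norm(a0)
    th0 = np.arccos(np.clip(a0[2], -1, 1))
    ph0 = np.arctan2(a0[1], a0[0])

    def residual(x):
        th, ph, cx, cy, cz = x
        a = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                      np.cos(th)])
        rel = points - (m + np.array([cx, cy, cz]))
        d = np.linalg.norm(np.cross(rel, a), axis=1)
        return d - d.mean()

    sol = least_squares(residual, x0=[th0, ph0, 0.0, 0.0, 0.0], method="lm")
    th, ph = sol.x[:2]
    axis = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                     np.cos(th)])
    return axis if axis @ a0 > 0 else -axis


def reference_plane(system: NucleosomeSystem) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(origin, e1, e2) of the reference nucleosome plane: perpendicular to
    the reference superhelix axis, through the reference DNA centroid.

    The axis is the best-fit cylinder axis of the core bp centers."""
    core = np.arange(-CORE_HALF_SPAN, CORE_HALF_SPAN + 1)
    ref = bp_centers(system.reference_coordinates, system, core)
    origin = ref.mean(axis=0)
    axis = _fit_cylinder_axis(ref)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ axis) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return origin, e1, e2


def project_dna_2d(frame_coordinates: np.ndarray, system: NucleosomeSystem,
                   superposed: bool = True) -> np.ndarray:
    """Per-bp (x, y) coordinates in the fixed reference nucleosome plane.

    The plane is defined once from the reference (not refit per frame) so
    unwrapping excursions read as outward motion."""
    if not superposed:
        raise ValueError("project_dna_2d needs a superposed frame")
    origin, e1, e2 = reference_plane(system)
    centers = bp_centers(frame_coordinates, system)
    rel = centers - origin
    return np.stack([rel @ e1, rel @ e2], axis=-1)
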