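"""Heavy-atom contact analysis between histone selections and DNA.

A contact is a pair of non-hydrogen atoms, one from each selection, at a
distance strictly below the cutoff (4.5 A by default — strictly less-than,
where many tools use <=).  Counting uses a KD-tree but is defined, and
tested, as the exact all-pairs count.  No periodic minimum image is applied:
frames are assumed whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.spatial import cKDTree

from .constants import CONTACT_CUTOFF
from .io import Ensemble
from .model import FULL_HALF_SPAN, NucleosomeSystem

__all__ = ["ContactSeries", "count_contacts", "contact_series",
           "tail_dna_contact_series", "smooth_series", "tail_dna_min_distance",
           "min_distance_series", "series_correlation"]


@dataclass
class ContactSeries:
    """Per-frame heavy-atom contact counts for one selection pair."""

    counts: np.ndarray
    selection_a: str
    selection_b: str
    cutoff: float
    run_id: str = "run"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be >= 0")

    def __len__(self) -> int:
        return len(self.counts)


def _strict_radius(cutoff: float) -> float:
    # KD-tree pair counting uses d <= r; shrink r to the previous float so
    # pairs exactly at the cutoff are excluded (strict less-than)
    return float(np.nextafter(cutoff, -np.inf))


def count_contacts(coordinates_a: np.ndarray, coordinates_b: np.ndarray,
                   cutoff: float = CONTACT_CUTOFF) -> int:
    """Number of (a, b) pairs with d(a, b) < cutoff, KD-tree accelerated but
    exactly equal to the all-pairs definition."""
    a = np.atleast_2d(np.asarray(coordinates_a, dtype=float))
    b = np.atleast_2d(np.asarray(coordinates_b, dtype=float))
    if a.size == 0 or b.size == 0:
        return 0
    return int(cKDTree(a).count_neighbors(cKDTree(b), _strict_radius(cutoff)))


def _checked_selections(system: NucleosomeSystem, sel_a, sel_b):
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if np.intersect1d(sel_a, sel_b).size:
        raise ValueError("contact selections must be disjoint")
    dropped = False
    for sel in (sel_a, sel_b):
        if not np.all(system.atom_is_heavy[sel]):
            dropped = True
    if dropped:
        warnings.warn("hydrogens present in contact selection; filtered out",
                      stacklevel=3)
        sel_a = sel_a[system.atom_is_heavy[sel_a]]
        sel_b = sel_b[system.atom_is_heavy[sel_b]]
    return sel_a, sel_b


def contact_series(ensemble: Ensemble, system: NucleosomeSystem,
                   sel_a, sel_b, cutoff: float = CONTACT_CUTOFF,
                   label_a: str = "a", label_b: str = "b") -> ContactSeries:
    """Per-frame contact counts between two atom-index selections."""
    sel_a, sel_b = _checked_selections(system, sel_a, sel_b)
    counts = np.empty(len(ensemble), dtype=int)
    r = _strict_radius(cutoff)
    for f in range(len(ensemble)):
        X = ensemble.coordinates[f]
        counts[f] = cKDTree(X[sel_a]).count_neighbors(cKDTree(X[sel_b]), r)
    return ContactSeries(counts=counts, selection_a=label_a, selection_b=label_b,
                         cutoff=cutoff, run_id=ensemble.run_id)


def tail_dna_contact_series(ensemble: Ensemble, system: NucleosomeSystem,
                            tail: tuple[str, int, str],
                            dna_region: str | tuple[int, int] = "total",
                            cutoff: float = CONTACT_CUTOFF) -> ContactSeries:
    """Contacts between one histone tail and a DNA region (``total``,
    ``inner``, ``outer``, ``linker``) or an explicit bp window.

    Region counts partition the total: inner + outer + linker = total per
    frame.
    """
    variant, copy_index, which = tail
    sel_tail = system.tail_atoms(variant, copy_index, which)
    if isinstance(dna_region, str):
        sel_dna = system.dna_atoms(region=dna_region)
        label_b = f"DNA:{dna_region}"
    else:
        sel_dna = system.dna_atoms(bp_window=tuple(dna_region))
        label_b = f"DNA:bp{dna_region[0]}..{dna_region[1]}"
    return contact_series(ensemble, system, sel_tail, sel_dna, cutoff=cutoff,
                          label_a=f"{variant}:{copy_index}:{which}",
                          label_b=label_b)


def smooth_series(values: np.ndarray, window_ns: float = 10.0,
                  poly_order: int = 1,
                  sampling_interval: float = 100.0) -> np.ndarray:
    """Savitzky-Golay smoothing with a time window given in ns.

    The window covers ``window_ns`` of trajectory (10 ns at 100 ps -> 101
    points, always made odd).  Output length equals input length; edge
    points are fitted with the largest symmetric window that fits, shrinking
    toward the ends.
    """
    y = np.asarray(values, dtype=float)
    n_half = int(round(window_ns * 1000.0 / sampling_interval)) // 2
    window = 2 * n_half + 1
    if window < poly_order + 2:
        raise ValueError("window too short for the polynomial order")
    if len(y) < window:
        raise ValueError(f"series of {len(y)} points shorter than the "
                         f"{window}-point window")
    out = savgol_filter(y, window, poly_order)
    # symmetric shrinking windows at the edges
    for i in range(n_half):
        for idx in (i, len(y) - 1 - i):
            h = min(idx, len(y) - 1 - idx)
            if 2 * h + 1 < poly_order + 2:
                out[idx] = y[idx]
            else:
                seg = y[idx - h: idx + h + 1]
                x = np.arange(-h, h + 1)
                coef = np.polynomial.polynomial.polyfit(x, seg, poly_order)
                out[idx] = coef[0]
    return out


def min_distance(coordinates_a: np.ndarray, coordinates_b: np.ndarray) -> float:
    """Smallest pair distance between two coordinate sets."""
    a = np.atleast_2d(coordinates_a)
    b = np.atleast_2d(coordinates_b)
    d, _ = cKDTree(b).query(a, k=1)
    return float(np.min(d))


def _proximal_window(system: NucleosomeSystem, copy_index: int,
                     bp_window: tuple[int, int] | None) -> tuple[int, int]:
    # copy 1 sits on the entry (negative-bp) side by the package convention
    if bp_window is not None:
        return bp_window
    lo, hi = 41, min(75, FULL_HALF_SPAN)
    return (-hi, -lo) if copy_index == 1 else (lo, hi)


def tail_dna_min_distance(frame_coordinates: np.ndarray,
                          system: NucleosomeSystem,
                          tail: tuple[str, int, str],
                          bp_window: tuple[int, int] | None = None) -> float:
    """Minimum heavy-atom distance between a tail and a DNA segment.

    The default segment is bp 41..75 on the tail copy's proximal side (the
    window may span into the linker)."""
    variant, copy_index, which = tail
    sel_tail = system.tail_atoms(variant, copy_index, which)
    window = _proximal_window(system, copy_index, bp_window)
    sel_dna = system.dna_atoms(bp_window=window)
    if len(sel_dna) == 0:
        raise ValueError(f"empty DNA window {window}")
    X = np.asarray(frame_coordinates)
    return min_distance(X[sel_tail], X[sel_dna])


def min_distance_series(ensemble: Ensemble, system: NucleosomeSystem,
                        tail: tuple[str, int, str],
                        bp_window: tuple[int, int] | None = None) -> np.ndarray:
    variant, copy_index, which = tail
    sel_tail = system.tail_atoms(variant, copy_index, which)
    window = _proximal_window(system, copy_index, bp_window)
    sel_dna = system.dna_atoms(bp_window=window)
    if len(sel_dna) == 0:
        raise ValueError(f"empty DNA window {window}")
    out = np.empty(len(ensemble))
    for f in range(len(ensemble)):
        X = ensemble.coordinates[f]
        out[f] = min_distance(X[sel_tail], X[sel_dna])
    return out


def series_correlation(series_a, series_b) -> float:
    """Pearson correlation of two raw (unsmoothed) per-frame series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series length mismatch")
    if len(a) < 3:
        raise ValueError("need at least 3 points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    return float(np.corrcoef(a, b)[0, 1])
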