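"""Free-energy profiles by Boltzmann inversion of occupancy histograms.

For a discrete observable (the unwrapped-bp count i) the standard free
energy relative to the most occupied state is

    dG(i) = -RT ln(f_i / f_max),    f_i = N_i / N_total,

with R = 1.987204e-3 kcal/(mol K).  States never visited have undefined dG
(NaN), not +inf: the relation is undefined at f_i = 0.  The same inversion
over a 2D histogram of two collective variables (DNA radius of gyration,
total DNA-histone contacts) gives a free-energy surface.  No smoothing or
reweighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, R_KCAL

__all__ = ["FreeEnergyProfile", "FreeEnergySurface", "free_energy_1d",
           "profile_standard_error", "average_profiles", "free_energy_2d",
           "barrier_difference", "fit_profile_slope"]


@dataclass
class FreeEnergyProfile:
    """dG over the unwrapped-bp grid; NaN where never observed."""

    i: np.ndarray
    delta_g: np.ndarray
    n_samples: np.ndarray
    temperature: float
    se: np.ndarray | None = None

    def __post_init__(self):
        defined = ~np.isnan(self.delta_g)
        if not defined.any():
            raise ValueError("profile defined nowhere")
        if abs(float(np.nanmin(self.delta_g))) > 1e-9:
            raise ValueError("profile must be anchored at dG = 0 at the mode")

    def value_at(self, i: int) -> float:
        pos = np.flatnonzero(self.i == i)
        if len(pos) == 0 or np.isnan(self.delta_g[pos[0]]):
            raise ValueError(f"dG undefined at i = {i}")
        return float(self.delta_g[pos[0]])


@dataclass
class FreeEnergySurface:
    """dG over a 2D collective-variable grid; NaN in empty bins."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    delta_g: np.ndarray
    occupancy: np.ndarray
    temperature: float

    def __post_init__(self):
        occupied = self.occupancy > 0
        if not occupied.any():
            raise ValueError("surface has no occupied bins")
        if abs(np.nanmin(self.delta_g[occupied])) > 1e-12:
            raise ValueError("surface must be anchored at dG = 0")


def free_energy_1d(unwrap_counts, temperature: float = DEFAULT_TEMPERATURE,
                   i_max: int | None = None) -> FreeEnergyProfile:
    """Boltzmann inversion of the occupancy of unwrapped-bp counts.

    ``unwrap_counts`` are per-frame integers (pool per run and side before
    calling if that is the convention wanted).  dG is 0 at the modal count.
    """
    counts = np.asarray(unwrap_counts, dtype=int).ravel()
    if counts.size == 0:
        raise ValueError("no frames")
    if np.any(counts < 0):
        raise ValueError("unwrapped counts must be >= 0")
    top = int(counts.max()) if i_max is None else int(i_max)
    grid = np.arange(top + 1)
    n_i = np.bincount(counts, minlength=top + 1).astype(float)
    f = n_i / counts.size
    rt = R_KCAL * temperature
    with np.errstate(divide="ignore"):
        dg = np.where(n_i > 0, -rt * np.log(f / f.max()), np.nan)
    dg = np.where(n_i > 0, dg - np.nanmin(dg), np.nan)  # exact 0 at the mode
    return FreeEnergyProfile(i=grid, delta_g=dg, n_samples=n_i.astype(int),
                             temperature=temperature)


def profile_standard_error(profiles: list[FreeEnergyProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Per-i standard error across run-and-side profiles.

    Returns (i grid, SE).  SE at i = sample sd over the profiles defined at
    i, divided by sqrt(of that number); NaN where fewer than 2 profiles are
    defined.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    top = max(int(p.i.max()) for p in profiles)
    grid = np.arange(top + 1)
    stack = np.full((len(profiles), top + 1), np.nan)
    for k, p in enumerate(profiles):
        stack[k, p.i] = p.delta_g
    defined = ~np.isnan(stack)
    n = defined.sum(axis=0)
    se = np.full(top + 1, np.nan)
    for j in range(top + 1):
        if n[j] >= 2:
            vals = stack[defined[:, j], j]
            se[j] = np.std(vals, ddof=1) / np.sqrt(n[j])
    return grid, se


def average_profiles(profiles: list[FreeEnergyProfile]) -> FreeEnergyProfile:
    """Mean profile over run-and-side profiles with the n-across SE, re-anchored
    so the pooled minimum is 0."""
    grid, se = profile_standard_error(profiles)
    stack = np.full((len(profiles), len(grid)), np.nan)
    n_samp = np.zeros(len(grid), dtype=int)
    for k, p in enumerate(profiles):
        stack[k, p.i] = p.delta_g
        n_samp[p.i] += p.n_samples
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    mean = mean - np.nanmin(mean)
    return FreeEnergyProfile(i=grid, delta_g=mean, n_samples=n_samp,
                             temperature=profiles[0].temperature, se=se)


def free_energy_2d(x_series, y_series, bins=(60, 40),
                   temperature: float = DEFAULT_TEMPERATURE) -> FreeEnergySurface:
    """dG = -RT ln(P / P_max) over a 2D occupancy histogram of two
    collective variables (e.g. DNA Rg vs total DNA-histone contacts)."""
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty series")
    if x.shape != y.shape:
        raise ValueError("series length mismatch")
    H, xe, ye = np.histogram2d(x, y, bins=bins)
    rt = R_KCAL * temperature
    with np.errstate(divide="ignore"):
        dg = np.where(H > 0, -rt * np.log(H / H.max()), np.nan)
    dg = np.where(H > 0, dg - np.nanmin(dg), np.nan)
    return FreeEnergySurface(x_edges=xe, y_edges=ye, delta_g=dg, occupancy=H,
                             temperature=temperature)


def barrier_difference(profile_a: FreeEnergyProfile,
                       profile_b: FreeEnergyProfile, i: int) -> float:
    """dG_a(i) - dG_b(i); errors if either profile is undefined at i."""
    return profile_a.value_at(i) - profile_b.value_at(i)


def fit_profile_slope(profile: FreeEnergyProfile, min_samples: int = 20,
                      i_min: int = 0) -> float:
    """Least-squares slope of dG vs i over well-sampled, defined states.

    For a zipper process with per-bp cost epsilon the profile is linear with
    slope epsilon, so the fitted slope recovers the generator parameter.
    """
    ok = (~np.isnan(profile.delta_g)) & (profile.n_samples >= min_samples) \
        & (profile.i >= i_min)
    if ok.sum() < 2:
        raise ValueError("not enough well-sampled states to fit a slope")
    coef = np.polynomial.polynomial.polyfit(profile.i[ok],
                                            profile.delta_g[ok], 1)
    return float(coef[1])
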