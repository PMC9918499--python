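"""Synthetic pseudo-atom nucleosome trajectories with exact ground truth.

The generator builds a bead model of the nucleosome — one bead per DNA base
pair on a left-handed superhelix with two straight 20-bp linkers, C-alpha-like
beads for every annotated histone-fold element on an inner cylinder, and tail
bead strings — and then evolves stochastic motions whose recovery downstream
analyses can be tested against:

* **End unwrapping** follows a zipper model: each DNA side's unwrapped count
  ``i`` performs single-bp Metropolis moves on the energy ``E(i) = i*epsilon``
  so its stationary law is geometric, ``P(i) ~ exp(-i*epsilon/RT)``.  Released
  bp are peeled radially off the superhelix by a fixed 12.5 A so that every
  unwrapped bp sits > 10 A from its reference position (the detection
  threshold is 7 A, leaving a wide margin).
* **Gaping** displaces the two SHL 3..7 half-turns apart along the superhelix
  axis by a mean-reverting AR(1) offset calibrated so the histogram mode of
  the measured SHL+/-4 distance equals ``gaping_mean``.
* **Core plasticity**: each annotated element receives an isotropic Gaussian
  rigid-body offset per frame with a per-element sigma (loops default to
  twice the helix sigma).
* **Tail binding**: the H2A-family C-tails toggle between a bound pose (beads
  3 A off outer-DNA beads, i.e. many heavy-atom contacts) and an unbound,
  solvent-protruding pose, with a bind probability that decreases with the
  same side's unwrapped count — programming the anti-correlation between
  unwrapping and tail-DNA contacts.  N-tails couple to the gaping offset the
  same way.

Ground truth is recorded before isotropic measurement noise is added, so
labels are exact at ``noise_sigma = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .constants import CONTACT_CUTOFF, R_KCAL
from .io import Ensemble
from .model import (
    CORE_HALF_SPAN,
    FULL_HALF_SPAN,
    KIND_CORE,
    KIND_DNA,
    KIND_TAIL,
    LINKER_BP,
    NucleosomeSystem,
    DNADuplex,
    default_chain,
    default_octamer_variants,
    shl_window,
)

__all__ = ["SyntheticParams", "GroundTruth", "generate_reference",
           "simulate_unwrap_counts", "simulate_trajectory", "write_fixture",
           "zipper_stationary_law"]

N_CORE_BP = 2 * CORE_HALF_SPAN + 1  # 147


def _default_core_sigma() -> dict[str, float]:
    # loops are floppier than helices; per-element override allowed
    return {"alphaN": 0.45, "alpha1": 0.45, "alpha2": 0.45, "alpha3": 0.45,
            "alphaC": 0.45, "L1": 0.9, "L2": 0.9}


def _default_bind_prob(i: int | np.ndarray) -> np.ndarray:
    """Bound probability of a coupled tail given the unwrapped count."""
    return np.clip(0.9 - 0.15 * np.asarray(i, dtype=float), 0.05, 0.95)


@dataclass
class SyntheticParams:
    """Generator knobs.  Lengths in Angstrom, temperature in K, energies in
    kcal/mol; ``seed`` fixes the entire random stream."""

    superhelix_radius: float = 41.9
    superhelix_pitch: float = 25.9
    total_turns: float = 1.65
    bp_spacing: float | None = None  # None: use the core-helix arc length/bp
    epsilon: float = 0.5
    temperature: float = 310.0
    gaping_mean: float = 27.0
    gaping_amplitude: float = 1.2
    gaping_relaxation: float = 20.0
    core_sigma: dict[str, float] = field(default_factory=_default_core_sigma)
    tail_bind_prob: Callable = None  # type: ignore[assignment]
    noise_sigma: float = 0.5
    n_frames: int = 1000
    seed: int = 0
    sampling_interval: float = 100.0  # ps
    max_unwrap: int = 25
    unwrap_displacement: float = 12.5
    h2a_like: str = "H2A.Z"
    h3_like: str = "H3"

    def __post_init__(self):
        if self.tail_bind_prob is None:
            self.tail_bind_prob = _default_bind_prob
        for name in ("superhelix_radius", "superhelix_pitch", "total_turns",
                     "temperature", "gaping_mean", "gaping_amplitude",
                     "gaping_relaxation", "sampling_interval", "unwrap_displacement"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.bp_spacing is not None and self.bp_spacing <= 0:
            raise ValueError("bp_spacing must be > 0")
        if self.noise_sigma < 0 or self.epsilon < 0:
            raise ValueError("noise_sigma and epsilon must be >= 0")
        if not 1 <= self.max_unwrap <= CORE_HALF_SPAN:
            raise ValueError("max_unwrap must be in 1..73")
        p = np.asarray(self.tail_bind_prob(np.arange(self.max_unwrap + 1)))
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("tail_bind_prob must return probabilities in [0, 1]")

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature


@dataclass
class GroundTruth:
    """Per-frame true labels, recorded before measurement noise."""

    entry_unwrapped: np.ndarray
    exit_unwrapped: np.ndarray
    gaping_distance: np.ndarray
    tail_contacts: dict[str, np.ndarray]
    tail_bound: dict[str, np.ndarray]
    core_displacement: dict[str, np.ndarray]
    bound_contact_floor: dict[str, int]

    @property
    def n_frames(self) -> int:
        return len(self.entry_unwrapped)

    def to_frame(self):
        import pandas as pd

        data = {
            "frame": np.arange(self.n_frames),
            "entry_unwrapped": self.entry_unwrapped,
            "exit_unwrapped": self.exit_unwrapped,
            "gaping_distance": self.gaping_distance,
        }
        for label, series in self.tail_contacts.items():
            data[f"contacts[{label}]"] = series
        for label, series in self.tail_bound.items():
            data[f"bound[{label}]"] = series.astype(int)
        for label, vec in self.core_displacement.items():
            data[f"coredisp[{label}]"] = np.linalg.norm(vec, axis=1)
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df) -> "GroundTruth":
        contacts = {c[len("contacts["):-1]: df[c].to_numpy()
                    for c in df.columns if c.startswith("contacts[")}
        bound = {c[len("bound["):-1]: df[c].to_numpy().astype(bool)
                 for c in df.columns if c.startswith("bound[")}
        return cls(
            entry_unwrapped=df["entry_unwrapped"].to_numpy(),
            exit_unwrapped=df["exit_unwrapped"].to_numpy(),
            gaping_distance=df["gaping_distance"].to_numpy(),
            tail_contacts=contacts, tail_bound=bound,
            core_displacement={}, bound_contact_floor={},
        )


# ---------------------------------------------------------------------------
# reference geometry
# ---------------------------------------------------------------------------

class _Geometry:
    """Reference bead placement plus the index bookkeeping the simulator
    needs (which atoms belong to which motion)."""

    def __init__(self, params: SyntheticParams):
        self.params = params
        R, pitch, turns = (params.superhelix_radius, params.superhelix_pitch,
                           params.total_turns)
        j = np.arange(-CORE_HALF_SPAN, CORE_HALF_SPAN + 1)
        theta = 2 * np.pi * turns * j / (N_CORE_BP - 1)
        z = pitch * turns * j / (N_CORE_BP - 1)
        core_xyz = np.stack([R * np.cos(theta), -R * np.sin(theta), z], axis=1)
        dtheta = 2 * np.pi * turns / (N_CORE_BP - 1)
        arc = np.hypot(R * dtheta, pitch * turns / (N_CORE_BP - 1))
        spacing = params.bp_spacing if params.bp_spacing is not None else arc

        dz_dj = pitch * turns / (N_CORE_BP - 1)

        def tangent(jj):
            # d/dj of (R cos th, -R sin th, z) with th = dtheta * j
            th = dtheta * jj
            t = np.array([-R * np.sin(th) * dtheta, -R * np.cos(th) * dtheta, dz_dj])
            return t / np.linalg.norm(t)

        t_lo, t_hi = tangent(-CORE_HALF_SPAN), tangent(CORE_HALF_SPAN)
        k = np.arange(1, LINKER_BP + 1)[:, None]
        entry_link = core_xyz[0] - k * spacing * t_lo     # bp -74..-93 outward
        exit_link = core_xyz[-1] + k * spacing * t_hi     # bp +74..+93 outward
        # assemble duplex in increasing bp order: -93..-74, core, +74..+93
        self.dna_bp = np.arange(-FULL_HALF_SPAN, FULL_HALF_SPAN + 1)
        self.dna_xyz = np.vstack([entry_link[::-1], core_xyz, exit_link])
        self.core_theta = theta
        self.radial = np.stack([np.cos(theta), -np.sin(theta),
                                np.zeros_like(theta)], axis=1)

        # histone chains
        variants = default_octamer_variants(params.h2a_like, params.h3_like)
        self.chains = [default_chain(v, c) for v, c in variants]
        r_core = 30.0
        names, kinds, chain_col, resid_col = [], [], [], []
        xyz = [self.dna_xyz]
        bp_col = [self.dna_bp.copy()]
        strand_col = [np.zeros(len(self.dna_bp), dtype=int)]
        dna_names = ["P"] * len(self.dna_bp)
        self.element_atoms: dict[str, np.ndarray] = {}
        self.tail_atoms: dict[str, np.ndarray] = {}
        offset = len(self.dna_bp)
        for ci, ch in enumerate(self.chains):
            phi0 = 2 * np.pi * ci / len(self.chains)
            # place beads in residue order so file residue numbering is
            # monotone within a chain (tails at their sequence positions)
            segments: list[tuple[int, int, str, str]] = []
            for which in ("N", "C"):
                try:
                    lo, hi = ch.tail_range(which)
                except ValueError:
                    continue
                segments.append((lo, hi, "tail", which))
            for elem, (lo, hi) in ch.core_annotations.items():
                segments.append((lo, hi, "core", elem))
            segments.sort()
            ei = 0
            for lo, hi, seg_kind, label in segments:
                n = hi - lo + 1
                if seg_kind == "core":
                    ang = phi0 + 0.35 * ei + 0.04 * np.arange(n)
                    zz = -12.0 + 24.0 * (ei / 6.0) + 0.5 * np.arange(n) % 8
                    pts = np.stack([r_core * np.cos(ang),
                                    -r_core * np.sin(ang), zz], axis=1)
                    self.element_atoms[f"{ch.label}:{label}"] = offset + np.arange(n)
                    kinds += [KIND_CORE] * n
                    ei += 1
                else:
                    pts = self._unbound_tail_xyz(phi0, label, n)
                    self.tail_atoms[f"{ch.label}:{label}"] = offset + np.arange(n)
                    kinds += [KIND_TAIL] * n
                xyz.append(pts)
                names += ["CA"] * n
                chain_col += [ci] * n
                resid_col += list(range(lo, hi + 1))
                offset += n
        n_protein = offset - len(self.dna_bp)
        self.xyz = np.vstack(xyz)
        self.names = dna_names + names
        self.kind = np.concatenate([np.full(len(self.dna_bp), KIND_DNA, dtype=np.int8),
                                    np.asarray(kinds, dtype=np.int8)])
        self.chain_col = np.concatenate([np.full(len(self.dna_bp), -1, dtype=int),
                                         np.asarray(chain_col, dtype=int)])
        self.resid_col = np.concatenate([np.zeros(len(self.dna_bp), dtype=int),
                                         np.asarray(resid_col, dtype=int)])
        self.bp_col = np.concatenate([self.dna_bp,
                                      np.full(n_protein, -999, dtype=int)])
        self.strand_col = np.concatenate([np.zeros(len(self.dna_bp), dtype=int),
                                          np.full(n_protein, -1, dtype=int)])

        # motion bookkeeping -------------------------------------------------
        bp_to_atom = {int(b): i for i, b in enumerate(self.dna_bp)}
        self.entry_core_atoms = np.array(
            [bp_to_atom[b] for b in range(-CORE_HALF_SPAN, 0)])          # -73 inward
        self.exit_core_atoms = np.array(
            [bp_to_atom[b] for b in range(CORE_HALF_SPAN, 0, -1)])       # +73 inward
        self.entry_linker_atoms = np.array(
            [bp_to_atom[b] for b in range(-FULL_HALF_SPAN, -CORE_HALF_SPAN)])
        self.exit_linker_atoms = np.array(
            [bp_to_atom[b] for b in range(CORE_HALF_SPAN + 1, FULL_HALF_SPAN + 1)])
        rad_all = np.zeros((len(self.dna_bp), 3))
        rad_all[LINKER_BP:LINKER_BP + N_CORE_BP] = self.radial
        rad_all[:LINKER_BP] = self.radial[0]
        rad_all[LINKER_BP + N_CORE_BP:] = self.radial[-1]
        self.dna_radial = rad_all

        # gaping half-turns: SHL 3..7 on each side, dyad region fixed
        lo3 = shl_window(3)[0]
        self.plus_half_atoms = np.array(
            [bp_to_atom[b] for b in range(lo3, CORE_HALF_SPAN + 1)])
        self.minus_half_atoms = np.array(
            [bp_to_atom[b] for b in range(-CORE_HALF_SPAN, -lo3 + 1)])

        # gaping calibration from the SHL +/-4 measurement windows
        w = 2
        lo4, hi4 = shl_window(4, half_width=w)
        plus_c = self.dna_xyz[[bp_to_atom[b] for b in range(lo4, hi4 + 1)]].mean(axis=0)
        minus_c = self.dna_xyz[[bp_to_atom[b] for b in range(-hi4, -lo4 + 1)]].mean(axis=0)
        self.gape_inplane = float(np.hypot(*(plus_c - minus_c)[:2]))
        self.gape_z0 = float(abs(plus_c[2] - minus_c[2]))
        self.gape_sign = float(np.sign(plus_c[2] - minus_c[2]) or 1.0)
        if params.gaping_mean <= self.gape_inplane:
            raise ValueError(
                f"gaping_mean {params.gaping_mean} below the in-plane window "
                f"separation {self.gape_inplane:.1f} A; unreachable")
        self.gape_delta_mean = (np.sqrt(params.gaping_mean ** 2
                                        - self.gape_inplane ** 2) - self.gape_z0)

        # coupled tails: C-tails follow outer DNA and couple to unwrapping,
        # N-tails couple to gaping.  copy 1 <-> entry (negative bp) side.
        self.coupled_tails: dict[str, dict] = {}
        for ch in self.chains:
            if ch.variant_id not in ("H2A", "H2A.Z"):
                continue
            side = -1 if ch.copy_index == 1 else +1
            for which, start in (("C", 66), ("N", 53)):
                try:
                    lo, hi = ch.tail_range(which)
                except ValueError:
                    continue
                n = hi - lo + 1
                targets = np.array([side * (start - m) for m in range(n)])
                self.coupled_tails[f"{ch.label}:{which}"] = {
                    "atoms": self.tail_atoms[f"{ch.label}:{which}"],
                    "target_atoms": np.array([bp_to_atom[int(b)] for b in targets]),
                    "side": side,
                    "mode": "unwrap" if which == "C" else "gaping",
                }

    def _unbound_tail_xyz(self, phi0: float, which: str, n: int) -> np.ndarray:
        sgn = 1.0 if which == "N" else -1.0
        r = 62.0 + 3.0 * np.arange(n)
        ang = phi0 + sgn * 0.25
        return np.stack([r * np.cos(ang), -r * np.sin(ang),
                         sgn * 18.0 * np.ones(n)], axis=1)

    def bound_tail_xyz(self, label: str, dna_xyz: np.ndarray) -> np.ndarray:
        info = self.coupled_tails[label]
        t = info["target_atoms"]
        return dna_xyz[t] + 3.0 * self.dna_radial[t]

    def build_system(self) -> NucleosomeSystem:
        return NucleosomeSystem(
            chains=self.chains, dna=DNADuplex.default(),
            reference_coordinates=self.xyz,
            atom_kind=self.kind, atom_chain=self.chain_col,
            atom_resid=self.resid_col, atom_bp=self.bp_col,
            atom_strand=self.strand_col, atom_name=self.names,
            atom_is_heavy=np.ones(len(self.xyz), dtype=bool),
        )


def generate_reference(params: SyntheticParams | None = None) -> NucleosomeSystem:
    """Build the pseudo-atom reference structure (all tails in their bound
    pose for the coupled H2A-family tails)."""
    params = params or SyntheticParams()
    geo = _Geometry(params)
    sys_ = geo.build_system()
    ref = sys_.reference_coordinates
    for label in geo.coupled_tails:
        ref[geo.coupled_tails[label]["atoms"]] = geo.bound_tail_xyz(label, geo.dna_xyz)
    return sys_


# ---------------------------------------------------------------------------
# stochastic processes
# ---------------------------------------------------------------------------

def zipper_stationary_law(epsilon: float, temperature: float,
                          max_unwrap: int) -> np.ndarray:
    """Exact stationary occupancy of the zipper chain: geometric, truncated."""
    i = np.arange(max_unwrap + 1)
    w = np.exp(-i * epsilon / (R_KCAL * temperature))
    return w / w.sum()


def _zipper_chain(n_frames: int, epsilon: float, rt: float, max_unwrap: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Single-bp Metropolis moves on E(i) = i*epsilon, reflecting at 0 and
    max_unwrap; detailed balance gives P(i) ~ exp(-i*epsilon/RT)."""
    acc_up = np.exp(-epsilon / rt)
    steps = rng.integers(0, 2, size=n_frames) * 2 - 1
    u = rng.random(n_frames)
    out = np.empty(n_frames, dtype=np.int64)
    i = 0
    for f in range(n_frames):
        j = i + steps[f]
        if 0 <= j <= max_unwrap and (steps[f] < 0 or u[f] < acc_up):
            i = j
        out[f] = i
    return out


def simulate_unwrap_counts(params: SyntheticParams,
                           rng: np.random.Generator | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit unwrapped-bp counts from the zipper chain alone (no
    coordinates).  Same Markov kernel the full simulator uses."""
    if params.n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = rng or np.random.default_rng(params.seed)
    entry = _zipper_chain(params.n_frames, params.epsilon, params.rt,
                          params.max_unwrap, rng)
    exit_ = _zipper_chain(params.n_frames, params.epsilon, params.rt,
                          params.max_unwrap, rng)
    return entry, exit_


def _ar1(n: int, mean: float, sd: float, relaxation: float,
         rng: np.random.Generator) -> np.ndarray:
    phi = float(np.exp(-1.0 / relaxation))
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    prev = rng.normal(mean, sd)  # start in the stationary law
    for f in range(n):
        prev = mean + phi * (prev - mean) + eps[f]
        x[f] = prev
    return x


def simulate_trajectory(params: SyntheticParams | None = None
                        ) -> tuple[NucleosomeSystem, Ensemble, GroundTruth]:
    """Run the full generator: returns the system, the (already reference-
    frame) ensemble, and exact pre-noise ground truth."""
    params = params or SyntheticParams()
    if params.n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(params.seed)
    geo = _Geometry(params)
    n, n_atoms = params.n_frames, len(geo.xyz)

    entry = _zipper_chain(n, params.epsilon, params.rt, params.max_unwrap, rng)
    exit_ = _zipper_chain(n, params.epsilon, params.rt, params.max_unwrap, rng)
    delta = _ar1(n, geo.gape_delta_mean, params.gaping_amplitude,
                 params.gaping_relaxation, rng)
    delta = np.clip(delta, -geo.gape_z0 + 1.0, None)  # keep gyres apart

    coords = np.tile(geo.xyz, (n, 1, 1))

    # gaping: symmetric axial displacement of the two half-turns
    shift = geo.gape_sign * delta / 2.0
    coords[:, geo.plus_half_atoms, 2] += shift[:, None]
    coords[:, geo.minus_half_atoms, 2] -= shift[:, None]
    gape_true = np.sqrt(geo.gape_inplane ** 2 + (geo.gape_z0 + delta) ** 2)

    # unwrapping: peel bp radially off the superhelix, linkers ride along
    disp = params.unwrap_displacement
    for counts, core_atoms, linker_atoms in (
            (entry, geo.entry_core_atoms, geo.entry_linker_atoms),
            (exit_, geo.exit_core_atoms, geo.exit_linker_atoms)):
        mask = np.arange(len(core_atoms))[None, :] < counts[:, None]
        coords[:, core_atoms, :] += (mask[:, :, None]
                                     * disp * geo.dna_radial[core_atoms][None, :, :])
        ride = (counts > 0).astype(float)
        coords[:, linker_atoms, :] += (ride[:, None, None]
                                       * disp * geo.dna_radial[linker_atoms][None, :, :])

    # per-element rigid core fluctuation
    core_displacement: dict[str, np.ndarray] = {}
    for label, atoms in geo.element_atoms.items():
        elem = label.split(":")[-1]
        sigma = params.core_sigma.get(elem, 0.45)
        off = rng.normal(0.0, sigma, size=(n, 3))
        coords[:, atoms, :] += off[:, None, :]
        core_displacement[label] = off

    # coupled tails: Bernoulli bound state, bound pose follows the target DNA
    tail_contacts: dict[str, np.ndarray] = {}
    tail_bound: dict[str, np.ndarray] = {}
    floors: dict[str, int] = {}
    for label, info in geo.coupled_tails.items():
        if info["mode"] == "unwrap":
            drive = entry if info["side"] < 0 else exit_
            p = np.asarray(params.tail_bind_prob(drive), dtype=float)
        else:  # gaping-coupled: less bound when the gyres are far apart
            zscore = (delta - geo.gape_delta_mean) / params.gaping_amplitude
            p = np.clip(0.9 - 0.3 * np.clip(zscore, 0.0, None), 0.05, 0.95)
        bound = rng.random(n) < p
        atoms = info["atoms"]
        bound_pose = coords[:, info["target_atoms"], :] \
            + 3.0 * geo.dna_radial[info["target_atoms"]][None, :, :]
        unbound_pose = geo.xyz[atoms][None, :, :]
        coords[:, atoms, :] = np.where(bound[:, None, None], bound_pose, unbound_pose)
        # exact pre-noise contact count: the bound pose is rigid w.r.t. its
        # target DNA window, so the bound count is a constant of the reference
        d = np.linalg.norm(geo.bound_tail_xyz(label, geo.dna_xyz)[:, None, :]
                           - geo.dna_xyz[None, :, :], axis=2)
        n_bound = int(np.sum(d < CONTACT_CUTOFF))
        tail_contacts[label] = np.where(bound, n_bound, 0)
        tail_bound[label] = bound
        # conservative floor a noisy measured count should not drop below
        floors[label] = max(1, n_bound // 2)

    truth = GroundTruth(entry_unwrapped=entry, exit_unwrapped=exit_,
                        gaping_distance=gape_true, tail_contacts=tail_contacts,
                        tail_bound=tail_bound, core_displacement=core_displacement,
                        bound_contact_floor=floors)

    if params.noise_sigma > 0:
        coords += rng.normal(0.0, params.noise_sigma, size=(n, n_atoms, 3))

    times = params.sampling_interval * np.arange(n)
    system = geo.build_system()
    for label in geo.coupled_tails:  # reference carries the bound tail pose
        system.reference_coordinates[geo.coupled_tails[label]["atoms"]] = \
            geo.bound_tail_xyz(label, geo.dna_xyz)
    ens = Ensemble(coords, times, params.sampling_interval,
                   run_id=f"synthetic-seed{params.seed}", superposed=True,
                   superpose_selection=system.core_ca_atoms())
    return system, ens, truth


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

_SEGIDS = "ABCEFGHJ"  # histone chains; DNA gets "N"


def topology_spec_for(system: NucleosomeSystem) -> dict:
    chains = []
    for k, ch in enumerate(system.chains):
        chains.append({"segid": _SEGIDS[k], "variant": ch.variant_id,
                       "copy": ch.copy_index})
    return {"dna": {"segids": ["N"]}, "chains": chains}


def write_fixture(system: NucleosomeSystem, ensemble: Ensemble, directory,
                  ground_truth: GroundTruth | None = None,
                  prefix: str = "synthetic") -> dict[str, Path]:
    """Write structure (PDB), trajectory (XTC), topology spec (TOML) and
    ground truth (TSV) so the full file pipeline can be exercised."""
    import warnings

    import MDAnalysis as mda

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_atoms = system.n_atoms
    segids, resids, resnames = [], [], []
    for i in range(n_atoms):
        if system.atom_kind[i] == KIND_DNA:
            segids.append("N")
            resids.append(int(system.atom_bp[i]) + FULL_HALF_SPAN + 1)
            resnames.append("DA")
        else:
            segids.append(_SEGIDS[system.atom_chain[i]])
            resids.append(int(system.atom_resid[i]))
            resnames.append("GLY")
    u = mda.Universe.empty(n_atoms, n_residues=n_atoms, n_segments=9,
                           atom_resindex=np.arange(n_atoms),
                           residue_segindex=[list("NABCEFGHJ").index(s)
                                             for s in segids],
                           trajectory=True)
    u.add_TopologyAttr("names", list(system.atom_name))
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("segids", list("NABCEFGHJ"))
    u.add_TopologyAttr("chainIDs", segids)
    u.atoms.positions = system.reference_coordinates
    pdb_path = directory / f"{prefix}.pdb"
    xtc_path = directory / f"{prefix}.xtc"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(pdb_path))
        with mda.Writer(str(xtc_path), n_atoms) as w:
            for f in range(len(ensemble)):
                u.atoms.positions = ensemble.coordinates[f]
                u.trajectory.ts.time = float(ensemble.times[f])
                u.trajectory.ts.dt = ensemble.sampling_interval
                w.write(u.atoms)
    spec = topology_spec_for(system)
    toml_path = directory / f"{prefix}_topology.toml"
    lines = ["[dna]", 'segids = ["N"]', ""]
    for ch in spec["chains"]:
        lines += ["[[chains]]", f'segid = "{ch["segid"]}"',
                  f'variant = "{ch["variant"]}"', f'copy = {ch["copy"]}', ""]
    toml_path.write_text("\n".join(lines))
    out = {"structure": pdb_path, "trajectory": xtc_path, "topology": toml_path}
    if ground_truth is not None:
        tsv_path = directory / f"{prefix}_truth.tsv"
        ground_truth.to_frame().to_csv(tsv_path, sep="\t", index=False)
        out["truth"] = tsv_path
    return out
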