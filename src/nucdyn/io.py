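"""Structure/trajectory input, histone-core superposition and equilibration
trimming.

File formats (PDB/GRO structures; XTC/DCD/TRR trajectories) are read and
written through MDAnalysis.  Frames are held in memory in Angstrom with
times in picoseconds.  Frames are assumed whole (molecules not split across
periodic images); no re-imaging is attempted here.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import (
    DNADuplex,
    HistoneChain,
    NucleosomeSystem,
    DEFAULT_CORE_ANNOTATIONS,
    DEFAULT_TAIL_RANGES,
    KIND_CORE,
    KIND_DNA,
    KIND_OTHER,
    KIND_TAIL,
    sequential_to_dyad,
)

__all__ = [
    "Frame",
    "Ensemble",
    "LoadError",
    "load_topology_spec",
    "load_structure",
    "load_trajectory",
    "superpose",
    "trim_equilibration",
    "kabsch_fit",
]


class LoadError(RuntimeError):
    """A structure or trajectory could not be interpreted."""


@dataclass
class Frame:
    """One snapshot: time (ps) and per-atom coordinates (Angstrom)."""

    time: float
    coordinates: np.ndarray


class Ensemble:
    """Time-ordered frames with a constant sampling interval.

    Attributes
    ----------
    coordinates : (n_frames, n_atoms, 3) array, Angstrom
    times : (n_frames,) array, ps, strictly increasing with constant spacing
    sampling_interval : ps between consecutive frames
    run_id : label used for provenance in downstream series
    superposed : whether frames were least-squares fitted to the reference
    parent : the untrimmed ensemble this one was cut from, if any
    """

    def __init__(self, coordinates, times, sampling_interval, run_id="run",
                 superposed=False, superpose_selection=None, fit_rmsd=None,
                 parent=None):
        self.coordinates = np.asarray(coordinates, dtype=float)
        self.times = np.asarray(times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coordinates):
            raise ValueError("times/coordinates length mismatch")
        if len(self.times) == 0:
            raise ValueError("an Ensemble needs at least one frame")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dt, sampling_interval, rtol=1e-6, atol=1e-6):
                raise ValueError("frame spacing inconsistent with sampling_interval")
        self.sampling_interval = float(sampling_interval)
        self.run_id = run_id
        self.superposed = superposed
        self.superpose_selection = superpose_selection
        self.fit_rmsd = fit_rmsd
        self.parent = parent

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), coordinates=self.coordinates[i])


def load_topology_spec(spec) -> dict:
    """Accept a topology spec as a dict or a TOML file path."""
    if isinstance(spec, dict):
        return spec
    with open(spec, "rb") as fh:
        return tomllib.load(fh)


def _is_heavy(name: str) -> bool:
    # name-based hydrogen rule: leading digits stripped, then H => hydrogen
    stripped = name.lstrip("0123456789")
    return not stripped.upper().startswith("H")


def load_structure(path, topology_spec) -> NucleosomeSystem:
    """Read a PDB/GRO structure and map it onto a nucleosome topology.

    The topology spec names the DNA segment(s) and assigns each histone
    segment a variant and copy index, e.g.::

        [dna]
        segids = ["D"]            # one bead-per-bp segment, or two strands
        [[chains]]
        segid = "A"
        variant = "H3"
        copy = 1

    One DNA segid means a pseudo-atom duplex (one residue per bp, sequential
    1..187); two segids mean strands paired antiparallel (residue k of strand
    one with residue n+1-k of strand two).  Per-chain ``n_tail``/``c_tail``/
    ``annotations`` entries override the packaged defaults (for tail-swapped
    constructs, say).

    Formats without segment names (GRO): when none of the named segids exist
    in the file, atoms are split into contiguous blocks wherever the residue
    numbering restarts, and the blocks are assigned in file order to the DNA
    segids followed by the chain segids in spec order.
    """
    import MDAnalysis as mda

    spec = load_topology_spec(topology_spec)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # unparseable records
        raise LoadError(f"cannot parse structure {path}: {exc}") from exc

    segids = {str(s) for s in u.atoms.segids}
    dna_spec = spec.get("dna", {})
    dna_segids = [str(s) for s in dna_spec.get("segids", [])]
    chain_segids = [str(c["segid"]) for c in spec.get("chains", [])]
    wanted = dna_segids + chain_segids
    groups: dict[str, np.ndarray]
    if any(w in segids for w in wanted):
        for s in wanted:
            if s not in segids:
                what = "DNA segment" if s in dna_segids else "histone chain segment"
                raise LoadError(f"{what} {s!r} missing from {path}")
        groups = {s: u.select_atoms(f"segid {s}").indices for s in wanted}
    else:
        # no segment names in the file: split on residue-number restarts
        resids = np.asarray(u.atoms.resids)
        starts = [0] + [i for i in range(1, len(resids))
                        if resids[i] < resids[i - 1]] + [len(resids)]
        blocks = [np.arange(a, b) for a, b in zip(starts, starts[1:])]
        if len(blocks) != len(wanted):
            raise LoadError(
                f"{path} has no named segments and its {len(blocks)} residue "
                f"blocks do not match the {len(wanted)} segments in the spec")
        groups = dict(zip(wanted, blocks))

    chains: list[HistoneChain] = []
    n_total = len(u.atoms)
    kind = np.full(n_total, KIND_OTHER, dtype=np.int8)
    chain_col = np.full(n_total, -1, dtype=int)
    resid_col = np.zeros(n_total, dtype=int)
    bp_col = np.full(n_total, -999, dtype=int)
    strand_col = np.full(n_total, -1, dtype=int)
    names = np.array([str(n) for n in u.atoms.names], dtype=object)
    heavy = np.array([_is_heavy(n) for n in names])
    try:
        masses = np.asarray(u.atoms.masses, dtype=float)
        if not np.all(np.isfinite(masses)) or np.any(masses <= 0):
            raise ValueError
    except Exception:
        masses = np.ones(n_total)

    all_resids = np.asarray(u.atoms.resids)
    all_resnames = np.array([str(r) for r in u.atoms.resnames], dtype=object)

    for k, ch_spec in enumerate(spec.get("chains", [])):
        segid = str(ch_spec["segid"])
        idx = groups[segid]
        by_resid = {int(r): str(n) for r, n in zip(all_resids[idx],
                                                   all_resnames[idx])}
        residues = [(by_resid[i], i) for i in sorted(by_resid)]
        variant = ch_spec["variant"]
        copy_index = int(ch_spec.get("copy", 1))
        n_tail, c_tail = DEFAULT_TAIL_RANGES.get(variant, (None, None))
        if "n_tail" in ch_spec:
            n_tail = tuple(ch_spec["n_tail"]) if ch_spec["n_tail"] else None
        if "c_tail" in ch_spec:
            c_tail = tuple(ch_spec["c_tail"]) if ch_spec["c_tail"] else None
        annotations = {k2: tuple(v) for k2, v in ch_spec.get(
            "annotations", DEFAULT_CORE_ANNOTATIONS.get(variant, {})).items()}
        chain = HistoneChain(variant_id=variant, copy_index=copy_index,
                             residues=residues, n_tail_range=n_tail,
                             c_tail_range=c_tail, core_annotations=annotations)
        chains.append(chain)
        chain_col[idx] = k
        resid_col[idx] = all_resids[idx]
        in_tail = np.zeros(len(idx), dtype=bool)
        for iv in (n_tail, c_tail):
            if iv is not None:
                in_tail |= (all_resids[idx] >= iv[0]) & (all_resids[idx] <= iv[1])
        kind[idx] = np.where(in_tail, KIND_TAIL, KIND_CORE)

    # DNA mapping
    if not dna_segids:
        raise LoadError("topology spec names no DNA segments")
    if len(dna_segids) == 1:
        idx = groups[dna_segids[0]]
        resids = all_resids[idx]
        n_bp = len(np.unique(resids))
        seq_pos = resids - resids.min() + 1
        kind[idx] = KIND_DNA
        strand_col[idx] = 0
        bp_col[idx] = [sequential_to_dyad(int(p), n_bp) for p in seq_pos]
    elif len(dna_segids) == 2:
        idx1, idx2 = groups[dna_segids[0]], groups[dna_segids[1]]
        n_bp = len(np.unique(all_resids[idx1]))
        if len(np.unique(all_resids[idx2])) != n_bp:
            raise LoadError("DNA strands have unequal residue counts")
        for s, idx, flip in ((0, idx1, False), (1, idx2, True)):
            resids = all_resids[idx]
            pos = resids - resids.min() + 1
            if flip:
                pos = n_bp + 1 - pos
            kind[idx] = KIND_DNA
            strand_col[idx] = s
            bp_col[idx] = [sequential_to_dyad(int(p), n_bp) for p in pos]
    else:
        raise LoadError("dna.segids must name one or two segments")

    dna = DNADuplex.default()
    coords = np.asarray(u.atoms.positions, dtype=float)
    return NucleosomeSystem(
        chains=chains, dna=dna, reference_coordinates=coords,
        atom_kind=kind, atom_chain=chain_col, atom_resid=resid_col,
        atom_bp=bp_col, atom_strand=strand_col, atom_name=names,
        atom_is_heavy=heavy, atom_mass=masses,
    )


def load_trajectory(path, system: NucleosomeSystem, sampling_interval: float,
                    run_id: str | None = None,
                    structure_path=None) -> Ensemble:
    """Read an XTC/DCD/TRR trajectory against a loaded system.

    ``sampling_interval`` (ps) assigns frame times when the file carries
    none; file times win over the stated interval (with a warning) when both
    are present and disagree.
    """
    import MDAnalysis as mda

    if structure_path is None:
        raise LoadError("structure_path (topology file) is required to read a trajectory")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(structure_path), str(path))
    except Exception as exc:
        raise LoadError(f"cannot read trajectory {path}: {exc}") from exc
    if len(u.atoms) != system.n_atoms:
        raise LoadError(
            f"trajectory atom count {len(u.atoms)} != system atom count {system.n_atoms}")
    coords, times = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            coords.append(ts.positions.astype(float).copy())
            times.append(float(ts.time))
    coords = np.asarray(coords)
    times = np.asarray(times)
    n = len(times)
    synthetic_times = sampling_interval * np.arange(n)
    if n > 1:
        dt = np.diff(times)
        if np.any(dt <= 0):
            times = synthetic_times  # file carries no usable times
        elif not np.allclose(dt, sampling_interval, rtol=1e-3, atol=1e-3):
            warnings.warn(
                f"file frame spacing {np.median(dt):g} ps disagrees with stated "
                f"sampling interval {sampling_interval:g} ps; file times win",
                stacklevel=2)
            sampling_interval = float(np.median(dt))
    return Ensemble(coords, times, sampling_interval,
                    run_id=run_id or Path(str(path)).stem)


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns (rotation 3x3, translation 3,) such that
    ``mobile @ R.T + t`` minimizes the RMSD to ``reference``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    pm, qm = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pm).T @ (Q - qm)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qm - R @ pm
    return R, t


def superpose(ensemble: Ensemble, system: NucleosomeSystem,
              selection: np.ndarray | None = None) -> Ensemble:
    """Rigid-body fit each frame to the reference structure.

    The fit selection defaults to the C-alpha (bead) atoms of the annotated
    histone-fold elements of every chain — the "histone core".  RMSD of the
    selection after fitting is stored per frame.
    """
    if selection is None:
        selection = system.core_ca_atoms()
    selection = np.asarray(selection, dtype=int)
    if len(selection) < 3:
        raise ValueError("superposition needs at least 3 selection atoms")
    ref = system.reference_coordinates[selection]
    out = np.empty_like(ensemble.coordinates)
    rmsd = np.empty(len(ensemble))
    for f in range(len(ensemble)):
        X = ensemble.coordinates[f]
        R, t = kabsch_fit(X[selection], ref)
        out[f] = X @ R.T + t
        d = out[f][selection] - ref
        rmsd[f] = np.sqrt(np.mean(np.sum(d * d, axis=1)))
    return Ensemble(out, ensemble.times, ensemble.sampling_interval,
                    run_id=ensemble.run_id, superposed=True,
                    superpose_selection=selection, fit_rmsd=rmsd,
                    parent=ensemble.parent)


def trim_equilibration(ensemble: Ensemble, t_cut_ns: float = 200.0) -> Ensemble:
    """Drop frames earlier than ``t_cut_ns``; the untrimmed ensemble stays
    reachable as ``.parent`` for all-time evolution plots."""
    if t_cut_ns < 0:
        raise ValueError("t_cut must be >= 0")
    keep = ensemble.times >= t_cut_ns * 1000.0
    if not np.any(keep):
        raise ValueError(f"trimming at {t_cut_ns} ns leaves no frames")
    if np.all(keep):
        return ensemble
    return Ensemble(ensemble.coordinates[keep], ensemble.times[keep],
                    ensemble.sampling_interval, run_id=ensemble.run_id,
                    superposed=ensemble.superposed,
                    superpose_selection=ensemble.superpose_selection,
                    fit_rmsd=None if ensemble.fit_rmsd is None
                    else ensemble.fit_rmsd[keep],
                    parent=ensemble)
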