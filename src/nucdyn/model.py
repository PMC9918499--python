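"""Nucleosome topology: chains, the dyad-centered base-pair coordinate system,
superhelical locations (SHLs) and DNA region classification.

The nucleosome core particle wraps 147 bp of DNA in ~1.65 left-handed
superhelical turns around a histone octamer (two copies each of H2A-family,
H2B, H3-family and H4).  Base pairs are indexed relative to the dyad (the
central bp, index 0): the core spans -73..+73 and two straight linkers of
20 bp extend the duplex to -93..+93 (187 bp total).  A superhelical location
(SHL) is the signed number of DNA helical turns away from the dyad; integer
SHLs mark the sites where the DNA major groove faces the histone surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SHL_PITCH_BP",
    "CORE_HALF_SPAN",
    "LINKER_BP",
    "FULL_HALF_SPAN",
    "INNER_OUTER_BOUNDARY",
    "HistoneChain",
    "DNADuplex",
    "NucleosomeSystem",
    "assign_shl",
    "shl_window",
    "classify_region",
    "sequential_to_dyad",
    "dyad_to_sequential",
    "default_chain",
    "default_octamer_variants",
    "DEFAULT_TAIL_RANGES",
    "DEFAULT_CORE_ANNOTATIONS",
    "DEFAULT_CHAIN_LENGTHS",
]

#: helical repeat used to convert bp index to superhelical location, bp/turn
SHL_PITCH_BP = 10.3
#: core DNA spans -CORE_HALF_SPAN..+CORE_HALF_SPAN around the dyad (147 bp)
CORE_HALF_SPAN = 73
#: straight linker length on each side, bp
LINKER_BP = 20
#: full duplex spans -FULL_HALF_SPAN..+FULL_HALF_SPAN (187 bp)
FULL_HALF_SPAN = CORE_HALF_SPAN + LINKER_BP
#: |bp| at and beyond which core DNA counts as "outer" (~SHL 3.5)
INNER_OUTER_BOUNDARY = 37

SECONDARY_STRUCTURE_ELEMENTS = ("alphaN", "alpha1", "alpha2", "alpha3", "alphaC", "L1", "L2")

# Residue bookkeeping for the standard human histones (numbering includes the
# initiator Met, matching the residue indices used for tail definitions).
DEFAULT_CHAIN_LENGTHS: dict[str, int] = {
    "H2A": 130,
    "H2A.Z": 128,
    "H2B": 126,
    "H3": 136,
    "H3.3": 136,
    "H4": 103,
}

# (n_tail, c_tail) residue intervals, inclusive; None = no disordered tail.
DEFAULT_TAIL_RANGES: dict[str, tuple[tuple[int, int] | None, tuple[int, int] | None]] = {
    "H2A": ((1, 16), (121, 130)),
    "H2A.Z": ((1, 18), (123, 128)),
    "H2B": ((1, 26), None),
    "H3": ((1, 38), None),
    "H3.3": ((1, 38), None),
    "H4": ((1, 20), None),
}

# Approximate histone-fold annotations (inclusive residue intervals).  These
# drive selections (fit atoms, per-element fluctuation) and the pseudo-atom
# generator; they are not used to build atomic models.
DEFAULT_CORE_ANNOTATIONS: dict[str, dict[str, tuple[int, int]]] = {
    "H2A": {"alpha1": (26, 37), "L1": (38, 45), "alpha2": (46, 73), "L2": (74, 77),
            "alpha3": (79, 89), "alphaC": (90, 97)},
    "H2A.Z": {"alpha1": (28, 39), "L1": (40, 47), "alpha2": (48, 75), "L2": (76, 79),
              "alpha3": (81, 91), "alphaC": (92, 99)},
    "H2B": {"alpha1": (37, 49), "L1": (50, 56), "alpha2": (57, 84), "L2": (85, 88),
            "alpha3": (89, 99), "alphaC": (100, 120)},
    "H3": {"alphaN": (45, 56), "alpha1": (63, 76), "L1": (77, 85), "alpha2": (86, 113),
           "L2": (114, 119), "alpha3": (120, 130)},
    "H3.3": {"alphaN": (45, 56), "alpha1": (63, 76), "L1": (77, 85), "alpha2": (86, 113),
             "L2": (114, 119), "alpha3": (120, 130)},
    "H4": {"alpha1": (31, 41), "L1": (42, 48), "alpha2": (49, 75), "L2": (76, 81),
           "alpha3": (82, 92)},
}

KNOWN_VARIANTS = tuple(DEFAULT_CHAIN_LENGTHS)


def assign_shl(bp_index: float, pitch: float = SHL_PITCH_BP) -> float:
    """Signed, continuous superhelical location of a base pair.

    SHL = bp_index / pitch with the dyad at SHL 0.  Integer SHL ``n``
    corresponds to the bp window ``round(pitch*n) +/- 2`` (see
    :func:`shl_window`).

    Raises
    ------
    ValueError
        If ``bp_index`` lies outside the duplex span (-93..+93).
    """
    if not -FULL_HALF_SPAN <= bp_index <= FULL_HALF_SPAN:
        raise ValueError(f"bp index {bp_index} outside duplex span +/-{FULL_HALF_SPAN}")
    return bp_index / pitch


def shl_window(n: int, pitch: float = SHL_PITCH_BP, half_width: int = 2) -> tuple[int, int]:
    """Inclusive bp window ``round(pitch*n) +/- half_width`` of integer SHL ``n``."""
    center = int(round(pitch * n))
    return center - half_width, center + half_width


def classify_region(
    bp_index: int,
    inner_outer_boundary: int = INNER_OUTER_BOUNDARY,
    core_half_span: int = CORE_HALF_SPAN,
) -> str:
    """Classify a bp as ``inner``, ``outer`` or ``linker``.

    Linker iff |i| > core_half_span; outer iff inner_outer_boundary <= |i|
    <= core_half_span; inner otherwise.  The three labels are exhaustive and
    mutually exclusive.
    """
    a = abs(int(bp_index))
    if a > FULL_HALF_SPAN:
        raise ValueError(f"bp index {bp_index} outside duplex span +/-{FULL_HALF_SPAN}")
    if a > core_half_span:
        return "linker"
    if a >= inner_outer_boundary:
        return "outer"
    return "inner"


def sequential_to_dyad(seq_index: int, n_bp: int = 2 * FULL_HALF_SPAN + 1) -> int:
    """Map 1-based sequential bp numbering (1..187) to dyad-centered indices."""
    if not 1 <= seq_index <= n_bp:
        raise ValueError(f"sequential bp index {seq_index} outside 1..{n_bp}")
    return seq_index - 1 - (n_bp - 1) // 2


def dyad_to_sequential(bp_index: int, n_bp: int = 2 * FULL_HALF_SPAN + 1) -> int:
    """Inverse of :func:`sequential_to_dyad`."""
    half = (n_bp - 1) // 2
    if not -half <= bp_index <= half:
        raise ValueError(f"bp index {bp_index} outside +/-{half}")
    return bp_index + 1 + half


def _check_interval(iv, lo, hi, what):
    a, b = iv
    if not (lo <= a <= b <= hi):
        raise ValueError(f"{what} interval {iv} not within residue span {lo}..{hi}")


@dataclass
class HistoneChain:
    """One histone chain with tail and histone-fold annotations.

    ``residues`` are (name, index) records in increasing index order; tails
    and core annotations are inclusive residue-index intervals that must be
    disjoint and lie within the chain span.
    """

    variant_id: str
    copy_index: int
    residues: list[tuple[str, int]]
    n_tail_range: tuple[int, int] | None = None
    c_tail_range: tuple[int, int] | None = None
    core_annotations: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.variant_id not in KNOWN_VARIANTS:
            raise ValueError(f"unknown histone variant {self.variant_id!r}")
        if self.copy_index not in (1, 2):
            raise ValueError("copy_index must be 1 or 2")
        idx = [i for _, i in self.residues]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("residue indices must be strictly increasing")
        lo, hi = idx[0], idx[-1]
        intervals = []
        for name, iv in (("n_tail", self.n_tail_range), ("c_tail", self.c_tail_range)):
            if iv is not None:
                _check_interval(iv, lo, hi, name)
                intervals.append((name, iv))
        for name, iv in self.core_annotations.items():
            _check_interval(iv, lo, hi, f"core element {name}")
            intervals.append((name, iv))
        intervals.sort(key=lambda t: t[1])
        for (na, (a0, a1)), (nb, (b0, b1)) in zip(intervals, intervals[1:]):
            if b0 <= a1:
                raise ValueError(f"annotations {na} {a0,a1} and {nb} {b0,b1} overlap")

    @property
    def first_residue(self) -> int:
        return self.residues[0][1]

    @property
    def last_residue(self) -> int:
        return self.residues[-1][1]

    def tail_range(self, which: str) -> tuple[int, int]:
        iv = self.n_tail_range if which.upper().startswith("N") else self.c_tail_range
        if iv is None:
            raise ValueError(f"{self.variant_id} copy {self.copy_index} has no {which}-tail")
        return iv

    @property
    def label(self) -> str:
        return f"{self.variant_id}:{self.copy_index}"


def default_chain(variant: str, copy_index: int) -> HistoneChain:
    """A :class:`HistoneChain` with the packaged default tail/core annotations."""
    n = DEFAULT_CHAIN_LENGTHS[variant]
    n_tail, c_tail = DEFAULT_TAIL_RANGES[variant]
    return HistoneChain(
        variant_id=variant,
        copy_index=copy_index,
        residues=[("RES", i) for i in range(1, n + 1)],
        n_tail_range=n_tail,
        c_tail_range=c_tail,
        core_annotations=dict(DEFAULT_CORE_ANNOTATIONS[variant]),
    )


def default_octamer_variants(h2a_like: str = "H2A", h3_like: str = "H3") -> list[tuple[str, int]]:
    """(variant, copy) list for a homotypic octamer."""
    out = []
    for variant in (h3_like, "H4", h2a_like, "H2B"):
        out.append((variant, 1))
        out.append((variant, 2))
    return out


@dataclass
class DNADuplex:
    """The 187-bp duplex in dyad-centered numbering.

    ``bp_index`` runs -93..+93 (dyad 0); ``pairs`` holds the two strands'
    nucleotide identifiers per bp; ``region`` labels each bp inner/outer/
    linker and partitions the duplex.
    """

    bp_index: np.ndarray
    pairs: list[tuple[str, str]]
    region: list[str]

    def __post_init__(self):
        self.bp_index = np.asarray(self.bp_index, dtype=int)
        if np.any(np.diff(self.bp_index) <= 0):
            raise ValueError("bp indices must be strictly increasing")
        if len(self.pairs) != len(self.bp_index) or len(self.region) != len(self.bp_index):
            raise ValueError("pairs/region length mismatch with bp_index")
        bad = set(self.region) - {"inner", "outer", "linker"}
        if bad:
            raise ValueError(f"unknown region labels {bad}")
        n_core = int(np.sum(np.abs(self.bp_index) <= CORE_HALF_SPAN))
        n_link = int(np.sum(np.abs(self.bp_index) > CORE_HALF_SPAN))
        if n_core != 2 * CORE_HALF_SPAN + 1 or n_link != 2 * LINKER_BP:
            raise ValueError(
                f"expected {2 * CORE_HALF_SPAN + 1} core and {2 * LINKER_BP} linker bp, "
                f"got {n_core}/{n_link}"
            )

    def __len__(self) -> int:
        return len(self.bp_index)

    @classmethod
    def default(cls, sequence: str | None = None,
                inner_outer_boundary: int = INNER_OUTER_BOUNDARY) -> "DNADuplex":
        """Build the default 187-bp duplex, optionally from a strand-1 sequence."""
        idx = np.arange(-FULL_HALF_SPAN, FULL_HALF_SPAN + 1)
        comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
        if sequence is None:
            sequence = "ATGC" * 47  # placeholder duplex; identity is irrelevant to geometry
            sequence = sequence[: len(idx)]
        if len(sequence) != len(idx):
            raise ValueError(f"sequence length {len(sequence)} != {len(idx)} bp")
        pairs = [(b, comp.get(b, "N")) for b in sequence.upper()]
        region = [classify_region(i, inner_outer_boundary) for i in idx]
        return cls(bp_index=idx, pairs=pairs, region=region)

    def bp_in_region(self, region: str) -> np.ndarray:
        """bp indices carrying the given region label."""
        mask = np.array([r == region for r in self.region])
        return self.bp_index[mask]


# atom-kind codes for the flat atom table
KIND_DNA = 0
KIND_CORE = 1
KIND_TAIL = 2
KIND_OTHER = 3


class NucleosomeSystem:
    """Topology + reference coordinates + a flat atom table.

    Every atom maps to exactly one histone residue (``chain_idx``/``resid``)
    or one nucleotide (``strand``/``bp``).  Coordinates are in Angstrom.
    """

    def __init__(
        self,
        chains: Sequence[HistoneChain],
        dna: DNADuplex,
        reference_coordinates: np.ndarray,
        atom_kind: np.ndarray,
        atom_chain: np.ndarray,
        atom_resid: np.ndarray,
        atom_bp: np.ndarray,
        atom_strand: np.ndarray,
        atom_name: Sequence[str],
        atom_is_heavy: np.ndarray,
        atom_mass: np.ndarray | None = None,
    ):
        self.chains = list(chains)
        self.dna = dna
        ref = np.asarray(reference_coordinates, dtype=float)
        if ref.ndim != 2 or ref.shape[1] != 3:
            raise ValueError("reference coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(ref)):
            raise ValueError("reference coordinates must be finite")
        self.reference_coordinates = ref
        n = len(ref)
        self.atom_kind = np.asarray(atom_kind, dtype=np.int8)
        self.atom_chain = np.asarray(atom_chain, dtype=int)
        self.atom_resid = np.asarray(atom_resid, dtype=int)
        self.atom_bp = np.asarray(atom_bp, dtype=int)
        self.atom_strand = np.asarray(atom_strand, dtype=int)
        self.atom_name = np.asarray(atom_name, dtype=object)
        self.atom_is_heavy = np.asarray(atom_is_heavy, dtype=bool)
        self.atom_mass = (np.ones(n) if atom_mass is None
                          else np.asarray(atom_mass, dtype=float))
        for arr, what in [
            (self.atom_kind, "kind"), (self.atom_chain, "chain"),
            (self.atom_resid, "resid"), (self.atom_bp, "bp"),
            (self.atom_strand, "strand"), (self.atom_name, "name"),
            (self.atom_is_heavy, "heavy"), (self.atom_mass, "mass"),
        ]:
            if len(arr) != n:
                raise ValueError(f"atom table column '{what}' length != n_atoms")
        is_dna = self.atom_kind == KIND_DNA
        if np.any(self.atom_bp[is_dna] < -FULL_HALF_SPAN) or np.any(
                self.atom_bp[is_dna] > FULL_HALF_SPAN):
            raise ValueError("DNA atom bp indices outside duplex span")
        if np.any(self.atom_chain[~is_dna] < 0):
            raise ValueError("protein atoms must map to a chain")
        self._bp_center_atoms = self._build_bp_center_atoms()

    # -- construction helpers -------------------------------------------------

    def _build_bp_center_atoms(self) -> dict[int, np.ndarray]:
        """Per-bp atom indices whose mean defines the bp center.

        Pseudo-atom systems carry one bead per bp; all-atom systems use the
        two paired C1' atoms.
        """
        out: dict[int, np.ndarray] = {}
        is_dna = self.atom_kind == KIND_DNA
        names = self.atom_name
        c1_mask = is_dna & np.array([n.replace("'", "").replace("*", "") == "C1"
                                     for n in names])
        use_c1 = bool(c1_mask.any())
        for bp in self.dna.bp_index:
            sel = (self.atom_bp == bp) & is_dna
            if use_c1:
                sel = sel & c1_mask
            idx = np.flatnonzero(sel)
            if len(idx) == 0:
                raise ValueError(f"no center-defining atoms for bp {bp}")
            out[int(bp)] = idx
        return out

    # -- basic facts ----------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.reference_coordinates)

    def chain_index(self, variant: str, copy_index: int) -> int:
        for k, ch in enumerate(self.chains):
            if ch.variant_id == variant and ch.copy_index == copy_index:
                return k
        raise KeyError(f"no chain {variant}:{copy_index}")

    # -- selections (index arrays into the atom table) ------------------------

    def bp_center_atoms(self, bp_index: int) -> np.ndarray:
        try:
            return self._bp_center_atoms[int(bp_index)]
        except KeyError:
            raise ValueError(f"bp {bp_index} not in duplex") from None

    def dna_atoms(self, region: str | None = None,
                  bp_window: tuple[int, int] | None = None,
                  heavy_only: bool = True) -> np.ndarray:
        """DNA atom indices, optionally restricted to a region label or an
        explicit inclusive bp window (the two mechanisms are independent)."""
        mask = self.atom_kind == KIND_DNA
        if heavy_only:
            mask &= self.atom_is_heavy
        if region is not None and region != "total":
            keep = set(int(b) for b in self.dna.bp_in_region(region))
            mask &= np.array([int(b) in keep for b in self.atom_bp])
        if bp_window is not None:
            lo, hi = bp_window
            mask &= (self.atom_bp >= lo) & (self.atom_bp <= hi)
        return np.flatnonzero(mask)

    def tail_atoms(self, variant: str, copy_index: int, which: str,
                   heavy_only: bool = True) -> np.ndarray:
        k = self.chain_index(variant, copy_index)
        lo, hi = self.chains[k].tail_range(which)
        mask = (self.atom_chain == k) & (self.atom_resid >= lo) & (self.atom_resid <= hi)
        mask &= self.atom_kind != KIND_DNA
        if heavy_only:
            mask &= self.atom_is_heavy
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError(f"empty tail selection {variant}:{copy_index}:{which}")
        return idx

    def element_atoms(self, variant: str, copy_index: int, element: str,
                      ca_only: bool = False) -> np.ndarray:
        k = self.chain_index(variant, copy_index)
        try:
            lo, hi = self.chains[k].core_annotations[element]
        except KeyError:
            raise KeyError(f"chain {variant}:{copy_index} has no element {element}") from None
        mask = (self.atom_chain == k) & (self.atom_resid >= lo) & (self.atom_resid <= hi)
        if ca_only:
            mask &= np.array([n == "CA" for n in self.atom_name])
        return np.flatnonzero(mask)

    def core_ca_atoms(self, include_loops: bool = False,
                      chains: Iterable[int] | None = None) -> np.ndarray:
        """C-alpha atoms of annotated histone-fold elements (the default
        superposition selection).  Loops L1/L2 are excluded unless asked for."""
        ca = np.array([n == "CA" for n in self.atom_name])
        mask = np.zeros(self.n_atoms, dtype=bool)
        which = range(len(self.chains)) if chains is None else chains
        for k in which:
            ch = self.chains[k]
            for name, (lo, hi) in ch.core_annotations.items():
                if not include_loops and name in ("L1", "L2"):
                    continue
                mask |= ((self.atom_chain == k) & (self.atom_resid >= lo)
                         & (self.atom_resid <= hi))
        mask &= ca
        return np.flatnonzero(mask)

    def histone_atoms(self, heavy_only: bool = True) -> np.ndarray:
        mask = self.atom_kind != KIND_DNA
        if heavy_only:
            mask &= self.atom_is_heavy
        return np.flatnonzero(mask)
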