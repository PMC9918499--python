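"""Histone variant sequence analytics.

Human H2A.Z shares only ~60 % sequence identity with canonical H2A despite
belonging to the same family; the divergence is concentrated in the tails
and the C-terminal docking domain.  This module carries the curated human
reference sequences, formal-charge bookkeeping (K/R = +1, D/E = -1, His
neutral at pH 7 — a choice that otherwise moves tail charges by whole
units), percent identity by global alignment, and the C-terminal tail-swap
construct arithmetic.

Two residue-numbering conventions for the C-tails circulate (H2A 120-130 /
H2A.Z 122-128 and H2A 121-130 / H2A.Z 123-128); both are kept as named
presets, anchored at the C-terminus so they survive off-by-one differences
in database numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = ["HistoneSequence", "load_packaged", "net_charge", "percent_identity",
           "swap_ctail", "ctail_range", "CTAIL_PRESETS", "read_fasta",
           "write_fasta"]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: C-tail presets as suffix lengths (H2A, H2A.Z): two published conventions
CTAIL_PRESETS: dict[str, dict[str, int]] = {
    "methods": {"H2A": 11, "H2A.Z": 7},   # H2A 120-130, H2A.Z 122-128
    "figures": {"H2A": 10, "H2A.Z": 6},   # H2A 121-130, H2A.Z 123-128
}

_PACKAGED = {"H2A": "h2a_human.fasta", "H2A.Z": "h2az1_human.fasta"}


@dataclass
class HistoneSequence:
    """One-letter histone sequence with its numbering offset (index of the
    first residue, normally 1 including the initiator Met)."""

    variant_id: str
    sequence: str
    numbering_offset: int = 1

    def __post_init__(self):
        bad = set(self.sequence.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-amino-acid letters in sequence: {sorted(bad)}")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def slice_residues(self, first: int, last: int) -> str:
        """Subsequence by residue numbers (inclusive)."""
        lo = first - self.numbering_offset
        hi = last - self.numbering_offset + 1
        if lo < 0 or hi > len(self.sequence) or lo >= hi:
            raise ValueError(f"residue range {first}..{last} outside sequence "
                             f"({self.numbering_offset}.."
                             f"{self.numbering_offset + len(self.sequence) - 1})")
        return self.sequence[lo:hi]


def load_packaged(variant: str) -> HistoneSequence:
    """The packaged curated human sequence for H2A or H2A.Z."""
    try:
        fname = _PACKAGED[variant]
    except KeyError:
        raise KeyError(f"no packaged sequence for {variant!r}") from None
    with resources.files("nucdyn.data").joinpath(fname).open() as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    return HistoneSequence(variant_id=variant, sequence=str(rec.seq))


def read_fasta(path) -> list[HistoneSequence]:
    return [HistoneSequence(variant_id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: list[HistoneSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.variant_id}\n")
            for i in range(0, len(s.sequence), 60):
                fh.write(s.sequence[i:i + 60] + "\n")


def net_charge(seq: HistoneSequence | str, residue_range: tuple[int, int] | None = None) -> int:
    """Formal side-chain charge at pH 7 over a residue range: K, R -> +1;
    D, E -> -1; His neutral; termini ignored."""
    if isinstance(seq, HistoneSequence):
        if residue_range is None:
            sub = seq.sequence
        else:
            sub = seq.slice_residues(*residue_range)
    else:
        sub = seq if residue_range is None else None
        if sub is None:
            s = HistoneSequence("H2A", seq)
            sub = s.slice_residues(*residue_range)
    return sum(+1 if c in "KR" else -1 if c in "DE" else 0 for c in sub)


def percent_identity(seq_a: HistoneSequence | str, seq_b: HistoneSequence | str,
                     scoring: str = "blosum62") -> float:
    """Percent identity from one optimal global alignment.

    identity = matching columns / alignment columns x 100.  The default
    scoring is BLOSUM62 with gap open -10 and extend -0.5 (the standard
    needle-style parameters); ``scoring="unit"`` uses match +1 / mismatch 0
    with the same gap costs, which effectively forbids gaps.
    """
    a = seq_a.sequence if isinstance(seq_a, HistoneSequence) else seq_a.upper()
    b = seq_b.sequence if isinstance(seq_b, HistoneSequence) else seq_b.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner(mode="global", open_gap_score=-10.0,
                                    extend_gap_score=-0.5)
    if scoring == "blosum62":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    elif scoring == "unit":
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
    else:
        raise ValueError(f"unknown scoring {scoring!r}")
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return 100.0 * matches / len(sa)


def ctail_range(seq: HistoneSequence, preset: str = "figures") -> tuple[int, int]:
    """Residue range of the C-terminal tail under a named preset, anchored
    at the sequence's C-terminus."""
    try:
        suffix = CTAIL_PRESETS[preset][seq.variant_id]
    except KeyError:
        raise KeyError(f"no C-tail preset {preset!r} for {seq.variant_id!r}") from None
    last = seq.numbering_offset + len(seq) - 1
    return last - suffix + 1, last


def swap_ctail(seq_h2a: HistoneSequence, seq_h2az: HistoneSequence,
               range_a: tuple[int, int] | None = None,
               range_z: tuple[int, int] | None = None,
               preset: str = "methods") -> tuple[HistoneSequence, HistoneSequence]:
    """Exchange the two C-terminal tails, giving the tail-swap constructs.

    Returns (H2A body + H2A.Z tail, H2A.Z body + H2A tail).  Explicit ranges
    must be terminal; by default the named preset picks them.  Swapping
    twice restores the originals.
    """
    if range_a is None:
        range_a = ctail_range(seq_h2a, preset)
    if range_z is None:
        range_z = ctail_range(seq_h2az, preset)
    for seq, rng in ((seq_h2a, range_a), (seq_h2az, range_z)):
        last = seq.numbering_offset + len(seq) - 1
        if rng[1] != last:
            raise ValueError(f"range {rng} is not terminal in {seq.variant_id} "
                             f"(last residue {last})")
    tail_a = seq_h2a.slice_residues(*range_a)
    tail_z = seq_h2az.slice_residues(*range_z)
    body_a = seq_h2a.sequence[: len(seq_h2a) - len(tail_a)]
    body_z = seq_h2az.sequence[: len(seq_h2az) - len(tail_z)]
    return (
        HistoneSequence(variant_id=seq_h2a.variant_id, sequence=body_a + tail_z,
                        numbering_offset=seq_h2a.numbering_offset),
        HistoneSequence(variant_id=seq_h2az.variant_id, sequence=body_z + tail_a,
                        numbering_offset=seq_h2az.numbering_offset),
    )
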