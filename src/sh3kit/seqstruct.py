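"""Sequence and structure utilities shared across the pipeline.

Small, exactly-specified primitives: DNA translation, gap-aware pairwise
identity on aligned rows, BLOSUM62 per-column conservation, relative solvent
accessibility (RSA), minimum inter-atomic distance, relative domain-position
conservation across orthologs, and min-max normalization of circular-dichroism
ellipticity series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.spatial.distance import cdist

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

# Empirical maximum solvent accessibilities (A^2) per residue (theoretical
# upper bounds from folded-protein surveys; Tien et al. style "empirical"
# column). Shipped as editable configuration, not hard-coded truth.
MAX_ACC_EMPIRICAL: dict[str, float] = {
    "A": 121.0, "R": 265.0, "N": 187.0, "D": 187.0, "C": 148.0,
    "E": 214.0, "Q": 214.0, "G": 97.0, "H": 216.0, "I": 195.0,
    "L": 191.0, "K": 230.0, "M": 203.0, "F": 228.0, "P": 154.0,
    "S": 143.0, "T": 163.0, "W": 264.0, "Y": 255.0, "V": 165.0,
}


def translate_dna(dna: str) -> str:
    """Translate a DNA string with the standard genetic code.

    Requires length divisible by 3 and unambiguous A/C/G/T characters.
    Stop codons translate to '*'; no further stop handling.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise ValueError(f"DNA length {len(dna)} not divisible by 3")
    if any(c not in "ACGT" for c in dna):
        bad = sorted({c for c in dna if c not in "ACGT"})
        raise ValueError(f"non-ACGT characters in DNA: {bad}")
    if not dna:
        return ""
    return str(Seq(dna).translate())


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues between two aligned rows.

    Columns where both rows are gaps are excluded; a gap aligned to a
    residue counts as a mismatch.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned rows differ in length: {len(a)} vs {len(b)}")
    matches = 0
    columns = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        columns += 1
        if x == y:
            matches += 1
    if columns == 0:
        raise ValueError("no non-gap columns shared between rows")
    return matches / columns


def _normalized_blosum62() -> tuple[dict[tuple[str, str], float], float, float]:
    mat = substitution_matrices.load("BLOSUM62")
    scores = {}
    vals = []
    for x in AA_ALPHABET:
        for y in AA_ALPHABET:
            s = float(mat[x, y])
            scores[(x, y)] = s
            vals.append(s)
    lo, hi = min(vals), max(vals)
    return scores, lo, hi


_B62, _B62_MIN, _B62_MAX = _normalized_blosum62()


def site_conservation(rows: Sequence[str]) -> np.ndarray:
    """Per-column conservation of an alignment under BLOSUM62.

    The substitution matrix is min-max normalized to [0, 1] over its 20x20
    standard-residue block; each column's score is the mean normalized
    similarity over all unordered pairs of non-gap residues. Columns with
    fewer than two non-gap residues, or containing residues outside the
    standard alphabet, score NaN.
    """
    if not rows:
        raise ValueError("empty alignment")
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("alignment rows differ in length")
    span = _B62_MAX - _B62_MIN
    out = np.full(L, np.nan)
    for j in range(L):
        col = [r[j] for r in rows if r[j] != GAP]
        if len(col) < 2:
            continue
        if any(c not in _B62_MIN_SET for c in col):
            warnings.warn(f"column {j}: non-standard residue, scored NaN")
            continue
        total = 0.0
        n = 0
        for i in range(len(col)):
            for k in range(i + 1, len(col)):
                total += (_B62[(col[i], col[k])] - _B62_MIN) / span
                n += 1
        out[j] = total / n
    return out


_B62_MIN_SET = set(AA_ALPHABET)


def rsa(acc: float, aa: str, max_acc: dict[str, float] | None = None) -> float:
    """Relative solvent accessibility: accessibility / residue maximum.

    Not clamped; values above 1 are allowed (and flagged with a warning)
    because empirical maxima can be exceeded in unusual conformations.
    """
    if acc < 0:
        raise ValueError("accessibility must be non-negative")
    table = MAX_ACC_EMPIRICAL if max_acc is None else max_acc
    if aa not in table:
        raise KeyError(f"no maximum accessibility for residue {aa!r}")
    value = acc / table[aa]
    if value > 1:
        warnings.warn(f"RSA {value:.3f} > 1 for residue {aa}")
    return value


def min_distance(atoms_a: np.ndarray, atoms_b: np.ndarray) -> float:
    """Minimum Euclidean distance between two non-empty 3D coordinate sets."""
    a = np.atleast_2d(np.asarray(atoms_a, dtype=float))
    b = np.atleast_2d(np.asarray(atoms_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("coordinate sets must be non-empty")
    return float(cdist(a, b).min())


def pdb_atom_coords(path: str, chain: str | None = None,
                    residues: Iterable[int] | None = None) -> np.ndarray:
    """Atom coordinates (N x 3, Angstrom) from a PDB file.

    Optionally restricted to one chain and/or a set of residue numbers.
    Only coordinates are consumed; no chain-topology logic.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", path)
    wanted = set(residues) if residues is not None else None
    coords = []
    for model in structure:
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for res in ch:
                if wanted is not None and res.id[1] not in wanted:
                    continue
                for atom in res:
                    coords.append(atom.coord)
        break  # first model only
    return np.asarray(coords, dtype=float)


@dataclass(frozen=True)
class DomainRecord:
    """One annotated domain in one protein: position is env_from, 1-based."""

    protein_id: str
    species: str
    protein_length: int
    domain_start: int
    domain_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.domain_start <= self.domain_end <= self.protein_length):
            raise ValueError(
                f"invalid domain bounds {self.domain_start}-{self.domain_end} "
                f"for length {self.protein_length}"
            )

    @property
    def rel_position(self) -> float:
        return self.domain_start / self.protein_length


def domain_position_conservation(
    ref: DomainRecord,
    orthologs: Sequence[DomainRecord],
    window: float = 0.10,
) -> tuple[list[bool], float]:
    """Positional conservation of orthologous domains.

    An ortholog's domain is conserved when its relative start position
    (domain start / protein length) lies within `window` of the reference's.
    Returns the per-ortholog flags and the conserved fraction.
    """
    flags = [abs(o.rel_position - ref.rel_position) <= window for o in orthologs]
    frac = sum(flags) / len(flags) if flags else float("nan")
    return flags, frac


def mean_ortholog_similarity(ref_row: str, ortholog_rows: Sequence[str]) -> float:
    """Mean pairwise identity between a reference aligned row and its orthologs."""
    if not ortholog_rows:
        raise ValueError("no ortholog rows")
    return float(np.mean([pairwise_identity(ref_row, o) for o in ortholog_rows]))


def normalized_ellipticity(theta: np.ndarray) -> np.ndarray:
    """Min-max normalized ellipticity fraction: (theta - min)/(max - min)."""
    t = np.asarray(theta, dtype=float)
    lo, hi = t.min(), t.max()
    if hi <= lo:
        raise ValueError("constant ellipticity series cannot be normalized")
    return (t - lo) / (hi - lo)
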