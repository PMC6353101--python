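"""Sequence and oligonucleotide primitives for COI barcode work.

Everything downstream (homology panels, specificity scoring, in-silico PCR)
is built on four primitives defined here: an IUPAC-alphabet sequence type,
oligos with a binding role, degenerate base matching, and pairwise percent
identity computed from a semi-global alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
#: The gap character is in the alphabet but expands to the empty set: a gap
#: never matches anything, including another gap.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset(),
}

ALPHABET = frozenset(IUPAC_SETS)

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}


class SequenceError(ValueError):
    """Raised for malformed sequences or FASTA input."""


@dataclass(frozen=True)
class IUPACSequence:
    """A nucleotide sequence over the IUPAC alphabet.

    Input is normalized at construction: case folded to upper, RNA ``U``
    mapped to ``T``. Characters outside the IUPAC alphabet (plus ``-``)
    are rejected.
    """

    id: str
    bases: str
    description: str = ""

    def __post_init__(self) -> None:
        norm = self.bases.upper().replace("U", "T")
        if not norm:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(norm) - ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        object.__setattr__(self, "bases", norm)

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    @property
    def is_gap_free(self) -> bool:
        return "-" not in self.bases

    def reverse_complement(self) -> "IUPACSequence":
        return reverse_complement(self)


@dataclass(frozen=True)
class Oligo:
    """A synthesized oligo (primer or hydrolysis probe), 5'→3'.

    Lengths far outside typical qPCR design bounds (15–35 nt) trigger a
    warning, not an error: the design software's own probe bounds were
    18–27 nt, but imported candidate lists occasionally stray.
    """

    name: str
    role: str  # forward | reverse | probe
    bases: IUPACSequence

    ROLES = ("forward", "reverse", "probe")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ValueError(f"oligo role must be one of {self.ROLES}, got {self.role!r}")
        if not self.bases.is_gap_free:
            raise SequenceError(f"oligo {self.name!r} contains gap characters")
        if not 15 <= len(self.bases) <= 35:
            warnings.warn(
                f"oligo {self.name!r} length {len(self.bases)} outside 15-35 nt",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.bases)


DYES = ("FAM", "VIC", "ABY", "JUN")


@dataclass(frozen=True)
class AssayDefinition:
    """One species' qPCR assay: primer pair + hydrolysis probe + run conditions."""

    species: str
    forward: Oligo
    reverse: Oligo
    probe: Oligo
    dye: str
    forward_conc_nM: float
    reverse_conc_nM: float
    probe_conc_nM: float
    annealing_temp_C: float
    expected_amplicon_bp: int

    def __post_init__(self) -> None:
        if self.dye not in DYES:
            raise ValueError(f"dye must be one of {DYES}, got {self.dye!r}")
        for label, conc in (
            ("forward", self.forward_conc_nM),
            ("reverse", self.reverse_conc_nM),
            ("probe", self.probe_conc_nM),
        ):
            if conc <= 0:
                raise ValueError(f"{label} concentration must be > 0 nM")
        if not 70 <= self.expected_amplicon_bp <= 150:
            raise ValueError(
                f"expected amplicon size {self.expected_amplicon_bp} outside 70-150 bp"
            )

    @property
    def oligos(self) -> tuple[Oligo, Oligo, Oligo]:
        return (self.forward, self.reverse, self.probe)


@dataclass(frozen=True)
class HomologyResult:
    """Pairwise homology between two barcodes: matches / compared positions."""

    species_a: str
    species_b: str
    matches: int
    compared_positions: int
    percent_exact: float = field(repr=False, default=0.0)

    def __post_init__(self) -> None:
        if not 0 <= self.matches <= self.compared_positions:
            raise ValueError("matches must lie in [0, compared_positions]")
        object.__setattr__(
            self, "percent_exact", 100.0 * self.matches / self.compared_positions
        )

    @property
    def percent_identity(self) -> int:
        """Integer percent, half-up, capped at 99 for non-identical pairs.

        A pair with any mismatch is never reported as 100% even when the
        exact value rounds up (e.g. 649/652 = 99.54% reports as 99%).
        """
        pct = int(self.percent_exact + 0.5)
        if self.matches < self.compared_positions:
            pct = min(pct, 99)
        return pct


# ---------------------------------------------------------------------------
# base-level operations

def iupac_match(a: str, b: str) -> bool:
    """True iff the concrete-base sets of two IUPAC codes intersect.

    Gaps match nothing (including other gaps).
    """
    try:
        return bool(IUPAC_SETS[a] & IUPAC_SETS[b])
    except KeyError as exc:
        raise SequenceError(f"not an IUPAC code: {exc.args[0]!r}") from None


def complement_base(b: str) -> str:
    try:
        return _COMPLEMENT[b]
    except KeyError:
        raise SequenceError(f"not an IUPAC code: {b!r}") from None


def reverse_complement(seq: IUPACSequence) -> IUPACSequence:
    """Watson-Crick reverse complement with IUPAC degeneracy mapped."""
    rc = "".join(_COMPLEMENT[b] for b in reversed(seq.bases))
    return IUPACSequence(id=seq.id, bases=rc, description=seq.description)


def hamming_mismatches(a: str, b: str) -> int:
    """Number of positions (equal-length strings) failing iupac_match."""
    if len(a) != len(b):
        raise SequenceError("hamming comparison requires equal lengths")
    return sum(not iupac_match(x, y) for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# vectorized ungapped offset scanning

_CODES = sorted(ALPHABET)
_CODE_INDEX = {c: i for i, c in enumerate(_CODES)}
_MATCH_MATRIX = np.array(
    [[iupac_match(x, y) for y in _CODES] for x in _CODES], dtype=bool
)


def encode_bases(bases: str) -> np.ndarray:
    """Map an IUPAC string to integer codes for array-based comparison."""
    try:
        return np.fromiter((_CODE_INDEX[b] for b in bases), dtype=np.int8, count=len(bases))
    except KeyError as exc:
        raise SequenceError(f"not an IUPAC code: {exc.args[0]!r}") from None


def offset_mismatch_counts(query: str, template: str) -> np.ndarray:
    """Mismatch count of ``query`` at every ungapped offset of ``template``.

    Returns an array of length ``len(template) - len(query) + 1`` where
    entry ``i`` is the number of positions failing :func:`iupac_match`
    when the query is laid on the template at offset ``i``.
    """
    L = len(query)
    if len(template) < L:
        raise SequenceError("template shorter than query")
    q = encode_bases(query)
    t = encode_bases(template)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    return (~_MATCH_MATRIX[windows, q]).sum(axis=1)


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)

def read_fasta(path: str | Path) -> list[IUPACSequence]:
    """Read a multi-record FASTA file into IUPACSequence objects.

    Records keep file order. Empty records and non-IUPAC characters are
    rejected with the offending record named.
    """
    path = Path(path)
    records: list[IUPACSequence] = []
    with path.open() as handle:
        first = handle.read(1)
        if first and first != ">":
            raise SequenceError(f"{path}: line 1: expected FASTA header starting with '>'")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            try:
                records.append(
                    IUPACSequence(id=rec.id, bases=str(rec.seq), description=rec.description)
                )
            except SequenceError as exc:
                raise SequenceError(f"{path}: record {rec.id!r}: {exc}") from None
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[IUPACSequence], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (60 columns by default)."""
    recs = [
        SeqRecord(Seq(s.bases), id=s.id, description=s.description or "")
        for s in seqs
    ]
    with Path(path).open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# pairwise identity

def _iupac_substitution_matrix(match: float, mismatch: float):
    letters = "".join(sorted(ALPHABET))
    mat = substitution_matrices.Array(letters, dims=2)
    for x in letters:
        for y in letters:
            mat[x, y] = match if iupac_match(x, y) else mismatch
    return mat


_ALIGNER_CACHE: dict[tuple[float, float, float], PairwiseAligner] = {}


def _aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> PairwiseAligner:
    key = (match, mismatch, gap)
    if key not in _ALIGNER_CACHE:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = _iupac_substitution_matrix(match, mismatch)
        aligner.open_gap_score = gap
        aligner.extend_gap_score = gap
        # free end gaps: semi-global, so length differences and terminal
        # overhangs are not penalized
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
        _ALIGNER_CACHE[key] = aligner
    return _ALIGNER_CACHE[key]


def percent_identity(
    a: IUPACSequence,
    b: IUPACSequence,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> HomologyResult:
    """Percent identity from a semi-global pairwise alignment.

    The two sequences are aligned globally with free terminal gaps
    (match +1 / mismatch −1 / gap −2 by default). ``matches`` counts aligned
    columns where the IUPAC base sets intersect; ``compared_positions``
    counts all aligned columns except terminal-overhang gap columns.
    Internal gap columns count as differences.
    """
    aligner = _aligner(match, mismatch, gap)
    alignment = aligner.align(a.bases, b.bases)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])

    n = len(row_a)
    start, end = 0, n
    # trim terminal overhangs: leading/trailing runs where either row is gapped
    while start < n and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1

    matches = 0
    compared = 0
    for x, y in zip(row_a[start:end], row_b[start:end]):
        compared += 1
        if iupac_match(x, y):
            matches += 1
    return HomologyResult(
        species_a=a.id, species_b=b.id, matches=matches, compared_positions=compared
    )
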