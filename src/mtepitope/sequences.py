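"""Protein sequence handling, region arithmetic, alignment and consensus.

Everything downstream of this module speaks in 1-based, closed residue
intervals (:class:`SequenceRegion`), the convention used throughout the
tubulin epitope-mapping literature (an epitope "β81-95" includes both
residue 81 and residue 95).
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

#: The 20 standard amino acids plus 'X' for unknown residues.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (names the offending record)."""


class RegionError(ValueError):
    """Raised when a region falls outside its parent sequence."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with 1-based residue numbering.

    Parameters
    ----------
    id : str
        Accession or free label.
    residues : str
        Uppercase residues over the 20-letter alphabet plus ``X``.
    description : str
        Free-text description (FASTA header remainder).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FastaFormatError(f"sequence {self.id!r}: empty sequence")
        bad = set(self.residues) - ALLOWED_RESIDUES
        if bad:
            raise FastaFormatError(
                f"sequence {self.id!r}: illegal residue character(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Return the residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise RegionError(
                f"position {position} outside sequence {self.id!r} "
                f"(length {len(self.residues)})"
            )
        return self.residues[position - 1]


@dataclass(frozen=True, order=True)
class SequenceRegion:
    """A closed 1-based interval ``[start, end]`` on a protein sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise RegionError(f"invalid region [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "SequenceRegion") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "SequenceRegion") -> bool:
        return self.start <= other.end and other.start <= self.end

    def intersect(self, other: "SequenceRegion") -> "SequenceRegion | None":
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return SequenceRegion(lo, hi) if lo <= hi else None

    def subtract(self, other: "SequenceRegion") -> "list[SequenceRegion]":
        """Set difference ``self \\ other`` as 0, 1 or 2 regions."""
        out: list[SequenceRegion] = []
        if other.start > self.start:
            out.append(SequenceRegion(self.start, min(self.end, other.start - 1)))
        if other.end < self.end:
            out.append(SequenceRegion(max(self.start, other.end + 1), self.end))
        if not other.overlaps(self):
            return [self]
        return out

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.start}-{self.end}"


@dataclass
class MultipleAlignment:
    """Rows of (sequence id, aligned string with ``-`` gaps)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("aligned rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def ungapped(self, index: int) -> str:
        return self.rows[index][1].replace("-", "")


@dataclass
class ConsensusResult:
    """Majority-rule consensus with per-column agreement fractions."""

    consensus: str
    agreement: list[float]
    low_confidence: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.consensus) != len(self.agreement):
            raise ValueError("consensus/agreement length mismatch")


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: "str | os.PathLike | io.TextIOBase") -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records.

    Sequences are uppercased; empty files, duplicate ids and illegal residue
    characters raise :class:`FastaFormatError` naming the offending record.
    """
    if isinstance(path, io.TextIOBase):
        handle = path
        close = False
    else:
        handle = open(path)
        close = True
    try:
        records: list[ProteinSequence] = []
        seen: set[str] = set()
        header: str | None = None
        chunks: list[str] = []

        def flush() -> None:
            if header is None:
                return
            ident, _, desc = header.partition(" ")
            if ident in seen:
                raise FastaFormatError(f"duplicate sequence id {ident!r}")
            seen.add(ident)
            records.append(
                ProteinSequence(id=ident, residues="".join(chunks).upper(),
                                description=desc.strip())
            )

        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
                if not header:
                    raise FastaFormatError("record with empty header")
            else:
                if header is None:
                    raise FastaFormatError("sequence data before first '>' header")
                chunks.append(line)
        flush()
    finally:
        if close:
            handle.close()
    if not records:
        raise FastaFormatError("empty FASTA file")
    return records


def write_fasta(
    sequences: Iterable[ProteinSequence],
    path: "str | os.PathLike | io.TextIOBase",
    width: int = 60,
) -> None:
    """Write sequences as FASTA with lines wrapped at ``width`` columns."""
    if isinstance(path, io.TextIOBase):
        handle = path
        close = False
    else:
        handle = open(path, "w")
        close = True
    try:
        for seq in sequences:
            header = seq.id if not seq.description else f"{seq.id} {seq.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(seq.residues), width):
                handle.write(seq.residues[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Region arithmetic and motif scanning


def extract_region(seq: ProteinSequence, region: SequenceRegion) -> str:
    """Residues ``region.start .. region.end`` inclusive (1-based)."""
    if region.end > len(seq):
        raise RegionError(
            f"region {region} outside sequence {seq.id!r} (length {len(seq)})"
        )
    return seq.residues[region.start - 1 : region.end]


def find_motif(seq: ProteinSequence, motif: str) -> list[int]:
    """1-based start positions of every (possibly overlapping) occurrence.

    Used to locate acid-labile Asp-Pro bonds: a ``DP`` hit at position p
    means the peptide bond between residues p and p+1 is formic-acid labile.
    """
    if len(motif) < 1:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    positions = []
    start = 0
    while True:
        idx = seq.residues.find(motif, start)
        if idx == -1:
            break
        positions.append(idx + 1)
        start = idx + 1
    return positions


# ---------------------------------------------------------------------------
# Pairwise global alignment


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix name and affine gap penalties.

    The defaults (BLOSUM62, gap open 10, gap extend 0.5 — a gap of length k
    costs ``10 + 0.5*(k-1)``) follow the common needle-style convention so
    that reported identities are reproducible.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def global_align(
    a: ProteinSequence,
    b: ProteinSequence,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> MultipleAlignment:
    """Optimal global alignment of two sequences as a 2-row alignment.

    Deterministic: among co-optimal alignments the aligner's first
    traceback (high-road, diagonal-preferring) is returned.
    """
    aligner = _make_aligner(scoring)
    alignment = aligner.align(a.residues, b.residues)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    return MultipleAlignment(rows=[(a.id, row_a), (b.id, row_b)])


def alignment_score(
    a: ProteinSequence,
    b: ProteinSequence,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> float:
    """Optimal global alignment score under ``scoring``."""
    return float(_make_aligner(scoring).score(a.residues, b.residues))


def _terminal_gap_columns(row: str) -> set[int]:
    cols: set[int] = set()
    for i, c in enumerate(row):
        if c != "-":
            break
        cols.add(i)
    for i in range(len(row) - 1, -1, -1):
        if row[i] != "-":
            break
        cols.add(i)
    return cols


def percent_identity(alignment: MultipleAlignment) -> float:
    """Percent identity of a 2-row alignment.

    Denominator: alignment columns excluding terminal-gap columns of either
    row. Internal gaps count as mismatches; ``X`` never matches anything.
    """
    if len(alignment.rows) != 2:
        raise ValueError("percent_identity requires a 2-row alignment")
    ra, rb = alignment.rows[0][1], alignment.rows[1][1]
    skip = _terminal_gap_columns(ra) | _terminal_gap_columns(rb)
    total = ident = 0
    for i, (x, y) in enumerate(zip(ra, rb)):
        if i in skip:
            continue
        total += 1
        if x == y and x != "-" and x != "X":
            ident += 1
    if total == 0:
        raise ValueError("alignment has no non-terminal-gap columns")
    return 100.0 * ident / total


# ---------------------------------------------------------------------------
# Consensus


def consensus(
    alignment: MultipleAlignment, low_confidence_below: float = 0.5
) -> ConsensusResult:
    """Per-column majority-rule consensus.

    Gaps are excluded from counting and ``X`` residues from voting; ties are
    broken toward the alphabetically lowest residue. All-gap (or all-``X``)
    columns yield ``-`` with agreement 0. Columns whose agreement falls
    below ``low_confidence_below`` are flagged.
    """
    if len(alignment.rows) < 2:
        raise ValueError("consensus requires at least 2 rows")
    cons_chars: list[str] = []
    agreement: list[float] = []
    flagged: list[int] = []
    for col in range(alignment.n_columns):
        symbols = [row[col] for _, row in alignment.rows]
        non_gap = [s for s in symbols if s != "-"]
        votable = [s for s in non_gap if s != "X"]
        if not votable:
            cons_chars.append("-")
            agreement.append(0.0)
            continue
        counts: dict[str, int] = {}
        for s in votable:
            counts[s] = counts.get(s, 0) + 1
        best = min(sorted(counts), key=lambda s: (-counts[s], s))
        frac = counts[best] / len(non_gap)
        cons_chars.append(best)
        agreement.append(frac)
        if frac < low_confidence_below:
            flagged.append(col + 1)
    return ConsensusResult("".join(cons_chars), agreement, flagged)


def consensus_table(result: ConsensusResult) -> str:
    """Tab-separated consensus report: position, symbol, agreement."""
    lines = ["position\tsymbol\tagreement"]
    for i, (sym, agr) in enumerate(zip(result.consensus, result.agreement), 1):
        lines.append(f"{i}\t{sym}\t{agr:.4f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Bundled reference stand-ins


def load_bundled(name: str) -> ProteinSequence:
    """Load one of the bundled synthetic reference sequences.

    ``"btub_pig"`` — stand-in for porcine brain β-tubulin (445 aa, Asp-Pro
    bonds at 31-32 and 304-305); ``"tbb1_arath"`` — stand-in for
    A. thaliana β-tubulin 1 (TBB1). Both are synthetic constructions with
    the documented properties of the corresponding database entries, not
    the database sequences themselves.
    """
    from importlib.resources import files

    fname = {"btub_pig": "btub_pig_synthetic.fasta",
             "tbb1_arath": "tbb1_arath_synthetic.fasta"}[name]
    data = files("mtepitope.data").joinpath(fname).read_text()
    return read_fasta(io.StringIO(data))[0]
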