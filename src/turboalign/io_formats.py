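"""Readers and writers for the text formats the tool touches.

FASTA in; CT, dot-bracket, aligned FASTA and Stockholm 1.0 out; plain-text
probability-matrix dumps.  All public formats use 1-based inclusive
coordinates (the CT convention); in-memory arrays are 0-based.

The domain types that every other module shares live here: `RnaSequence`,
`SequenceSet`, `SecondaryStructure` and `MultipleAlignment`.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import AlignIO, SeqIO

#: canonical residue alphabet, in the index order used by all numeric tables
BASE_ORDER = "ACGU"
VALID_BASES = frozenset(BASE_ORDER)
GAP = "-"

_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


def normalize_residues(raw: str) -> str:
    """Uppercase, map T->U, and reject anything outside {A,C,G,U}.

    Ambiguity codes are rejected rather than randomized so that the whole
    pipeline stays deterministic.
    """
    s = raw.upper().replace("T", "U")
    bad = sorted(set(s) - VALID_BASES)
    if bad:
        raise ValueError(
            f"unsupported residue(s) {','.join(bad)}: only A/C/G/U(T) are "
            "accepted (IUPAC ambiguity codes are not supported)"
        )
    return s


def encode(residues: str) -> np.ndarray:
    """Residue string -> int8 array over the BASE_ORDER indexing."""
    return np.fromiter((_BASE_INDEX[b] for b in residues), dtype=np.int8,
                       count=len(residues))


@dataclass(frozen=True)
class RnaSequence:
    """A single RNA sequence, post-normalization (A/C/G/U only)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise ValueError(f"non-normalized residues in {self.id!r}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        return encode(self.residues)


@dataclass(frozen=True)
class SequenceSet:
    """An ordered set of input sequences with unique ids."""

    sequences: tuple[RnaSequence, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) < 1:
            raise ValueError("a SequenceSet needs at least one sequence")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")

    @property
    def H(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[RnaSequence]:
        return iter(self.sequences)

    def __getitem__(self, i: int) -> RnaSequence:
        return self.sequences[i]


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs (i, j), 1-based, i < j, at most one partner per index."""

    length: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i},{j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"index in more than one pair near ({i},{j})")
            seen.add(i)
            seen.add(j)

    def partner_map(self) -> dict[int, int]:
        pm: dict[int, int] = {}
        for i, j in self.pairs:
            pm[i] = j
            pm[j] = i
        return pm

    def is_noncrossing(self) -> bool:
        ps = sorted(self.pairs)
        for a in range(len(ps)):
            i, j = ps[a]
            for k, l in ps[a + 1:]:
                if i < k < j < l:
                    return False
        return True

    def validate_min_hairpin(self, min_hairpin: int) -> None:
        for i, j in self.pairs:
            if j - i < min_hairpin + 1:
                raise ValueError(
                    f"pair ({i},{j}) closes a hairpin shorter than {min_hairpin}"
                )


@dataclass(frozen=True)
class MultipleAlignment:
    """Gapped rows over {A,C,G,U,-}; all rows the same length."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        ncol = len(self.rows[0][1])
        for sid, gapped in self.rows:
            if len(gapped) != ncol:
                raise ValueError(f"ragged alignment row {sid!r}")
            bad = set(gapped) - VALID_BASES - {GAP}
            if bad:
                raise ValueError(f"invalid characters in row {sid!r}: {sorted(bad)}")

    @property
    def columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.rows)

    def row(self, sid: str) -> str:
        for rid, gapped in self.rows:
            if rid == sid:
                return gapped
        raise KeyError(sid)

    def degapped(self, sid: str) -> str:
        return self.row(sid).replace(GAP, "")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> SequenceSet:
    """Read a multi-record nucleotide FASTA; T/t are mapped to U, case raised.

    Rejects empty files, duplicate ids and ambiguity codes.  Record order is
    preserved everywhere downstream.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seqs = []
    for rec in records:
        seqs.append(RnaSequence(rec.id, normalize_residues(str(rec.seq))))
    return SequenceSet(tuple(seqs))


# ---------------------------------------------------------------------------
# CT and dot-bracket structures

def read_ct(path: str | Path) -> tuple[RnaSequence, SecondaryStructure]:
    """Read a standard 6-column CT file (one structure).

    Columns: index, base, index-1, index+1, pairing partner (0 = unpaired),
    natural index.  Pair pointers must be reciprocal and indices contiguous.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty CT file {path}")
    head = lines[0].split()
    n = int(head[0])
    title = " ".join(head[1:]) if len(head) > 1 else Path(str(path)).stem
    if len(lines) - 1 != n:
        raise ValueError(f"CT header says {n} rows, found {len(lines) - 1}")
    partner = [0] * (n + 1)
    bases = []
    for row, ln in enumerate(lines[1:], start=1):
        f = ln.split()
        if len(f) < 6:
            raise ValueError(f"CT row {row}: expected 6 columns")
        idx = int(f[0])
        if idx != row:
            raise ValueError(f"CT row {row}: index gap (found {idx})")
        bases.append(f[1])
        partner[row] = int(f[4])
    for i in range(1, n + 1):
        j = partner[i]
        if j != 0 and (not (1 <= j <= n) or partner[j] != i):
            raise ValueError(f"non-reciprocal pair columns at row {i} (partner {j})")
    pairs = frozenset((i, partner[i]) for i in range(1, n + 1)
                      if partner[i] > i)
    seq = RnaSequence(title or "ct", normalize_residues("".join(bases)))
    return seq, SecondaryStructure(n, pairs)


def _dotbracket(seq: RnaSequence, s: SecondaryStructure) -> str:
    if not s.is_noncrossing():
        raise ValueError("crossing pairs cannot be written as dot-bracket")
    chars = ["."] * s.length
    for i, j in s.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return f">{seq.id}\n{seq.residues}\n{''.join(chars)}\n"


def _ct(seq: RnaSequence, s: SecondaryStructure) -> str:
    pm = s.partner_map()
    out = [f"{s.length} {seq.id}"]
    for i in range(1, s.length + 1):
        out.append(
            f"{i} {seq.residues[i - 1]} {i - 1} {(i + 1) % (s.length + 1)} "
            f"{pm.get(i, 0)} {i}"
        )
    return "\n".join(out) + "\n"


def write_structure(seq: RnaSequence, s: SecondaryStructure, fmt: str) -> str:
    """Render a structure as `ct` or `dot-bracket` text."""
    if s.length != seq.length:
        raise ValueError("structure length does not match sequence length")
    if fmt == "ct":
        return _ct(seq, s)
    if fmt in ("dot-bracket", "db"):
        return _dotbracket(seq, s)
    raise ValueError(f"unknown structure format {fmt!r}")


# ---------------------------------------------------------------------------
# Alignments

def write_alignment(msa: MultipleAlignment, fmt: str) -> str:
    """Render an alignment as `aligned-fasta` or `stockholm` text."""
    if fmt in ("aligned-fasta", "afa", "fasta"):
        return "".join(f">{sid}\n{gapped}\n" for sid, gapped in msa.rows)
    if fmt in ("stockholm", "sto"):
        width = max(len(sid) for sid, _ in msa.rows) + 2
        body = "".join(f"{sid:<{width}}{gapped}\n" for sid, gapped in msa.rows)
        return f"# STOCKHOLM 1.0\n\n{body}//\n"
    raise ValueError(f"unknown alignment format {fmt!r}")


def read_alignment(text: str, fmt: str) -> MultipleAlignment:
    """Parse aligned-fasta or Stockholm text back into a MultipleAlignment."""
    biofmt = {"aligned-fasta": "fasta", "afa": "fasta", "fasta": "fasta",
              "stockholm": "stockholm", "sto": "stockholm"}[fmt]
    aln = AlignIO.read(StringIO(text), biofmt)
    rows = tuple(
        (rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in aln
    )
    return MultipleAlignment(rows)


# ---------------------------------------------------------------------------
# Probability-matrix dumps: "i j value" triplets, 1-based, small values omitted

DUMP_THRESHOLD = 1e-6


def dump_matrix(mat: np.ndarray, threshold: float = DUMP_THRESHOLD) -> str:
    out = []
    for i, j in zip(*np.nonzero(mat >= threshold)):
        out.append(f"{i + 1} {j + 1} {mat[i, j]:.10g}")
    return "\n".join(out) + ("\n" if out else "")


def load_matrix(text: str, shape: tuple[int, int]) -> np.ndarray:
    mat = np.zeros(shape)
    for ln in text.splitlines():
        if not ln.strip():
            continue
        i, j, v = ln.split()
        mat[int(i) - 1, int(j) - 1] = float(v)
    return mat
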