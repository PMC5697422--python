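"""File I/O: sequences (FASTA / plain text / literals), constraint files,
CT output, and deterministic fixture sequences for testing."""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, List, Optional, TextIO, Union

from Bio import SeqIO

from .core import InvalidSequenceError, RnaSequence, SecondaryStructure

PRINTED_14MER = "GCUCUAAAAGAGAG"


def read_sequences(source: Union[str, Path]) -> List[RnaSequence]:
    """Read sequences from FASTA, one-per-line text, or a literal string.

    If *source* names an existing file it is parsed as FASTA when it starts
    with '>' and as plain one-sequence-per-line text otherwise; any other
    string is treated as a literal sequence.  T is accepted and mapped to U,
    lowercase is uppercased; any other symbol is an error naming the
    offending record.
    """
    path = Path(source)
    if not path.exists():
        text = str(source).strip()
        if not text:
            raise InvalidSequenceError("empty sequence source")
        return [RnaSequence("seq", text)]
    raw = path.read_text()
    if not raw.strip():
        raise InvalidSequenceError(f"{path}: empty file")
    out: List[RnaSequence] = []
    if raw.lstrip().startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            try:
                out.append(RnaSequence(rec.id or "seq", str(rec.seq)))
            except InvalidSequenceError as e:
                raise InvalidSequenceError(f"record {rec.id!r}: {e}") from e
    else:
        for k, line in enumerate(raw.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                out.append(RnaSequence(f"line{k}", line))
            except InvalidSequenceError as e:
                raise InvalidSequenceError(f"{path} line {k}: {e}") from e
    if not out:
        raise InvalidSequenceError(f"{path}: no sequences found")
    return out


@dataclass(frozen=True)
class ConstraintSpec:
    """Forced-unpaired positions (0-based internally) plus structure filters."""

    forced_unpaired: FrozenSet[int] = frozenset()
    min_helix_count: int = 0
    min_helix_len_filter: int = 1


def read_constraints(path: Union[str, Path], n: int) -> ConstraintSpec:
    """Parse a constraint file against a sequence of length *n*.

    Accepted lines: ``unpaired <pos>`` with a 1-based position; a mask
    string of length *n* with 'x' forced unpaired and '.' free;
    ``min_helix_count <k>``; ``min_helix_len <k>``.  Blank lines and
    ``#`` comments are ignored.
    """
    forced: set = set()
    min_count = 0
    min_len = 1
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        key = fields[0].lower()
        if key == "unpaired" and len(fields) == 2:
            pos = int(fields[1])
            if not (1 <= pos <= n):
                raise ValueError(
                    f"{path} line {lineno}: position {pos} outside 1..{n}"
                )
            forced.add(pos - 1)
        elif key == "min_helix_count" and len(fields) == 2:
            min_count = int(fields[1])
        elif key == "min_helix_len" and len(fields) == 2:
            min_len = int(fields[1])
        elif set(line) <= {".", "x", "X"}:
            if len(line) != n:
                raise ValueError(
                    f"{path} line {lineno}: mask length {len(line)} != n={n}"
                )
            forced.update(i for i, ch in enumerate(line) if ch in "xX")
        else:
            raise ValueError(f"{path} line {lineno}: cannot parse {line!r}")
    return ConstraintSpec(
        forced_unpaired=frozenset(forced),
        min_helix_count=min_count,
        min_helix_len_filter=min_len,
    )


def write_ct(seq: RnaSequence, s: SecondaryStructure, out: TextIO) -> None:
    """Write one structure in standard 6-column connectivity-table format."""
    n = seq.n
    partner = s.partner_array(n)
    out.write(f"{n} {seq.id}\n")
    for i in range(n):
        prev_i = i  # 0 for the first residue in 1-based terms
        next_i = i + 2 if i + 1 < n else 0
        pair = partner[i] + 1 if partner[i] >= 0 else 0
        out.write(f"{i + 1} {seq.residues[i]} {prev_i} {next_i} {pair} {i + 1}\n")


def make_fixture(
    kind: str,
    n: Optional[int] = None,
    k: Optional[int] = None,
    seed: Optional[int] = None,
) -> RnaSequence:
    """Deterministic test sequences.

    ``printed14mer`` is the designed 14-nt oligonucleotide
    GCUCUAAAAGAGAG; ``concatamer`` tandem-repeats it ``k`` times (the 28mer
    and 42mer benchmarks are its 2x and 3x concatamers); ``random`` draws
    ``n`` residues uniformly from A/C/G/U with the given seed.
    """
    if kind == "printed14mer":
        return RnaSequence("14mer", PRINTED_14MER)
    if kind == "concatamer":
        if not k or k < 1:
            raise ValueError("concatamer requires k >= 1")
        return RnaSequence(f"{14 * k}mer", PRINTED_14MER * k)
    if kind == "random":
        if n is None or n < 1:
            raise ValueError("random fixture requires n >= 1")
        if seed is None:
            raise ValueError("random fixture requires a seed")
        rng = random.Random(seed)
        residues = "".join(rng.choice("ACGU") for _ in range(n))
        return RnaSequence(f"random-n{n}-s{seed}", residues)
    raise ValueError(f"unknown fixture kind {kind!r}")
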