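"""Sequence input/output and mutation counting for antibody libraries.

Sequences are represented as :class:`Chain` objects carrying an identifier,
a role (heavy / light / single) and an upper-case amino-acid sequence over
the 20 standard one-letter codes.  Mutation counting between library
variants is strictly positional: variants produced by targeted mutagenesis
of a common parent share a residue numbering, so no alignment is performed
and a length mismatch is a hard error.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO as _BioSeqIO

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

#: Gap characters silently stripped on read.
GAP_CHARS = "-."


class ChainRole(str, enum.Enum):
    HEAVY = "heavy"
    LIGHT = "light"
    SINGLE = "single"


class SequenceAlphabetError(ValueError):
    """A residue outside the 20-letter standard alphabet was encountered."""

    def __init__(self, seq_id: str, position: int, char: str):
        self.seq_id = seq_id
        self.position = position  # 1-based
        self.char = char
        super().__init__(
            f"sequence {seq_id!r}: non-standard residue {char!r} at position {position}"
        )


@dataclass(frozen=True)
class Chain:
    """One amino-acid chain of an antibody (or a stand-alone protein).

    Parameters
    ----------
    id : str
        Identifier, unique within a library.
    sequence : str
        Upper-case sequence over the 20 standard codes.
    role : ChainRole
        Heavy, light, or single-domain.
    """

    id: str
    sequence: str
    role: ChainRole = ChainRole.SINGLE

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"chain {self.id!r}: empty sequence")
        for i, c in enumerate(self.sequence):
            if c not in _STANDARD_SET:
                raise SequenceAlphabetError(self.id, i + 1, c)

    def __len__(self) -> int:
        return len(self.sequence)


def canonicalize(
    raw: str, seq_id: str = "<anonymous>", x_to: str | None = None
) -> str:
    """Upper-case a raw sequence string, stripping whitespace and gaps.

    Raises :class:`SequenceAlphabetError` (with 1-based position in the
    cleaned sequence) on any residue outside the standard alphabet.
    `x_to` optionally maps the unknown-residue code 'X' to a chosen
    standard code instead of rejecting it (an approximation — other
    ambiguity codes B, J, O, U, Z are always rejected).
    """
    cleaned = "".join(
        c for c in raw.upper() if not c.isspace() and c not in GAP_CHARS
    )
    if x_to is not None:
        if x_to not in _STANDARD_SET:
            raise ValueError(f"x_to must be a standard code, got {x_to!r}")
        cleaned = cleaned.replace("X", x_to)
    if not cleaned:
        raise ValueError(f"sequence {seq_id!r}: empty after canonicalization")
    for i, c in enumerate(cleaned):
        if c not in _STANDARD_SET:
            raise SequenceAlphabetError(seq_id, i + 1, c)
    return cleaned


def read_sequences(
    path: str | Path,
    format: str = "fasta",
    role: ChainRole = ChainRole.SINGLE,
    x_to: str | None = None,
) -> list[Chain]:
    """Read sequences from a FASTA or plain one-sequence-per-line file.

    The first whitespace-delimited header token becomes the chain id for
    FASTA input; plain input is numbered ``seq1, seq2, ...``.  File order is
    preserved.
    """
    path = Path(path)
    chains: list[Chain] = []
    if format == "fasta":
        for record in _BioSeqIO.parse(str(path), "fasta"):
            seq = canonicalize(str(record.seq), record.id, x_to=x_to)
            chains.append(Chain(id=record.id, sequence=seq, role=role))
    elif format == "plain":
        with open(path) as fh:
            for n, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                seq_id = f"seq{n}"
                chains.append(
                    Chain(id=seq_id, sequence=canonicalize(line, seq_id, x_to=x_to), role=role)
                )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'fasta' or 'plain')")
    if not chains:
        raise ValueError(f"{path}: no sequences found")
    return chains


def write_sequences(chains: Iterable[Chain], path: str | Path, width: int = 60) -> None:
    """Write chains to FASTA, wrapping sequence lines at `width` columns."""
    with open(path, "w") as fh:
        for c in chains:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


def count_mutations(a: Chain | str, b: Chain | str) -> int:
    """Number of positions at which two equal-length sequences differ.

    This is the Hamming distance; symmetric, zero iff identical.  A length
    mismatch raises rather than silently aligning — callers with variants of
    unequal length must pre-align.
    """
    sa = a.sequence if isinstance(a, Chain) else a
    sb = b.sequence if isinstance(b, Chain) else b
    if len(sa) != len(sb):
        raise ValueError(
            f"length mismatch ({len(sa)} vs {len(sb)}): sequences must be "
            "pre-aligned for positional mutation counting"
        )
    return sum(x != y for x, y in zip(sa, sb))


@dataclass
class MutationTable:
    """Pairwise mutation counts across a library of paired-chain variants.

    ``counts`` maps an unordered id pair (stored sorted) to per-role counts.
    """

    pairs: dict = field(default_factory=dict)  # (id_a, id_b) -> {"heavy", "light", "total"}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, heavy: int, light: int) -> None:
        if heavy < 0 or light < 0:
            raise ValueError("mutation counts must be nonnegative")
        self.pairs[self._key(a, b)] = {
            "heavy": heavy,
            "light": light,
            "total": heavy + light,
        }

    def total(self, a: str, b: str) -> int:
        if a == b:
            return 0
        return self.pairs[self._key(a, b)]["total"]

    def totals(self) -> list[int]:
        """All pairwise totals, in sorted-key order."""
        return [self.pairs[k]["total"] for k in sorted(self.pairs)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id_a": k[0], "id_b": k[1], **v} for k, v in sorted(self.pairs.items())
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "heavy", "light", "total"])


def mutation_table(
    variants: Sequence[tuple[Chain, Chain]] | Sequence[Chain],
) -> MutationTable:
    """Compute all pairwise mutation counts for a library.

    `variants` is either a list of (heavy, light) chain pairs or a list of
    single chains (the light count is then 0).
    """
    table = MutationTable()
    items = list(variants)
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            vi, vj = items[i], items[j]
            if isinstance(vi, Chain):
                h = count_mutations(vi, vj)
                l = 0
                ida, idb = vi.id, vj.id
            else:
                h = count_mutations(vi[0], vj[0])
                l = count_mutations(vi[1], vj[1])
                ida = vi[0].id.rsplit("_", 1)[0]
                idb = vj[0].id.rsplit("_", 1)[0]
            table.add(ida, idb, h, l)
    return table
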