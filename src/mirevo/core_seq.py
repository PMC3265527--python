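"""Sequence domain types, region conventions, and FASTA I/O.

Conventions used throughout the package:

* All sequences are RNA, 5'→3', over the alphabet ``{A, C, G, U}``.  DNA
  input is accepted and ``T`` is silently normalized to ``U``.
* Coordinates are 0-based, half-open.
* The miRNA *seed* is positions 1–8 from the 5' end (indices ``0..7``);
  the *13–16* block is indices ``12..15``; everything outside the seed is
  the *out-seed* region (so 13–16 is a reported sub-part of out-seed).
* Because the miRNA:site duplex is antiparallel, the seed's complement on
  a site of the same length ``N`` occupies the site's *last* 8 positions,
  indices ``{N-8, .., N-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

MIN_MIRNA_LEN = 17  # positions 13-16 must exist, with a non-empty tail


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad alphabet, bad FASTA)."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA thymine to uracil; validate the alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise SequenceError(
            f"illegal symbol(s) {sorted(bad)} in sequence (expected A/C/G/U or T)"
        )
    return s


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA with its region decomposition.

    Attributes
    ----------
    id : str
        Identifier (FASTA header word).
    sequence : str
        Mature sequence, 5'→3', RNA alphabet.
    """

    id: str
    sequence: str
    seed_positions: tuple = field(init=False)
    pos_13_16: tuple = field(init=False)
    out_seed_positions: tuple = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        n = len(self.sequence)
        if n < MIN_MIRNA_LEN:
            raise SequenceError(
                f"miRNA {self.id!r} is {n} nt; at least {MIN_MIRNA_LEN} nt required"
            )
        seed = tuple(range(0, 8))
        p1316 = tuple(range(12, 16))
        out = tuple(i for i in range(n) if i not in seed)
        object.__setattr__(self, "seed_positions", seed)
        object.__setattr__(self, "pos_13_16", p1316)
        object.__setattr__(self, "out_seed_positions", out)

    @property
    def n(self) -> int:
        """Length N in nucleotides."""
        return len(self.sequence)


@dataclass(frozen=True)
class UTRSequence:
    """A 3'UTR sequence carrier."""

    gene_id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if len(self.sequence) < 1:
            raise SequenceError(f"UTR {self.gene_id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA file as ``[(id, sequence), ...]``.

    Sequences are uppercased and T→U normalized; record order is preserved.
    Raises :class:`SequenceError` on illegal characters, naming the record.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = normalize_rna(str(rec.seq))
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r} in {path}: {exc}") from exc
        records.append((rec.id, seq))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(path, records) -> None:
    """Write ``[(id, sequence), ...]`` to a FASTA file."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def reverse_complement(seq: str) -> str:
    """Watson–Crick complement (A↔U, C↔G) of an RNA string, reversed."""
    s = normalize_rna(seq)
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def site_region_indices(mirna_or_n) -> tuple[frozenset, frozenset]:
    """Site-side region index sets for a miRNA of length N.

    In the antiparallel duplex, site position ``N-1-k`` binds miRNA
    position ``k``, so the seed-binding block on the site is
    ``S = {N-8, .., N-1}`` (0-based) and the out-seed block is
    ``{0, .., N-9}``.
    """
    n = mirna_or_n.n if isinstance(mirna_or_n, MiRNA) else int(mirna_or_n)
    if n < 9:
        raise SequenceError(f"length {n} < 9: the out-seed block would be empty")
    seed = frozenset(range(n - 8, n))
    out = frozenset(range(0, n - 8))
    return seed, out


def base_fractions(seq: str) -> dict[str, float]:
    """Fractions of A, C, G, U in a sequence (empty sequence → all zero)."""
    n = len(seq)
    if n == 0:
        return {b: 0.0 for b in "ACGU"}
    return {b: seq.count(b) / n for b in "ACGU"}
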