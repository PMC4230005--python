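"""Protein sequences as numerical sequences, plus FASTA input.

A protein sequence over the 20-letter alphabet is encoded positionwise by
substituting each residue with its PCA total score, producing the real
vector the dot-plot comparison operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .scoring import score_table

__all__ = ["NumericalSequence", "encode_sequence", "read_fasta", "InvalidResidueError"]

logger = logging.getLogger(__name__)


class InvalidResidueError(ValueError):
    """A residue outside the 20-letter standard alphabet.

    Carries the 1-based ``position`` and the offending ``symbol``.
    """

    def __init__(self, seq_id: str, position: int, symbol: str):
        self.seq_id = seq_id
        self.position = position
        self.symbol = symbol
        super().__init__(
            f"sequence {seq_id!r}: invalid residue {symbol!r} at position "
            f"{position} (only the 20 standard one-letter codes are scored)"
        )


@dataclass(frozen=True)
class NumericalSequence:
    """A protein sequence together with its per-position score vector."""

    id: str
    residues: str
    scores: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.residues)


def encode_sequence(
    seq_id: str,
    residues: str,
    scores: Mapping[str, float] | None = None,
    *,
    on_invalid: str = "error",
) -> NumericalSequence:
    """Encode a protein sequence as its total-score vector.

    Parameters
    ----------
    seq_id : str
        Identifier carried through to reports.
    residues : str
        Amino acids in one-letter code; whitespace is stripped and lowercase
        accepted (uppercased).
    scores : mapping, optional
        symbol -> total score; defaults to the packaged table.
    on_invalid : {"error", "drop"}
        Strict by default: a residue outside the scored alphabet raises
        :class:`InvalidResidueError`.  ``"drop"`` removes such positions with
        a logged warning — note this shifts every downstream coordinate, so
        use it only when that is acceptable.
    """
    if scores is None:
        scores = score_table()
    cleaned = "".join(residues.split()).upper()
    if not cleaned:
        raise ValueError(f"sequence {seq_id!r} is empty")
    if on_invalid not in ("error", "drop"):
        raise ValueError(f"on_invalid must be 'error' or 'drop', got {on_invalid!r}")

    kept: list[str] = []
    vals: list[float] = []
    for pos, aa in enumerate(cleaned, start=1):
        try:
            vals.append(scores[aa])
            kept.append(aa)
        except KeyError:
            if on_invalid == "error":
                raise InvalidResidueError(seq_id, pos, aa) from None
            logger.warning(
                "sequence %r: dropping unscored residue %r at position %d",
                seq_id, aa, pos,
            )
    if not kept:
        raise ValueError(f"sequence {seq_id!r} has no scorable residues")
    return NumericalSequence(id=seq_id, residues="".join(kept),
                             scores=np.array(vals, dtype=float))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, residues), ...]`` in file order.

    Wrapped lines are concatenated and whitespace stripped.  Duplicate IDs
    are accepted but disambiguated with a ``.2``, ``.3`` ... suffix (logged).
    Missing files, files with no records, and records with empty sequences
    each raise a distinct error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split())
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        rid = rec.id
        n = seen.get(rid, 0) + 1
        seen[rid] = n
        if n > 1:
            new_id = f"{rid}.{n}"
            logger.warning("duplicate FASTA id %r renamed to %r", rid, new_id)
            rid = new_id
        records.append((rid, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def encode_fasta(
    path: str | Path,
    scores: Mapping[str, float] | None = None,
    *,
    on_invalid: str = "error",
) -> list[NumericalSequence]:
    """Read a FASTA file and encode every record."""
    return [
        encode_sequence(rid, seq, scores, on_invalid=on_invalid)
        for rid, seq in read_fasta(path)
    ]
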