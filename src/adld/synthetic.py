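"""Controlled synthetic sequence pairs for testing the diagram geometry.

Random sequences are drawn uniformly over the 20-letter alphabet from an
explicitly threaded seeded generator (no global random state).  An
:class:`EditRecipe` applies an ordered list of substitutions, insertions
and deletions, which lets tests construct pairs whose ADLD geometry is
known in advance: a block insertion of length k shifts the downstream
artery run onto the by-path track at offset -k, a substitution punches a
one-position gap into an artery run, and so on.

No attempt is made at evolutionary realism — no substitution-rate
matrices, no indel length distributions.  These are geometric probes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .properties import AMINO_ACIDS

__all__ = ["Edit", "EditRecipe", "random_sequence", "apply_recipe", "write_pair_fasta"]

_ALPHABET = np.array(list(AMINO_ACIDS))


def random_sequence(length: int, rng: np.random.Generator | int) -> str:
    """Uniform random protein sequence of ``length`` residues.

    ``rng`` is a seeded :class:`numpy.random.Generator` or an integer seed;
    the same seed always yields the same sequence.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return "".join(rng.choice(_ALPHABET, size=length))


@dataclass(frozen=True)
class Edit:
    """One edit: kind in {substitute, insert, delete}.

    ``position`` is 1-based and interpreted against the sequence state at
    application time.  ``payload`` carries the new residues for substitute
    and insert; ``length`` is the number of positions deleted or the
    payload length otherwise.
    """

    kind: str
    position: int
    payload: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("substitute", "insert", "delete"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if self.kind == "delete":
            if self.length < 1:
                raise ValueError("delete needs length >= 1")
        else:
            if not self.payload:
                raise ValueError(f"{self.kind} needs a payload")
            bad = set(self.payload) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"payload residues outside alphabet: {sorted(bad)}")
            object.__setattr__(self, "length", len(self.payload))


@dataclass(frozen=True)
class EditRecipe:
    """An ordered list of edits applied left to right."""

    edits: tuple[Edit, ...] = ()

    @classmethod
    def from_json(cls, path: str | Path) -> "EditRecipe":
        """Load a recipe from a JSON list of {kind, position, payload|length}."""
        with open(path, encoding="utf-8") as fh:
            spec = json.load(fh)
        return cls(tuple(
            Edit(kind=e["kind"], position=int(e["position"]),
                 payload=e.get("payload", ""), length=int(e.get("length", 0)))
            for e in spec
        ))


def _apply_one(residues: str, e: Edit) -> str:
    n = len(residues)
    p = e.position
    if e.kind == "insert":
        if p > n + 1:
            raise IndexError(f"insert position {p} beyond sequence end {n}+1")
        return residues[: p - 1] + e.payload + residues[p - 1:]
    if e.kind == "delete":
        if p + e.length - 1 > n:
            raise IndexError(f"delete [{p}, {p + e.length - 1}] beyond sequence end {n}")
        return residues[: p - 1] + residues[p - 1 + e.length:]
    # substitute: same length, and every new residue must differ from the old
    if p + len(e.payload) - 1 > n:
        raise IndexError(f"substitute [{p}, {p + len(e.payload) - 1}] beyond end {n}")
    old = residues[p - 1: p - 1 + len(e.payload)]
    for k, (a, b) in enumerate(zip(old, e.payload)):
        if a == b:
            raise ValueError(
                f"substitution at position {p + k} replaces {a!r} with itself"
            )
    return residues[: p - 1] + e.payload + residues[p - 1 + len(e.payload):]


def apply_recipe(residues: str, recipe: EditRecipe | Iterable[Edit]) -> str:
    """Apply the recipe's edits left to right; the empty recipe is identity."""
    edits: Sequence[Edit] = recipe.edits if isinstance(recipe, EditRecipe) else tuple(recipe)
    out = residues
    for e in edits:
        out = _apply_one(out, e)
    return out


def substitute_elsewhere(residues: str, position: int,
                         rng: np.random.Generator | int) -> Edit:
    """A single-residue substitution at ``position`` drawn from the other 19."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    old = residues[position - 1]
    choices = [a for a in AMINO_ACIDS if a != old]
    return Edit(kind="substitute", position=position,
                payload=str(rng.choice(choices)))


def write_pair_fasta(path: str | Path, original: str, edited: str,
                     ids: tuple[str, str] = ("original", "edited")) -> None:
    """Write the (original, edited) pair as a 2-record FASTA file."""
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in zip(ids, (original, edited)):
            fh.write(f">{rid}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k: k + 60] + "\n")
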