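"""Physicochemical property table for the 20 standard amino acids.

Each residue is described by nine properties: molecular weight (mW, Da),
hydropathy index (hI), pKa of the carboxyl group (pK1), pKa of the amino
group (pK2), isoelectric point (pI), solubility in water (S, g/L), number
of triplet codons (cN), frequency in human proteins (F, %) and van der
Waals radius of the side chain (vR, pm).  This 20x9 matrix is the input of
the principal-component scoring that assigns every residue its single
numeric "total score".

The table ships with the package as a CSV resource; rows are keyed strictly
by one-letter symbol, in fixed alphabetical order, so every downstream
matrix is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "PROPERTY_NAMES",
    "AminoAcidPropertyTable",
    "load_default_table",
    "property_matrix",
]

#: The 20 standard one-letter codes, alphabetical — the fixed row order.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: The nine property columns, in fixed order.
PROPERTY_NAMES: tuple[str, ...] = (
    "mW", "hI", "pK1", "pK2", "pI", "S", "cN", "F", "vR",
)

_VALID_CODON_COUNTS = {1, 2, 3, 4, 6}


class PropertyTableError(ValueError):
    """Raised when the packaged property table fails an integrity check."""


@dataclass(frozen=True)
class AminoAcidPropertyTable:
    """The 20x9 amino-acid property matrix with symbol-keyed access.

    Attributes
    ----------
    symbols : tuple of str
        The 20 one-letter codes, in row order.
    names : tuple of str
        Full amino-acid names; informational metadata only — all lookups
        are keyed by symbol.
    properties : tuple of str
        The nine property names, in column order.
    values : numpy.ndarray
        Shape ``(20, 9)``; row *i* holds the properties of ``symbols[i]``.
    """

    symbols: tuple[str, ...]
    names: tuple[str, ...]
    properties: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 9):
            raise PropertyTableError(
                f"property table must be 20x9, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise PropertyTableError("property table contains non-finite entries")
        if tuple(self.symbols) != AMINO_ACIDS:
            raise PropertyTableError(
                "property table rows must be the 20 standard amino acids "
                "in alphabetical symbol order"
            )
        if tuple(self.properties) != PROPERTY_NAMES:
            raise PropertyTableError("unexpected property column order")
        c_n = v[:, PROPERTY_NAMES.index("cN")]
        if not np.all(c_n == np.round(c_n)) or not set(c_n.astype(int)) <= _VALID_CODON_COUNTS:
            raise PropertyTableError("codon counts must be integers in {1,2,3,4,6}")
        object.__setattr__(self, "values", v)

    def row(self, symbol: str) -> np.ndarray:
        """Property vector of one residue, by one-letter symbol."""
        try:
            i = self.symbols.index(symbol)
        except ValueError:
            raise KeyError(f"unknown amino-acid symbol {symbol!r}") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        """The table as a DataFrame indexed by symbol."""
        df = pd.DataFrame(self.values, index=list(self.symbols),
                          columns=list(self.properties))
        df.insert(0, "name", list(self.names))
        return df


def load_default_table() -> AminoAcidPropertyTable:
    """Load the packaged 20x9 amino-acid property table.

    Raises
    ------
    PropertyTableError
        If the packaged CSV is missing rows, columns or carries
        out-of-domain values (a corrupted installation).
    """
    ref = resources.files("adld.data").joinpath("amino_acid_properties.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    expected_cols = ["symbol", "name", *PROPERTY_NAMES]
    if list(df.columns) != expected_cols:
        raise PropertyTableError(
            f"packaged table has columns {list(df.columns)}, "
            f"expected {expected_cols}"
        )
    df = df.sort_values("symbol", kind="stable").reset_index(drop=True)
    return AminoAcidPropertyTable(
        symbols=tuple(df["symbol"]),
        names=tuple(df["name"]),
        properties=PROPERTY_NAMES,
        values=df[list(PROPERTY_NAMES)].to_numpy(dtype=float),
    )


def property_matrix(table: AminoAcidPropertyTable) -> np.ndarray:
    """The raw 20x9 value matrix in canonical row/column order (a copy)."""
    return table.values.copy()
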