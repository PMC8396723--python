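"""A minimal multiple-sequence-alignment container.

Alignments are consumed, not produced, by this package: region alignments
come from an external aligner (or from the synthetic generator, which
knows the true homology).  Characters are over {A,C,G,T,N,-}; anything
else is treated as N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_VALID = set("ACGTN-")


@dataclass
class Alignment:
    """Aligned sequences: equal-length rows over {A,C,G,T,N,-}."""

    taxa: list[str]
    rows: list[str]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in number")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal length")
        cleaned = []
        for row in self.rows:
            row = row.upper()
            if set(row) - _VALID:
                row = "".join(c if c in _VALID else "N" for c in row)
            cleaned.append(row)
        self.rows = cleaned

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def matrix(self) -> np.ndarray:
        """(rows, cols) array of single-byte characters."""
        if self._matrix is None:
            self._matrix = np.frombuffer(
                "".join(self.rows).encode(), dtype="S1"
            ).reshape(self.n_rows, self.n_cols)
        return self._matrix

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def ungapped_to_aligned(self, taxon: str) -> np.ndarray:
        """Map each ungapped position of a taxon's sequence to its column."""
        row = np.frombuffer(self.row(taxon).encode(), dtype="S1")
        return np.nonzero(row != b"-")[0]

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "Alignment":
        return cls(taxa=list(sequences), rows=list(sequences.values()))

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from .io import read_fasta

        return cls.from_sequences(read_fasta(path))

    def to_fasta(self, path) -> None:
        from .io import write_fasta

        write_fasta(dict(zip(self.taxa, self.rows)), path)

    def subset(self, taxa: list[str]) -> "Alignment":
        return Alignment(taxa=list(taxa), rows=[self.row(t) for t in taxa])
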