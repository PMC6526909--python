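"""Discrete morphological character matrix.

A :class:`CharacterMatrix` holds, for every (taxon, character) pair, a
*state-set*: a singleton for an ordinary observation, a larger set for a
polymorphic cell, and the character's full observed alphabet (flagged
missing) for ``?``/gap cells.  Per-character non-negative integer weights
support weighted parsimony and the resampling schemes.

States are small integers.  Symbols in input files map as ``0``–``9`` → 0–9
and ``A``–``Z``/``a``–``z`` → 10, 11, … in file order (see
:mod:`morphostrat.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["Cell", "CharacterMatrix", "MatrixEncoding"]

MAX_STATES = 32  # states are packed into uint32 bitmasks


@dataclass(frozen=True)
class Cell:
    """One matrix entry: a non-empty state-set plus a missing flag."""

    states: frozenset
    missing: bool = False

    @property
    def is_polymorphic(self) -> bool:
        return not self.missing and len(self.states) > 1


class CharacterMatrix:
    """taxa × characters table of state-sets with per-character weights."""

    def __init__(
        self,
        taxa: list[str],
        cells: list[list[Cell]],
        weights: list[int] | None = None,
        state_symbols: list[list[int]] | None = None,
    ):
        self.taxa = list(taxa)
        self.cells = cells
        self.n_chars = len(cells[0]) if cells else 0
        if state_symbols is None:
            state_symbols = self._observed_alphabets()
        self.state_symbols = state_symbols
        self.weights = list(weights) if weights is not None else [1] * self.n_chars
        self._encoding: MatrixEncoding | None = None
        self.validate()

    # -- construction helpers -----------------------------------------

    @classmethod
    def from_states(
        cls,
        taxa: list[str],
        rows: list[list],
        weights: list[int] | None = None,
    ) -> "CharacterMatrix":
        """Build from plain python rows: each entry an int, an iterable of
        ints (polymorphism), or ``None`` (missing)."""
        n_chars = len(rows[0])
        alphabets: list[set] = [set() for _ in range(n_chars)]
        for row in rows:
            for j, entry in enumerate(row):
                if entry is None:
                    continue
                if isinstance(entry, (int, np.integer)):
                    alphabets[j].add(int(entry))
                else:
                    alphabets[j].update(int(s) for s in entry)
        for j, a in enumerate(alphabets):
            if not a:
                a.add(0)  # all-missing character: degenerate one-state alphabet
        cells = []
        for row in rows:
            crow = []
            for j, entry in enumerate(row):
                if entry is None:
                    crow.append(Cell(frozenset(alphabets[j]), missing=True))
                elif isinstance(entry, (int, np.integer)):
                    crow.append(Cell(frozenset([int(entry)])))
                else:
                    crow.append(Cell(frozenset(int(s) for s in entry)))
            cells.append(crow)
        return cls(taxa, cells, weights, [sorted(a) for a in alphabets])

    def _observed_alphabets(self) -> list[list[int]]:
        out = []
        for j in range(self.n_chars):
            seen: set = set()
            for i in range(len(self.taxa)):
                cell = self.cells[i][j]
                if not cell.missing:
                    seen.update(cell.states)
            if not seen:
                seen = set().union(*(self.cells[i][j].states for i in range(len(self.taxa)))) or {0}
            out.append(sorted(seen))
        return out

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon labels: {', '.join(dup)}")
        if any(not t for t in self.taxa):
            raise ValidationError("taxon labels must be non-empty")
        if len(self.cells) != len(self.taxa):
            raise ValidationError("one row of cells required per taxon")
        for i, row in enumerate(self.cells):
            if len(row) != self.n_chars:
                raise ValidationError(
                    f"row for {self.taxa[i]} has {len(row)} cells, expected {self.n_chars}"
                )
        for j, (alpha, w) in enumerate(zip(self.state_symbols, self.weights)):
            if w < 0:
                raise ValidationError(f"character {j + 1}: negative weight")
            if max(alpha, default=0) >= MAX_STATES:
                raise ValidationError(f"character {j + 1}: more than {MAX_STATES} states")
            allowed = set(alpha)
            for i in range(len(self.taxa)):
                cell = self.cells[i][j]
                if not cell.states:
                    raise ValidationError(
                        f"empty state-set at ({self.taxa[i]}, character {j + 1})"
                    )
                if not cell.states <= allowed:
                    raise ValidationError(
                        f"state outside alphabet at ({self.taxa[i]}, character {j + 1})"
                    )
                if cell.missing and cell.states != frozenset(allowed):
                    raise ValidationError(
                        f"missing cell must hold the full state-set at "
                        f"({self.taxa[i]}, character {j + 1})"
                    )

    # -- accessors -----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_taxa, self.n_chars)

    def column(self, j: int) -> list[Cell]:
        return [self.cells[i][j] for i in range(self.n_taxa)]

    def row(self, taxon: str) -> list[Cell]:
        return self.cells[self.taxa.index(taxon)]

    def with_weights(self, weights) -> "CharacterMatrix":
        """Same cells, new per-character weights (no copy of the cells)."""
        return CharacterMatrix(self.taxa, self.cells, list(weights), self.state_symbols)

    def subset_taxa(self, keep: list[str]) -> "CharacterMatrix":
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in keep if t not in idx]
        if missing:
            raise ValidationError(f"taxa absent from matrix: {', '.join(missing)}")
        return CharacterMatrix(
            list(keep), [self.cells[idx[t]] for t in keep], self.weights, self.state_symbols
        )

    # -- bitmask encoding for the parsimony kernels --------------------

    def encoding(self) -> "MatrixEncoding":
        if self._encoding is None:
            masks = np.zeros((self.n_taxa, self.n_chars), dtype=np.uint32)
            full = np.zeros(self.n_chars, dtype=np.uint32)
            for j, alpha in enumerate(self.state_symbols):
                for s in alpha:
                    full[j] |= np.uint32(1 << s)
            for i in range(self.n_taxa):
                for j, cell in enumerate(self.cells[i]):
                    m = 0
                    for s in cell.states:
                        m |= 1 << s
                    masks[i, j] = m
            self._encoding = MatrixEncoding(
                taxa={t: i for i, t in enumerate(self.taxa)},
                masks=masks,
                full_masks=full,
                weights=np.asarray(self.weights, dtype=np.int64),
                n_states=[len(a) for a in self.state_symbols],
            )
        return self._encoding


@dataclass
class MatrixEncoding:
    """Bit-packed view of a matrix used by the scoring kernels."""

    taxa: dict
    masks: np.ndarray       # (n_taxa, n_chars) uint32, bit s set ⇔ state s allowed
    full_masks: np.ndarray  # (n_chars,) uint32 full alphabet per character
    weights: np.ndarray     # (n_chars,) int64
    n_states: list = field(default_factory=list)
    _uniq: tuple | None = None

    def unique_columns(self) -> tuple[np.ndarray, np.ndarray]:
        """Site-pattern compression: (unique mask columns, inverse index).

        Identical columns have identical step counts on every tree, so the
        search scorer evaluates each pattern once and aggregates weights.
        """
        if self._uniq is None:
            uniq, inverse = np.unique(self.masks, axis=1, return_inverse=True)
            self._uniq = (uniq, inverse.ravel())
        return self._uniq
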