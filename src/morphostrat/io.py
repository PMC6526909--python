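"""Readers and writers for matrices (NEXUS / TNT xread), trees and age tables.

Character-matrix support targets the plain dialects used for morphological
data: non-interleaved STANDARD data, ``?`` for missing, ``-`` for gaps
(scored identically to missing — inapplicable and unknown are not
distinguished), ``{..}``/``(..)``/``[..]`` for polymorphism, and digit or
letter state symbols.  Letter symbols map to integers alphabetically
(``A`` → 10, ``B`` → 11, …) so that writing and re-reading a matrix is the
identity on state-sets.  Per-character integer weights round-trip through a
NEXUS ``ASSUMPTIONS``/``WTSET`` block.

Tree files (Newick or a NEXUS TREES block) are parsed with dendropy.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy
import pandas as pd

from .ages import AgeTable
from .errors import ParseError, ValidationError
from .matrix import Cell, CharacterMatrix
from .trees import Tree, normalize_label

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_trees",
    "write_trees",
    "read_ages",
    "write_ages",
]

_OPEN = {"{": "}", "(": ")", "[": "]"}


def _symbol_to_state(sym: str) -> int:
    if sym.isdigit():
        return int(sym)
    if sym.isalpha():
        base = ord(sym.upper()) - ord("A")
        return 10 + base
    raise ValueError(sym)


def _state_to_symbol(state: int) -> str:
    if state < 10:
        return str(state)
    if state < 36:
        return chr(ord("A") + state - 10)
    raise ValidationError(f"state {state} not representable as a single symbol")


def _parse_cells(text: str, missing: str, gap: str, alphabet: set | None, lineno: int):
    """Parse one row's cell text into a list of (state-set | None)."""
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in (missing, gap):
            out.append(None)
            i += 1
            continue
        if ch in _OPEN:
            closer = _OPEN[ch]
            j = text.find(closer, i)
            if j < 0:
                raise ParseError(f"unclosed polymorphism bracket {ch!r}", lineno)
            states = set()
            for sym in text[i + 1 : j]:
                if sym.isspace() or sym == ",":
                    continue
                states.add(_checked_state(sym, alphabet, lineno))
            if not states:
                raise ParseError("empty polymorphism brackets", lineno)
            out.append(frozenset(states))
            i = j + 1
            continue
        out.append(frozenset([_checked_state(ch, alphabet, lineno)]))
        i += 1
    return out


def _checked_state(sym: str, alphabet: set | None, lineno: int) -> int:
    try:
        state = _symbol_to_state(sym)
    except ValueError:
        raise ParseError(f"unrecognised state symbol {sym!r}", lineno) from None
    if alphabet is not None and sym.upper() not in alphabet:
        raise ParseError(f"symbol {sym!r} outside declared alphabet", lineno)
    return state


# ---------------------------------------------------------------------------
# NEXUS character data


def _read_nexus_matrix(lines: list[str]) -> CharacterMatrix:
    ntax = nchar = None
    missing, gap = "?", "-"
    alphabet: set | None = None
    rows: list[tuple[str, list]] = []
    weights: dict[int, int] = {}
    in_data = in_matrix = in_assumptions = False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("[!")[0].strip() if not in_matrix else raw.strip()
        low = line.lower()
        if re.match(r"begin\s+(data|characters)\s*;", low):
            in_data = True
            continue
        if re.match(r"begin\s+assumptions\s*;", low):
            in_assumptions = True
            continue
        if low.startswith("end;") or low.startswith("endblock;"):
            in_data = in_matrix = in_assumptions = False
            continue
        if in_assumptions and low.startswith("wtset"):
            weights.update(_parse_wtset(line, lineno))
            continue
        if not in_data:
            continue
        if low.startswith("dimensions"):
            m_ntax = re.search(r"ntax\s*=\s*(\d+)", low)
            m_nchar = re.search(r"nchar\s*=\s*(\d+)", low)
            if not m_nchar:
                raise ParseError("DIMENSIONS without NCHAR", lineno)
            nchar = int(m_nchar.group(1))
            ntax = int(m_ntax.group(1)) if m_ntax else None
            continue
        if low.startswith("format"):
            m = re.search(r"missing\s*=\s*(\S)", low)
            if m:
                missing = m.group(1)
            m = re.search(r"gap\s*=\s*(\S)", low)
            if m:
                gap = m.group(1)
            m = re.search(r'symbols\s*=\s*"([^"]*)"', line, flags=re.I)
            if m:
                alphabet = {s.upper() for s in m.group(1) if not s.isspace()}
            continue
        if low.startswith("matrix"):
            in_matrix = True
            continue
        if in_matrix:
            if line == ";":
                in_matrix = False
                continue
            if not line:
                continue
            body = line[:-1] if line.endswith(";") else line
            if line.endswith(";"):
                in_matrix = False
            if not body.strip():
                continue
            taxon, cells_text = _split_taxon(body, lineno)
            cells = _parse_cells(cells_text, missing, gap, alphabet, lineno)
            if nchar is not None and len(cells) != nchar:
                raise ParseError(
                    f"taxon {taxon}: {len(cells)} characters, NCHAR={nchar}", lineno
                )
            rows.append((taxon, cells))

    if not rows:
        raise ParseError("no MATRIX rows found in NEXUS input")
    if ntax is not None and len(rows) != ntax:
        raise ParseError(f"{len(rows)} taxa parsed but NTAX={ntax}")
    return _assemble(rows, weights)


def _split_taxon(body: str, lineno: int) -> tuple[str, str]:
    body = body.strip()
    if body.startswith("'"):
        j = body.find("'", 1)
        if j < 0:
            raise ParseError("unterminated quoted taxon label", lineno)
        return normalize_label(body[1:j]), body[j + 1 :]
    parts = body.split(None, 1)
    if len(parts) != 2:
        raise ParseError("matrix row needs a taxon label and cell text", lineno)
    return normalize_label(parts[0]), parts[1]


def _parse_wtset(line: str, lineno: int) -> dict[int, int]:
    """``WTSET * name = w1: chars, w2: chars;`` with 1-based ranges."""
    m = re.match(r"wtset\s+\*?\s*\S+\s*=\s*(.*);\s*$", line, flags=re.I)
    if not m:
        raise ParseError("malformed WTSET statement", lineno)
    out: dict[int, int] = {}
    for clause in m.group(1).split(","):
        clause = clause.strip()
        if not clause:
            continue
        try:
            w_text, positions = clause.split(":")
            w = int(w_text)
        except ValueError:
            raise ParseError(f"malformed WTSET clause {clause!r}", lineno) from None
        for token in positions.split():
            if "-" in token:
                a, b = token.split("-")
                for p in range(int(a), int(b) + 1):
                    out[p - 1] = w
            else:
                out[int(token) - 1] = w
    return out


# ---------------------------------------------------------------------------
# TNT xread


def _read_tnt_matrix(lines: list[str]) -> CharacterMatrix:
    nchar = ntax = None
    rows: list[tuple[str, list]] = []
    started = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not started:
            if line.lower().startswith("xread"):
                started = True
            continue
        if not line or line.startswith("'"):
            continue  # title / comment line
        if nchar is None:
            m = re.match(r"(\d+)\s+(\d+)\s*$", line)
            if not m:
                raise ParseError("expected 'nchar ntax' after xread", lineno)
            nchar, ntax = int(m.group(1)), int(m.group(2))
            continue
        if line == ";":
            break
        body = line[:-1] if line.endswith(";") else line
        if not body.strip():
            continue
        taxon, cells_text = _split_taxon(body, lineno)
        cells = _parse_cells(cells_text, "?", "-", None, lineno)
        if len(cells) != nchar:
            raise ParseError(f"taxon {taxon}: {len(cells)} characters, expected {nchar}", lineno)
        rows.append((taxon, cells))
        if line.endswith(";"):
            break
    if not started:
        raise ParseError("no xread statement found")
    if not rows:
        raise ParseError("no matrix rows found after xread")
    if ntax is not None and len(rows) != ntax:
        raise ParseError(f"{len(rows)} taxa parsed but xread declared {ntax}")
    return _assemble(rows, {})


def _assemble(rows: list[tuple[str, list]], weights: dict[int, int]) -> CharacterMatrix:
    taxa = [t for t, _ in rows]
    if len(set(taxa)) != len(taxa):
        dup = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ParseError(f"duplicate taxon label(s): {', '.join(dup)}")
    matrix = CharacterMatrix.from_states(taxa, [cells for _, cells in rows])
    if weights:
        w = list(matrix.weights)
        for j, wj in weights.items():
            if not 0 <= j < matrix.n_chars:
                raise ParseError(f"WTSET character index {j + 1} out of range")
            w[j] = wj
        matrix = matrix.with_weights(w)
    return matrix


# ---------------------------------------------------------------------------
# public matrix API


def read_matrix(path, format: str | None = None) -> CharacterMatrix:
    """Read a morphological matrix from NEXUS or TNT ``xread`` text.

    ``format`` is ``"nexus"``, ``"tnt"`` or ``None`` to auto-detect.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if format is None:
        head = text.lstrip()[:200].lower()
        format = "nexus" if head.startswith("#nexus") else "tnt" if "xread" in head else None
        if format is None:
            raise ParseError(f"{path}: cannot auto-detect matrix format")
    if format == "nexus":
        return _read_nexus_matrix(lines)
    if format == "tnt":
        return _read_tnt_matrix(lines)
    raise ValueError(f"unknown matrix format: {format!r}")


def _format_cell(cell: Cell, brackets: str = "{}") -> str:
    if cell.missing:
        return "?"
    if len(cell.states) == 1:
        return _state_to_symbol(next(iter(cell.states)))
    syms = "".join(_state_to_symbol(s) for s in sorted(cell.states))
    return brackets[0] + syms + brackets[1]


def write_matrix(matrix: CharacterMatrix, path, format: str = "nexus") -> None:
    path = Path(path)
    if format == "nexus":
        symbols = sorted({s for alpha in matrix.state_symbols for s in alpha})
        sym_text = " ".join(_state_to_symbol(s) for s in symbols)
        out = [
            "#NEXUS",
            "BEGIN DATA;",
            f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};",
            f'FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="{sym_text}";',
            "MATRIX",
        ]
        width = max(len(t) for t in matrix.taxa) + 2
        for i, taxon in enumerate(matrix.taxa):
            row = "".join(_format_cell(c) for c in matrix.cells[i])
            out.append(f"{taxon:<{width}}{row}")
        out += [";", "END;"]
        if any(w != 1 for w in matrix.weights):
            groups: dict[int, list[int]] = {}
            for j, w in enumerate(matrix.weights):
                groups.setdefault(w, []).append(j + 1)
            clauses = ", ".join(
                f"{w}: {' '.join(map(str, idx))}" for w, idx in sorted(groups.items())
            )
            out += ["BEGIN ASSUMPTIONS;", f"WTSET * weights = {clauses};", "END;"]
    elif format == "tnt":
        out = ["xread", f"{matrix.n_chars} {matrix.n_taxa}"]
        width = max(len(t) for t in matrix.taxa) + 2
        for i, taxon in enumerate(matrix.taxa):
            row = "".join(_format_cell(c, "[]") for c in matrix.cells[i])
            out.append(f"{taxon:<{width}}{row}")
        out.append(";")
    else:
        raise ValueError(f"unknown matrix format: {format!r}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# trees


def read_trees(path) -> list[Tree]:
    """Read all trees from a Newick file or a NEXUS TREES block."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty tree file")
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    try:
        tlist = dendropy.TreeList.get(
            data=text, schema=schema, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ParseError(f"{path}: {exc}") from exc
    if not tlist:
        raise ParseError(f"{path}: no trees found")
    return [Tree.from_dendropy(t) for t in tlist]


def write_trees(trees: list[Tree], path, format: str = "newick", lengths: bool = False) -> None:
    path = Path(path)
    newicks = [t.newick(lengths=lengths, labels=True) for t in trees]
    if format == "newick":
        path.write_text("\n".join(newicks) + "\n")
    elif format == "nexus":
        out = ["#NEXUS", "BEGIN TREES;"]
        out += [f"TREE tree_{i + 1} = [&R] {nwk}" for i, nwk in enumerate(newicks)]
        out += ["END;"]
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unknown tree format: {format!r}")


# ---------------------------------------------------------------------------
# age tables


def read_ages(path) -> AgeTable:
    """Read a ``taxon,fad,lad`` CSV into an :class:`AgeTable` (Ma)."""
    try:
        # round_trip parsing: ages written by write_ages re-read bit-exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    need = {"taxon", "fad", "lad"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: header must contain columns taxon,fad,lad")
    ranges = {}
    for _, rec in df.iterrows():
        taxon = normalize_label(str(rec["taxon"]))
        try:
            fad, lad = float(rec["fad"]), float(rec["lad"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: non-numeric age for taxon {taxon}") from None
        if taxon in ranges:
            raise ParseError(f"{path}: duplicate taxon {taxon}")
        ranges[taxon] = (fad, lad)
    return AgeTable(ranges)


def write_ages(ages: AgeTable, path) -> None:
    df = pd.DataFrame(
        [(t, fad, lad) for t, (fad, lad) in ages.ranges.items()],
        columns=["taxon", "fad", "lad"],
    )
    df.to_csv(path, index=False)
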