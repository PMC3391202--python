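"""Discrete character matrices: TNT/NEXUS I/O, supraspecific-OTU scoring,
Fitch parsimony length and ensemble fit indices.

Characters are unordered with small non-negative integer states.  A cell is a
*state set*: a singleton for a fixed score, a multi-element set for a
polymorphic score (``[0 1]``), and the full set of states observed in that
character for missing data (``?``).  Tree *search* is out of scope — these
routines score a given topology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .tree import TimeTree, TreeError

__all__ = [
    "CharacterMatrix",
    "MatrixParseError",
    "read_matrix",
    "score_supraspecific_otu",
    "fitch_length",
    "ensemble_indices",
    "EnsembleIndices",
]

MAX_STATES = 10


class MatrixParseError(ValueError):
    """Malformed character-matrix input."""


@dataclass
class CharacterMatrix:
    """Taxa x characters matrix of state sets."""

    taxa: list[str]
    cells: list[list[frozenset[int]]]          # [taxon][character]
    missing: list[list[bool]] = None           # True where the cell was "?"

    def __post_init__(self) -> None:
        ncols = {len(row) for row in self.cells}
        if len(ncols) > 1:
            raise MatrixParseError(f"ragged matrix: row lengths {sorted(ncols)}")
        if len(self.taxa) != len(self.cells):
            raise MatrixParseError("taxon count does not match row count")
        for row in self.cells:
            for cell in row:
                if not cell:
                    raise MatrixParseError("empty state set")
                if max(cell) >= MAX_STATES:
                    raise MatrixParseError(f"state out of range in {sorted(cell)}")
        if self.missing is None:
            self.missing = [[False] * self.n_characters for _ in self.taxa]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def column(self, j: int) -> dict[str, frozenset[int]]:
        return {t: self.cells[i][j] for i, t in enumerate(self.taxa)}

    def observed_states(self, j: int) -> frozenset[int]:
        """States observed in character ``j``, missing cells excluded."""
        out: set[int] = set()
        for i in range(self.n_taxa):
            if not self.missing[i][j]:
                out |= self.cells[i][j]
        return frozenset(out)

    def to_tnt(self) -> str:
        lines = [f"xread {self.n_characters} {self.n_taxa}"]
        for i, taxon in enumerate(self.taxa):
            cells = []
            for j, cell in enumerate(self.cells[i]):
                if self.missing[i][j]:
                    cells.append("?")
                elif len(cell) == 1:
                    cells.append(str(next(iter(cell))))
                else:
                    cells.append("[" + "".join(str(s) for s in sorted(cell)) + "]")
            lines.append(f"{taxon.replace(' ', '_')}  {''.join(cells)}")
        return "\n".join(lines) + "\n;\n"


def _parse_row(text: str, where: str) -> tuple[list[frozenset[int]], list[bool]]:
    cells: list[frozenset[int]] = []
    miss: list[bool] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c.isspace():
            i += 1
        elif c.isdigit():
            cells.append(frozenset({int(c)}))
            miss.append(False)
            i += 1
        elif c in "?-":
            cells.append(frozenset())  # placeholder, filled after full parse
            miss.append(True)
            i += 1
        elif c in "[{(":
            close = {"[": "]", "{": "}", "(": ")"}[c]
            end = text.find(close, i)
            if end < 0:
                raise MatrixParseError(f"unclosed {c!r} in {where}")
            states = frozenset(int(ch) for ch in text[i + 1:end] if ch.isdigit())
            if not states:
                raise MatrixParseError(f"empty polymorphic cell in {where}")
            cells.append(states)
            miss.append(False)
            i = end + 1
        else:
            raise MatrixParseError(f"unknown symbol {c!r} in {where}")
    return cells, miss


def read_matrix(text: str) -> CharacterMatrix:
    """Parse a TNT ``xread`` block or a NEXUS ``characters``/``data`` block.

    Polymorphic cells may be written ``[01]``, ``[0 1]``, ``{01}`` or ``(01)``;
    ``?`` (or ``-``) marks missing data and is expanded to the full set of
    states observed in that character.
    """
    body = None
    m = re.search(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)(.*?);", text,
                  re.DOTALL | re.IGNORECASE)
    if m:
        nchar, ntax = int(m.group(1)), int(m.group(2))
        body = m.group(3)
    else:
        m = re.search(r"matrix(.*?);", text, re.DOTALL | re.IGNORECASE)
        if not m:
            raise MatrixParseError("no xread or NEXUS matrix block found")
        body = m.group(1)
        nchar = ntax = None
        dims = re.search(r"ntax\s*=\s*(\d+).*?nchar\s*=\s*(\d+)", text,
                         re.DOTALL | re.IGNORECASE)
        if dims:
            ntax, nchar = int(dims.group(1)), int(dims.group(2))

    taxa: list[str] = []
    cells: list[list[frozenset[int]]] = []
    miss: list[list[bool]] = []
    for line in body.strip().splitlines():
        line = line.strip()
        if not line or line.startswith("[") and line.endswith("]"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixParseError(f"cannot split taxon/states in line {line!r}")
        taxon, states = parts
        row, mrow = _parse_row(states, f"row {taxon!r}")
        taxa.append(taxon)
        cells.append(row)
        miss.append(mrow)

    if ntax is not None and len(taxa) != ntax:
        raise MatrixParseError(f"expected {ntax} taxa, parsed {len(taxa)}")
    if nchar is not None:
        for t, row in zip(taxa, cells):
            if len(row) != nchar:
                raise MatrixParseError(
                    f"row {t!r} has {len(row)} characters, expected {nchar}"
                )

    # expand missing cells to the observed state set of their character
    for j in range(len(cells[0]) if cells else 0):
        obs = frozenset().union(
            *(cells[i][j] for i in range(len(taxa)) if not miss[i][j])
        ) or frozenset({0})
        for i in range(len(taxa)):
            if miss[i][j]:
                cells[i][j] = obs
    return CharacterMatrix(taxa=taxa, cells=cells, missing=miss)


def score_supraspecific_otu(member_scores: Sequence[int]) -> frozenset[int]:
    """Collapse five exemplar species' scores into one supraspecific OTU cell.

    For a binary character the rule is a vote: a 0-4 or 1-4 minority is
    outvoted ({0} resp. {1}); a 2-3 split is recorded as polymorphic {0, 1}.
    The documented exception for a non-binary character applies when at least
    four of the five exemplars agree on one state, which is then fixed.
    """
    scores = list(member_scores)
    if len(scores) != 5:
        raise ValueError(f"expected 5 member scores, got {len(scores)}")
    if all(s in (0, 1) for s in scores):
        total = sum(scores)
        if total <= 1:
            return frozenset({0})
        if total >= 4:
            return frozenset({1})
        return frozenset({0, 1})
    counts = {s: scores.count(s) for s in set(scores)}
    state, n = max(counts.items(), key=lambda kv: kv[1])
    if n >= 4:
        return frozenset({state})
    raise ValueError(
        f"non-binary member scores {scores} without a 4/5 majority are "
        "outside the documented scoring scheme"
    )


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def _check_alignment(tree: TimeTree, matrix: CharacterMatrix) -> None:
    tips = set(tree.tip_labels())
    taxa = set(matrix.taxa)
    if tips != taxa:
        raise TreeError(
            f"tip/taxon mismatch: only in tree {sorted(tips - taxa)}, "
            f"only in matrix {sorted(taxa - tips)}"
        )


def fitch_length(tree: TimeTree, matrix: CharacterMatrix) -> tuple[np.ndarray, int]:
    """Minimum unordered state changes per character on a fixed topology.

    On a binary tree this is the Fitch set recursion (children's intersection
    if nonempty, else their union at the cost of one step); the implementation
    uses the equivalent unit-cost dynamic program, which stays exact on
    polytomies.  Polymorphic tips enter as their full state set.  Returns
    ``(per_character_steps, total)``.
    """
    _check_alignment(tree, matrix)
    col_of = {t: i for i, t in enumerate(matrix.taxa)}
    steps = np.zeros(matrix.n_characters, dtype=int)
    big = 10 ** 6
    for j in range(matrix.n_characters):
        states = sorted(matrix.observed_states(j)) or [0]
        idx = {s: i for i, s in enumerate(states)}
        cost: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_tip:
                cell = matrix.cells[col_of[node.label]][j]
                c = np.full(len(states), big)
                for s in cell:
                    if s in idx:
                        c[idx[s]] = 0
                cost[id(node)] = c
                continue
            c = np.zeros(len(states))
            for child in node.children:
                cc = cost[id(child)]
                c = c + np.minimum(cc, cc.min() + 1)
            cost[id(node)] = c
        steps[j] = int(cost[id(tree.root)].min())
    return steps, int(steps.sum())


def _star_tree_steps(matrix: CharacterMatrix, j: int) -> int:
    """Maximum (star-tree) steps for character ``j``: one change per tip not
    matching the best central state; polymorphic tips contribute their
    cheapest state (they match the central state whenever it is in their set)."""
    obs = matrix.observed_states(j)
    if not obs:
        return 0
    best = min(
        sum(1 for i in range(matrix.n_taxa) if s not in matrix.cells[i][j])
        for s in obs
    )
    return best


@dataclass
class EnsembleIndices:
    """Ensemble character-fit (homoplasy) indices for a matrix on a tree.

    ``ci_all``/``ci_excl`` are the consistency index over all characters and
    excluding parsimony-uninformative ones; ``ri`` the retention index;
    ``rc`` the rescaled consistency index.  Printed fit indices in the
    literature differ in which CI enters RC, so the convention is explicit.
    """

    steps: np.ndarray          # observed steps s_i
    min_steps: np.ndarray      # m_i = (# observed states) - 1
    max_steps: np.ndarray      # g_i = star-tree steps
    informative: np.ndarray    # parsimony-informative flags (g_i > m_i)
    rc_convention: str = "ci_all"

    @property
    def total_steps(self) -> int:
        return int(self.steps.sum())

    @property
    def ci_all(self) -> float:
        s = self.steps.sum()
        return float(self.min_steps.sum() / s) if s else float("nan")

    @property
    def ci_excl(self) -> float:
        mask = self.informative
        s = self.steps[mask].sum()
        return float(self.min_steps[mask].sum() / s) if s else float("nan")

    @property
    def ri(self) -> float:
        g, m, s = self.max_steps.sum(), self.min_steps.sum(), self.steps.sum()
        if g == m:
            return float("nan")
        return float((g - s) / (g - m))

    @property
    def rc(self) -> float:
        ci = self.ci_all if self.rc_convention == "ci_all" else self.ci_excl
        return ci * self.ri

    def summary(self) -> str:
        return (
            f"tree length      {self.total_steps}\n"
            f"CI (all chars)   {self.ci_all:.3f}\n"
            f"CI (informative) {self.ci_excl:.3f}\n"
            f"RI               {self.ri:.3f}\n"
            f"RC ({self.rc_convention})     {self.rc:.3f}"
        )


def ensemble_indices(
    tree: TimeTree, matrix: CharacterMatrix, rc_convention: str = "ci_all"
) -> EnsembleIndices:
    """Consistency, retention and rescaled consistency indices on a topology.

    Per character: minimum steps m = (# observed states) - 1, observed steps s
    from :func:`fitch_length`, maximum steps g on the star tree.  Ensemble
    CI = sum(m)/sum(s), RI = (sum(g)-sum(s))/(sum(g)-sum(m)), RC = CI * RI.
    A character is parsimony-informative when g > m.
    """
    if rc_convention not in ("ci_all", "ci_excl"):
        raise ValueError(f"unknown rc_convention {rc_convention!r}")
    steps, _ = fitch_length(tree, matrix)
    m = np.array([
        max(len(matrix.observed_states(j)) - 1, 0)
        for j in range(matrix.n_characters)
    ])
    g = np.array([_star_tree_steps(matrix, j) for j in range(matrix.n_characters)])
    informative = g > m
    return EnsembleIndices(
        steps=steps, min_steps=m, max_steps=g,
        informative=informative, rc_convention=rc_convention,
    )
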