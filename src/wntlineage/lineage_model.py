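"""The invariant *C. elegans* embryonic lineage.

Cells are named in Sulston nomenclature: a founder prefix (``AB``, ``MS``,
``E``, ``C``, ``D``, ``P0``–``P4``, ``Z2``, ``Z3``, plus the transient
``EMS``) followed by a suffix of division polarities, one character per
division, drawn from ``a``/``p`` (anterior/posterior), ``l``/``r``
(left/right) and ``d``/``v`` (dorsal/ventral).  The suffix therefore encodes
the cell's entire division history: ``ABplaaaapp`` is the posterior daughter
of the posterior daughter of ``ABplaaaa``.

The module provides name parsing/validation, parent and cousin resolution,
polarity-history extraction, a :class:`LineageTree` container linking
per-cell records into divisions, and newick-style text export/import.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "SUFFIX_ALPHABET",
    "FOUNDERS",
    "EARLY_PARENT",
    "EARLY_DAUGHTERS",
    "FOUNDER_POLARITY",
    "AXIS_OF_CHAR",
    "OPPOSITE_CHAR",
    "LineageError",
    "NameError_",
    "CellName",
    "CellRecord",
    "Division",
    "LineageTree",
    "parse_name",
    "parent_of",
    "daughters_of",
    "polarity_history",
    "polarity_char",
    "cousin_pair",
    "build_tree",
    "canonical_names",
    "tree_to_newick",
    "tree_from_newick",
]

SUFFIX_ALPHABET = frozenset("aplrdv")

#: Fixed early-lineage divisions, parent -> (first, second) daughter.  The
#: second-listed daughter is the posterior-equivalent one (P1, P2, P3, P4,
#: E, Z3); E is the Wnt-signalled daughter of EMS and is treated as
#: posterior-equivalent by default.
EARLY_DAUGHTERS: dict[str, tuple[str, str]] = {
    "P0": ("AB", "P1"),
    "P1": ("EMS", "P2"),
    "EMS": ("MS", "E"),
    "P2": ("C", "P3"),
    "P3": ("D", "P4"),
    "P4": ("Z2", "Z3"),
}

EARLY_PARENT: dict[str, str] = {
    d: p for p, (d1, d2) in EARLY_DAUGHTERS.items() for d in (d1, d2)
}

FOUNDERS = frozenset(EARLY_DAUGHTERS) | frozenset(EARLY_PARENT)

#: Effective a/p polarity of each founder relative to its sibling, used when
#: a history label has to extend through the early cleavages.  P0 has none.
FOUNDER_POLARITY: dict[str, str] = {}
for _p, (_d1, _d2) in EARLY_DAUGHTERS.items():
    FOUNDER_POLARITY[_d1] = "a"
    FOUNDER_POLARITY[_d2] = "p"

#: Divisions separating each founder from the zygote.
FOUNDER_DEPTH: dict[str, int] = {"P0": 0}
while len(FOUNDER_DEPTH) < len(FOUNDERS):
    for _p, (_d1, _d2) in EARLY_DAUGHTERS.items():
        if _p in FOUNDER_DEPTH:
            FOUNDER_DEPTH.setdefault(_d1, FOUNDER_DEPTH[_p] + 1)
            FOUNDER_DEPTH.setdefault(_d2, FOUNDER_DEPTH[_p] + 1)

AXIS_OF_CHAR = {
    "a": "a-p", "p": "a-p",
    "l": "l-r", "r": "l-r",
    "d": "d-v", "v": "d-v",
}

OPPOSITE_CHAR = {"a": "p", "p": "a", "l": "r", "r": "l", "d": "v", "v": "d"}

#: Daughter ordering within an axis: anterior/left/dorsal child first.
_CHAR_ORDER = {"a": 0, "p": 1, "l": 0, "r": 1, "d": 0, "v": 1}

# longest founder first so "EMS" never parses as "E" + junk
_FOUNDER_RE = re.compile(
    "^(%s)" % "|".join(sorted(FOUNDERS, key=len, reverse=True))
)


class LineageError(ValueError):
    """Base error for lineage-model violations."""


class NameError_(LineageError):
    """Malformed Sulston cell name."""


@dataclass(frozen=True, order=True)
class CellName:
    """A validated Sulston cell name (founder prefix + polarity suffix)."""

    founder: str
    suffix: str

    def __str__(self) -> str:
        return self.founder + self.suffix

    @property
    def generation(self) -> int:
        """Number of divisions since the founder."""
        return len(self.suffix)

    @property
    def depth(self) -> int:
        """Number of divisions since the zygote P0 (topological depth)."""
        return FOUNDER_DEPTH[self.founder] + len(self.suffix)

    def is_root(self) -> bool:
        return self.founder == "P0" and not self.suffix


def parse_name(name: str) -> CellName:
    """Parse and validate a Sulston cell name.

    Raises :class:`NameError_` naming the offending character when the
    founder prefix is unknown or the suffix leaves the {a,p,l,r,d,v}
    alphabet.  Round-trips: ``str(parse_name(x)) == x``.
    """
    if isinstance(name, CellName):
        return name
    if not name:
        raise NameError_("empty cell name")
    m = _FOUNDER_RE.match(name)
    if m is None:
        raise NameError_(f"unknown founder prefix in {name!r}")
    founder, suffix = m.group(1), name[m.end():]
    bad = [c for c in suffix if c not in SUFFIX_ALPHABET]
    if bad:
        raise NameError_(
            f"illegal suffix character(s) {','.join(sorted(set(bad)))} in {name!r}"
        )
    return CellName(founder, suffix)


def parent_of(name: CellName | str) -> CellName:
    """Parent of a cell: drop the last suffix character, or resolve a
    founder through the fixed early-lineage table.  P0 has no parent."""
    cn = parse_name(name)
    if cn.suffix:
        return CellName(cn.founder, cn.suffix[:-1])
    if cn.founder == "P0":
        raise LineageError("P0 is the zygote and has no parent")
    return CellName(EARLY_PARENT[cn.founder], "")


def daughters_of(name: CellName | str, axis: str = "a-p") -> tuple[CellName, CellName]:
    """Canonical daughters of a cell, first-listed daughter first.

    Founders divide per the early-lineage table (``axis`` ignored); suffixed
    cells append the two characters of ``axis``.
    """
    cn = parse_name(name)
    if not cn.suffix and cn.founder in EARLY_DAUGHTERS:
        d1, d2 = EARLY_DAUGHTERS[cn.founder]
        return CellName(d1, ""), CellName(d2, "")
    c1, c2 = axis.split("-")
    return CellName(cn.founder, cn.suffix + c1), CellName(cn.founder, cn.suffix + c2)


def polarity_history(name: CellName | str, k: int) -> str:
    """Last ``k`` suffix characters of a name, most recent last.

    Returns a shorter string when the cell has fewer than ``k`` recorded
    divisions past its founder (founders themselves give ``""``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cn = parse_name(name)
    return cn.suffix[-k:]


def polarity_char(name: CellName | str) -> Optional[str]:
    """The polarity character of this cell's own birth division.

    Last suffix character for suffixed names; the founder's effective a/p
    polarity for founders (``None`` for P0).
    """
    cn = parse_name(name)
    if cn.suffix:
        return cn.suffix[-1]
    return FOUNDER_POLARITY.get(cn.founder)


def cousin_pair(name: CellName | str, high_char: str) -> CellName:
    """Matched Low-High cousin of a High-High cell.

    For a cell whose last two divisions were both toward ``high_char``
    (e.g. ``...pp`` with ``high_char='p'``), the matched cousin shares the
    grandparent but descends from the opposite-polarity parent:
    ``grandparent + opposite(high_char) + high_char``.  The pairing is
    injective over a tree because each HH cell determines its cousin
    uniquely and vice versa.
    """
    cn = parse_name(name)
    if high_char not in SUFFIX_ALPHABET:
        raise ValueError(f"invalid polarity character {high_char!r}")
    if len(cn.suffix) < 2:
        raise LineageError(
            f"{cn}: needs at least two recorded divisions for cousin pairing"
        )
    if cn.suffix[-2:] != high_char * 2:
        raise LineageError(
            f"{cn} does not end in {high_char!r}{high_char!r}; not a High-High cell"
        )
    other = OPPOSITE_CHAR[high_char]
    return CellName(cn.founder, cn.suffix[:-2] + other + high_char)


@dataclass
class CellRecord:
    """One cell's measurements from a lineage-traced embryo.

    ``blot`` is the mean nuclear reporter intensity over the cell's
    lifetime, corrected for local non-nuclear background; it can be
    negative.  Positions, totals and per-timepoint traces are optional.
    """

    cell: CellName
    birth_time: float = float("nan")
    end_time: float = float("nan")
    blot: float = float("nan")
    total: Optional[float] = None
    pos_birth: Optional[tuple[float, float, float]] = None
    pos_end: Optional[tuple[float, float, float]] = None
    trace: Optional[list[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        self.cell = parse_name(self.cell)


@dataclass(frozen=True)
class Division:
    """One division: parent plus its two daughters in canonical order
    (anterior/left/dorsal first) and the axis implied by their names."""

    parent: CellName
    daughter1: CellName
    daughter2: CellName
    axis: str
    time: float = float("nan")

    @property
    def anterior(self) -> CellName:
        return self.daughter1

    @property
    def posterior(self) -> CellName:
        return self.daughter2


class LineageTree:
    """A lineage tree over recorded cells of one embryo.

    Maps names to :class:`CellRecord`, exposes parent/daughter links and
    division enumeration.  Cells whose parent is unrecorded are roots of
    observed subtrees.  Internal cells have exactly 0 or 2 recorded
    daughters when complete; a single recorded daughter is kept but its
    division is not enumerated.
    """

    def __init__(
        self,
        records: Iterable[CellRecord] = (),
        embryo_id: str = "",
        reporter: str = "",
        condition: str = "",
    ) -> None:
        self.embryo_id = embryo_id
        self.reporter = reporter
        self.condition = condition
        self.cells: dict[CellName, CellRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: CellRecord) -> None:
        if rec.cell in self.cells:
            raise LineageError(f"duplicate cell name {rec.cell}")
        self.cells[rec.cell] = rec

    def __contains__(self, name: CellName | str) -> bool:
        return parse_name(name) in self.cells

    def __len__(self) -> int:
        return len(self.cells)

    def __getitem__(self, name: CellName | str) -> CellRecord:
        return self.cells[parse_name(name)]

    def get(self, name: CellName | str) -> Optional[CellRecord]:
        return self.cells.get(parse_name(name))

    def parent(self, name: CellName | str) -> Optional[CellName]:
        """Recorded parent, or None if unrecorded or root."""
        cn = parse_name(name)
        if cn.is_root():
            return None
        p = parent_of(cn)
        return p if p in self.cells else None

    def daughters(self, name: CellName | str) -> list[CellName]:
        """Recorded daughters in canonical order (a<p, l<r, d<v)."""
        cn = parse_name(name)
        out = []
        if not cn.suffix and cn.founder in EARLY_DAUGHTERS:
            for d in EARLY_DAUGHTERS[cn.founder]:
                dcn = CellName(d, "")
                if dcn in self.cells:
                    out.append(dcn)
            return out
        for c in "apdlrv":
            dcn = CellName(cn.founder, cn.suffix + c)
            if dcn in self.cells:
                out.append(dcn)
        out.sort(key=lambda d: _CHAR_ORDER[d.suffix[-1]])
        return out

    def roots(self) -> list[CellName]:
        """Cells whose parent is not recorded (observed-subtree roots)."""
        return sorted(n for n in self.cells if self.parent(n) is None)

    def descendants(self, name: CellName | str) -> Iterator[CellName]:
        """All recorded strict descendants, preorder."""
        stack = list(reversed(self.daughters(name)))
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(self.daughters(n)))

    def subtree(self, name: CellName | str) -> Iterator[CellName]:
        """The cell itself plus all recorded descendants, preorder."""
        cn = parse_name(name)
        yield cn
        yield from self.descendants(cn)

    def divisions(self) -> list[Division]:
        """All divisions with both daughters recorded, sorted by parent."""
        out = []
        for name in sorted(self.cells):
            ds = self.daughters(name)
            if len(ds) == 2:
                axis = (
                    "a-p"
                    if not ds[0].suffix
                    else AXIS_OF_CHAR[ds[0].suffix[-1]]
                )
                rec = self.cells[name]
                out.append(Division(name, ds[0], ds[1], axis, rec.end_time))
        return out

    def n_divisions(self) -> int:
        return len(self.divisions())


def build_tree(
    records: Iterable[CellRecord],
    embryo_id: str = "",
    reporter: str = "",
    condition: str = "",
) -> LineageTree:
    """Link per-cell records into a :class:`LineageTree`.

    Duplicate names raise; cells with no recorded parent become roots of
    observed subtrees.
    """
    return LineageTree(records, embryo_id=embryo_id, reporter=reporter, condition=condition)


def canonical_names(n_rounds: int) -> list[CellName]:
    """All cell names through ``n_rounds`` synchronous division rounds
    starting from P0 (P0 itself is round 0)."""
    names = [CellName("P0", "")]
    frontier = [CellName("P0", "")]
    for _ in range(n_rounds):
        nxt: list[CellName] = []
        for cn in frontier:
            # Z2/Z3 are the germline pair and do not divide in the embryo
            if not cn.suffix and cn.founder in ("Z2", "Z3"):
                continue
            d1, d2 = daughters_of(cn)
            nxt.extend((d1, d2))
        names.extend(nxt)
        frontier = nxt
    return names


# ---------------------------------------------------------------------------
# newick-style text serialisation
#
# Hand-rolled rather than delegated to a phylogenetics library because the
# dialect carries internal-node labels plus [&key=value] attribute blocks on
# any node, and every name is plain alphanumeric so no quoting is needed.

def _node_newick(tree: LineageTree, name: CellName, attrs: tuple[str, ...]) -> str:
    ds = tree.daughters(name)
    rec = tree.cells[name]
    ann = ",".join(
        f"{a}={getattr(rec, a)!r}" if isinstance(getattr(rec, a), str)
        else f"{a}={getattr(rec, a)}"
        for a in attrs
        if getattr(rec, a) is not None
    )
    label = str(name) + (f"[&{ann}]" if ann else "")
    if not ds:
        return label
    inner = ",".join(_node_newick(tree, d, attrs) for d in ds)
    return f"({inner}){label}"


def tree_to_newick(
    tree: LineageTree, attrs: tuple[str, ...] = ("birth_time", "end_time", "blot")
) -> str:
    """Serialise a tree as nested-parenthesis text with node labels and
    optional ``[&key=value]`` attribute annotations; one statement per
    observed-subtree root."""
    return "".join(_node_newick(tree, r, attrs) + ";\n" for r in tree.roots())


_TOKEN_RE = re.compile(r"\(|\)|,|;|[^(),;\[\]]+(?:\[&[^\]]*\])?")
_LABEL_RE = re.compile(r"^(?P<name>[^\[\]]+)(?:\[&(?P<ann>[^\]]*)\])?$")


def tree_from_newick(text: str, **tree_kwargs) -> LineageTree:
    """Parse the dialect written by :func:`tree_to_newick`."""
    tree = LineageTree(**tree_kwargs)

    def make_record(label: str) -> None:
        m = _LABEL_RE.match(label.strip())
        if m is None:
            raise LineageError(f"bad newick label {label!r}")
        rec = CellRecord(parse_name(m.group("name")))
        if m.group("ann"):
            for pair in m.group("ann").split(","):
                key, _, val = pair.partition("=")
                if not hasattr(rec, key):
                    raise LineageError(f"unknown attribute {key!r}")
                setattr(
                    rec,
                    key,
                    val.strip("'\"") if val.startswith(("'", '"')) else float(val),
                )
        tree.add(rec)

    depth = 0
    for tok in _TOKEN_RE.findall(text):
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth -= 1
            if depth < 0:
                raise LineageError("unbalanced parentheses in newick text")
        elif tok in (",", ";") or not tok.strip():
            continue
        else:
            make_record(tok)
    if depth != 0:
        raise LineageError("unbalanced parentheses in newick text")
    return tree
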