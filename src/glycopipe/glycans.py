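"""Glycan trees, composition vectors, database I/O and Y-ion enumeration.

A glycan attached to a peptide is modelled as a rooted tree of
monosaccharide residues with the reducing end at the root (for N-glycans
the root is the HexNAc bonded to the sequon asparagine).  Glycosidic-bond
cleavages that retain the peptide produce Y ions: the peptide backbone
plus the mass of a root-containing subtree.  Y-ion mass sets, not full
topologies, are what a spectrum can distinguish.

Database format: UTF-8 text, one glycan per line as a bracketed encoding
``(N(N(H(H)(H))))`` with symbols H/N/A/G/F for Hex/HexNAc/NeuAc/NeuGc/dHex,
optionally followed by a tab and an identifier; ``#`` starts a comment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .masses import CROSS_RING_02X_OFFSET, MONOSACCHARIDES, MONOSACCHARIDE_SYMBOLS

__all__ = [
    "GlycanComposition",
    "GlycanTree",
    "YIonSet",
    "CORE_IONS",
    "GlycanParseError",
    "parse_glycan",
    "load_glycan_db",
    "enumerate_y_ions",
    "core_ion_masses",
    "core_ion_offsets",
    "reversed_y_masses",
]

COMPOSITION_ORDER = ("Hex", "HexNAc", "NeuAc", "NeuGc", "dHex")

HEXNAC = MONOSACCHARIDES["HexNAc"]
HEX = MONOSACCHARIDES["Hex"]
DHEX = MONOSACCHARIDES["dHex"]

#: The nine trimannosyl-core ion offsets relative to the naked peptide,
#: keyed by the conventional label.  Y-abcde counts (Hex, dHex) extras:
#: Y-01001 and Y-02001 are the core-fucosylated Y1/Y2.
CORE_IONS: dict[str, float] = {
    "Y0": 0.0,
    "Y1": HEXNAC,
    "0,2X0": CROSS_RING_02X_OFFSET,
    "Y2": 2 * HEXNAC,
    "Y3": 2 * HEXNAC + HEX,
    "Y4": 2 * HEXNAC + 2 * HEX,
    "Y5": 2 * HEXNAC + 3 * HEX,
    "Y-01001": HEXNAC + DHEX,
    "Y-02001": 2 * HEXNAC + DHEX,
}


class GlycanParseError(ValueError):
    """Malformed bracketed glycan encoding."""


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide count vector (#Hex, #HexNAc, #NeuAc, #NeuGc, #dHex)."""

    hex: int = 0
    hexnac: int = 0
    neuac: int = 0
    neugc: int = 0
    dhex: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.as_tuple()):
            raise ValueError("negative monosaccharide count")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.hex, self.hexnac, self.neuac, self.neugc, self.dhex)

    @property
    def mass(self) -> float:
        """Attached-glycan mass: residue masses only, no terminal water."""
        return float(
            np.dot(self.as_tuple(), [MONOSACCHARIDES[m] for m in COMPOSITION_ORDER])
        )

    @classmethod
    def from_counter(cls, counts: Counter[str]) -> "GlycanComposition":
        return cls(
            hex=counts.get("Hex", 0),
            hexnac=counts.get("HexNAc", 0),
            neuac=counts.get("NeuAc", 0),
            neugc=counts.get("NeuGc", 0),
            dhex=counts.get("dHex", 0),
        )

    def __str__(self) -> str:
        return "(%d,%d,%d,%d,%d)" % self.as_tuple()


@dataclass
class GlycanTree:
    """Rooted glycan tree; children are semantically unordered."""

    symbol: str  # monosaccharide name, e.g. "HexNAc"
    children: list["GlycanTree"] = field(default_factory=list)
    id: str | None = None

    def walk(self) -> Iterator["GlycanTree"]:
        yield self
        for child in self.children:
            yield from child.walk()

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.walk())

    @property
    def composition(self) -> GlycanComposition:
        return GlycanComposition.from_counter(Counter(n.symbol for n in self.walk()))

    @property
    def mass(self) -> float:
        return sum(MONOSACCHARIDES[n.symbol] for n in self.walk())

    def canonical(self) -> str:
        """Canonical encoding: children sorted recursively.

        Two rooted trees are isomorphic (children unordered) iff their
        canonical strings are equal.
        """
        sym = {v: k for k, v in MONOSACCHARIDE_SYMBOLS.items()}[self.symbol]
        inner = "".join(sorted(c.canonical() for c in self.children))
        return f"({sym}{inner})"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GlycanTree({self.canonical()}, id={self.id!r})"


def parse_glycan(encoding: str, id: str | None = None) -> GlycanTree:
    """Parse a bracketed encoding like ``(N(N(H(H)(H))))`` into a tree."""
    s = encoding.strip()
    pos = 0

    def parse_node() -> GlycanTree:
        nonlocal pos
        if pos >= len(s) or s[pos] != "(":
            raise GlycanParseError(f"expected '(' at position {pos} in {encoding!r}")
        pos += 1
        if pos >= len(s) or s[pos] not in MONOSACCHARIDE_SYMBOLS:
            raise GlycanParseError(
                f"unknown monosaccharide symbol at position {pos} in {encoding!r}"
            )
        node = GlycanTree(MONOSACCHARIDE_SYMBOLS[s[pos]])
        pos += 1
        while pos < len(s) and s[pos] == "(":
            node.children.append(parse_node())
        if pos >= len(s) or s[pos] != ")":
            raise GlycanParseError(f"expected ')' at position {pos} in {encoding!r}")
        pos += 1
        return node

    root = parse_node()
    if pos != len(s):
        raise GlycanParseError(f"trailing characters at position {pos} in {encoding!r}")
    root.id = id
    return root


def load_glycan_db(path: str | Path) -> list[GlycanTree]:
    """Read a glycan database file, deduplicated by rooted-tree isomorphism.

    Order is stable by first occurrence.  Malformed lines raise
    :class:`GlycanParseError` naming the line number.
    """
    trees: list[GlycanTree] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            try:
                tree = parse_glycan(parts[0], id=parts[1] if len(parts) > 1 else None)
            except GlycanParseError as exc:
                raise GlycanParseError(f"{path}, line {lineno}: {exc}") from None
            key = tree.canonical()
            if key not in seen:
                seen.add(key)
                if tree.id is None:
                    tree.id = f"G{len(trees) + 1}"
                trees.append(tree)
    return trees


def write_glycan_db(trees: Iterable[GlycanTree], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in trees:
            fh.write(t.canonical() + (f"\t{t.id}" if t.id else "") + "\n")


@dataclass
class YIonSet:
    """Glycan-part masses of all Y ions of one glycan.

    ``entries`` is a multiset of (glycan-part mass, subtree node count):
    one entry per connected subtree containing the root, plus the empty
    subtree (Y0, mass 0).  Matching uses :attr:`distinct_masses`; the
    multiplicity is retained only for reporting, since a spectrum peak
    cannot distinguish isobaric subtrees.
    """

    entries: list[tuple[float, int]]
    total_mass: float

    @property
    def distinct_masses(self) -> np.ndarray:
        """Sorted unique glycan-part masses (0.01 mDa merge)."""
        masses = sorted(m for m, _ in self.entries)
        out: list[float] = []
        for m in masses:
            if not out or m - out[-1] > 1e-5:
                out.append(m)
        return np.asarray(out)


def enumerate_y_ions(tree: GlycanTree) -> YIonSet:
    """All Y-ion glycan-part masses of ``tree``.

    A Y ion corresponds to a connected subtree containing the root (the
    residues still attached to the peptide after one or more glycosidic
    cleavages), plus Y0 for the loss of the whole glycan.  Computed by
    tree DP: the root-containing subtrees of a node are all ways of
    combining, per child, either nothing or a root-containing subtree of
    that child.
    """

    def subtree_masses(node: GlycanTree) -> list[tuple[float, int]]:
        combos: list[tuple[float, int]] = [(MONOSACCHARIDES[node.symbol], 1)]
        for child in node.children:
            child_opts = [(0.0, 0)] + subtree_masses(child)
            combos = [
                (m + cm, n + cn) for m, n in combos for cm, cn in child_opts
            ]
        return combos

    entries = [(0.0, 0)] + subtree_masses(tree)
    return YIonSet(entries=entries, total_mass=tree.mass)


def core_ion_offsets(composition: GlycanComposition | None = None) -> dict[str, float]:
    """Core-ion offsets, optionally restricted to composition-consistent ions.

    Y3/Y4/Y5 require at least 1/2/3 Hex; the core-fucosylated ions require
    at least one dHex; Y2 and the fucosylated forms require 2 HexNAc.
    Restricting the theoretical core set avoids penalising glycans for
    ions they cannot produce.
    """
    if composition is None:
        return dict(CORE_IONS)
    c = composition
    required = {
        "Y0": True,
        "Y1": c.hexnac >= 1,
        "0,2X0": c.hexnac >= 1,
        "Y2": c.hexnac >= 2,
        "Y3": c.hexnac >= 2 and c.hex >= 1,
        "Y4": c.hexnac >= 2 and c.hex >= 2,
        "Y5": c.hexnac >= 2 and c.hex >= 3,
        "Y-01001": c.hexnac >= 1 and c.dhex >= 1,
        "Y-02001": c.hexnac >= 2 and c.dhex >= 1,
    }
    return {label: off for label, off in CORE_IONS.items() if required[label]}


def core_ion_masses(peptide_backbone_neutral: float) -> dict[str, float]:
    """Neutral masses of the 9 trimannosyl core ions for a backbone mass."""
    if peptide_backbone_neutral <= 0:
        raise ValueError("backbone mass must be positive")
    return {k: peptide_backbone_neutral + v for k, v in CORE_IONS.items()}


def reversed_y_masses(y: YIonSet, total_glycan_mass: float | None = None) -> list[float]:
    """Reverse-decoy masses: entire glycan mass minus each Y-ion mass."""
    total = y.total_mass if total_glycan_mass is None else total_glycan_mass
    if any(m > total + 1e-9 for m, _ in y.entries):
        raise ValueError("Y-ion mass exceeds total glycan mass")
    return [total - m for m, _ in y.entries]
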