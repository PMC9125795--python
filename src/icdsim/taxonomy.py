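"""ICD-style classification taxonomy: a rooted tree of disease classes.

The International Classification of Diseases (ICD) arranges diseases on a
single axis: chapters (e.g. chapter IV, metabolic diseases) contain groups
(e.g. E10-E14, diabetes mellitus), which contain three-character categories
(e.g. E10), which contain four-digit codes (e.g. E10.1).  The ICD itself has
no single top node; this module inserts a synthetic ``ROOT`` above the
chapters so the whole classification is one rooted tree, on which depths,
ancestor chains and least common subsumers are well defined.

Trees are loaded from a generic tab-delimited edge list (the canonical
format, so ICD-9 / ICD-10 / national modifications / toy trees are all
handled uniformly) or from ClaML, the XML dialect in which official ICD
releases are distributed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from lxml import etree

__all__ = [
    "Level",
    "TaxonomyNode",
    "Taxonomy",
    "Resolution",
    "ResolvedCode",
    "TaxonomyError",
    "StructuralError",
    "AmbiguityError",
    "LookupError_",
    "normalize_code",
    "load_taxonomy",
    "save_edge_list",
]

ROOT_CODE = "ROOT"


class TaxonomyError(ValueError):
    """Base class for taxonomy construction and lookup failures."""


class StructuralError(TaxonomyError):
    """The node set does not form a valid rooted tree (cycle, orphan, ...)."""


class AmbiguityError(TaxonomyError):
    """Two distinct nodes normalize to the same lookup key."""


class LookupError_(TaxonomyError):
    """A node or code is not present in the taxonomy."""


class Level(enum.Enum):
    """Hierarchy levels, top to bottom."""

    ROOT = "root"
    CHAPTER = "chapter"
    GROUP = "group"
    CATEGORY = "category"
    CODE = "code"

    @property
    def rank(self) -> int:
        return _LEVEL_RANK[self]


_LEVEL_RANK = {
    Level.ROOT: 0,
    Level.CHAPTER: 1,
    Level.GROUP: 2,
    Level.CATEGORY: 3,
    Level.CODE: 4,
}


class Resolution(enum.Enum):
    EXACT = "exact"
    TRUNCATED_TO_ANCESTOR = "truncated_to_ancestor"
    FAILED = "failed"


@dataclass(frozen=True)
class TaxonomyNode:
    """One class in the taxonomy (a chapter, group, category or code)."""

    code: str
    label: str
    level: Level
    parent_code: str | None  # None only for the root

    def __repr__(self) -> str:  # keep reprs short in error messages
        return f"TaxonomyNode({self.code!r}, level={self.level.value})"


@dataclass(frozen=True)
class ResolvedCode:
    """Outcome of resolving a raw input code against a taxonomy.

    Real-world inputs contain dotted, undotted and over-specific (five-digit)
    variants of the codes a given catalogue actually contains; resolution
    records how far the query had to be massaged to land on a node.
    """

    query: str
    node: TaxonomyNode | None
    resolution: Resolution

    @property
    def ok(self) -> bool:
        return self.resolution is not Resolution.FAILED


def normalize_code(raw: str) -> str:
    """Canonical lookup key for an ICD-style code.

    Uppercases, strips surrounding whitespace and removes the dot between
    the third and fourth character (``"e10.1"`` -> ``"E101"``).  Chapter
    numerals and group ranges such as ``"E10-E14"`` pass through unchanged
    (they carry no dot in that position).
    """
    if not isinstance(raw, str) or not raw.strip():
        raise TaxonomyError("cannot normalize an empty code")
    s = raw.strip().upper()
    if len(s) > 3 and s[3] == ".":
        s = s[:3] + s[4:]
    return s


@dataclass
class Taxonomy:
    """A rooted classification tree keyed by normalized code."""

    nodes: dict[str, TaxonomyNode]
    version_tag: str = "unversioned"
    _parent: dict[str, str | None] = field(default_factory=dict, repr=False)
    _depth: dict[str, int] = field(default_factory=dict, repr=False)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_nodes(cls, nodes: Iterable[TaxonomyNode], version_tag: str = "unversioned") -> "Taxonomy":
        """Build and validate a taxonomy from an iterable of nodes.

        A synthetic root is inserted above any chapters that list no parent
        when the input itself lacks a root node.
        """
        node_list = list(nodes)
        has_root = any(n.level is Level.ROOT for n in node_list)
        if not has_root:
            node_list = [
                TaxonomyNode(ROOT_CODE, "synthetic root", Level.ROOT, None)
            ] + [
                TaxonomyNode(n.code, n.label, n.level, n.parent_code or ROOT_CODE)
                if n.parent_code in (None, "") and n.level is not Level.ROOT
                else n
                for n in node_list
            ]

        keyed: dict[str, TaxonomyNode] = {}
        for n in node_list:
            key = normalize_code(n.code)
            if key in keyed:
                raise AmbiguityError(
                    f"codes {keyed[key].code!r} and {n.code!r} both normalize to {key!r}"
                )
            keyed[key] = n

        tax = cls(nodes=keyed, version_tag=version_tag)
        tax._validate()
        return tax

    def _validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.level is Level.ROOT]
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one root node, found {len(roots)}")
        root = roots[0]
        if root.parent_code not in (None, ""):
            raise StructuralError(f"root node {root.code!r} must not have a parent")

        parent: dict[str, str | None] = {}
        for key, n in self.nodes.items():
            if n.level is Level.ROOT:
                parent[key] = None
                continue
            if n.parent_code in (None, ""):
                raise StructuralError(f"non-root node {n.code!r} has no parent")
            pkey = normalize_code(n.parent_code)
            if pkey not in self.nodes:
                raise StructuralError(
                    f"node {n.code!r} references missing parent {n.parent_code!r}"
                )
            p = self.nodes[pkey]
            if p.level.rank >= n.level.rank:
                raise StructuralError(
                    f"level of {n.code!r} ({n.level.value}) does not descend "
                    f"from its parent {p.code!r} ({p.level.value})"
                )
            parent[key] = pkey
        self._parent = parent

        # Walking parent links must reach the root from every node without
        # revisiting: with a unique root and |edges| = |nodes|-1 this also
        # rules out cycles and disconnected components.
        depth: dict[str, int] = {normalize_code(root.code): 0}

        def _depth_of(key: str, trail: set[str]) -> int:
            if key in depth:
                return depth[key]
            if key in trail:
                raise StructuralError(f"cycle detected at {self.nodes[key].code!r}")
            trail.add(key)
            d = _depth_of(parent[key], trail) + 1  # type: ignore[arg-type]
            depth[key] = d
            return d

        for key in self.nodes:
            _depth_of(key, set())
        self._depth = depth

    # -- basic queries ----------------------------------------------------

    @property
    def root(self) -> TaxonomyNode:
        return next(n for n in self.nodes.values() if n.level is Level.ROOT)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, code: str) -> bool:
        return normalize_code(code) in self.nodes

    def __iter__(self) -> Iterator[TaxonomyNode]:
        return iter(self.nodes.values())

    def get(self, code: str) -> TaxonomyNode:
        key = normalize_code(code)
        try:
            return self.nodes[key]
        except KeyError:
            raise LookupError_(f"code {code!r} not in taxonomy") from None

    def parent(self, node: TaxonomyNode) -> TaxonomyNode | None:
        pkey = self._parent[self._key(node)]
        return None if pkey is None else self.nodes[pkey]

    def children(self, node: TaxonomyNode) -> list[TaxonomyNode]:
        key = self._key(node)
        return [self.nodes[k] for k, p in self._parent.items() if p == key]

    def leaves(self) -> list[TaxonomyNode]:
        """Nodes with no children, in insertion order."""
        parents = set(p for p in self._parent.values() if p is not None)
        return [n for k, n in self.nodes.items() if k not in parents]

    def _key(self, node: TaxonomyNode) -> str:
        key = normalize_code(node.code)
        if key not in self.nodes:
            raise LookupError_(f"node {node.code!r} not in taxonomy")
        return key

    # -- structural queries ------------------------------------------------

    def depth(self, node: TaxonomyNode) -> int:
        """Number of edges from the root down to *node* (root has depth 0)."""
        return self._depth[self._key(node)]

    def ancestors(self, node: TaxonomyNode) -> list[TaxonomyNode]:
        """Ancestor-or-self chain from *node* up to the root (inclusive)."""
        chain = [node]
        key = self._key(node)
        while (pkey := self._parent[key]) is not None:
            chain.append(self.nodes[pkey])
            key = pkey
        return chain

    def lca(self, a: TaxonomyNode, b: TaxonomyNode) -> TaxonomyNode:
        """Least common subsumer: the deepest ancestor-or-self of both nodes."""
        seen = {normalize_code(n.code) for n in self.ancestors(a)}
        for n in self.ancestors(b):
            if normalize_code(n.code) in seen:
                return n
        raise StructuralError("nodes share no common ancestor")  # unreachable in a tree

    def resolve(self, raw: str) -> ResolvedCode:
        """Resolve a raw input code, truncating over-specific codes.

        Exact match on the normalized key wins; failing that, the key is
        shortened one character at a time (a five-digit ``E10.11`` falls back
        to ``E10.1``, then ``E10``, ...) and the first hit is reported as
        ``truncated_to_ancestor``.  A miss is encoded in the result rather
        than raised, so batch scoring can skip and log.
        """
        key = normalize_code(raw)
        if key in self.nodes:
            return ResolvedCode(raw, self.nodes[key], Resolution.EXACT)
        trunc = key[:-1]
        while trunc:
            if trunc in self.nodes:
                return ResolvedCode(raw, self.nodes[trunc], Resolution.TRUNCATED_TO_ANCESTOR)
            trunc = trunc[:-1]
        return ResolvedCode(raw, None, Resolution.FAILED)


# ---------------------------------------------------------------------------
# Loaders / writers
# ---------------------------------------------------------------------------

_EDGE_LIST_COLUMNS = ["code", "parent", "level", "label"]


def _parse_edge_list(lines: Iterable[str]) -> Iterator[TaxonomyNode]:
    it = iter(lines)
    try:
        header = next(it)
    except StopIteration:
        raise StructuralError("empty edge-list file") from None
    cols = [c.strip().lower() for c in header.rstrip("\n").split("\t")]
    if cols[: len(_EDGE_LIST_COLUMNS)] != _EDGE_LIST_COLUMNS:
        raise StructuralError(
            f"edge-list header must be {_EDGE_LIST_COLUMNS!r}, got {cols!r}"
        )
    for lineno, line in enumerate(it, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise StructuralError(f"edge-list line {lineno}: expected >=3 fields")
        code, parent, level = parts[0], parts[1], parts[2]
        label = parts[3] if len(parts) > 3 else ""
        try:
            lv = Level(level.strip().lower())
        except ValueError:
            raise StructuralError(
                f"edge-list line {lineno}: unknown level {level!r}"
            ) from None
        yield TaxonomyNode(code.strip(), label, lv, parent.strip() or None)


# ClaML Class/@kind values seen in official ICD releases mapped onto levels.
# Three-character rubrics and their four-digit subdivisions both carry
# kind="category" in ClaML; the tree position (parent's level) disambiguates.
_CLAML_KIND = {"chapter": Level.CHAPTER, "block": Level.GROUP, "category": None}


def _parse_claml(source: str | Path | IO) -> Iterator[TaxonomyNode]:
    tree = etree.parse(source if not isinstance(source, Path) else str(source))
    classes = tree.findall(".//Class")
    if not classes:
        raise StructuralError("no Class elements found in ClaML document")
    kind_of: dict[str, str] = {}
    super_of: dict[str, str | None] = {}
    label_of: dict[str, str] = {}
    for cl in classes:
        code = cl.get("code")
        kind = (cl.get("kind") or "").lower()
        if code is None:
            continue
        sup = cl.find("SuperClass")
        super_of[code] = sup.get("code") if sup is not None else None
        kind_of[code] = kind
        rubric = cl.find("Rubric[@kind='preferred']/Label")
        if rubric is None:
            rubric = cl.find("Rubric/Label")
        label_of[code] = "".join(rubric.itertext()).strip() if rubric is not None else ""

    def level_of(code: str) -> Level:
        kind = kind_of.get(code, "")
        mapped = _CLAML_KIND.get(kind)
        if mapped is not None:
            return mapped
        # kind="category": a category whose parent is also a category is a
        # four-digit code; one hanging under a block is a three-char category.
        parent = super_of.get(code)
        if parent is not None and kind_of.get(parent) == "category":
            return Level.CODE
        return Level.CATEGORY

    for code in kind_of:
        yield TaxonomyNode(code, label_of.get(code, ""), level_of(code), super_of.get(code))


def load_taxonomy(
    source: str | Path | IO,
    format: str = "edge_list",
    version_tag: str | None = None,
) -> Taxonomy:
    """Load a taxonomy from an edge-list or ClaML file.

    Parameters
    ----------
    source
        Path or open text stream.
    format
        ``"edge_list"`` (tab-delimited ``code parent level label``) or
        ``"claml"`` (ICD distribution XML).
    version_tag
        Free-text tag stored on the taxonomy (defaults to the file stem).
    """
    if format not in ("edge_list", "claml"):
        raise TaxonomyError(f"unknown taxonomy format {format!r}")
    tag = version_tag
    if tag is None:
        tag = Path(source).stem if isinstance(source, (str, Path)) else "stream"
    if format == "edge_list":
        if isinstance(source, (str, Path)):
            with open(source, encoding="utf-8") as fh:
                nodes = list(_parse_edge_list(fh))
        else:
            nodes = list(_parse_edge_list(source))
    else:
        nodes = list(_parse_claml(source))
    return Taxonomy.from_nodes(nodes, version_tag=tag)


def save_edge_list(taxonomy: Taxonomy, path: str | Path) -> None:
    """Write the taxonomy back out in the canonical edge-list format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_EDGE_LIST_COLUMNS) + "\n")
        for node in taxonomy:
            fh.write(
                f"{node.code}\t{node.parent_code or ''}\t{node.level.value}\t{node.label}\n"
            )
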