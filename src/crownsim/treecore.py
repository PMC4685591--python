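"""Time-calibrated bifurcating trees with extinct and extant tips.

The tree model follows the convention of a birth-death process observed over a
fixed window: time runs forward from the origin (t = 0) to the present
(t = T).  A tree begins with a split into exactly two *origin lineages* at
time 0 (the origin of the total group).  A speciating lineage terminates and
is replaced by two daughters, so every internal lineage has exactly two
children and its death time equals its daughters' birth time.  Extant status
is an explicit flag, never inferred from floating-point equality with T.

Newick serialization encodes extant status in a tip-label suffix: ``|A``
(alive at the present) or ``|X`` (extinct).  Branch lengths are forward time
durations, so node times are recovered by summing branch lengths from the
root, which sits at time 0.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

import dendropy

from .errors import (
    NewickParseError,
    TreeValidationError,
    UnknownFixtureError,
)

#: Sentinel returned by MRCA queries when the common ancestor is the initial
#: split itself (time 0): the two origin lineages have no ancestral *lineage*
#: in common, only the origin event.
ORIGIN = "origin"

#: Node-time agreement tolerance for round-trips (time units).
TIME_TOL = 1e-9

_SUFFIX_EXTANT = "|A"
_SUFFIX_EXTINCT = "|X"


@dataclass
class Lineage:
    """One lineage: a single branch living from ``birth_time`` to ``death_time``.

    ``parent_id`` is ``None`` for the two origin lineages.  A lineage with
    children speciated at ``death_time`` (bifurcation: the parent is replaced
    by its two daughters).  ``extant`` marks survival to the present.
    """

    id: int
    parent_id: Optional[int]
    birth_time: float
    death_time: float
    extant: bool
    child_ids: list[int] = field(default_factory=list)
    label: Optional[str] = None

    @property
    def is_tip(self) -> bool:
        return not self.child_ids


@dataclass
class PhyloTree:
    """A complete (extinct + extant) time-calibrated tree over [0, T].

    ``origin_ids`` are the two lineages born at time 0 from the initial split.
    """

    lineages: dict[int, Lineage]
    present_time: float
    origin_ids: tuple[int, int]

    @property
    def origin_time(self) -> float:
        return 0.0

    def __len__(self) -> int:
        return len(self.lineages)

    def tips(self) -> Iterator[Lineage]:
        return (l for l in self.lineages.values() if l.is_tip)

    def extant_tips(self) -> list[Lineage]:
        return [l for l in self.lineages.values() if l.extant]

    @property
    def n_extant(self) -> int:
        return sum(1 for l in self.lineages.values() if l.extant)

    def ancestor_path(self, lineage_id: int) -> list[int]:
        """Root-ward walk: the lineage itself, then its ancestors up to an
        origin lineage (inclusive)."""
        if lineage_id not in self.lineages:
            raise TreeValidationError(f"unknown lineage id: {lineage_id!r}")
        path = []
        cur: Optional[int] = lineage_id
        while cur is not None:
            path.append(cur)
            cur = self.lineages[cur].parent_id
        return path

    def toposort(self) -> list[int]:
        """Lineage ids, parents before children."""
        order: list[int] = []
        stack = list(self.origin_ids)
        while stack:
            lid = stack.pop()
            order.append(lid)
            stack.extend(self.lineages[lid].child_ids)
        return order

    def validate(self) -> None:
        """Check structural invariants; raise TreeValidationError on failure."""
        roots = [l for l in self.lineages.values() if l.parent_id is None]
        if len(roots) != 2:
            raise TreeValidationError(
                f"expected exactly 2 origin lineages, found {len(roots)}"
            )
        for r in roots:
            if abs(r.birth_time) > TIME_TOL:
                raise TreeValidationError(
                    f"origin lineage {r.id} born at {r.birth_time}, expected 0"
                )
        order = self.toposort()
        if len(order) != len(self.lineages):
            raise TreeValidationError("parent graph is not connected to the origin pair")
        T = self.present_time
        for lin in self.lineages.values():
            if lin.birth_time > T + TIME_TOL:
                raise TreeValidationError(f"lineage {lin.id} born after the present")
            if lin.death_time < lin.birth_time - TIME_TOL:
                raise TreeValidationError(f"lineage {lin.id} dies before its birth")
            if lin.extant and lin.child_ids:
                raise TreeValidationError(f"extant lineage {lin.id} has children")
            if lin.child_ids:
                if len(lin.child_ids) != 2:
                    raise TreeValidationError(
                        f"lineage {lin.id} has {len(lin.child_ids)} children; "
                        "bifurcation requires exactly 2"
                    )
                for c in lin.child_ids:
                    child = self.lineages[c]
                    if abs(child.birth_time - lin.death_time) > TIME_TOL:
                        raise TreeValidationError(
                            f"child {c} born at {child.birth_time}, parent {lin.id} "
                            f"speciated at {lin.death_time}"
                        )


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _split_label(raw: Optional[str]) -> tuple[Optional[str], Optional[bool]]:
    """Split a ``name|A`` / ``name|X`` label into (name, extant or None)."""
    if raw is None:
        return None, None
    if raw.endswith(_SUFFIX_EXTANT):
        return raw[: -len(_SUFFIX_EXTANT)], True
    if raw.endswith(_SUFFIX_EXTINCT):
        return raw[: -len(_SUFFIX_EXTINCT)], False
    return raw, None


def read_newick(
    text: str,
    *,
    present_time: Optional[float] = None,
    default_extant: Optional[bool] = None,
) -> PhyloTree:
    """Parse a Newick string with branch lengths into a :class:`PhyloTree`.

    The Newick root is the virtual origin at time 0 and must have exactly two
    children (the origin lineages).  Tip status is read from the ``|A``/``|X``
    label suffix; tips without a suffix take ``default_extant`` if given,
    otherwise raise.  ``present_time`` defaults to the (common) time of the
    extant tips, or the latest tip time when no tip is extant.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    root = dtree.seed_node
    if root.edge.length not in (None, 0, 0.0):
        raise TreeValidationError(
            f"root edge length must be absent or 0, got {root.edge.length}"
        )
    if len(root.child_nodes()) != 2:
        raise TreeValidationError(
            f"root must split into exactly 2 origin lineages, "
            f"found {len(root.child_nodes())}"
        )

    lineages: dict[int, Lineage] = {}
    next_id = 0
    # Preorder walk assigning ids so parents always precede children.
    stack: list[tuple[dendropy.Node, Optional[int], float]] = [
        (child, None, 0.0) for child in reversed(root.child_nodes())
    ]
    origin_ids: list[int] = []
    while stack:
        node, parent_id, birth = stack.pop()
        blen = node.edge.length
        if blen is None:
            raise TreeValidationError("branch lengths are mandatory")
        if blen < 0:
            raise TreeValidationError(f"negative branch length: {blen}")
        death = birth + blen
        raw = node.taxon.label if node.taxon is not None else node.label
        name, status = _split_label(raw)
        children = node.child_nodes()
        if children and len(children) != 2:
            raise TreeValidationError(
                f"polytomy at node {raw!r}: {len(children)} children"
            )
        if not children:
            if status is None:
                status = default_extant
            if status is None:
                raise NewickParseError(
                    f"tip {raw!r} lacks an |A/|X status suffix and no "
                    "default_extant was given"
                )
        else:
            status = False  # internal lineages died at their speciation
        lid = next_id
        next_id += 1
        lineages[lid] = Lineage(
            id=lid,
            parent_id=parent_id,
            birth_time=birth,
            death_time=death,
            extant=bool(status),
            label=name,
        )
        if parent_id is None:
            origin_ids.append(lid)
        else:
            lineages[parent_id].child_ids.append(lid)
        for child in reversed(children):
            stack.append((child, lid, death))

    extant_times = [l.death_time for l in lineages.values() if l.extant]
    if present_time is None:
        if extant_times:
            present_time = max(extant_times)
        else:
            present_time = max(l.death_time for l in lineages.values())
    for t in extant_times:
        if abs(t - present_time) > TIME_TOL:
            raise TreeValidationError(
                f"extant tip at time {t} does not reach the present {present_time}"
            )
    # Snap extant tips exactly to T so downstream arithmetic is exact.
    for lin in lineages.values():
        if lin.extant:
            lin.death_time = present_time

    tree = PhyloTree(
        lineages=lineages,
        present_time=present_time,
        origin_ids=(origin_ids[0], origin_ids[1]),
    )
    tree.validate()
    return tree


def _fmt_len(x: float) -> str:
    """Canonical branch-length format: shortest exact repr of the float."""
    return repr(float(x))


def write_newick(tree: PhyloTree, extant_only: bool = False) -> str:
    """Serialize a tree to Newick with ``|A``/``|X`` tip-status suffixes.

    With ``extant_only``, extinct lineages are pruned and unary nodes are
    suppressed while path lengths from the origin are preserved.  If a whole
    origin-lineage subtree is extinct the output is the surviving subtree,
    carrying its distance from the origin as a root edge length.
    """
    keep: Optional[set[int]] = None
    if extant_only:
        keep = set()
        for lid in reversed(tree.toposort()):
            lin = tree.lineages[lid]
            if lin.extant or any(c in keep for c in lin.child_ids):
                keep.add(lid)
        if not keep:
            raise TreeValidationError("cannot prune a tree with no extant tips")

    def node_label(lin: Lineage, tip: bool) -> str:
        name = lin.label if lin.label is not None else f"L{lin.id}"
        if tip:
            return name + (_SUFFIX_EXTANT if lin.extant else _SUFFIX_EXTINCT)
        return name

    def kept_children(lid: int) -> list[int]:
        cs = tree.lineages[lid].child_ids
        if keep is not None:
            cs = [c for c in cs if c in keep]
        return cs

    def skip_unary(lid: int) -> int:
        # After pruning, a node with a single kept child is suppressed by
        # descending to the first tip or kept bifurcation.
        cs = kept_children(lid)
        while len(cs) == 1:
            lid = cs[0]
            cs = kept_children(lid)
        return lid

    def render(root_id: int) -> str:
        # Iterative post-order rendering (simulated trees can be deep).
        out: dict[int, str] = {}
        root_eff = skip_unary(root_id)
        stack: list[tuple[int, float, bool]] = [(root_eff, 0.0, False)]
        while stack:
            lid, start, expanded = stack.pop()
            lin = tree.lineages[lid]
            cs = [skip_unary(c) for c in kept_children(lid)]
            if not cs:
                out[lid] = f"{node_label(lin, tip=True)}:{_fmt_len(lin.death_time - start)}"
            elif not expanded:
                stack.append((lid, start, True))
                for c in reversed(cs):
                    stack.append((c, lin.death_time, False))
            else:
                inner = ",".join(out[c] for c in cs)
                out[lid] = (
                    f"({inner}){node_label(lin, tip=False)}"
                    f":{_fmt_len(lin.death_time - start)}"
                )
        return out[root_eff]

    roots = [r for r in tree.origin_ids if keep is None or r in keep]
    if len(roots) == 2:
        return f"({render(roots[0])},{render(roots[1])});"
    return f"{render(roots[0])};"


# ---------------------------------------------------------------------------
# Brute-force MRCA oracle
# ---------------------------------------------------------------------------


def mrca_oracle(
    tree: PhyloTree, tip_ids: Iterable[int]
) -> Union[int, str]:
    """Most recent common ancestor by explicit root-ward path intersection.

    Deliberately brute force: each tip's full ancestor path is materialized
    and the paths intersected, so this serves as an independent check on the
    fast crown-finding code.  Returns :data:`ORIGIN` when the tips span both
    origin lineages (their only common ancestor is the initial split at
    time 0); a single tip is its own MRCA.
    """
    ids = list(tip_ids)
    if not ids:
        raise TreeValidationError("tip_ids must be nonempty")
    paths = [set(tree.ancestor_path(t)) for t in ids]
    common = set.intersection(*paths)
    if not common:
        return ORIGIN
    # Ancestors of any one tip form a chain, so the deepest common node is
    # simply the one born latest.
    return max(common, key=lambda lid: tree.lineages[lid].birth_time)


# ---------------------------------------------------------------------------
# Fixture catalogue
# ---------------------------------------------------------------------------

_FIXTURE_PKG = "crownsim.fixtures"


def _catalogue_rows() -> dict[str, dict]:
    res = importlib.resources.files(_FIXTURE_PKG) / "catalogue.tsv"
    rows: dict[str, dict] = {}
    lines = res.read_text().strip().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        fields = line.split("\t")
        fields += [""] * (len(header) - len(fields))  # undefined-crown rows
        rec = dict(zip(header, fields))
        rows[rec["name"]] = rec
    return rows


def fixture_names() -> list[str]:
    return sorted(_catalogue_rows())


def fixture_info(name: str) -> dict:
    """Side-car metadata for a fixture: tip counts, crown node and crown time.

    ``crown_time``/``crown_fraction`` are ``None`` when the crown is undefined
    (fewer than two extant tips).
    """
    rows = _catalogue_rows()
    if name not in rows:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; valid names: {', '.join(sorted(rows))}"
        )
    rec = rows[name]
    return {
        "name": name,
        "present_time": float(rec["present_time"]),
        "n_tips": int(rec["n_tips"]),
        "n_extant": int(rec["n_extant"]),
        "crown_node": rec["crown_node"] or None,
        "crown_time": float(rec["crown_time"]) if rec["crown_time"] else None,
        "crown_fraction": float(rec["crown_fraction"]) if rec["crown_fraction"] else None,
    }


def make_fixture(name: str) -> PhyloTree:
    """Build a catalogued fixture tree with a documented crown node and time."""
    info = fixture_info(name)
    res = importlib.resources.files(_FIXTURE_PKG) / f"{name}.nwk"
    return read_newick(res.read_text().strip(), present_time=info["present_time"])
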