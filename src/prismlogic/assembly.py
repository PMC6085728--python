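"""Face motifs, the triangular prism, and structural-state classification.

A :class:`Complex` is a set of strand *instances* plus a set of bonds
between domain instances.  Bonds are validated (complementary names,
equal lengths, at most one bond per domain instance).  The rigid 21-bp
face sides are marked as non-displaceable; everything the reaction
engine may rewrite lives on the vertical edges and the input strands.

The prism's reachable structural states are the closed prism, the three
mono-SD states (one vertical edge displaced), the three di-SD states
(two edges displaced, faces still linked by one 10-bp duplex), and the
tri-SD state in which the two faces have separated.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple, Union

from .errors import AssemblyError, ClassificationError
from .strand_model import ArchitectureSpec, Strand, build_canonical_strands

__all__ = [
    "DomainInstance",
    "Complex",
    "PrismState",
    "assemble_face",
    "assemble_prism",
    "build_prism",
    "prism_state",
]

#: (strand instance id, domain index)
DomainInstance = Tuple[int, int]

EDGES = (1, 2, 3)


@dataclass
class Complex:
    """Strand instances plus a domain-level bond set."""

    strands: Dict[int, Strand] = field(default_factory=dict)
    bonds: Dict[DomainInstance, DomainInstance] = field(default_factory=dict)
    rigid: set = field(default_factory=set)
    #: assembly-time bonds allowed to re-form once both partners are free
    native: set = field(default_factory=set)
    meta: Dict[str, object] = field(default_factory=dict)

    # -- construction -----------------------------------------------------

    def add_strand(self, inst_id: int, strand: Strand) -> None:
        if inst_id in self.strands:
            raise AssemblyError(f"duplicate strand instance id {inst_id}")
        self.strands[inst_id] = strand

    def domain_at(self, di: DomainInstance):
        sid, idx = di
        return self.strands[sid].domains[idx]

    def add_bond(self, a: DomainInstance, b: DomainInstance, rigid: bool = False) -> None:
        da, db = self.domain_at(a), self.domain_at(b)
        if da.partner_name != db.name:
            raise AssemblyError(
                f"cannot bond non-complementary domains {da.name!r} / {db.name!r}"
            )
        if da.length != db.length:
            raise AssemblyError(
                f"cannot bond domains of unequal length {da.name!r} / {db.name!r}"
            )
        if a in self.bonds or b in self.bonds:
            raise AssemblyError("domain instance already bonded")
        self.bonds[a] = b
        self.bonds[b] = a
        if rigid:
            self.rigid.add(frozenset((a, b)))

    def remove_bond(self, a: DomainInstance) -> None:
        b = self.bonds.pop(a)
        del self.bonds[b]
        self.rigid.discard(frozenset((a, b)))

    def is_paired(self, di: DomainInstance) -> bool:
        return di in self.bonds

    # -- queries ----------------------------------------------------------

    @property
    def strand_names(self) -> Tuple[str, ...]:
        return tuple(sorted(s.name for s in self.strands.values()))

    @property
    def total_paired_nt(self) -> int:
        return sum(self.domain_at(a).length for a in self.bonds) // 2

    def unpaired_runs(self, sid: int) -> List[Tuple[int, int]]:
        """Maximal runs of consecutive unpaired domains on one strand,
        as inclusive (start, stop) index pairs."""
        runs, start = [], None
        n = len(self.strands[sid].domains)
        for i in range(n):
            if (sid, i) not in self.bonds:
                if start is None:
                    start = i
            elif start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, n - 1))
        return runs

    def components(self) -> List[List[int]]:
        """Connected components of the strand graph (bonds as edges)."""
        adj: Dict[int, set] = {sid: set() for sid in self.strands}
        for a, b in self.bonds.items():
            adj[a[0]].add(b[0])
        seen, comps = set(), []
        for sid in sorted(self.strands):
            if sid in seen:
                continue
            stack, comp = [sid], []
            seen.add(sid)
            while stack:
                cur = stack.pop()
                comp.append(cur)
                for nb in adj[cur]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            comps.append(sorted(comp))
        return comps

    def subcomplex(self, sids: Iterable[int]) -> "Complex":
        keep = set(sids)
        sub = Complex(
            strands={sid: self.strands[sid] for sid in keep},
            meta=dict(self.meta),
        )
        for a, b in self.bonds.items():
            if a[0] in keep and a < b:
                sub.bonds[a] = b
                sub.bonds[b] = a
                if frozenset((a, b)) in self.rigid:
                    sub.rigid.add(frozenset((a, b)))
        for pair in self.native:
            if all(di[0] in keep for di in pair):
                sub.native.add(pair)
        return sub

    def renumbered(self, id_map: Mapping[int, int]) -> "Complex":
        out = Complex(meta=dict(self.meta))
        for sid, s in self.strands.items():
            out.strands[id_map[sid]] = s
        for a, b in self.bonds.items():
            na, nb = (id_map[a[0]], a[1]), (id_map[b[0]], b[1])
            out.bonds[na] = nb
            if frozenset((a, b)) in self.rigid:
                out.rigid.add(frozenset((na, nb)))
        for pair in self.native:
            out.native.add(frozenset((id_map[di[0]], di[1]) for di in pair))
        return out

    def merged_with(self, other: "Complex") -> "Complex":
        out = Complex(meta={**self.meta, **other.meta})
        for src in (self, other):
            for sid, s in src.strands.items():
                out.add_strand(sid, s)
            for a, b in src.bonds.items():
                out.bonds[a] = b
            out.rigid |= src.rigid
            out.native |= src.native
        return out

    def label(self) -> str:
        return "+".join(self.strand_names)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        bonds = sorted(
            {tuple(sorted((a, b))) for a, b in self.bonds.items()}
        )
        return {
            "strands": {str(sid): s.name for sid, s in sorted(self.strands.items())},
            "bonds": [
                {
                    "a": list(a),
                    "b": list(b),
                    "rigid": frozenset((a, b)) in self.rigid,
                }
                for a, b in bonds
            ],
            "meta": {k: v for k, v in self.meta.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def edge_list(self) -> List[Tuple[str, str]]:
        """Strand-level graph edges for visualization."""
        out = set()
        for a, b in self.bonds.items():
            n1 = f"{self.strands[a[0]].name}#{a[0]}"
            n2 = f"{self.strands[b[0]].name}#{b[0]}"
            out.add(tuple(sorted((n1, n2))))
        return sorted(out)


@dataclass(frozen=True)
class PrismState:
    """Which vertical edges are displaced and whether the faces are
    still joined by at least one edge duplex."""

    opened_edges: FrozenSet[int]
    connected: bool

    def __post_init__(self) -> None:
        if (self.opened_edges == frozenset(EDGES)) != (not self.connected):
            raise ClassificationError(
                "faces are disconnected exactly when all three edges are open"
            )

    @property
    def label(self) -> str:
        if not self.opened_edges:
            return "closed"
        tags = "/".join(f"C{i}" for i in sorted(self.opened_edges))
        n = len(self.opened_edges)
        return {1: "mono-SD", 2: "di-SD", 3: "tri-SD"}[n] + f"({tags})"

    @classmethod
    def closed(cls) -> "PrismState":
        return cls(frozenset(), True)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _idx(strand: Strand, name: str) -> int:
    for i, d in enumerate(strand.domains):
        if d.name == name:
            return i
    raise AssemblyError(f"strand {strand.name!r} has no domain {name!r}")


def assemble_face(
    strands: Union[Mapping[str, Strand], ArchitectureSpec],
    face: str,
    start_id: int = 0,
) -> Complex:
    """Assemble one triangular face motif (``"A"`` or ``"B"``).

    Returns a single connected complex of four strands (L plus three
    shorts) whose three sides are rigid 21-bp duplexes and whose three
    vertex tails dangle unpaired.  The two termini of L meet in the
    middle of the L/A2 (or L/B2) side, leaving one backbone nick there.
    """
    if isinstance(strands, ArchitectureSpec):
        strands = build_canonical_strands(strands)[1]
    if face not in ("A", "B"):
        raise AssemblyError(f"face must be 'A' or 'B', got {face!r}")
    names = ["L"] + [f"{face}{i}" for i in EDGES]
    for n in names:
        if n not in strands:
            raise AssemblyError(f"missing strand {n!r} for face {face}")
    c = Complex(meta={"face": face, "nicks": (f"L/{face}2",)})
    ids = {}
    for off, n in enumerate(names):
        ids[n] = start_id + off
        c.add_strand(start_id + off, strands[n])
    L = strands["L"]
    s1, s2 = strands[f"{face}1"], strands[f"{face}2"]
    s3 = strands[f"{face}3"]
    c.add_bond((ids["L"], _idx(L, "s1")), (ids[f"{face}1"], _idx(s1, "s1*")), rigid=True)
    c.add_bond((ids["L"], _idx(L, "s3")), (ids[f"{face}3"], _idx(s3, "s3*")), rigid=True)
    c.add_bond((ids["L"], _idx(L, "s2a")), (ids[f"{face}2"], _idx(s2, "s2a*")), rigid=True)
    c.add_bond((ids["L"], _idx(L, "s2b")), (ids[f"{face}2"], _idx(s2, "s2b*")), rigid=True)
    return c


#: For each vertical edge: (A strand, A tail domains, B strand, B stem domains)
_EDGE_PAIRING = {
    1: ("A1", ("e1",), "B1", ("e1*",)),
    2: ("A2", ("e2a", "e2b"), "B2", ("e2a*", "e2b*")),
    3: ("A3", ("t2*", "e2a"), "B3", ("t2", "e2a*")),
}


def assemble_prism(face_a: Complex, face_b: Complex) -> Complex:
    """Hetero-dimerize the two face motifs into the closed prism.

    Each vertical edge is the 10-bp duplex of an A tail with the inner
    part of the corresponding B tail; the 6-nt toeholds at the B-tail
    termini stay exposed.
    """
    if face_a.meta.get("face") != "A" or face_b.meta.get("face") != "B":
        raise AssemblyError("assemble_prism expects a face-A and a face-B complex")
    clash = set(face_a.strands) & set(face_b.strands)
    if clash:
        next_id = max(face_a.strands) + 1
        id_map = {sid: next_id + i for i, sid in enumerate(sorted(face_b.strands))}
        face_b = face_b.renumbered(id_map)
    prism = face_a.merged_with(face_b)
    prism.meta = {"assembly": "prism", "nicks": ("L/A2", "L/B2")}
    by_name: Dict[str, int] = {}
    for sid, s in prism.strands.items():
        by_name.setdefault(s.name, sid)
    a_ids = {n: sid for sid, s in face_a.strands.items() for n in [s.name]}
    b_ids = {n: sid for sid, s in face_b.strands.items() for n in [s.name]}
    for edge, (an, a_doms, bn, b_doms) in _EDGE_PAIRING.items():
        sa, sb = prism.strands[a_ids[an]], prism.strands[b_ids[bn]]
        for da, db in zip(a_doms, b_doms):
            pa = (a_ids[an], _idx(sa, da))
            pb = (b_ids[bn], _idx(sb, db))
            try:
                prism.add_bond(pa, pb)
            except AssemblyError as exc:
                raise AssemblyError(f"tail mismatch on edge {edge}: {exc}") from exc
            prism.native.add(frozenset((pa, pb)))
    return prism


def build_prism(
    strands: Union[Mapping[str, Strand], ArchitectureSpec, None] = None,
) -> Complex:
    """Convenience: canonical strands -> face A + face B -> closed prism."""
    if strands is None or isinstance(strands, ArchitectureSpec):
        strands = build_canonical_strands(strands or ArchitectureSpec())[1]
    fa = assemble_face(strands, "A", start_id=0)
    fb = assemble_face(strands, "B", start_id=4)
    return assemble_prism(fa, fb)


def _edge_closed(c: Complex, edge: int) -> bool:
    an, a_doms, bn, b_doms = _EDGE_PAIRING[edge]
    a_ids = [sid for sid, s in c.strands.items() if s.name == an]
    b_ids = [sid for sid, s in c.strands.items() if s.name == bn]
    if not a_ids or not b_ids:
        return False
    for aid in a_ids:
        sa = c.strands[aid]
        ok = True
        for dn in a_doms:
            di = (aid, _idx(sa, dn))
            partner = c.bonds.get(di)
            if partner is None or c.strands[partner[0]].name != bn:
                ok = False
                break
        if ok:
            return True
    return False


def prism_state(c: Complex, partner: Optional[Complex] = None) -> PrismState:
    """Classify a prism-derived complex into its canonical state.

    ``c`` must contain the face-A strands (A1-A3).  After a tri-SD
    deconstruction the face-B strands live in a separate complex; pass
    it as ``partner`` or omit it — either way the state is reported as
    disconnected.
    """
    names = set(s.name for s in c.strands.values())
    if not {"A1", "A2", "A3"} <= names:
        raise ClassificationError(
            "complex is not prism-derived (face-A strands A1-A3 not found)"
        )
    opened = frozenset(e for e in EDGES if not _edge_closed(c, e))
    connected = opened != frozenset(EDGES)
    return PrismState(opened, connected)
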