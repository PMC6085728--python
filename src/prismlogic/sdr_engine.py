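"""Deterministic domain-level strand-displacement semantics.

The engine reduces a mixture of complexes and free strands to a fixed
point using four rules, applied in strict priority order:

``fold``
    Every free strand with a hairpin declaration folds first; the stem
    pairs intramolecularly and the caged domains become unavailable for
    intermolecular initiation.
``sequester``
    Free strands that are mutually complementary pair off in solution
    (descending pairing gain).  A strand captured in such a solution
    duplex is wholly inert toward complexes, and equimolar partners
    annihilate pairwise.  This encodes the experimental observation that
    complementary inputs bind each other preferentially instead of
    invading the prism.
``reclose``
    Unpaired complementary domains that are co-localized in the same
    complex re-pair (intramolecular zipping).  This is what restores the
    closed prism after an erase strand strips an opener off an edge.
``invade``
    Toehold-mediated strand displacement: a free, uncaged segment whose
    domains are the reverse complement of a contiguous run on a complex
    strand binds the run's unpaired stretch (>= ``min_toehold`` nt) and
    displaces every incumbent paired inside the run.  Invasions that
    would leave an incumbent partially displaced (its duplex continues
    beyond the run) are rejected: such toehold-exchange intermediates
    stall and revert.  Among applicable invasions the engine applies the
    one with the highest pairing gain, ties broken lexicographically.

There are no rate constants and no stochastic trajectories: the model
targets endpoint measurements (fluorescence after a fixed incubation),
where every applicable displacement has run to completion.  Inputs are
treated as present in excess over the prism (default 5 copies per input
species against one prism, matching a 165 nM : 33 nM ratio), while
sequestration annihilates equimolar input pairs completely.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

from .assembly import Complex, DomainInstance
from .errors import EngineError
from .strand_model import Strand

__all__ = [
    "Reaction",
    "SpeciesEntry",
    "ReactionSystem",
    "InvasionCandidate",
    "fold_hairpins",
    "resolve_solution_hybridization",
    "enumerate_invasions",
    "react_to_fixed_point",
    "erase",
]

DEFAULT_EXCESS = 5  # input copies per prism copy (165 nM vs 33 nM)


@dataclass(frozen=True)
class Reaction:
    """One applied (or attempted) reaction, for the audit trace."""

    rule: str
    reactants: Tuple[str, ...]
    products: Tuple[str, ...]
    pairing_gain: int
    note: str = ""

    def to_record(self) -> dict:
        return {
            "rule": self.rule,
            "reactants": list(self.reactants),
            "products": list(self.products),
            "pairing_gain": self.pairing_gain,
            "note": self.note,
        }


@dataclass
class SpeciesEntry:
    complex: Complex
    count: int
    inert: bool = False


@dataclass(frozen=True)
class InvasionCandidate:
    """A single applicable toehold-mediated displacement."""

    gain: int
    invader_label: str
    target_label: str
    target_entry: int
    target_sid: int
    run: Tuple[int, int]            # inclusive domain-index range on the target strand
    source_entry: Optional[int]     # None if the invader is a free strand
    source_name: str                # free-strand name, or strand name within source complex
    source_sid: Optional[int]
    invader_start: int              # first invader domain index of the pairing

    @property
    def sort_key(self):
        return (
            -self.gain,
            self.invader_label,
            self.target_label,
            self.target_sid,
            self.run,
            self.invader_start,
        )


class ReactionSystem:
    """A mixture of complexes and free strands with counted copies."""

    def __init__(self, min_toehold: int = 2, sequester_min_nt: Optional[int] = None):
        self.min_toehold = int(min_toehold)
        #: minimum duplex length for solution-phase sequestration
        self.sequester_min_nt = (
            self.min_toehold if sequester_min_nt is None else int(sequester_min_nt)
        )
        self.complexes: List[SpeciesEntry] = []
        self.free: Dict[str, Tuple[Strand, int]] = {}
        self.trace: List[Reaction] = []

    # -- population -------------------------------------------------------

    def add_complex(self, c: Complex, count: int = 1, inert: bool = False) -> None:
        self.complexes.append(SpeciesEntry(c, count, inert))

    def add_free(self, strand: Strand, count: int = 1) -> None:
        if strand.name in self.free:
            s, n = self.free[strand.name]
            self.free[strand.name] = (s, n + count)
        else:
            self.free[strand.name] = (strand, count)

    # -- bookkeeping ------------------------------------------------------

    def strand_census(self) -> Counter:
        """Multiset of strand names over the whole system (conserved by
        every rule)."""
        census: Counter = Counter()
        for name, (_, n) in self.free.items():
            census[name] += n
        for e in self.complexes:
            if e.count <= 0:
                continue
            for s in e.complex.strands.values():
                census[s.name] += e.count
        return census

    def total_bond_nt(self) -> int:
        return sum(e.complex.total_paired_nt * e.count for e in self.complexes if e.count > 0)

    def live_entries(self) -> List[Tuple[int, SpeciesEntry]]:
        return [(i, e) for i, e in enumerate(self.complexes) if e.count > 0]

    def trace_records(self) -> List[dict]:
        return [r.to_record() for r in self.trace]

    def write_trace(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.trace:
                fh.write(json.dumps(r.to_record()) + "\n")

    def _gc(self) -> None:
        self.complexes = [e for e in self.complexes if e.count > 0]
        self.free = {k: v for k, v in self.free.items() if v[1] > 0}


# ---------------------------------------------------------------------------
# fold
# ---------------------------------------------------------------------------


def fold_hairpins(sys: ReactionSystem) -> ReactionSystem:
    """Fold every free strand carrying a hairpin declaration."""
    for name in sorted(sys.free):
        strand, count = sys.free[name]
        if strand.hairpin is None or count <= 0:
            continue
        c = Complex(meta={"folded": name})
        c.add_strand(0, strand)
        (a1, b1), (a2, b2) = strand.hairpin.seg1, strand.hairpin.seg2
        gain = 0
        for k in range(b1 - a1 + 1):
            c.add_bond((0, a1 + k), (0, b2 - k))
            gain += strand.domains[a1 + k].length
        sys.free[name] = (strand, 0)
        sys.add_complex(c, count)
        sys.trace.append(
            Reaction("fold", (name,), (c.label(),), gain, note=f"count={count}")
        )
    sys._gc()
    return sys


# ---------------------------------------------------------------------------
# sequester
# ---------------------------------------------------------------------------


def _duplex_bonds(s1: Strand, s2: Strand) -> Tuple[List[Tuple[int, int]], int]:
    """Greedy maximal antiparallel pairing between two strands.

    Returns domain-index bond pairs (i on s1, j on s2) and the total
    paired length in nucleotides.
    """
    used1: set = set()
    used2: set = set()
    bonds: List[Tuple[int, int]] = []
    total = 0
    while True:
        best = None  # (nt, i, j, k)
        for i in range(len(s1.domains)):
            if i in used1:
                continue
            for j in range(len(s2.domains)):
                if j in used2:
                    continue
                k, nt = 0, 0
                while (
                    i + k < len(s1.domains)
                    and j - k >= 0
                    and (i + k) not in used1
                    and (j - k) not in used2
                    and s1.domains[i + k].partner_name == s2.domains[j - k].name
                    and s1.domains[i + k].length == s2.domains[j - k].length
                ):
                    nt += s1.domains[i + k].length
                    k += 1
                if k and (best is None or nt > best[0]):
                    best = (nt, i, j, k)
        if best is None:
            break
        nt, i, j, k = best
        for m in range(k):
            bonds.append((i + m, j - m))
            used1.add(i + m)
            used2.add(j - m)
        total += nt
    return bonds, total


def resolve_solution_hybridization(sys: ReactionSystem) -> ReactionSystem:
    """Pair complementary free strands into inert solution duplexes,
    greedily in descending order of pairing gain; equimolar partners
    annihilate pairwise."""
    while True:
        names = sorted(n for n, (_, c) in sys.free.items() if c > 0)
        best = None  # (gain, n1, n2, bonds)
        for a, n1 in enumerate(names):
            s1 = sys.free[n1][0]
            if s1.hairpin is not None:
                continue  # hairpins fold instead of pairing in solution
            for n2 in names[a + 1 :]:
                s2 = sys.free[n2][0]
                if s2.hairpin is not None:
                    continue
                bonds, gain = _duplex_bonds(s1, s2)
                if gain < sys.sequester_min_nt:
                    continue
                if best is None or gain > best[0]:
                    best = (gain, n1, n2, bonds)
        if best is None:
            return sys
        gain, n1, n2, bonds = best
        s1, c1 = sys.free[n1]
        s2, c2 = sys.free[n2]
        consumed = min(c1, c2)
        duplex = Complex(meta={"waste": True})
        duplex.add_strand(0, s1)
        duplex.add_strand(1, s2)
        for i, j in bonds:
            duplex.add_bond((0, i), (1, j))
        sys.free[n1] = (s1, c1 - consumed)
        sys.free[n2] = (s2, c2 - consumed)
        sys.add_complex(duplex, consumed, inert=True)
        sys.trace.append(
            Reaction(
                "sequester",
                (n1, n2),
                (duplex.label(),),
                gain,
                note=f"annihilated {consumed} pair(s)",
            )
        )
        sys._gc()


# ---------------------------------------------------------------------------
# reclose
# ---------------------------------------------------------------------------


def _strands_share_bond(c: Complex, sid1: int, sid2: int) -> bool:
    return any(a[0] == sid1 and b[0] == sid2 for a, b in c.bonds.items())


def _reclose_complex(c: Complex) -> int:
    """Pair up co-localized complementary unpaired domains.

    Co-localization is taken literally: a pair may re-form only if it is
    a native (assembly-time) bond whose partners are both vacant again,
    or if the two domains sit on strands that are already bonded to each
    other (zipping next to an existing duplex).  Merely sharing a complex
    is not enough — two segments held apart on a rigid scaffold do not
    hybridize.  Returns the total nucleotides re-paired.
    """
    gained = 0
    while True:
        unpaired = [
            (sid, i)
            for sid in sorted(c.strands)
            for i in range(len(c.strands[sid].domains))
            if (sid, i) not in c.bonds
        ]
        found = False
        for a in range(len(unpaired)):
            if unpaired[a] in c.bonds:
                continue
            da = c.domain_at(unpaired[a])
            for b in range(a + 1, len(unpaired)):
                if unpaired[b] in c.bonds:
                    continue
                db = c.domain_at(unpaired[b])
                if da.partner_name != db.name or da.length != db.length:
                    continue
                pair = frozenset((unpaired[a], unpaired[b]))
                colocalized = pair in c.native or (
                    unpaired[a][0] != unpaired[b][0]
                    and _strands_share_bond(c, unpaired[a][0], unpaired[b][0])
                )
                if not colocalized:
                    continue
                c.add_bond(unpaired[a], unpaired[b])
                gained += da.length
                found = True
                break
            if found:
                break
        if not found:
            return gained


def _reclose(sys: ReactionSystem) -> bool:
    applied = False
    for _, e in sys.live_entries():
        if e.inert:
            continue
        gained = _reclose_complex(e.complex)
        if gained:
            applied = True
            sys.trace.append(
                Reaction("reclose", (e.complex.label(),), (e.complex.label(),), gained)
            )
    return applied


# ---------------------------------------------------------------------------
# invade
# ---------------------------------------------------------------------------


def _valid_target_runs(sys: ReactionSystem, c: Complex, sid: int) -> List[Tuple[int, int, int]]:
    """Enumerate contiguous domain runs on strand ``sid`` that can host a
    full toehold-mediated displacement.

    Yields ``(p, q, gain)`` where [p, q] is the inclusive run and gain is
    the unpaired (toehold) length in nucleotides.
    """
    strand = c.strands[sid]
    n = len(strand.domains)
    out = []
    for p in range(n):
        for q in range(p, n):
            positions = [(sid, i) for i in range(p, q + 1)]
            if any(
                frozenset((pos, c.bonds[pos])) in c.rigid
                for pos in positions
                if pos in c.bonds
            ):
                continue
            unpaired_nt = sum(
                strand.domains[i].length for i in range(p, q + 1) if (sid, i) not in c.bonds
            )
            broken_nt = sum(
                strand.domains[i].length for i in range(p, q + 1) if (sid, i) in c.bonds
            )
            if unpaired_nt < sys.min_toehold or broken_nt == 0:
                continue
            # full-displacement requirement: every incumbent must lose all
            # of its pairing with this strand inside the run
            ok = True
            partners = set()
            for pos in positions:
                if pos in c.bonds:
                    partners.add(c.bonds[pos][0])
            for pid in partners:
                if pid == sid:
                    # intramolecular stem: every self-bond must be broken
                    for x, y in c.bonds.items():
                        if x[0] == sid and y[0] == sid and x < y:
                            if not (p <= x[1] <= q or p <= y[1] <= q):
                                ok = False
                else:
                    for x, y in c.bonds.items():
                        if x[0] == sid and y[0] == pid and not (p <= x[1] <= q):
                            ok = False
            if ok:
                out.append((p, q, unpaired_nt))
    return out


def _find_subsequence(hay: Sequence[str], needle: Sequence[str]) -> List[int]:
    hits = []
    for v in range(len(hay) - len(needle) + 1):
        if all(hay[v + i] == needle[i] for i in range(len(needle))):
            hits.append(v)
    return hits


def enumerate_invasions(sys: ReactionSystem) -> List[InvasionCandidate]:
    """List every applicable displacement in deterministic priority order
    (descending pairing gain, then lexicographic labels)."""
    candidates: List[InvasionCandidate] = []
    # invader segments: free strands, plus unpaired runs on non-inert complexes
    free_sources = []
    for name in sorted(sys.free):
        strand, count = sys.free[name]
        if count <= 0 or strand.hairpin is not None:
            continue
        free_sources.append((name, strand))
    for ti, te in sys.live_entries():
        if te.inert:
            continue
        tc = te.complex
        for sid in sorted(tc.strands):
            for p, q, gain in _valid_target_runs(sys, tc, sid):
                needed = [
                    tc.strands[sid].domains[j].partner_name for j in range(q, p - 1, -1)
                ]
                # free-strand invaders
                for name, strand in free_sources:
                    for v in _find_subsequence(strand.domain_names, needed):
                        candidates.append(
                            InvasionCandidate(
                                gain, name, tc.label(), ti, sid, (p, q),
                                None, name, None, v,
                            )
                        )
                # complex-resident invaders (e.g. an uncaged hairpin payload)
                for si, se in sys.live_entries():
                    if se.inert or si == ti:
                        continue
                    sc = se.complex
                    for ssid in sorted(sc.strands):
                        for (a, b) in sc.unpaired_runs(ssid):
                            seg = [d.name for d in sc.strands[ssid].domains[a : b + 1]]
                            for v in _find_subsequence(seg, needed):
                                candidates.append(
                                    InvasionCandidate(
                                        gain, sc.label(), tc.label(), ti, sid, (p, q),
                                        si, sc.strands[ssid].name, ssid, a + v,
                                    )
                                )
    candidates.sort(key=lambda c: c.sort_key)
    return candidates


def _apply_invasion(sys: ReactionSystem, cand: InvasionCandidate) -> None:
    te = sys.complexes[cand.target_entry]
    target = te.complex.subcomplex(te.complex.strands)  # deep-enough copy
    te.count -= 1
    if cand.source_entry is None:
        strand, cnt = sys.free[cand.source_name]
        sys.free[cand.source_name] = (strand, cnt - 1)
        inv_sid = max(target.strands) + 1
        inv = Complex()
        inv.add_strand(inv_sid, strand)
        inv_positions_base = inv_sid
    else:
        se = sys.complexes[cand.source_entry]
        se.count -= 1
        offset = max(target.strands) + 1
        id_map = {sid: offset + i for i, sid in enumerate(sorted(se.complex.strands))}
        inv = se.complex.renumbered(id_map)
        inv_positions_base = id_map[cand.source_sid]
    merged = target.merged_with(inv)
    p, q = cand.run
    sid = cand.target_sid
    broken = 0
    for i in range(p, q + 1):
        if (sid, i) in merged.bonds:
            broken += merged.domain_at((sid, i)).length
            merged.remove_bond((sid, i))
    formed = 0
    L = q - p + 1
    for m in range(L):
        tpos = (sid, q - m)
        ipos = (inv_positions_base, cand.invader_start + m)
        merged.add_bond(tpos, ipos)
        formed += merged.domain_at(tpos).length
    # release: split disconnected components; fully unpaired single
    # strands return to the free pool
    products = []
    for comp in merged.components():
        sub = merged.subcomplex(comp)
        if len(comp) == 1 and not sub.bonds:
            strand = sub.strands[comp[0]]
            sys.add_free(strand, 1)
            products.append(strand.name)
        else:
            sys.add_complex(sub, 1)
            products.append(sub.label())
    sys.trace.append(
        Reaction(
            "invade",
            (cand.invader_label, cand.target_label),
            tuple(products),
            formed - broken,
            note=f"run={cand.run} strand={merged.strands[sid].name}",
        )
    )
    sys._gc()


# ---------------------------------------------------------------------------
# fixed point
# ---------------------------------------------------------------------------


def react_to_fixed_point(
    sys: ReactionSystem,
    choose: Optional[Callable[[List[InvasionCandidate]], InvasionCandidate]] = None,
    max_iter: Optional[int] = None,
) -> ReactionSystem:
    """Iterate fold -> sequester -> reclose -> invade until no rule
    applies.  ``choose`` may pick any candidate from the enumerated
    invasion list (used to verify confluence); the default takes the
    highest-priority one.
    """
    total_copies = sum(n for _, n in sys.free.values()) + sum(
        e.count for e in sys.complexes
    )
    guard = max_iter if max_iter is not None else 50 + 10 * (total_copies + sys.total_bond_nt())
    for _ in range(guard):
        before = len(sys.trace)
        fold_hairpins(sys)
        resolve_solution_hybridization(sys)
        _reclose(sys)
        if len(sys.trace) != before:
            continue
        cands = enumerate_invasions(sys)
        if not cands:
            return sys
        cand = cands[0] if choose is None else choose(cands)
        _apply_invasion(sys, cand)
    raise EngineError(
        f"no fixed point after {guard} iterations; trace tail: "
        f"{[r.to_record() for r in sys.trace[-5:]]}"
    )


# ---------------------------------------------------------------------------
# erase
# ---------------------------------------------------------------------------


def erase(
    sys: ReactionSystem,
    erase_strand: Strand,
    copies: int = DEFAULT_EXCESS,
) -> ReactionSystem:
    """Strip a bound opener off the prism with its full-complement erase
    strand and let the vacated edge re-close.

    The erase strand hybridizes to the opener's external toehold,
    displaces it from the prism into a waste duplex, and the reclose
    rule re-forms the original edge pairing.  If no matching bound
    opener is present the call is a no-op recorded in the trace.
    """
    wanted = tuple(
        d.partner_name for d in reversed(erase_strand.domains)
    )
    bound = False
    for _, e in sys.live_entries():
        if e.inert:
            continue
        for sid, s in e.complex.strands.items():
            if s.domain_names == wanted and any(
                (sid, i) in e.complex.bonds for i in range(len(s.domains))
            ):
                bound = True
    if not bound:
        sys.trace.append(
            Reaction(
                "erase", (erase_strand.name,), (), 0,
                note="no matching bound opener; no-op",
            )
        )
        return sys
    sys.add_free(erase_strand, copies)
    return react_to_fixed_point(sys)
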