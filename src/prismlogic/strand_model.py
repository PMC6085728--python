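"""Domain/strand algebra for the reconfigurable DNA triangular prism.

The prism and all of its inputs are described at *domain* resolution: a
domain is a contiguous stretch of nucleotides that hybridizes as a unit,
and a strand is an ordered 5'->3' list of domains.  Two domains pair if
and only if one is the Watson-Crick partner of the other (written with a
trailing ``*``).  All reaction semantics in :mod:`prismlogic.sdr_engine`
are defined over this algebra; concrete nucleotides are only needed for
the sequence-fixture generator and the orthogonality audit below.

Architecture summary (lengths are the defaults of :class:`ArchitectureSpec`):

* Each triangular face is one long strand ``L`` plus three short strands;
  every face side is a rigid 21-bp duplex.
* Face-A short strands carry 10-nt tails, face-B short strands carry
  16-nt tails; a vertical prism edge is the 10-bp hybrid of an A tail
  with the inner part of a B tail, leaving a 6-nt toehold on the B tail.
* An opener ``Ci`` is the full 16-nt complement of the ``Bi`` tail, so it
  can bind the exposed toehold and displace the A tail (opening edge i).
* Gate-specific inputs (hairpin-caged C2, the 2-nt-extended C3, the
  XOR-extended C1/C2, the erasable Is/Es pairs) are built from the same
  domain registry.

One deliberate sequence aliasing is baked into the registry: the edge-3
tail is composed of the domains ``t2* e2a`` (the first ten nucleotides of
C2).  This is what lets a single strand carry the C3 sequence *and* act
as the opener of the C2-caging hairpin in the AND gate: the hairpin stem
is complementary to the C3 portion of that input, and simultaneously
cages the toehold-proximal half of C2.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DomainLookupError, GenerationError, InputError, SpecError

__all__ = [
    "Domain",
    "Hairpin",
    "Strand",
    "ArchitectureSpec",
    "DomainRegistry",
    "build_canonical_strands",
    "complement_strand",
    "generate_sequences",
    "orthogonality_violations",
    "max_complementary_stretch",
    "reverse_complement",
    "write_fasta",
    "read_fasta",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _check_alphabet(s: str) -> None:
    if not set(s) <= set("ACGT"):
        raise InputError(f"sequence contains non-ACGT characters: {s!r}")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _max_stretch(s1: str, s2: str) -> Tuple[int, int]:
    """Longest run of ``s1`` reverse-complementary to a run of ``s2``;
    returns (length, end index of the run within s1, exclusive)."""
    t = reverse_complement(s2)
    best, end1 = 0, 0
    prev = [0] * (len(t) + 1)
    for i, a in enumerate(s1, start=1):
        cur = [0] * (len(t) + 1)
        for j, b in enumerate(t, start=1):
            if a == b:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best, end1 = cur[j], i
        prev = cur
    return best, end1


def max_complementary_stretch(s1: str, s2: str) -> int:
    """Length of the longest contiguous run of ``s1`` that is
    reverse-complementary to a run of ``s2``.

    Computed as the longest common substring of ``s1`` and the reverse
    complement of ``s2`` via dynamic programming.
    """
    _check_alphabet(s1)
    _check_alphabet(s2)
    return _max_stretch(s1, s2)[0]


# ---------------------------------------------------------------------------
# Domains and strands
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Domain:
    """A named, fixed-length hybridization unit.

    ``name`` ending in ``*`` marks the Watson-Crick partner of the base
    domain with the same stem name.
    """

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SpecError(f"domain {self.name!r} must have length >= 1")

    @property
    def is_complement(self) -> bool:
        return self.name.endswith("*")

    @property
    def partner_name(self) -> str:
        return self.name[:-1] if self.is_complement else self.name + "*"


@dataclass(frozen=True)
class Hairpin:
    """Intramolecular stem declaration: two equal-length domain-index
    ranges (inclusive) that pair antiparallel, caging the enclosed part
    of the strand."""

    seg1: Tuple[int, int]
    seg2: Tuple[int, int]


@dataclass(frozen=True)
class Strand:
    """An ordered 5'->3' list of domains, optionally with a hairpin
    declaration and a concrete nucleotide sequence."""

    name: str
    domains: Tuple[Domain, ...]
    hairpin: Optional[Hairpin] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            _check_alphabet(self.sequence)
            if len(self.sequence) != self.length:
                raise SpecError(
                    f"strand {self.name!r}: sequence length {len(self.sequence)} "
                    f"!= sum of domain lengths {self.length}"
                )
        if self.hairpin is not None:
            self._validate_hairpin()

    def _validate_hairpin(self) -> None:
        hp = self.hairpin
        (a1, b1), (a2, b2) = hp.seg1, hp.seg2
        n = len(self.domains)
        if not (0 <= a1 <= b1 < n and 0 <= a2 <= b2 < n):
            raise SpecError(f"strand {self.name!r}: hairpin indices out of range")
        if b1 >= a2:
            raise SpecError(f"strand {self.name!r}: hairpin segments overlap or are unordered")
        seg1 = self.domains[a1 : b1 + 1]
        seg2 = self.domains[a2 : b2 + 1]
        if len(seg1) != len(seg2):
            raise SpecError(f"strand {self.name!r}: hairpin segments differ in domain count")
        nt1 = sum(d.length for d in seg1)
        nt2 = sum(d.length for d in seg2)
        if nt1 != nt2:
            raise SpecError(f"strand {self.name!r}: hairpin segments differ in length")
        for d1, d2 in zip(seg1, reversed(seg2)):
            if d1.partner_name != d2.name or d1.length != d2.length:
                raise SpecError(
                    f"strand {self.name!r}: hairpin segments are not mutually complementary"
                )

    @property
    def length(self) -> int:
        return sum(d.length for d in self.domains)

    @property
    def domain_names(self) -> Tuple[str, ...]:
        return tuple(d.name for d in self.domains)

    def with_sequence(self, seq: str) -> "Strand":
        return Strand(self.name, self.domains, self.hairpin, seq)

    def domain_offsets(self) -> List[int]:
        """Start offset of each domain within the nucleotide sequence."""
        offs, pos = [], 0
        for d in self.domains:
            offs.append(pos)
            pos += d.length
        return offs


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchitectureSpec:
    """Lengths (nt) defining the prism architecture.

    The defaults reproduce the published design: 21-bp face sides,
    10-nt A tails, 16-nt B tails with a 6-nt toehold, 10-nt erase
    toeholds, 10/14-nt XOR extensions, a 2-nt AND-gate toehold, and a
    6-nt hairpin loop.
    """

    side_bp: int = 21
    a_tail_nt: int = 10
    b_tail_nt: int = 16
    toehold_nt: int = 6
    erase_toehold_nt: int = 10
    xor_ext5_nt: int = 10
    xor_ext3_nt: int = 14
    and_extra_nt: int = 2
    hairpin_loop_nt: int = 6

    def __post_init__(self) -> None:
        for f, v in self.__dict__.items():
            if v < 1:
                raise SpecError(f"architecture field {f} must be positive, got {v}")
        if self.b_tail_nt != self.a_tail_nt + self.toehold_nt:
            raise SpecError(
                "B-tail length must equal A-tail length + toehold length "
                f"({self.b_tail_nt} != {self.a_tail_nt} + {self.toehold_nt})"
            )
        if self.a_tail_nt <= self.toehold_nt:
            raise SpecError("A-tail must be longer than the toehold (hairpin cage needs a pad)")
        if self.xor_ext3_nt < self.xor_ext5_nt:
            raise SpecError("XOR 3' extension must be at least as long as the 5' extension")
        if self.hairpin_loop_nt < 4:
            raise SpecError("hairpin loop must be at least 4 nt")


class DomainRegistry:
    """All domains of one architecture, with complement lookup."""

    def __init__(self, base_lengths: Mapping[str, int]):
        self._domains: Dict[str, Domain] = {}
        for name, length in base_lengths.items():
            if name.endswith("*"):
                raise SpecError("register base domains without the '*' suffix")
            self._domains[name] = Domain(name, length)
            self._domains[name + "*"] = Domain(name + "*", length)

    def __contains__(self, name: str) -> bool:
        return name in self._domains

    def __iter__(self):
        return iter(self._domains.values())

    @property
    def base_domains(self) -> List[Domain]:
        return [d for d in self._domains.values() if not d.is_complement]

    def get(self, name: str) -> Domain:
        try:
            return self._domains[name]
        except KeyError:
            raise DomainLookupError(f"unknown domain {name!r}") from None

    def complement(self, d: Domain | str) -> Domain:
        name = d if isinstance(d, str) else d.name
        return self.get(self.get(name).partner_name)


def _registry_for(spec: ArchitectureSpec) -> DomainRegistry:
    half = spec.side_bp // 2
    e2a = spec.a_tail_nt - spec.toehold_nt
    pad = spec.xor_ext3_nt - spec.xor_ext5_nt
    base = {
        # face sides (side 2 is split by the nick where L's termini meet)
        "s1": spec.side_bp,
        "s2a": half,
        "s2b": spec.side_bp - half,
        "s3": spec.side_bp,
        # vertical edges; edge 3 reuses t2*/e2a (see module docstring)
        "t1": spec.toehold_nt,
        "t2": spec.toehold_nt,
        "t3": spec.toehold_nt,
        "e1": spec.a_tail_nt,
        "e2a": e2a,
        "e2b": spec.a_tail_nt - e2a,
        # gate-specific accessories
        "z": spec.and_extra_nt,
        "hploop": spec.hairpin_loop_nt,
        "E1": spec.xor_ext5_nt,
        "E2": spec.xor_ext5_nt,
        "x1": spec.erase_toehold_nt,
        "x2": spec.erase_toehold_nt,
    }
    if pad > 0:
        base["p1"] = pad
        base["p2"] = pad
    return DomainRegistry(base)


def complement(registry: DomainRegistry, d: Domain | str) -> Domain:
    """The Watson-Crick partner of a registered domain (an involution)."""
    return registry.complement(d)


def build_canonical_strands(
    spec: ArchitectureSpec = ArchitectureSpec(),
) -> Tuple[DomainRegistry, Dict[str, Strand]]:
    """Construct every strand of the platform from an architecture spec.

    Returns the domain registry and a name->strand mapping containing the
    structural strands (L, A1-A3, B1-B3), the plain openers C1-C3, the
    INHIBIT blockers C1p/C2p, the XOR-extended openers C1-ext/C2-ext, the
    AND-gate pair C2-hairpin / C3-ext2, and the erasable openers
    Is1/Es1, Is2/Es2.
    """
    reg = _registry_for(spec)
    g = reg.get

    def mk(name: str, *domain_names: str, hairpin: Optional[Hairpin] = None) -> Strand:
        return Strand(name, tuple(g(n) for n in domain_names), hairpin)

    pad = spec.xor_ext3_nt > spec.xor_ext5_nt
    xor1 = ["E1", "t1*", "e1"] + (["p1"] if pad else []) + ["E2*"]
    xor2 = ["E2", "t2*", "e2a", "e2b"] + (["p2"] if pad else []) + ["E1*"]

    strands = [
        # structural strands; the same L is used in both faces
        mk("L", "s2b", "s3", "s1", "s2a"),
        mk("A1", "s1*", "e1"),
        mk("A2", "s2a*", "s2b*", "e2a", "e2b"),
        mk("A3", "s3*", "t2*", "e2a"),
        mk("B1", "s1*", "e1*", "t1"),
        mk("B2", "s2a*", "s2b*", "e2b*", "e2a*", "t2"),
        mk("B3", "s3*", "e2a*", "t2", "t3"),
        # plain openers: full complements of the B tails
        mk("C1", "t1*", "e1"),
        mk("C2", "t2*", "e2a", "e2b"),
        mk("C3", "t3*", "t2*", "e2a"),
        # INHIBIT blockers: full complements of the openers
        mk("C1p", "e1*", "t1"),
        mk("C2p", "e2b*", "e2a*", "t2"),
        # XOR-extended openers (mutually complementary extensions)
        mk("C1-ext", *xor1),
        mk("C2-ext", *xor2),
        # AND gate: hairpin-caged C2 and the 2-nt-extended C3 that opens it
        mk(
            "C2-hairpin",
            "z*", "e2a*", "t2", "hploop", "t2*", "e2a", "e2b",
            hairpin=Hairpin((1, 2), (4, 5)),
        ),
        mk("C3-ext2", "t3*", "t2*", "e2a", "z"),
        # erasable openers and their erase strands
        mk("Is1", "x1", "t1*", "e1"),
        mk("Es1", "e1*", "t1", "x1*"),
        mk("Is2", "x2", "t2*", "e2a", "e2b"),
        mk("Es2", "e2b*", "e2a*", "t2", "x2*"),
    ]
    return reg, {s.name: s for s in strands}


def complement_strand(registry: DomainRegistry, s: Strand, name: Optional[str] = None) -> Strand:
    """The full reverse complement of a strand (no hairpin carried over)."""
    doms = tuple(registry.complement(d) for d in reversed(s.domains))
    return Strand(name or s.name + "-comp", doms)


# ---------------------------------------------------------------------------
# Sequence fixture generation
# ---------------------------------------------------------------------------


@dataclass
class SequenceConstraints:
    """Design-hygiene constraints for the sequence-fixture generator."""

    max_unintended_stretch: int = 5
    gc_min: float = 0.40
    gc_max: float = 0.60
    max_homopolymer: int = 4
    max_rounds: int = 2000


def _gc_choices(length: int, lo: float, hi: float) -> List[int]:
    lo_n = int(np.ceil(lo * length - 1e-9))
    hi_n = int(np.floor(hi * length + 1e-9))
    if lo_n > hi_n:
        # window empty at this length: take the closest achievable count
        mid = round((lo + hi) / 2 * length)
        return [int(mid)]
    return list(range(lo_n, hi_n + 1))


def _has_homopolymer(seq: str, cap: int) -> bool:
    run, prev = 0, ""
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        if run > cap:
            return True
    return False


def _sample_domain(rng: np.random.Generator, length: int, cons: SequenceConstraints) -> str:
    choices = _gc_choices(length, cons.gc_min, cons.gc_max)
    for _ in range(200):
        n_gc = int(rng.choice(choices))
        flags = np.zeros(length, dtype=bool)
        flags[rng.choice(length, size=n_gc, replace=False)] = True
        letters = [
            ("G" if rng.random() < 0.5 else "C") if f else ("A" if rng.random() < 0.5 else "T")
            for f in flags
        ]
        seq = "".join(letters)
        if not _has_homopolymer(seq, cons.max_homopolymer):
            return seq
    raise GenerationError(f"could not sample a {length}-nt domain within constraints")


def _intended_partners(strands: Mapping[str, Strand]) -> Dict[frozenset, bool]:
    """Strand pairs (including self-pairs) that share at least one
    complementary domain pair, i.e. that are *meant* to hybridize."""
    out: Dict[frozenset, bool] = {}
    names = sorted(strands)
    for i, n1 in enumerate(names):
        d1 = set(strands[n1].domain_names)
        for n2 in names[i:]:
            d2 = set(strands[n2].domain_names)
            intended = any(Domain(n, 1).partner_name in d2 for n in d1)
            out[frozenset((n1, n2))] = intended
    return out


class Violation(NamedTuple):
    """One orthogonality-audit failure."""

    kind: str        # "domain" or "strand"
    name1: str
    name2: str
    stretch: int
    culprits: Tuple[str, ...]  # base domains overlapping the stretch


def _stems_at(strand: Strand, end: int, length: int) -> Tuple[str, ...]:
    """Base-domain stems overlapping sequence positions [end-length, end)."""
    lo, hi = end - length, end
    stems, pos = [], 0
    for d in strand.domains:
        if pos < hi and pos + d.length > lo:
            stems.append(d.name[:-1] if d.is_complement else d.name)
        pos += d.length
    return tuple(dict.fromkeys(stems))


def orthogonality_violations(
    assignment: Mapping[str, str],
    strands: Mapping[str, Strand],
    k: int,
) -> List[Violation]:
    """Audit a sequence assignment against the orthogonality cap ``k``.

    Two checks are performed:

    * domain level: for every pair of registered domains (base and
      starred forms, a domain against itself included) that are not
      Watson-Crick partners, the longest complementary stretch must be
      <= k;
    * strand level: for every pair of assembled strands with *no*
      intended complementarity (no shared complementary domain pair,
      including a strand against itself), the longest complementary
      stretch must be <= k.  Junction-spanning stretches are thereby
      audited wherever they could seed an unintended reaction.
    """
    viol: List[Violation] = []
    full = dict(assignment)
    for n, seq in assignment.items():
        full[n + "*"] = reverse_complement(seq)
    dnames = sorted(full)
    for i, n1 in enumerate(dnames):
        for n2 in dnames[i:]:
            if Domain(n1, 1).partner_name == n2:
                continue
            m = max_complementary_stretch(full[n1], full[n2])
            if m > k:
                stems = tuple(
                    dict.fromkeys(s[:-1] if s.endswith("*") else s for s in (n1, n2))
                )
                viol.append(Violation("domain", n1, n2, m, stems))
    seqs = {name: _strand_seq(s, assignment) for name, s in strands.items()}
    intended = _intended_partners(strands)
    snames = sorted(strands)
    for i, n1 in enumerate(snames):
        for n2 in snames[i:]:
            if intended[frozenset((n1, n2))]:
                continue
            m, end1 = _max_stretch(seqs[n1], seqs[n2])
            if m > k:
                viol.append(
                    Violation("strand", n1, n2, m, _stems_at(strands[n1], end1, m))
                )
    return viol


def _strand_seq(s: Strand, assignment: Mapping[str, str]) -> str:
    parts = []
    for d in s.domains:
        if d.is_complement:
            parts.append(reverse_complement(assignment[d.name[:-1]]))
        else:
            parts.append(assignment[d.name])
    return "".join(parts)


def generate_sequences(
    spec: ArchitectureSpec = ArchitectureSpec(),
    seed: int = 0,
    constraints: Optional[SequenceConstraints] = None,
) -> Dict[str, Strand]:
    """Deterministically generate concrete nucleotide sequences for every
    canonical strand, satisfying the orthogonality audit.

    The generator samples each base domain independently (GC window,
    homopolymer cap) and then runs an iterative repair loop: while the
    audit reports a violation, the first offending base domain is
    resampled.  The result is reproducible for a fixed seed.
    """
    cons = constraints or SequenceConstraints()
    if cons.max_unintended_stretch < 1:
        raise GenerationError(
            "orthogonality cap k < 1 is unsatisfiable: any A/T or G/C pair "
            "between two domains is a length-1 complementary stretch"
        )
    reg, strands = build_canonical_strands(spec)
    rng = np.random.default_rng(seed)
    assignment = {d.name: _sample_domain(rng, d.length, cons) for d in reg.base_domains}
    for _ in range(cons.max_rounds):
        viol = orthogonality_violations(assignment, strands, cons.max_unintended_stretch)
        if not viol:
            break
        target = viol[0].culprits[0]
        assignment[target] = _sample_domain(rng, len(assignment[target]), cons)
    else:
        viol = orthogonality_violations(assignment, strands, cons.max_unintended_stretch)
    if viol:
        v = viol[0]
        raise GenerationError(
            f"orthogonality constraint unsatisfiable after {cons.max_rounds} rounds: "
            f"{v.name1} vs {v.name2} share a {v.stretch}-nt complementary stretch "
            f"(cap {cons.max_unintended_stretch})"
        )
    return {name: s.with_sequence(_strand_seq(s, assignment)) for name, s in strands.items()}


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def write_fasta(strands: Mapping[str, Strand], path_or_handle) -> None:
    """Write concrete strand sequences as FASTA (one record per strand)."""
    records = []
    for name in sorted(strands):
        s = strands[name]
        if s.sequence is None:
            raise InputError(f"strand {name!r} has no concrete sequence to export")
        records.append(SeqRecord(Seq(s.sequence), id=name, description=""))
    SeqIO.write(records, path_or_handle, "fasta")


def fasta_bytes(strands: Mapping[str, Strand]) -> bytes:
    buf = io.StringIO()
    write_fasta(strands, buf)
    return buf.getvalue().encode()


def read_fasta(path_or_handle, strands: Mapping[str, Strand]) -> Dict[str, Strand]:
    """Attach sequences from a FASTA file to a canonical strand set."""
    out = dict(strands)
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        if rec.id not in out:
            raise InputError(f"FASTA record {rec.id!r} is not a canonical strand")
        out[rec.id] = out[rec.id].with_sequence(str(rec.seq).upper())
    return out
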