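# Methods

## Scope and modelling level

The package models the prism platform at *domain* resolution: a domain
is a contiguous nucleotide stretch that hybridizes as a unit, a strand
is an ordered 5′→3′ domain list, and a complex is a strand set plus a
bond set between domain instances (each domain in at most one bond,
bonded domains complementary and equal-length).  This is the standard
abstraction for strand-displacement circuits: all of the platform's
logic is decided by which domains can pair, not by their exact
nucleotides, so every gate output is provably invariant to the concrete
sequence fixture (and tested to be).

Deliberately out of scope: reaction kinetics and rate constants (the
platform is read out at an endpoint after a fixed incubation, so only
the reachable fixed point matters), nearest-neighbour thermodynamics,
gel mobility, thermal melting, serum degradation, and dye photophysics
beyond point-dipole Förster transfer.

## Domain architecture

Defaults (all overridable through `ArchitectureSpec` / the YAML config):
21-bp face sides, 10-nt A tails, 16-nt B tails (= A tail + 6-nt
toehold), 10-nt erase toeholds, 10-nt/14-nt XOR extensions, 2-nt AND
toehold, 6-nt hairpin loop.  Edge *i* is the duplex of the A*i* tail
with the inner 10 nt of the B*i* tail; the opener C*i* is the full
16-nt reverse complement of the B*i* tail.

One aliasing is forced by the AND-gate design and is therefore part of
the architecture rather than a free choice.  The AND gate's input 2 is
the C3 sequence plus 2 nt, and it must open input 1's hairpin whose
10-nt stem cages the displacement-initiating half of C2.  For a single
strand to do both, the 3′-terminal 10 nt of C3 must equal the first
10 nt of C2 (toehold `t2*` plus the 4-nt pad `e2a`).  The registry
encodes this by composing the edge-3 tail from the domains `t2* e2a`;
the engine's full-displacement rule (below) keeps this shared
subsequence from triggering cross-edge reactions, mirroring the fact
that a 10-of-16-nt match with no free toehold cannot complete a
displacement.

The hairpin input is `z* e2a* t2 loop t2* e2a e2b` with stem
`(e2a*,t2):(t2*,e2a)` — stem length 10 nt, loop 6 nt (≥ 4 nt for
steric sanity), and a 2-nt external toehold `z*`.  The exact stem/loop
layout of the original design is not published; this layout satisfies
every stated constraint (the stem and toehold are complementary to
input 2; the caged C2 cannot act until released).  Likewise the XOR
extension register is not published for the unequal 10/14-nt lengths;
here each input's 10-nt 5′ extension pairs the terminal 10 nt of the
partner's 14-nt 3′ extension (two 10-bp duplexes, 4-nt pads unpaired),
which suffices for mutual sequestration.

## Reaction semantics

`react_to_fixed_point` applies four rules in strict priority:

1. **fold** — free strands with hairpin declarations fold; paired stem
   domains are unavailable for initiation.  A folded hairpin is a
   complex: it can be invaded (through its external toehold) but does
   not take part in solution sequestration.
2. **sequester** — free strands pair greedily (descending total duplex
   length, ties lexicographic) into inert solution duplexes; equimolar
   partners annihilate.  Minimum duplex length = `min_toehold` (2 nt).
   Sequestration is strand-level: a captured strand is wholly inert
   even where domains dangle unpaired.  This encodes the experimental
   "bind each other preferentially" behaviour of the XOR and INHIBIT
   inputs without kinetics.
3. **reclose** — unpaired complementary domains re-pair only when
   co-localized: either a native (assembly-time) edge bond whose two
   partners are vacant again, or zipping between two strands that
   already share a bond.  Merely co-existing in one complex is *not*
   co-localization — two segments held on a rigid scaffold (e.g. a
   freed A3 tail and the edge-2 toehold) do not hybridize.  This is
   what restores the closed prism after an erase.
4. **invade** — toehold-mediated displacement.  A contiguous run on a
   complex strand can be invaded if its unpaired (toehold) length is
   ≥ `min_toehold` (default 2 nt, the smallest functional toehold in
   the platform), at least one bond is displaced, no rigid face bond is
   touched, and every incumbent is *fully* displaced — an incumbent
   retaining pairing adjacent to the run would make the intermediate a
   stalling, reversible toehold exchange, so such partial invasions are
   rejected.  The invader may be a free strand or an unpaired segment
   of a non-inert complex (this is how the activated hairpin's C2
   payload reaches edge 2).  Net pairing gain equals the toehold
   length; since every rule strictly increases total pairing (or
   consumes free strands), the fixed point exists and an iteration
   guard merely backstops implementation errors.

Priorities encode the published preferences (hairpins form before
anything else; complementary inputs neutralize each other before
touching the prism).  Among invasions the engine fires the largest
pairing gain first, ties broken lexicographically for reproducibility;
the final prism state is confluent under permutations of same-priority
reactions on every gate instance (verified by randomized interleaving
in the tests).

**Stoichiometry.**  Inputs are added at 5 copies per prism copy,
matching the experimental 165 nM : 33 nM ratio, while sequestration
annihilates equimolar partners completely.  The excess matters: in the
AND gate one input-2 copy opens edge 3 directly and another activates
the hairpin, reproducing the observed deconstruction at (1/1).

## Signal model

State → effective dye–quencher distance → NFI = 1 − E(r):
closed → 5.5 nm; mono-SD(C3) → 5.8 nm (the lid rotation barely moves
the dye: a "tiny increase", between baseline and threshold); mono-SD of
edge 1 or 2 and all di-SD states → 12 nm (opened lid, far above
threshold); tri-SD → ∞ (full recovery, NFI 1.0).  The Förster radius is
calibrated as R₀ = 5.5/(0.6)^{1/6} ≈ 5.99 nm so that the two published
closed-state quantities — r = 5.5 nm and 37.5 % residual fluorescence —
are exactly mutually consistent; this lies in the literature range for
a ROX/BHQ-2 pair.  The orientation factor κ² is absorbed into R₀
(point dipoles, dynamic averaging).  Opened-state distances are lookup
values, not tracked coordinates: the opened lid is floppy, and only the
ordering of the per-state intensities and their relation to the 0.6
threshold carry logical meaning.  Per-state bar heights beyond these
threshold relations are not claimed.

The geometry module places the two triangles analytically; with the
default eclipsed faces the nick–nick distance equals the strut length
(3.40 nm).  The published geometric estimate of 5.4 nm between the
nicks involves an unpublished construction (face stagger and helix
offsets); the twist and helix-radius parameters are exposed for
exploration but no default claim of 5.4 nm is made.

## Sequence fixture generator

The original nucleotide sequences are not reproduced here; the
generator emits, deterministically per seed, an assignment satisfying
every structural constraint: intended duplexes perfectly complementary,
GC fraction 40–60 % per domain (where the length permits), homopolymer
runs ≤ 4, and an orthogonality cap of k = 5 nt — strictly below the
6-nt functional toehold, so no unintended displacement can initiate in
the engine's own semantics.  The audit checks all non-partner domain
pairs (base and starred forms, self-pairs included) plus full-strand
scans for every strand pair with no intended complementarity, which
catches junction-spanning stretches.  Generation is rejection-free at
the domain level followed by an iterative repair loop that resamples
the domain underlying the first reported violation; seeds 1–3 converge
in well under a second.  Junction-spanning stretches between strands
that *do* share intended complementarity are not audited (they are
dominated by the intended duplex); k = 0 is rejected as unsatisfiable.

The fixture emulates sequence-level realism only to the degree the
domain-level logic needs: passing tests show the architecture and
reaction semantics are coherent, not that these particular nucleotides
would fold and displace cleanly in a cuvette (no thermodynamic ensemble
check is performed).

## Problem sizes

Everything here is desk-scale by construction: one prism, ≤ 5 input
species, ≤ 10 copies per species.  The property suites run every
published gate instance (51 input combinations) with several randomized
interleavings each; the whole test suite completes in well under a
minute on one CPU.

## Known limitations

- Endpoint determinism cannot represent yield, leak, or partial
  conversion; every gate row is exactly 0 or 1 (or 0/1/2).
- Strand-level sequestration is an engineering idealization of the
  XOR inhibition mechanism; the physical blocking mode (steric vs
  thermodynamic) is not resolved by endpoint data.
- The reclose co-localization criterion is topological (shared bond or
  native pair), a proxy for real geometry.
- The AND-gate aliasing means plain C3 and the blocker C2′ share a
  10-nt cross-complementarity; the two never co-occur in any published
  gate, and the engine's full-displacement rule keeps the pairing
  inert against assembled structures.
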