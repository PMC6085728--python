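"""Domain algebra, canonical strand construction, and the sequence fixture."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prismlogic.errors import DomainLookupError, GenerationError, InputError, SpecError
from prismlogic.strand_model import (
    ArchitectureSpec,
    Domain,
    Hairpin,
    SequenceConstraints,
    Strand,
    build_canonical_strands,
    fasta_bytes,
    generate_sequences,
    max_complementary_stretch,
    orthogonality_violations,
    read_fasta,
    reverse_complement,
    write_fasta,
)

# ---------------------------------------------------------------------------
# complementation
# ---------------------------------------------------------------------------


def test_complement_is_involution_and_preserves_length(registry):
    for d in registry:
        partner = registry.complement(d)
        assert partner.length == d.length
        assert registry.complement(partner) == d


def test_complement_of_unknown_domain_raises(registry):
    with pytest.raises(DomainLookupError):
        registry.complement("nonexistent")


def test_nucleotide_reverse_complement():
    assert reverse_complement("ACGTAC") == "GTACGT"
    with pytest.raises(InputError):
        reverse_complement("ACGU")


# ---------------------------------------------------------------------------
# canonical strands
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "name,length",
    [
        ("C1", 16),      # full complement of the 16-nt B1 tail
        ("C2", 16),
        ("C3", 16),
        ("C1-ext", 40),  # 10 + 16 + 14 nt XOR extension layout
        ("C2-ext", 40),
        ("C3-ext2", 18),  # C3 plus the 2-nt AND toehold
        ("L", 63),        # three 21-bp sides
        ("A1", 31),
        ("B1", 37),
        ("Is1", 26),
        ("Es1", 26),
    ],
)
def test_canonical_strand_lengths(strands, name, length):
    assert strands[name].length == length


def test_a_and_b_tails_have_published_lengths(strands, arch):
    for i in (1, 2, 3):
        a = strands[f"A{i}"]
        tail_nt = sum(d.length for d in a.domains if not d.name.startswith("s"))
        assert tail_nt == arch.a_tail_nt == 10
        b = strands[f"B{i}"]
        tail_nt = sum(d.length for d in b.domains if not d.name.startswith("s"))
        assert tail_nt == arch.b_tail_nt == 16


def test_openers_complement_the_full_b_tails(strands, registry):
    for i in (1, 2, 3):
        b_tail = [d for d in strands[f"B{i}"].domains if not d.name.startswith("s")]
        opener = strands[f"C{i}"].domains
        assert [d.name for d in opener] == [
            registry.complement(d).name for d in reversed(b_tail)
        ]


def test_hairpin_declaration_is_valid_and_cages_the_c2_toehold(strands):
    hp = strands["C2-hairpin"]
    assert hp.hairpin is not None
    (a1, b1), (a2, b2) = hp.hairpin.seg1, hp.hairpin.seg2
    caged = {d.name for d in hp.domains[a2 : b2 + 1]}
    assert "t2*" in caged  # the displacement-initiating part of C2 is caged


def test_invalid_hairpin_declarations_are_rejected(registry):
    t2, t2c = registry.get("t2"), registry.get("t2*")
    with pytest.raises(SpecError):
        Strand("bad", (t2, t2c), hairpin=Hairpin((0, 0), (0, 0)))  # overlap
    with pytest.raises(SpecError):
        Strand("bad", (t2, t2), hairpin=Hairpin((0, 0), (1, 1)))  # not complementary


def test_architecture_invariants_enforced():
    with pytest.raises(SpecError):
        ArchitectureSpec(b_tail_nt=15)  # != a_tail + toehold
    with pytest.raises(SpecError):
        ArchitectureSpec(side_bp=0)
    with pytest.raises(SpecError):
        ArchitectureSpec(xor_ext3_nt=5)  # shorter than the 5' extension


def test_strand_structure_is_seed_independent():
    s1 = generate_sequences(seed=1)
    s2 = generate_sequences(seed=2)
    for name in s1:
        assert s1[name].domain_names == s2[name].domain_names
        assert s1[name].sequence != s2[name].sequence or s1[name].length < 8


# ---------------------------------------------------------------------------
# complementarity scan
# ---------------------------------------------------------------------------


def _stretch_oracle(s1: str, s2: str) -> int:
    """All-substring-pairs scan (quartic brute force)."""
    rc = reverse_complement(s2)
    best = 0
    for i in range(len(s1)):
        for j in range(i + 1, len(s1) + 1):
            sub = s1[i:j]
            if sub in rc:
                best = max(best, j - i)
    return best


def test_max_complementary_stretch_examples():
    assert max_complementary_stretch("AAAA", "TTTT") == 4
    assert max_complementary_stretch("AAAA", "AAAA") == 0
    with pytest.raises(InputError):
        max_complementary_stretch("AXGT", "ACGT")


def test_max_complementary_stretch_matches_brute_force_on_random_20mers():
    rng = np.random.default_rng(7)
    for _ in range(50):
        s1 = "".join(rng.choice(list("ACGT"), 20))
        s2 = "".join(rng.choice(list("ACGT"), 20))
        assert max_complementary_stretch(s1, s2) == _stretch_oracle(s1, s2)


@settings(max_examples=100, derandomize=True)
@given(
    st.text(alphabet="ACGT", min_size=0, max_size=12),
    st.text(alphabet="ACGT", min_size=0, max_size=12),
)
def test_max_complementary_stretch_properties(s1, s2):
    m = max_complementary_stretch(s1, s2)
    assert m == _stretch_oracle(s1, s2)
    assert m == max_complementary_stretch(s2, s1)  # symmetric


# ---------------------------------------------------------------------------
# sequence fixture generator
# ---------------------------------------------------------------------------


def test_generated_sequences_are_deterministic_per_seed():
    a = fasta_bytes(generate_sequences(seed=1))
    b = fasta_bytes(generate_sequences(seed=1))
    c = fasta_bytes(generate_sequences(seed=2))
    assert a == b
    assert a != c


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_generated_sequences_pass_orthogonality_audit(seed):
    seqs = generate_sequences(seed=seed)
    assignment = {}
    for s in seqs.values():
        for d, off in zip(s.domains, s.domain_offsets()):
            if not d.is_complement:
                assignment.setdefault(d.name, s.sequence[off : off + d.length])
    assert orthogonality_violations(assignment, seqs, 5) == []
    # and every intended duplex is perfectly complementary
    for i in (1, 2, 3):
        b_tail = seqs[f"B{i}"].sequence[21:]
        assert seqs[f"C{i}"].sequence == reverse_complement(b_tail)


def test_generated_sequences_respect_design_hygiene():
    seqs = generate_sequences(seed=1)
    for s in seqs.values():
        assert "AAAAA" not in s.sequence
        assert "TTTTT" not in s.sequence
        for d, off in zip(s.domains, s.domain_offsets()):
            if d.is_complement or d.length < 10:
                continue
            sub = s.sequence[off : off + d.length]
            gc = (sub.count("G") + sub.count("C")) / d.length
            assert 0.40 - 1e-9 <= gc <= 0.60 + 1e-9


def test_unsatisfiable_orthogonality_cap_raises():
    with pytest.raises(GenerationError):
        generate_sequences(seed=1, constraints=SequenceConstraints(max_unintended_stretch=0))


def test_fasta_round_trip(strands):
    seqs = generate_sequences(seed=1)
    buf = io.StringIO()
    write_fasta(seqs, buf)
    buf.seek(0)
    back = read_fasta(buf, strands)
    for name in seqs:
        assert back[name].sequence == seqs[name].sequence
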