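"""Shared enumeration of every published gate instance (gate x input
vector, plus the ten BCD digits), used by the engine property tests."""

from itertools import product
from typing import Callable, Dict, Iterator, List, Optional, Tuple

from prismlogic.assembly import PrismState, build_prism
from prismlogic.logic import BCD_BIT_STRANDS, builtin_gates, encode_bcd, _system_prism_state
from prismlogic.sdr_engine import ReactionSystem, react_to_fixed_point


def all_gate_mixes() -> Iterator[Tuple[str, Tuple[str, ...]]]:
    """Yield (label, input strand names) for every instance."""
    for name, gate in sorted(builtin_gates().items()):
        for inputs in product(range(gate.valence), repeat=gate.arity):
            mix = gate.strands_for(inputs)
            yield f"{name}{inputs}", tuple(sorted(mix.elements()))
    for digit in range(10):
        bits = encode_bcd(digit)
        names = tuple(s for s, b in zip(BCD_BIT_STRANDS, bits) if b)
        yield f"evenodd({digit})", names


def run_mix(
    strands,
    mix: Tuple[str, ...],
    choose: Optional[Callable] = None,
    excess: int = 5,
) -> Tuple[ReactionSystem, PrismState]:
    sys_ = ReactionSystem()
    sys_.add_complex(build_prism(strands), 1)
    for name in mix:
        sys_.add_free(strands[name], excess)
    react_to_fixed_point(sys_, choose=choose)
    return sys_, _system_prism_state(sys_)
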