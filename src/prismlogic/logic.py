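"""Gate library and truth-table evaluation on the prism platform.

Every gate maps logical input values to multisets of input strands,
mixes them with one closed prism in a single event, runs the
displacement engine to its fixed point, and decodes the outcome:

* binary gates threshold the normalized fluorescence at 0.6 (strictly
  greater than the threshold means output 1);
* the ternary gate decodes the final structure itself (closed -> 0,
  mono-SD(C1) -> 1, di-SD(C1/C2) -> 2), with the fluorescence reported
  alongside as the measured observable.

The built-in library covers the seven published gates — OR, AND, XOR,
INHIBIT (two variants via the blockers C1p/C2p), the two three-input
INHIBIT-OR combinations, and the two-input ternary INHIBIT — plus the
four-bit BCD even/odd identifier that reuses the same prism with the
inputs C2-hairpin, C3-ext2, C1p and C2 on bits N4..N1.
"""

from __future__ import annotations

import csv
import io
import json
from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import sdr_engine
from .assembly import PrismState, build_prism, prism_state
from .errors import DecodeError, InputError
from .geometry_signal import SignalModel, nfi
from .sdr_engine import DEFAULT_EXCESS, ReactionSystem, react_to_fixed_point
from .strand_model import ArchitectureSpec, Strand, build_canonical_strands

__all__ = [
    "GateSpec",
    "TruthTable",
    "builtin_gates",
    "evaluate",
    "truth_table",
    "encode_bcd",
    "classify_parity",
    "run_cycle",
    "BCD_BIT_STRANDS",
]


@dataclass(frozen=True)
class GateSpec:
    """A named logic gate on the prism platform.

    ``encoding`` holds, for each input position, the strand names added
    for each nonzero value; value 0 is always the empty multiset.
    ``decoder`` is ``"threshold"`` (binary) or ``"ternary"``.
    """

    name: str
    arity: int
    valence: int
    encoding: Tuple[Mapping[int, Tuple[str, ...]], ...]
    decoder: str = "threshold"

    def __post_init__(self) -> None:
        if len(self.encoding) != self.arity:
            raise InputError(f"gate {self.name!r}: encoding arity mismatch")
        for enc in self.encoding:
            if enc.get(0, ()) != ():
                raise InputError(f"gate {self.name!r}: value 0 must encode no strands")

    def strands_for(self, inputs: Sequence[int]) -> Counter:
        if len(inputs) != self.arity:
            raise InputError(
                f"gate {self.name!r} takes {self.arity} inputs, got {len(inputs)}"
            )
        mix: Counter = Counter()
        for pos, val in enumerate(inputs):
            if not 0 <= val < self.valence:
                raise InputError(
                    f"gate {self.name!r}: input value {val} outside 0..{self.valence - 1}"
                )
            for sname in self.encoding[pos].get(val, ()):
                mix[sname] += 1
        return mix


@dataclass(frozen=True)
class EvalResult:
    output: int
    state: PrismState
    nfi: float
    trace: Tuple[dict, ...]


@dataclass(frozen=True)
class TruthTable:
    gate: str
    rows: Tuple[Tuple[Tuple[int, ...], str, float, int], ...]

    @property
    def outputs(self) -> Tuple[int, ...]:
        return tuple(r[3] for r in self.rows)

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        n = len(self.rows[0][0])
        w.writerow([f"input_{i+1}" for i in range(n)] + ["structure", "nfi", "output"])
        for inputs, label, val, out in self.rows:
            w.writerow(list(inputs) + [label, f"{val:.4f}", out])
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps(
            {
                "gate": self.gate,
                "rows": [
                    {"inputs": list(i), "structure": s, "nfi": v, "output": o}
                    for i, s, v, o in self.rows
                ],
            },
            indent=2,
        )


def builtin_gates() -> Dict[str, GateSpec]:
    """The published gate library, keyed by lower-case gate name."""
    b = lambda *names: {1: tuple(names)}  # noqa: E731
    gates = [
        GateSpec("OR", 2, 2, (b("C1"), b("C2"))),
        GateSpec("AND", 2, 2, (b("C2-hairpin"), b("C3-ext2"))),
        GateSpec("XOR", 2, 2, (b("C1-ext"), b("C2-ext"))),
        GateSpec("INHIBIT", 2, 2, (b("C1"), b("C1p"))),
        GateSpec("INHIBIT-2", 2, 2, (b("C2"), b("C2p"))),
        GateSpec("INHIBIT-OR", 3, 2, (b("C1"), b("C1p"), b("C2"))),
        GateSpec("INHIBIT-OR-ALT", 3, 2, (b("C1"), b("C2"), b("C2p"))),
        GateSpec(
            "TERNARY-INHIBIT",
            2,
            3,
            (
                {1: ("C1",), 2: ("C1", "C2")},
                {1: ("C2p",), 2: ("C2p", "C1p")},
            ),
            decoder="ternary",
        ),
    ]
    return {g.name.lower(): g for g in gates}


def _fresh_system(
    strands: Mapping[str, Strand],
    mix: Counter,
    min_toehold: int,
    excess: int,
) -> ReactionSystem:
    sys_ = ReactionSystem(min_toehold=min_toehold)
    sys_.add_complex(build_prism(strands), 1)
    for sname in sorted(mix):
        if sname not in strands:
            raise InputError(f"encoding names unknown strand {sname!r}")
        sys_.add_free(strands[sname], excess * mix[sname])
    return sys_


def _system_prism_state(sys_: ReactionSystem) -> PrismState:
    for _, e in sys_.live_entries():
        names = set(s.name for s in e.complex.strands.values())
        if {"A1", "A2", "A3"} <= names:
            return prism_state(e.complex)
    raise DecodeError("no face-A complex found in the reacted system")


_TERNARY_DECODER = {
    "closed": 0,
    "mono-SD(C1)": 1,
    "di-SD(C1/C2)": 2,
}


def evaluate(
    gate: GateSpec,
    inputs: Sequence[int],
    strands: Optional[Mapping[str, Strand]] = None,
    model: Optional[SignalModel] = None,
    min_toehold: int = 2,
    excess: int = DEFAULT_EXCESS,
) -> EvalResult:
    """Run one gate instance: encode, react to fixed point, read out."""
    strands = strands or build_canonical_strands()[1]
    model = model or SignalModel()
    mix = gate.strands_for(inputs)
    sys_ = _fresh_system(strands, mix, min_toehold, excess)
    react_to_fixed_point(sys_)
    state = _system_prism_state(sys_)
    value = nfi(state, model)
    if gate.decoder == "threshold":
        out = int(value > model.threshold)
    elif gate.decoder == "ternary":
        if state.label not in _TERNARY_DECODER:
            raise DecodeError(
                f"structure {state.label!r} has no assigned ternary output"
            )
        out = _TERNARY_DECODER[state.label]
    else:
        raise InputError(f"unknown decoder {gate.decoder!r}")
    return EvalResult(out, state, value, tuple(sys_.trace_records()))


def truth_table(
    gate: GateSpec,
    strands: Optional[Mapping[str, Strand]] = None,
    model: Optional[SignalModel] = None,
    **kwargs,
) -> TruthTable:
    """Evaluate all valence^arity input vectors in lexicographic order."""
    strands = strands or build_canonical_strands()[1]
    model = model or SignalModel()
    rows = []
    for inputs in product(range(gate.valence), repeat=gate.arity):
        res = evaluate(gate, inputs, strands=strands, model=model, **kwargs)
        rows.append((inputs, res.state.label, res.nfi, res.output))
    return TruthTable(gate.name, tuple(rows))


# ---------------------------------------------------------------------------
# BCD even/odd identifier
# ---------------------------------------------------------------------------

#: bit -> input strand for the even/odd identifier (N4, N3, N2, N1)
BCD_BIT_STRANDS = ("C2-hairpin", "C3-ext2", "C1p", "C2")


def encode_bcd(digit: int) -> Tuple[int, int, int, int]:
    """Standard 8421 binary-coded-decimal bits (N4, N3, N2, N1)."""
    if not 0 <= digit <= 9:
        raise InputError(f"digit must be 0..9, got {digit}")
    return ((digit >> 3) & 1, (digit >> 2) & 1, (digit >> 1) & 1, digit & 1)


def classify_parity(
    digit: int,
    strands: Optional[Mapping[str, Strand]] = None,
    model: Optional[SignalModel] = None,
    **kwargs,
) -> Tuple[int, float]:
    """Even/odd identification of one decimal digit.

    BCD-encodes the digit, maps the four bits onto the strand inputs
    (N4 -> C2-hairpin, N3 -> C3-ext2, N2 -> C1p, N1 -> C2), reacts, and
    thresholds the fluorescence: output 1 marks an odd digit.
    """
    bits = encode_bcd(digit)
    gate = GateSpec(
        "EVEN-ODD",
        4,
        2,
        tuple({1: (s,)} for s in BCD_BIT_STRANDS),
    )
    res = evaluate(gate, bits, strands=strands, model=model, **kwargs)
    return res.output, res.nfi


# ---------------------------------------------------------------------------
# open/erase cycling
# ---------------------------------------------------------------------------


def run_cycle(
    edge: int,
    n_cycles: int,
    strands: Optional[Mapping[str, Strand]] = None,
    model: Optional[SignalModel] = None,
    min_toehold: int = 2,
    excess: int = DEFAULT_EXCESS,
) -> List[float]:
    """Open/erase switching on vertical edge 1 or 2.

    Each cycle adds the erasable opener Is (prism opens, fluorescence
    high) and then the erase strand Es (opener stripped into waste, edge
    re-closes, fluorescence low).  Returns the 2*n_cycles fluorescence
    readings; the final state is closed.
    """
    if edge not in (1, 2):
        raise InputError("cycling is defined on edge 1 or 2 (the labelled lids)")
    if n_cycles < 1:
        raise InputError("n_cycles must be >= 1")
    strands = strands or build_canonical_strands()[1]
    model = model or SignalModel()
    is_strand = strands[f"Is{edge}"]
    es_strand = strands[f"Es{edge}"]
    sys_ = ReactionSystem(min_toehold=min_toehold)
    sys_.add_complex(build_prism(strands), 1)
    readings: List[float] = []
    for _ in range(n_cycles):
        sys_.add_free(is_strand, excess)
        react_to_fixed_point(sys_)
        readings.append(nfi(_system_prism_state(sys_), model))
        sdr_engine.erase(sys_, es_strand, copies=excess)
        readings.append(nfi(_system_prism_state(sys_), model))
    return readings
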