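"""Published reference values for the bombinin H2 self-association system.

These numbers summarise the microsecond-scale all-atom simulation study of
27 bombinin H2 peptides in water that this package's synthetic scenarios
emulate: the times at which individual chains first adopted a stable
single-helix conformation, the neighbouring chains at that moment (5 A
criterion) and the oligomer each transition took place in.  They are used
as *inputs* when scripting reconstruction scenarios, never as fitted
output.
"""
from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReportedTransition", "REPORTED_TRANSITIONS", "REPORTED_TRANSITION_TIMES_NS"]


@dataclass(frozen=True)
class ReportedTransition:
    chain_id: str
    time_ns: float
    neighbours: tuple[str, ...]
    aggregate: str


#: Helix-loop-helix -> single-helix transitions of the nine chains that
#: straightened during the reference 27-chain simulation.
REPORTED_TRANSITIONS: tuple[ReportedTransition, ...] = (
    ReportedTransition("A", 903.0, ("E", "F", "M", "W", "Y"), "27-mer"),
    ReportedTransition("B", 917.0, ("G", "H", "K", "N", "P", "S", "Z"), "27-mer"),
    ReportedTransition("D", 931.0, ("H", "O", "P"), "27-mer"),
    ReportedTransition("E", 735.0, ("A", "K", "M", "R", "S", "T"), "27-mer"),
    ReportedTransition("F", 404.0, ("A", "C", "E", "I", "M", "R", "U", "W", "Y"), "19-mer"),
    ReportedTransition("J", 1516.0, ("N", "U", "V", "a"), "27-mer"),
    ReportedTransition("V", 25.0, ("a",), "Dimer"),
    ReportedTransition("W", 70.0, ("A", "F", "Y"), "Tetramer"),
    ReportedTransition("a", 22.0, ("V",), "Dimer"),
)

#: Chain id -> first stable single-helix time (ns).
REPORTED_TRANSITION_TIMES_NS: dict[str, float] = {
    t.chain_id: t.time_ns for t in REPORTED_TRANSITIONS
}
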