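"""Terminal telomere-motif tandem array detection and T2T classification.

Fungal chromosome ends carry tandem arrays of a 6-mer telomere motif:
CCCTAA on the 5' (sequence start) side and its reverse complement TTAGGG on
the 3' (sequence end) side.  A scaffold is telomere-to-telomere (T2T) when
both termini carry an array of at least ``min_copies`` exact motif copies.

Counting is motif-specific rather than generic tandem-repeat discovery: we
count exact motif copies in the maximal chain of tandem runs, allowing short
interruptions (``max_interruption`` bases, default one motif length) between
runs, which is the tolerance a generic tandem repeat finder would apply to
near-perfect telomere arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome_model import Assembly

logger = logging.getLogger(__name__)

START_MOTIF = "CCCTAA"
END_MOTIF = "TTAGGG"


@dataclass
class TelomereParams:
    """Tunable parameters of the telomere scan."""

    start_motif: str = START_MOTIF
    end_motif: str = END_MOTIF
    terminal_window: int = 1000
    max_interruption: int = 6
    min_copies: int = 3

    def __post_init__(self) -> None:
        if not self.start_motif or not self.end_motif:
            raise ValueError("motifs must be non-empty")
        if self.terminal_window < max(len(self.start_motif), len(self.end_motif)):
            raise ValueError("terminal_window must be >= motif length")
        if self.min_copies < 1:
            raise ValueError("min_copies must be >= 1")


@dataclass
class TelomereReport:
    """Per-scaffold terminal motif copy counts and T2T status."""

    scaffold_id: str
    start_copies: int
    end_copies: int
    start_present: bool
    end_present: bool
    t2t: bool = field(init=False)

    def __post_init__(self) -> None:
        self.t2t = self.start_present and self.end_present


def _motif_occurrences(sequence: str, motif: str) -> list[int]:
    """All start positions of exact motif occurrences (including overlapping)."""
    starts = []
    i = sequence.find(motif)
    while i != -1:
        starts.append(i)
        i = sequence.find(motif, i + 1)
    return starts


def longest_tandem_run(
    sequence: str,
    motif: str,
    max_interruption: int = 6,
    prefer: str = "left",
) -> tuple[int, tuple[int, int]]:
    """Count exact motif copies in the best chain of tandem runs.

    Non-overlapping motif occurrences chain together when the gap between
    the end of one copy and the start of the next is at most
    ``max_interruption`` bases.  Returns ``(copies, (span_start, span_end))``
    for the chain with the most copies; ties are broken toward the left end
    of the sequence when ``prefer == "left"`` and toward the right end
    otherwise.  Absent motif: ``(0, (0, 0))``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if len(motif) < 2:
        raise ValueError("motif length must be >= 2")
    m = len(motif)
    starts = _motif_occurrences(sequence, motif)
    if not starts:
        return 0, (0, 0)

    # Greedy left-to-right chaining over non-overlapping occurrences: an
    # occurrence overlapping the previous accepted copy is skipped; a gap
    # larger than max_interruption closes the chain.
    chains: list[tuple[int, int, int]] = []  # (copies, span_start, span_end)
    copies = 1
    chain_start = last = starts[0]
    for s in starts[1:]:
        if s < last + m:
            continue
        if s - (last + m) <= max_interruption:
            copies += 1
            last = s
        else:
            chains.append((copies, chain_start, last + m))
            copies = 1
            chain_start = last = s
    chains.append((copies, chain_start, last + m))

    best = max(chains, key=lambda c: c[0])
    ties = [c for c in chains if c[0] == best[0]]
    if prefer == "right":
        chosen = max(ties, key=lambda c: c[2])
    else:
        chosen = min(ties, key=lambda c: c[1])
    return chosen[0], (chosen[1], chosen[2])


def scan_assembly_telomeres(
    assembly: Assembly, params: TelomereParams | None = None
) -> list[TelomereReport]:
    """Scan both termini of every scaffold for telomere arrays.

    ``start_copies`` is counted within the first ``terminal_window`` bases
    (CCCTAA), ``end_copies`` within the last ``terminal_window`` bases
    (TTAGGG).  Scaffolds shorter than the window are scanned whole, with a
    warning.
    """
    if len(assembly) == 0:
        raise ValueError("assembly is empty")
    params = params or TelomereParams()
    reports = []
    for scaffold in assembly:
        w = params.terminal_window
        if len(scaffold) < w:
            logger.warning(
                "scaffold %s (%d bp) shorter than terminal window (%d bp); "
                "scanning whole scaffold",
                scaffold.id, len(scaffold), w,
            )
            w = len(scaffold)
        start_copies, _ = longest_tandem_run(
            scaffold.sequence[:w], params.start_motif,
            params.max_interruption, prefer="left",
        )
        end_copies, _ = longest_tandem_run(
            scaffold.sequence[-w:], params.end_motif,
            params.max_interruption, prefer="right",
        )
        reports.append(
            TelomereReport(
                scaffold_id=scaffold.id,
                start_copies=start_copies,
                end_copies=end_copies,
                start_present=start_copies >= params.min_copies,
                end_present=end_copies >= params.min_copies,
            )
        )
    return reports
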