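"""Assembly curation decision engine with a complete audit log.

The pipeline mirrors a manual telomere-to-telomere curation workflow:

1. drop contigs shorter than the minimum input read length;
2. quarantine contigs matching mitochondrial references;
3. merge contigs that share a terminal overlap above the merge threshold;
4. split contigs with cross-assembly (chimera) evidence;
5. trim terminal bases without short-read coverage support;
6. rename scaffolds in decreasing length order.

Every decision is logged as a :class:`CurationAction` carrying the measured
evidence and enough parameters to re-apply it: :func:`replay_actions`
reproduces the final assembly from the baseline byte-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .assembly_compare import (
    OverlapReport,
    _anchor_arrays,
    chain_anchors,
    contig_correspondence,
    detect_terminal_overlap,
)
from .genome_model import (
    AlignmentRecord,
    Assembly,
    AssemblyStats,
    Scaffold,
    compute_assembly_stats,
    reverse_complement,
    union_aligned_length,
)
from .telomere_scan import (
    TelomereParams,
    TelomereReport,
    longest_tandem_run,
    scan_assembly_telomeres,
)

logger = logging.getLogger(__name__)

ACTION_KINDS = (
    "select", "drop_short", "flag_mito", "merge", "split", "trim",
    "recruit_reads", "rename",
)


@dataclass
class CurationConfig:
    """All thresholds of the curation pipeline.

    Defaults encode the workflow's decision rules: merge terminal overlaps
    of at least 50 kb, drop contigs shorter than the 10 kb minimum input
    read length, recruit reads of at least 10 kb that align elsewhere over
    less than 80% of their length, and trim terminal bases with no
    short-read support.
    """

    min_overlap: int = 50_000
    min_contig_length: int = 10_000
    min_read_length: int = 10_000
    drop_aligned_fraction: float = 0.80
    trim_min_depth: int = 1
    telomere: TelomereParams = field(default_factory=TelomereParams)
    k: int = 21
    mito_cover_fraction: float = 0.5
    max_gap: int = 10_000
    min_anchors: int = 50
    min_split_span: int = 50_000
    terminal_search: int = 200_000

    def __post_init__(self) -> None:
        if not (0 < self.drop_aligned_fraction <= 1):
            raise ValueError("drop_aligned_fraction must be in (0, 1]")
        for name in ("min_overlap", "min_contig_length", "min_read_length",
                     "trim_min_depth", "k", "max_gap", "min_anchors",
                     "min_split_span", "terminal_search"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CandidateSummary:
    """Continuity and telomere-support summary of one draft assembly."""

    assembler_name: str
    n_contigs: int
    n_contigs_ge_100kb: int
    n50: int
    l50: int
    t2t_count: int


@dataclass
class CurationAction:
    """One logged curation decision."""

    ordinal: int
    action_kind: str
    subjects: list[str]
    parameters: dict
    result_ids: list[str]

    def __post_init__(self) -> None:
        if self.action_kind not in ACTION_KINDS:
            raise ValueError(f"unknown action kind {self.action_kind!r}")


@dataclass
class CurationResult:
    """Final assembly plus the audit trail and summary reports."""

    assembly: Assembly
    actions: list[CurationAction]
    telomere_reports: list[TelomereReport]
    stats: AssemblyStats
    mitochondrial: list[Scaffold] = field(default_factory=list)
    dropped: list[Scaffold] = field(default_factory=list)
    coverage: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# baseline selection
# ---------------------------------------------------------------------------

def rank_candidates(candidates: Sequence[CandidateSummary]) -> list[CandidateSummary]:
    """Deterministic ranking: T2T count desc, contig count asc, N50 desc."""
    if not candidates:
        raise ValueError("no candidate assemblies to rank")
    return sorted(
        candidates,
        key=lambda c: (-c.t2t_count, c.n_contigs, -c.n50, c.assembler_name),
    )


def select_baseline(candidates: Sequence[CandidateSummary]) -> CandidateSummary:
    """Pick the baseline draft assembly (best-ranked candidate)."""
    return rank_candidates(candidates)[0]


def summarize_candidate(
    assembly: Assembly,
    name: str | None = None,
    telomere_params: TelomereParams | None = None,
    long_contig_threshold: int = 100_000,
) -> CandidateSummary:
    """Build a :class:`CandidateSummary` directly from an assembly."""
    stats = compute_assembly_stats(assembly)
    reports = scan_assembly_telomeres(assembly, telomere_params)
    return CandidateSummary(
        assembler_name=name or assembly.name,
        n_contigs=stats.n_scaffolds,
        n_contigs_ge_100kb=sum(1 for l in stats.lengths if l >= long_contig_threshold),
        n50=stats.n50,
        l50=stats.l50,
        t2t_count=sum(1 for r in reports if r.t2t),
    )


# ---------------------------------------------------------------------------
# individual operations
# ---------------------------------------------------------------------------

def drop_short_contigs(
    assembly: Assembly, min_contig_length: int = 10_000, _start_ordinal: int = 1
) -> tuple[Assembly, list[CurationAction]]:
    """Remove contigs shorter than the threshold (keep iff length >= it)."""
    kept, actions = [], []
    ordinal = _start_ordinal
    for s in assembly:
        if len(s) < min_contig_length:
            actions.append(
                CurationAction(
                    ordinal, "drop_short", [s.id],
                    {"length": len(s), "min_contig_length": min_contig_length}, [],
                )
            )
            ordinal += 1
        else:
            kept.append(s)
    return Assembly(assembly.name, kept), actions


def flag_mitochondrial(
    assembly: Assembly,
    mito_references: Assembly | None,
    config: CurationConfig | None = None,
) -> list[str]:
    """Ids of contigs whose anchor-chain coverage by any mitochondrial
    reference reaches ``mito_cover_fraction`` of their length."""
    config = config or CurationConfig()
    if mito_references is None or len(mito_references) == 0:
        logger.warning("no mitochondrial references supplied; nothing flagged")
        return []
    flagged = []
    for s in assembly:
        aset = _anchor_arrays(
            Assembly("query", [s]), mito_references, config.k
        )
        chains = chain_anchors(aset, config.max_gap)
        covered = union_aligned_length(
            c.a_span for c in chains if c.anchor_count >= 5
        )
        if covered / len(s) >= config.mito_cover_fraction:
            flagged.append(s.id)
    return flagged


def _normalized_merge(report: OverlapReport, len_b: int):
    """Normalise a reverse-orientation overlap to forward geometry.

    Returns ``(a_terminus, b_terminus, b_span, b_reversed)`` where the
    coordinates refer to the (possibly reverse-complemented) b sequence.
    """
    if report.orientation == "forward":
        return report.a_terminus, report.b_terminus, report.b_span, False
    s, e = report.b_span
    flipped = {"start": "end", "end": "start"}[report.b_terminus]
    return report.a_terminus, flipped, (len_b - e, len_b - s), True


def merge_by_overlap(
    scaffold_a: Scaffold,
    scaffold_b: Scaffold,
    overlap_report: OverlapReport,
    merged_id: str | None = None,
) -> Scaffold:
    """Concatenate two contigs across a detected terminal overlap.

    Overlap bases are taken from ``scaffold_a``; ``scaffold_b`` is
    reverse-complemented first when the overlap orientation is reverse.
    The merged length is |a| + |b| - overlap.
    """
    if not overlap_report.is_merge_candidate:
        raise ValueError(
            f"overlap of {overlap_report.overlap_length} bp between "
            f"{scaffold_a.id!r} and {scaffold_b.id!r} is not a merge candidate"
        )
    a_term, b_term, b_span, b_reversed = _normalized_merge(
        overlap_report, len(scaffold_b)
    )
    b_seq = (
        reverse_complement(scaffold_b.sequence) if b_reversed else scaffold_b.sequence
    )
    if a_term == "end" and b_term == "start":
        merged = scaffold_a.sequence + b_seq[b_span[1]:]
    elif a_term == "start" and b_term == "end":
        merged = b_seq[:b_span[0]] + scaffold_a.sequence
    else:
        raise ValueError(
            f"termini mismatch: a_{a_term} cannot dovetail with b_{b_term}"
        )
    return Scaffold(merged_id or f"{scaffold_a.id}+{scaffold_b.id}", merged)


def merge_coverage(
    coverage_a: np.ndarray,
    coverage_b: np.ndarray,
    overlap_report: OverlapReport,
) -> np.ndarray:
    """Coverage array for a merged contig, mirroring :func:`merge_by_overlap`."""
    a_term, b_term, b_span, b_reversed = _normalized_merge(
        overlap_report, len(coverage_b)
    )
    cov_b = coverage_b[::-1] if b_reversed else coverage_b
    if a_term == "end" and b_term == "start":
        return np.concatenate([coverage_a, cov_b[b_span[1]:]])
    return np.concatenate([cov_b[:b_span[0]], coverage_a])


def split_at_breakpoint(
    scaffold: Scaffold,
    breakpoint: int,
    evidence: Mapping | None = None,
    force: bool = False,
    part_ids: tuple[str, str] | None = None,
) -> tuple[Scaffold, Scaffold]:
    """Split a scaffold into two parts at ``breakpoint``.

    ``evidence`` must contain cross-assembly correspondence support
    (``"correspondence"``) and/or at least two centromere calls
    (``"centromeres"``) unless ``force`` is set.
    """
    if not (0 < breakpoint < len(scaffold)):
        raise ValueError(
            f"breakpoint {breakpoint} outside (0, {len(scaffold)}) for {scaffold.id!r}"
        )
    if not force:
        evidence = evidence or {}
        has_corr = bool(evidence.get("correspondence"))
        has_cen = len(evidence.get("centromeres", [])) >= 2
        if not (has_corr or has_cen):
            raise ValueError(
                f"refusing to split {scaffold.id!r} without correspondence or "
                "dual-centromere evidence (use force=True to override)"
            )
    ids = part_ids or (f"{scaffold.id}.1", f"{scaffold.id}.2")
    return (
        Scaffold(ids[0], scaffold.sequence[:breakpoint]),
        Scaffold(ids[1], scaffold.sequence[breakpoint:]),
    )


def refine_breakpoint_at_telomere_junction(
    sequence: str,
    breakpoint: int,
    params: TelomereParams | None = None,
    search: int = 5000,
    max_junction_gap: int = 100,
) -> int:
    """Snap a proposed breakpoint to a back-to-back telomere array boundary.

    A chimera joining two complete chromosomes carries the end-motif array
    of the left chromosome immediately followed by the start-motif array of
    the right one.  Anchor-chain midpoints locate such junctions only to
    within the telomere array length plus k, so when an end-motif run and a
    following start-motif run both occur within ``search`` bp of the
    proposal, the breakpoint is moved to the end of the end-motif run
    (= the true chromosome boundary).  Otherwise the proposal is returned
    unchanged.
    """
    params = params or TelomereParams()
    lo = max(0, breakpoint - search)
    hi = min(len(sequence), breakpoint + search)
    window = sequence[lo:hi]
    end_copies, end_span = longest_tandem_run(
        window, params.end_motif, params.max_interruption
    )
    start_copies, start_span = longest_tandem_run(
        window, params.start_motif, params.max_interruption
    )
    if end_copies >= params.min_copies and start_copies >= params.min_copies:
        gap = start_span[0] - end_span[1]
        if 0 <= gap <= max_junction_gap:
            return lo + end_span[1]
    return breakpoint


def trim_unsupported_ends(
    scaffold: Scaffold,
    coverage: np.ndarray,
    trim_min_depth: int = 1,
) -> tuple[Scaffold, int, int]:
    """Remove maximal terminal runs with depth below ``trim_min_depth``.

    Internal low-depth runs are untouched.  Returns the trimmed scaffold and
    the number of bases removed at each end.  Trimming is idempotent; a
    wholly unsupported scaffold raises rather than emitting an empty record.
    """
    depth = np.asarray(coverage)
    if len(depth) != len(scaffold):
        raise ValueError(
            f"coverage length {len(depth)} != scaffold length {len(scaffold)} "
            f"for {scaffold.id!r}"
        )
    supported = np.flatnonzero(depth >= trim_min_depth)
    if supported.size == 0:
        raise ValueError(f"scaffold {scaffold.id!r} has no supported bases")
    left = int(supported[0])
    right = len(scaffold) - int(supported[-1]) - 1
    if left == 0 and right == 0:
        return scaffold, 0, 0
    trimmed = scaffold.sequence[left:len(scaffold) - right]
    return Scaffold(scaffold.id, trimmed), left, right


def partition_unassigned_reads(
    alignments: Iterable[AlignmentRecord],
    excluded_scaffolds: Iterable[str],
    config: CurationConfig | None = None,
    read_lengths: Mapping[str, int] | None = None,
) -> list[str]:
    """Read ids to recruit for local reassembly of ``excluded_scaffolds``.

    A read is kept iff it is at least ``min_read_length`` long and the
    union of its alignments to scaffolds *outside* the excluded set covers
    less than ``drop_aligned_fraction`` of its length.  ``read_lengths``
    may supply reads with no alignments at all (kept when long enough).
    """
    config = config or CurationConfig()
    excluded = set(excluded_scaffolds)
    by_read: dict[str, list[AlignmentRecord]] = {}
    lengths: dict[str, int] = dict(read_lengths or {})
    for rec in alignments:
        by_read.setdefault(rec.query_id, []).append(rec)
        lengths.setdefault(rec.query_id, rec.query_length)
    kept = []
    for read_id in lengths:
        qlen = lengths[read_id]
        if qlen < config.min_read_length:
            continue
        elsewhere = [
            (r.query_start, r.query_end)
            for r in by_read.get(read_id, [])
            if r.target_id not in excluded
        ]
        fraction = union_aligned_length(elsewhere) / qlen
        if fraction < config.drop_aligned_fraction:
            kept.append(read_id)
    return kept


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _coverage_dict(coverage) -> dict[str, np.ndarray]:
    if coverage is None:
        return {}
    if isinstance(coverage, Mapping):
        return {k: np.asarray(v) for k, v in coverage.items()}
    return {t.scaffold_id: np.asarray(t.depth) for t in coverage}


def curate(
    baseline_assembly: Assembly,
    alternate_assemblies: Sequence[Assembly] = (),
    coverage=None,
    mito_refs: Assembly | None = None,
    config: CurationConfig | None = None,
) -> CurationResult:
    """Run the full curation pipeline on a baseline assembly.

    Stage order: drop_short -> flag_mito -> merge -> split -> trim ->
    rename (decreasing length).  ``coverage`` maps baseline contig ids to
    per-base depth arrays (or is a list of CoverageTracks); it is carried
    through merges and splits so end trimming applies to derived scaffolds.
    Deterministic given identical inputs and configuration.
    """
    if len(baseline_assembly) == 0:
        raise ValueError("baseline assembly is empty")
    config = config or CurationConfig()
    cov = _coverage_dict(coverage)
    actions: list[CurationAction] = []
    ordinal = 1

    def log(kind: str, subjects: list[str], params: dict, results: list[str]):
        nonlocal ordinal
        actions.append(CurationAction(ordinal, kind, subjects, params, results))
        ordinal += 1

    # stage 1: drop short contigs
    working: list[Scaffold] = []
    dropped: list[Scaffold] = []
    for s in baseline_assembly:
        if len(s) < config.min_contig_length:
            dropped.append(s)
            log("drop_short", [s.id],
                {"length": len(s), "min_contig_length": config.min_contig_length}, [])
        else:
            working.append(s)

    # stage 2: quarantine mitochondrial contigs
    mitochondrial: list[Scaffold] = []
    if mito_refs is not None and len(mito_refs) > 0:
        flagged = set(
            flag_mitochondrial(Assembly("working", working), mito_refs, config)
        )
        still = []
        for s in working:
            if s.id in flagged:
                mitochondrial.append(s)
                log("flag_mito", [s.id],
                    {"mito_cover_fraction": config.mito_cover_fraction}, [s.id])
            else:
                still.append(s)
        working = still

    # stage 3: merge terminal overlaps (longest-first, repeat to fixpoint)
    while True:
        candidates: list[tuple[OverlapReport, Scaffold, Scaffold]] = []
        for i in range(len(working)):
            for j in range(i + 1, len(working)):
                a, b = working[i], working[j]
                if len(b) > len(a):
                    a, b = b, a  # overlap bases come from the longer contig
                report = detect_terminal_overlap(
                    a, b, k=config.k, min_overlap=config.min_overlap,
                    terminal_search=config.terminal_search, max_gap=config.max_gap,
                )
                if report.is_merge_candidate:
                    candidates.append((report, a, b))
        if not candidates:
            break
        report, a, b = max(
            candidates, key=lambda t: (t[0].overlap_length, t[1].id, t[2].id)
        )
        merged = merge_by_overlap(a, b, report)
        log(
            "merge", [a.id, b.id],
            {
                "overlap_length": report.overlap_length,
                "orientation": report.orientation,
                "a_terminus": report.a_terminus,
                "b_terminus": report.b_terminus,
                "a_span": list(report.a_span),
                "b_span": list(report.b_span),
            },
            [merged.id],
        )
        if a.id in cov and b.id in cov:
            cov[merged.id] = merge_coverage(cov.pop(a.id), cov.pop(b.id), report)
        working = [s for s in working if s.id not in {a.id, b.id}] + [merged]

    # stage 4: split chimeras on cross-assembly correspondence evidence
    if alternate_assemblies:
        current = Assembly("working", working)
        breakpoint_lists: dict[str, list[int]] = {}
        evidence_map: dict[str, list] = {}
        for alt in alternate_assemblies:
            aset = _anchor_arrays(current, alt, config.k)
            entries = contig_correspondence(
                aset,
                min_anchors=config.min_anchors,
                min_span=config.min_split_span,
                max_gap=config.max_gap,
            )
            for entry in entries:
                if entry.is_split_candidate:
                    breakpoint_lists.setdefault(entry.a_scaffold, []).extend(
                        entry.breakpoints
                    )
                    evidence_map.setdefault(entry.a_scaffold, []).append(entry)
        new_working = []
        for s in working:
            proposals = sorted(breakpoint_lists.get(s.id, []))
            if not proposals:
                new_working.append(s)
                continue
            # cluster proposals from multiple alternates within max_gap
            clustered: list[int] = []
            for bp in proposals:
                if clustered and bp - clustered[-1] <= config.max_gap:
                    clustered[-1] = (clustered[-1] + bp) // 2
                else:
                    clustered.append(bp)
            pieces = [s]
            offset = 0
            for bp in clustered:
                target = pieces[-1]
                local = refine_breakpoint_at_telomere_junction(
                    target.sequence, bp - offset, config.telomere
                )
                n = len(pieces)
                left, right = split_at_breakpoint(
                    target, local,
                    evidence={"correspondence": evidence_map[s.id]},
                    part_ids=(f"{s.id}.{n}", f"{s.id}.{n + 1}"),
                )
                log(
                    "split", [target.id],
                    {"breakpoint": offset + local, "breakpoint_local": local,
                     "proposed": bp, "evidence": "correspondence"},
                    [left.id, right.id],
                )
                if target.id in cov or s.id in cov:
                    src = cov.pop(target.id, None)
                    if src is None:
                        src = cov.pop(s.id)
                    cov[left.id] = src[:local]
                    cov[right.id] = src[local:]
                pieces[-1:] = [left, right]
                offset += local
            new_working.extend(pieces)
        working = new_working

    # stage 5: trim unsupported ends
    if cov:
        trimmed_working = []
        for s in working:
            if s.id not in cov:
                trimmed_working.append(s)
                continue
            trimmed, left, right = trim_unsupported_ends(
                s, cov[s.id], config.trim_min_depth
            )
            if left or right:
                log("trim", [s.id],
                    {"left": left, "right": right,
                     "trim_min_depth": config.trim_min_depth}, [s.id])
                cov[s.id] = cov[s.id][left:len(cov[s.id]) - right]
            trimmed_working.append(trimmed)
        working = trimmed_working

    # stage 6: rename in decreasing length order
    order = sorted(working, key=lambda s: (-len(s), s.id))
    mapping = {s.id: f"scaffold_{i}" for i, s in enumerate(order, start=1)}
    renamed = [Scaffold(mapping[s.id], s.sequence) for s in order]
    log("rename", [s.id for s in order], {"mapping": mapping},
        [mapping[s.id] for s in order])
    cov = {mapping.get(k, k): v for k, v in cov.items() if k in mapping}

    final = Assembly(f"{baseline_assembly.name}.curated", renamed)
    return CurationResult(
        assembly=final,
        actions=actions,
        telomere_reports=scan_assembly_telomeres(final, config.telomere),
        stats=compute_assembly_stats(final),
        mitochondrial=mitochondrial,
        dropped=dropped,
        coverage=cov,
    )


def replay_actions(
    baseline_assembly: Assembly, actions: Sequence[CurationAction]
) -> Assembly:
    """Re-apply a curation action log to the baseline assembly.

    Uses only the logged parameters (no re-measurement); the result must be
    byte-identical to the assembly the log was recorded from.
    """
    scaffolds = {s.id: s for s in baseline_assembly}
    for act in actions:
        if act.action_kind in {"drop_short", "flag_mito"}:
            for sid in act.subjects:
                scaffolds.pop(sid, None)
        elif act.action_kind == "merge":
            a = scaffolds.pop(act.subjects[0])
            b = scaffolds.pop(act.subjects[1])
            p = act.parameters
            report = OverlapReport(
                a_scaffold=a.id, b_scaffold=b.id,
                a_terminus=p["a_terminus"], b_terminus=p["b_terminus"],
                overlap_length=p["overlap_length"], orientation=p["orientation"],
                is_merge_candidate=True,
                a_span=tuple(p["a_span"]), b_span=tuple(p["b_span"]),
            )
            merged = merge_by_overlap(a, b, report, merged_id=act.result_ids[0])
            scaffolds[merged.id] = merged
        elif act.action_kind == "split":
            target = scaffolds.pop(act.subjects[0])
            local = act.parameters.get(
                "breakpoint_local", act.parameters["breakpoint"]
            )
            left, right = split_at_breakpoint(
                target, local, force=True,
                part_ids=(act.result_ids[0], act.result_ids[1]),
            )
            scaffolds[left.id] = left
            scaffolds[right.id] = right
        elif act.action_kind == "trim":
            sid = act.subjects[0]
            s = scaffolds[sid]
            left, right = act.parameters["left"], act.parameters["right"]
            scaffolds[sid] = Scaffold(sid, s.sequence[left:len(s) - right])
        elif act.action_kind == "rename":
            mapping = act.parameters["mapping"]
            scaffolds = {
                mapping[k]: Scaffold(mapping[k], v.sequence)
                for k, v in scaffolds.items()
                if k in mapping
            }
    order = sorted(scaffolds.values(), key=lambda s: (-len(s), s.id))
    return Assembly(f"{baseline_assembly.name}.curated", order)
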