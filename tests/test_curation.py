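import numpy as np
import pytest

from t2tcurate.assembly_compare import detect_terminal_overlap
from t2tcurate.curation import (
    CandidateSummary,
    CurationConfig,
    curate,
    drop_short_contigs,
    flag_mitochondrial,
    merge_by_overlap,
    partition_unassigned_reads,
    rank_candidates,
    refine_breakpoint_at_telomere_junction,
    replay_actions,
    select_baseline,
    split_at_breakpoint,
    trim_unsupported_ends,
)
from t2tcurate.genome_model import AlignmentRecord, Assembly, Scaffold
from t2tcurate.synthetic import _apply_noise, make_benchmark

from conftest import random_sequence


# ---------------------------------------------------------------------------
# baseline selection
# ---------------------------------------------------------------------------

def _cand(name, n, t2t, n50=5_000_000, ge100=7, l50=3):
    return CandidateSummary(name, n, ge100, n50, l50, t2t)


def test_select_baseline_prefers_t2t_support():
    cands = [
        _cand("asm_a", 9, 5, n50=6_400_000),
        _cand("asm_b", 25, 3),
        _cand("asm_c", 12, 4),
        _cand("asm_d", 40, 2),
        _cand("asm_e", 15, 5, n50=5_000_000),  # tied T2T, more contigs
    ]
    best = select_baseline(cands)
    assert best.assembler_name == "asm_a"
    ranked = rank_candidates(cands)
    assert [c.assembler_name for c in ranked][:2] == ["asm_a", "asm_e"]


def test_select_baseline_single_candidate_and_tiebreak():
    only = _cand("solo", 9, 5)
    assert select_baseline([only]) is only
    a, b = _cand("x", 9, 4), _cand("y", 12, 4)
    assert select_baseline([a, b]).assembler_name == "x"
    with pytest.raises(ValueError):
        select_baseline([])


# ---------------------------------------------------------------------------
# drop / flag
# ---------------------------------------------------------------------------

def test_drop_short_boundary_semantics(rng):
    assembly = Assembly(
        "a",
        [
            Scaffold("keep", random_sequence(rng, 10_000)),
            Scaffold("drop", random_sequence(rng, 5_000)),
        ],
    )
    out, actions = drop_short_contigs(assembly, 10_000)
    assert out.ids == ["keep"]
    assert [a.subjects for a in actions] == [["drop"]]


def test_drop_short_noop_when_all_long(rng):
    assembly = Assembly("a", [Scaffold("s", random_sequence(rng, 50_000))])
    out, actions = drop_short_contigs(assembly, 10_000)
    assert out.ids == ["s"] and actions == []


def test_flag_mitochondrial_on_noisy_copy(rng):
    mito = random_sequence(rng, 28_000, gc=0.3)
    contig = Scaffold("m", _apply_noise(rng, mito, 0.01))
    nuclear = Scaffold("n", random_sequence(rng, 60_000))
    refs = Assembly("refs", [Scaffold("related_mito", mito)])
    flagged = flag_mitochondrial(Assembly("a", [contig, nuclear]), refs)
    assert flagged == ["m"]


def test_flag_mitochondrial_ignores_small_insert(rng):
    mito = random_sequence(rng, 28_000, gc=0.3)
    insert = mito[:3_000]
    nuclear = Scaffold(
        "n", random_sequence(rng, 30_000) + insert + random_sequence(rng, 30_000)
    )
    refs = Assembly("refs", [Scaffold("related_mito", mito)])
    assert flag_mitochondrial(Assembly("a", [nuclear]), refs) == []


def test_flag_mitochondrial_without_references(rng, caplog):
    assembly = Assembly("a", [Scaffold("s", random_sequence(rng, 20_000))])
    with caplog.at_level("WARNING"):
        assert flag_mitochondrial(assembly, None) == []
    assert any("no mitochondrial references" in m for m in caplog.messages)


# ---------------------------------------------------------------------------
# merge / split / trim
# ---------------------------------------------------------------------------

def test_merge_reconstructs_truth_chromosome(rng):
    chrom = random_sequence(rng, 300_000)
    p = 150_000
    a = Scaffold("a", chrom[:p + 60_000])
    b = Scaffold("b", chrom[p:])
    report = detect_terminal_overlap(a, b)
    merged = merge_by_overlap(a, b, report)
    assert merged.sequence == chrom
    assert len(merged) == len(a) + len(b) - report.overlap_length


def test_merge_rejects_subthreshold_overlap(rng):
    chrom = random_sequence(rng, 200_000)
    a = Scaffold("a", chrom[:110_000])
    b = Scaffold("b", chrom[100_000:])
    report = detect_terminal_overlap(a, b)  # 10 kb < 50 kb rule
    assert not report.is_merge_candidate
    with pytest.raises(ValueError):
        merge_by_overlap(a, b, report)


def test_split_conserves_length_and_guards(rng):
    s = Scaffold("s", random_sequence(rng, 10_000))
    left, right = split_at_breakpoint(s, 4_000, force=True)
    assert len(left) + len(right) == len(s)
    assert left.sequence + right.sequence == s.sequence
    with pytest.raises(ValueError):
        split_at_breakpoint(s, 0, force=True)
    with pytest.raises(ValueError):
        split_at_breakpoint(s, len(s), force=True)
    with pytest.raises(ValueError):
        split_at_breakpoint(s, 4_000)  # no evidence, no force


def test_refine_breakpoint_snaps_to_telomere_junction(rng):
    left = random_sequence(rng, 20_000) + "TTAGGG" * 14
    right = "CCCTAA" * 13 + random_sequence(rng, 20_000)
    seq = left + right
    proposed = len(left) + int(rng.integers(-3000, 3000))
    assert refine_breakpoint_at_telomere_junction(seq, proposed) == len(left)
    # far from any junction: proposal returned unchanged
    plain = random_sequence(rng, 50_000).replace("TTAGGG", "TTAGGC")
    assert refine_breakpoint_at_telomere_junction(plain, 25_000) == 25_000


def test_trim_removes_only_terminal_unsupported_runs(rng):
    seq = random_sequence(rng, 1_000)
    depth = np.full(1_000, 20)
    depth[:100] = 0
    depth[400:450] = 0  # internal zero run untouched
    trimmed, left, right = trim_unsupported_ends(Scaffold("s", seq), depth)
    assert (left, right) == (100, 0)
    assert trimmed.sequence == seq[100:]
    again, l2, r2 = trim_unsupported_ends(trimmed, depth[100:])
    assert (l2, r2) == (0, 0) and again.sequence == trimmed.sequence


def test_trim_matches_linear_scan_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(50, 500))
        depth = (rng.random(n) > 0.3).astype(int)
        if not depth.any():
            continue
        seq = random_sequence(rng, n)
        trimmed, left, right = trim_unsupported_ends(Scaffold("s", seq), depth)
        exp_left = 0
        while depth[exp_left] == 0:
            exp_left += 1
        exp_right = 0
        while depth[n - 1 - exp_right] == 0:
            exp_right += 1
        assert (left, right) == (exp_left, exp_right)
        assert len(trimmed) == n - exp_left - exp_right


def test_trim_refuses_fully_unsupported_scaffold(rng):
    with pytest.raises(ValueError):
        trim_unsupported_ends(
            Scaffold("s", random_sequence(rng, 100)), np.zeros(100)
        )


# ---------------------------------------------------------------------------
# read partitioning
# ---------------------------------------------------------------------------

def test_partition_reads_applies_both_gates():
    alns = [
        AlignmentRecord("dropped", 10_000, 0, 8_000, "chr1", "+"),   # 0.80 >= 0.80
        AlignmentRecord("kept", 10_000, 0, 7_900, "chr1", "+"),      # 0.79 < 0.80
        AlignmentRecord("short", 9_000, 0, 0 + 100, "chr1", "+"),    # < 10 kb
        AlignmentRecord("local", 12_000, 0, 12_000, "rebuild_me", "+"),
    ]
    kept = partition_unassigned_reads(
        alns, excluded_scaffolds=["rebuild_me"],
        read_lengths={"unaligned": 15_000, "tiny": 2_000},
    )
    assert set(kept) == {"kept", "local", "unaligned"}


def test_partition_reads_unions_split_alignments():
    alns = [
        AlignmentRecord("r", 10_000, 0, 6_000, "chr1", "+"),
        AlignmentRecord("r", 10_000, 4_000, 9_000, "chr2", "-"),
    ]
    # union 9000/10000 = 0.9 >= 0.8 -> dropped
    assert partition_unassigned_reads(alns, excluded_scaffolds=[]) == []


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def test_curate_fixed_point_on_perfect_baseline(rng):
    scaffolds = [
        Scaffold(f"c{i}", random_sequence(rng, 120_000)) for i in range(3)
    ]
    baseline = Assembly("perfect", scaffolds)
    coverage = {s.id: np.full(len(s), 25) for s in baseline}
    result = curate(baseline, [], coverage, None)
    kinds = {a.action_kind for a in result.actions}
    assert kinds == {"rename"}
    assert sorted(s.sequence for s in result.assembly) == \
        sorted(s.sequence for s in baseline)
    assert result.assembly.ids == ["scaffold_1", "scaffold_2", "scaffold_3"]


def test_curate_is_deterministic():
    b = make_benchmark(3)
    r1 = curate(b.baseline, b.alternates, b.coverage, b.mito_ref)
    r2 = curate(b.baseline, b.alternates, b.coverage, b.mito_ref)
    assert [s.sequence for s in r1.assembly] == [s.sequence for s in r2.assembly]
    assert [(a.action_kind, a.subjects, a.parameters) for a in r1.actions] == \
        [(a.action_kind, a.subjects, a.parameters) for a in r2.actions]


def test_curate_base_conservation_and_replay():
    """Final length = baseline - dropped - quarantined - overlap - trimmed."""
    b = make_benchmark(4)
    result = curate(b.baseline, b.alternates, b.coverage, b.mito_ref)
    expected = b.baseline.total_length()
    for act in result.actions:
        if act.action_kind == "drop_short":
            expected -= act.parameters["length"]
        elif act.action_kind == "trim":
            expected -= act.parameters["left"] + act.parameters["right"]
    expected -= sum(len(s) for s in result.mitochondrial)
    for act in result.actions:
        if act.action_kind == "merge":
            expected -= act.parameters["b_span"][1] - act.parameters["b_span"][0]
    assert result.assembly.total_length() == expected

    replayed = replay_actions(b.baseline, result.actions)
    assert replayed.ids == result.assembly.ids
    assert [s.sequence for s in replayed] == [s.sequence for s in result.assembly]


def test_curate_empty_baseline_errors():
    with pytest.raises(ValueError):
        curate(Assembly("empty", []))


def test_config_validation():
    with pytest.raises(ValueError):
        CurationConfig(drop_aligned_fraction=0.0)
    with pytest.raises(ValueError):
        CurationConfig(min_overlap=-1)
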