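import numpy as np
import pytest

from t2tcurate.genome_model import Assembly, CoverageTrack, GeneFeature, Scaffold
from t2tcurate.landscape import (
    coverage_window_track,
    detect_centromere,
    detect_tandem_cluster,
    gc_window_track,
    gene_count_track,
    peak_regions,
    window_track,
)
from t2tcurate.synthetic import (
    ChromosomeSpec,
    GenomeSpec,
    RrnaClusterSpec,
    generate_genome,
    simulate_coverage,
)

from conftest import random_sequence


# ---------------------------------------------------------------------------
# window tracks
# ---------------------------------------------------------------------------

def test_all_g_window_saturates():
    track = gc_window_track(Scaffold("s", "G" * 1000), 1000)
    assert track.values.tolist() == [100.0]


def test_uniform_coverage_log2_closed_form():
    track = coverage_window_track(CoverageTrack("s", np.full(2000, 4)), 1000)
    assert track.values == pytest.approx([np.log2(5.0)] * 2)


def test_all_n_window_flagged_missing():
    track = gc_window_track(Scaffold("s", "N" * 1000 + "G" * 500), 1000)
    assert np.isnan(track.values[0]) and track.values[1] == 100.0


def test_window_size_floor():
    with pytest.raises(ValueError):
        window_track(Scaffold("s", "ACGT" * 100), 50, "gc_percent")


def test_tracks_match_per_base_oracle(rng):
    """GC and log2-coverage windows vs direct per-window recomputation."""
    for _ in range(100):
        n = int(rng.integers(900, 3000))
        w = int(rng.integers(100, 400))
        seq = random_sequence(rng, n, gc=float(rng.uniform(0.2, 0.8)))
        depth = rng.integers(0, 50, size=n)
        gc = gc_window_track(Scaffold("s", seq), w)
        cov = coverage_window_track(CoverageTrack("s", depth), w)
        assert len(gc) == -(-n // w)
        for i in range(len(gc)):
            sub = seq[i * w:(i + 1) * w]
            expected = 100.0 * (sub.count("G") + sub.count("C")) / len(sub)
            assert gc.values[i] == pytest.approx(expected)
            dsub = depth[i * w:(i + 1) * w]
            assert cov.values[i] == pytest.approx(np.log2(dsub.mean() + 1))


def test_gc_mass_conservation(rng):
    seq = random_sequence(rng, 12_345, gc=0.43)
    w = 1000
    track = gc_window_track(Scaffold("s", seq), w)
    masses = []
    for i, v in enumerate(track.values):
        sub = seq[i * w:(i + 1) * w]
        non_n = len(sub) - sub.count("N")
        masses.append(v * non_n / 100.0)
    assert sum(masses) == pytest.approx(seq.count("G") + seq.count("C"))


def test_gene_counts_sum_to_feature_count(rng):
    L = 250_000
    features = [
        GeneFeature("s", int(p), int(p) + 100, "+", "gene")
        for p in rng.integers(0, L - 100, size=77)
    ]
    track = gene_count_track(features, "s", L, 100_000)
    assert track.values.sum() == 77
    assert len(track) == 3


# ---------------------------------------------------------------------------
# centromere
# ---------------------------------------------------------------------------

def _planted_chromosome(seed, fraction):
    spec = GenomeSpec(
        chromosomes=[ChromosomeSpec(400_000, centromere_fraction=fraction)],
        include_mito=False,
        seed=seed,
    )
    genome, features, truth = generate_genome(spec)
    s = genome[0]
    gc = gc_window_track(s, 1000)
    genes = gene_count_track(features, s.id, len(s), 1000)
    return s, gc, genes, truth.chromosomes[s.id]


def test_centromere_recovered_at_midpoint():
    s, gc, genes, truth = _planted_chromosome(5, 0.5)
    call = detect_centromere(gc, genes, scaffold_length=len(s))
    assert call.classification == "metacentric"
    assert abs(call.position - sum(truth.centromere) // 2) <= 2000
    assert not call.low_confidence


def test_offcentre_centromere_is_submetacentric():
    s, gc, genes, truth = _planted_chromosome(6, 0.25)
    call = detect_centromere(gc, genes, scaffold_length=len(s))
    assert call.classification == "submetacentric"
    assert call.arm_ratio == pytest.approx(3.0, rel=0.1)
    assert call.arm_short + call.arm_long == len(s)


def test_uniform_tracks_flagged_low_confidence(rng):
    seq = random_sequence(rng, 200_000)
    s = Scaffold("flat", seq)
    gc = gc_window_track(s, 1000)
    genes = gene_count_track(
        [GeneFeature("flat", int(p), int(p) + 100, "+", "gene")
         for p in rng.integers(0, len(seq) - 100, size=60)],
        "flat", len(seq), 1000,
    )
    call = detect_centromere(gc, genes, scaffold_length=len(s))
    assert call.low_confidence


def test_centromere_requires_enough_windows(rng):
    s = Scaffold("short", random_sequence(rng, 50_000))
    gc = gc_window_track(s, 1000)
    genes = gene_count_track([], "short", len(s), 1000)
    with pytest.raises(ValueError):
        detect_centromere(gc, genes)


def test_centromere_recovery_rate_over_seeded_genomes():
    """>= 95% of 40 planted genomes recovered within +-2 windows."""
    hits = 0
    for seed in range(40):
        fraction = 0.3 + 0.4 * (seed % 5) / 4
        s, gc, genes, truth = _planted_chromosome(1000 + seed, fraction)
        call = detect_centromere(gc, genes, scaffold_length=len(s))
        if abs(call.position - sum(truth.centromere) // 2) <= 2000:
            hits += 1
    assert hits >= 38


# ---------------------------------------------------------------------------
# tandem rRNA cluster
# ---------------------------------------------------------------------------

def _rrna(scaffold, pos, label, strand="+", ident=None):
    return GeneFeature(
        scaffold, pos, pos + 100, strand, "rRNA",
        {"ID": ident or f"{label}@{pos}", "product": f"{label} ribosomal RNA"},
    )


def test_single_unit_counts_one():
    feats = [_rrna("s", 0, "18S"), _rrna("s", 200, "5.8S"), _rrna("s", 400, "26S")]
    call = detect_tandem_cluster(feats)
    assert call.copies == 1
    assert call.span == (0, 500)
    assert len(call.member_feature_ids) == 3


def test_planted_tandem_copies_with_spacers(rng):
    feats = []
    pos = 0
    for _ in range(4):
        for label in ("18S", "5.8S", "26S"):
            feats.append(_rrna("s", pos, label))
            pos += 100 + int(rng.integers(100, 4900))
    call = detect_tandem_cluster(feats)
    assert call.copies == 4
    assert len(call.member_feature_ids) == 12


def test_gap_cap_prevents_chaining_across_chromosome():
    feats = []
    pos = 0
    for label in ("18S", "5.8S", "26S"):
        feats.append(_rrna("s", pos, label)); pos += 300
    pos += 200_000  # far-away second copy must not chain
    for label in ("18S", "5.8S", "26S"):
        feats.append(_rrna("s", pos, label)); pos += 300
    assert detect_tandem_cluster(feats).copies == 1


def test_no_unit_occurrence_counts_zero():
    feats = [_rrna("s", 0, "5.8S"), _rrna("s", 200, "26S")]
    call = detect_tandem_cluster(feats)
    assert call.copies == 0 and call.span == (0, 0)


def test_minus_strand_cluster_detected():
    feats = []
    pos = 0
    for _ in range(3):
        for label in ("26S", "5.8S", "18S"):  # reversed order on minus strand
            feats.append(_rrna("s", pos, label, strand="-"))
            pos += 300
    assert detect_tandem_cluster(feats).copies == 3


def test_tandem_cluster_matches_bruteforce_oracle(rng):
    """Detector equals an oracle scoring every substring of the labels."""
    labels = ["18S", "5.8S", "26S"]

    def oracle(seq_labels, unit):
        best = 0
        n, u = len(seq_labels), len(unit)
        for start in range(n):
            copies = 0
            i = start
            while i + u <= n and tuple(seq_labels[i:i + u]) == tuple(unit):
                copies += 1
                i += u
            best = max(best, copies)
        return best

    for _ in range(60):
        seq_labels = [labels[int(i)] for i in rng.integers(0, 3, size=rng.integers(1, 15))]
        feats = [_rrna("s", 300 * i, lab) for i, lab in enumerate(seq_labels)]
        assert detect_tandem_cluster(feats).copies == oracle(seq_labels, labels)


# ---------------------------------------------------------------------------
# coverage peaks
# ---------------------------------------------------------------------------

def test_flat_track_has_no_peaks():
    assert peak_regions(CoverageTrack("s", np.full(10_000, 30))) == []


def test_all_zero_track_has_no_peaks():
    assert peak_regions(CoverageTrack("s", np.zeros(5000, dtype=int))) == []


def test_planted_high_coverage_region_recovered():
    genome = Assembly(
        "g", [Scaffold("c", random_sequence(np.random.default_rng(3), 200_000))]
    )
    (track,) = simulate_coverage(
        genome, mean_depth=30, boost=(("c", 100_000, 120_000), 50.0), seed=3
    )
    peaks = peak_regions(track, fold_over_median=10)
    assert len(peaks) == 1
    s, e = peaks[0]
    overlap = min(e, 120_000) - max(s, 100_000)
    assert overlap >= 0.95 * 20_000


def test_nearby_peaks_merge_across_small_gap():
    depth = np.full(10_000, 30)
    depth[2000:3000] = 500
    depth[3500:4500] = 500  # 500 bp gap < 1 kb merge rule
    peaks = peak_regions(CoverageTrack("s", depth))
    assert len(peaks) == 1
    assert peaks[0] == (2000, 4500)
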