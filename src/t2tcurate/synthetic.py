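"""Seeded planted-truth genome, assembly, coverage and expression simulation.

This module emulates the structures the curation toolkit reasons about, at
desk scale, so every detector can be tested against known ground truth:

* chromosomes with terminal (CCCTAA)n / (TTAGGG)n arrays of known copy
  number, an AT-rich gene-free centromere, and (optionally) a tandem rRNA
  cistron array;
* candidate assemblies derived from the truth genome by fragmentation,
  terminal-overlap duplication, chimeric joins, junk contigs and
  substitution noise, with base-exact provenance;
* per-base coverage tracks with unsupported (zero-depth) segments and
  high-coverage repeat peaks;
* negative-binomial count tables with planted log2 fold changes and a
  documented stand-in test statistic (Welch t on log2 counts with
  Benjamini-Hochberg step-up adjustment) — not a reimplementation of any
  external differential-expression model.

All randomness flows from the integer seed; identical seed and spec give
byte-identical outputs.

Guard bases: 7-12 bp of motif-free 'GT' alternation are written
immediately interior to each planted telomere array so that a randomly
drawn motif copy in the body can never chain onto the planted array and
corrupt the planted copy number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests

from .genome_model import Assembly, CoverageTrack, GeneFeature, Scaffold, reverse_complement
from .telomere_scan import END_MOTIF, START_MOTIF

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_START_GUARD = "GTGTGTG"  # blocks CCCTAA chaining past the array
_END_GUARD = "GTGTGTGTGTGT"  # blocks TTAGGG chaining before the array


# ---------------------------------------------------------------------------
# specs and truth
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeSpec:
    length: int
    start_telomere_copies: int = 13
    end_telomere_copies: int = 14
    centromere_fraction: float = 0.5
    centromere_width: int = 30_000
    at_boost: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.centromere_fraction < 1):
            raise ValueError("centromere_fraction must be in (0, 1)")
        if self.centromere_width >= self.length:
            raise ValueError("centromere wider than chromosome")


@dataclass
class RrnaClusterSpec:
    chromosome_index: int = 0
    copies: int = 7
    unit_lengths: tuple[int, int, int] = (1800, 160, 3400)  # 18S, 5.8S, 26S
    spacer_length: int = 300  # ITS1/ITS2 and inter-repeat spacers
    position_fraction: float = 0.75


@dataclass
class GenomeSpec:
    """Planted-truth genome specification; the seed fixes all randomness."""

    chromosomes: list[ChromosomeSpec]
    rrna_cluster: RrnaClusterSpec | None = None
    mito_length: int = 28_000
    include_mito: bool = True
    base_gc: float = 0.48
    gene_density_bp: int = 3000  # one gene per this many bases
    gene_length: int = 1500
    seed: int = 0


@dataclass
class ChromosomeTruth:
    start_telomere_copies: int
    end_telomere_copies: int
    centromere: tuple[int, int]
    rrna_span: tuple[int, int] | None = None
    rrna_copies: int = 0


@dataclass
class TruthRecord:
    """Ground truth of one generated artifact set."""

    chromosomes: dict[str, ChromosomeTruth] = field(default_factory=dict)
    mito_sequence: str | None = None
    contig_provenance: dict[str, list] = field(default_factory=dict)
    planted_log2fc: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, ChromosomeTruth):
                return o.__dict__
            raise TypeError(o)
        payload = {
            "chromosomes": {k: v.__dict__ for k, v in self.chromosomes.items()},
            "mito_length": len(self.mito_sequence) if self.mito_sequence else 0,
            "contig_provenance": self.contig_provenance,
            "planted_log2fc": self.planted_log2fc,
        }
        return json.dumps(payload, indent=1, default=enc)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _overwrite(arr: np.ndarray, pos: int, text: str) -> None:
    raw = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    arr[pos:pos + len(raw)] = raw


def generate_genome(
    spec: GenomeSpec,
) -> tuple[Assembly, list[GeneFeature], TruthRecord]:
    """Generate a planted-truth genome with features and a truth record.

    Each chromosome is (CCCTAA) x n_start + body + (TTAGGG) x n_end at its
    exact specified length; the centromere window is AT-boosted and
    gene-free; the rRNA cluster (if any) is planted as tandem labelled unit
    copies; gene features are scattered outside the centromere.
    """
    rng = np.random.default_rng(spec.seed)
    scaffolds: list[Scaffold] = []
    features: list[GeneFeature] = []
    truth = TruthRecord()

    for ci, chrom in enumerate(spec.chromosomes):
        name = f"chr_{ci + 1}"
        L = chrom.length
        arr = _random_bases(rng, L, spec.base_gc)

        start_arr = START_MOTIF * chrom.start_telomere_copies
        end_arr = END_MOTIF * chrom.end_telomere_copies
        _overwrite(arr, 0, start_arr + _START_GUARD)
        _overwrite(arr, L - len(end_arr) - len(_END_GUARD), _END_GUARD + end_arr)

        cen_mid = int(L * chrom.centromere_fraction)
        cen_lo = max(0, cen_mid - chrom.centromere_width // 2)
        cen_hi = min(L, cen_lo + chrom.centromere_width)
        cen_gc = max(0.02, spec.base_gc - chrom.at_boost)
        arr[cen_lo:cen_hi] = _random_bases(rng, cen_hi - cen_lo, cen_gc)

        rrna_span = None
        rrna_copies = 0
        cluster = spec.rrna_cluster
        if cluster is not None and cluster.chromosome_index == ci:
            unit_seqs = [
                _random_bases(rng, ul, spec.base_gc) for ul in cluster.unit_lengths
            ]
            labels = ("18S", "5.8S", "26S")
            pos = int(L * cluster.position_fraction)
            span_start = pos
            for copy_i in range(cluster.copies):
                for label, useq in zip(labels, unit_seqs):
                    arr[pos:pos + len(useq)] = useq
                    features.append(
                        GeneFeature(
                            scaffold_id=name,
                            start=pos,
                            end=pos + len(useq),
                            strand="+",
                            feature_type="rRNA",
                            attributes={
                                "ID": f"{name}_rrna_{copy_i}_{label}",
                                "product": f"{label} ribosomal RNA",
                            },
                        )
                    )
                    pos += len(useq)
                    if label != "26S":
                        pos += cluster.spacer_length  # ITS1 / ITS2
                pos += cluster.spacer_length  # inter-repeat spacer
            rrna_span = (span_start, pos - cluster.spacer_length)
            rrna_copies = cluster.copies
            if pos >= L:
                raise ValueError("rRNA cluster extends past chromosome end")

        n_genes = L // spec.gene_density_bp
        placed = 0
        attempts = 0
        margin = 200
        while placed < n_genes and attempts < n_genes * 20:
            attempts += 1
            s = int(rng.integers(margin, L - spec.gene_length - margin))
            e = s + spec.gene_length
            if s < cen_hi and e > cen_lo:
                continue
            if rrna_span and s < rrna_span[1] and e > rrna_span[0]:
                continue
            features.append(
                GeneFeature(
                    scaffold_id=name, start=s, end=e,
                    strand="+" if rng.integers(2) else "-",
                    feature_type="gene",
                    attributes={"ID": f"{name}_g{placed:05d}"},
                )
            )
            placed += 1

        scaffolds.append(Scaffold(name, arr.tobytes().decode("ascii")))
        truth.chromosomes[name] = ChromosomeTruth(
            start_telomere_copies=chrom.start_telomere_copies,
            end_telomere_copies=chrom.end_telomere_copies,
            centromere=(cen_lo, cen_hi),
            rrna_span=rrna_span,
            rrna_copies=rrna_copies,
        )

    if spec.include_mito:
        mito = _random_bases(rng, spec.mito_length, max(0.05, spec.base_gc - 0.2))
        truth.mito_sequence = mito.tobytes().decode("ascii")

    features.sort(key=lambda f: (f.scaffold_id, f.start))
    return Assembly("truth", scaffolds), features, truth


# ---------------------------------------------------------------------------
# candidate assemblies
# ---------------------------------------------------------------------------

@dataclass
class ContigPiece:
    """A slice of a truth chromosome placed into a candidate contig."""

    chromosome: str
    start: int
    end: int
    reverse: bool = False


@dataclass
class ContigSpec:
    name: str
    pieces: list[ContigPiece]
    flank_left: int = 0  # random unsupported bases prepended
    flank_right: int = 0


@dataclass
class CandidatePlan:
    name: str
    contigs: list[ContigSpec]
    junk_contigs: list[int] = field(default_factory=list)
    include_mito: bool = False
    noise_rate: float = 0.0


def identity_plan(genome: Assembly, name: str = "identity") -> CandidatePlan:
    return CandidatePlan(
        name=name,
        contigs=[
            ContigSpec(s.id, [ContigPiece(s.id, 0, len(s))]) for s in genome
        ],
    )


def _apply_noise(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = rng.binomial(len(arr), rate)
    pos = rng.choice(len(arr), size=n, replace=False)
    shift = rng.integers(1, 4, size=n)
    idx = np.searchsorted(_BASES, arr[pos])  # ACGT are sorted
    arr[pos] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def derive_candidate_assemblies(
    genome: Assembly,
    plans: Sequence[CandidatePlan],
    seed: int = 0,
    mito_sequence: str | None = None,
) -> tuple[list[Assembly], TruthRecord]:
    """Build candidate assemblies from fragmentation plans.

    Contig provenance is recorded base-exactly in the returned truth
    record as ``{candidate}/{contig}: [[chromosome, start, end, reverse,
    dst_start, dst_end], ...]`` with flanks labelled ``"flank"``.
    """
    rng = np.random.default_rng(seed)
    truth = TruthRecord()
    assemblies = []
    for plan in plans:
        scaffolds = []
        for cspec in plan.contigs:
            for p in cspec.pieces:
                src = genome[p.chromosome]
                if not (0 <= p.start < p.end <= len(src)):
                    raise ValueError(
                        f"piece [{p.start},{p.end}) outside {p.chromosome!r}"
                    )
            parts = []
            prov = []
            dst = 0
            if cspec.flank_left:
                parts.append(
                    _random_bases(rng, cspec.flank_left, 0.5).tobytes().decode()
                )
                prov.append(["flank", 0, cspec.flank_left, False, 0, cspec.flank_left])
                dst += cspec.flank_left
            for p in cspec.pieces:
                seg = genome[p.chromosome].sequence[p.start:p.end]
                if p.reverse:
                    seg = reverse_complement(seg)
                seg = _apply_noise(rng, seg, plan.noise_rate)
                parts.append(seg)
                prov.append(
                    [p.chromosome, p.start, p.end, p.reverse, dst, dst + len(seg)]
                )
                dst += len(seg)
            if cspec.flank_right:
                parts.append(
                    _random_bases(rng, cspec.flank_right, 0.5).tobytes().decode()
                )
                prov.append(
                    ["flank", 0, cspec.flank_right, False, dst, dst + cspec.flank_right]
                )
            scaffolds.append(Scaffold(cspec.name, "".join(parts)))
            truth.contig_provenance[f"{plan.name}/{cspec.name}"] = prov
        for ji, jlen in enumerate(plan.junk_contigs):
            junk = _random_bases(rng, jlen, 0.5).tobytes().decode()
            scaffolds.append(Scaffold(f"{plan.name}_junk{ji + 1}", junk))
        if plan.include_mito:
            if mito_sequence is None:
                raise ValueError(f"plan {plan.name!r} requests mito but none given")
            scaffolds.append(Scaffold(f"{plan.name}_mito", mito_sequence))
        assemblies.append(Assembly(plan.name, scaffolds))
    return assemblies, truth


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------

def simulate_coverage(
    genome: Assembly,
    mean_depth: float = 30.0,
    zero_end: int = 0,
    boost: tuple[tuple[str, int, int], float] | None = None,
    dispersion: float = 0.05,
    seed: int = 0,
) -> list[CoverageTrack]:
    """Per-base negative-binomial coverage around a smooth local mean.

    The local mean is ``mean_depth`` modulated by per-kilobase gamma
    multipliers (mean 1); the first and last ``zero_end`` bases of every
    scaffold are forced to zero; ``boost = ((scaffold_id, start, end),
    multiplier)`` multiplies the local mean over one interval.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    rng = np.random.default_rng(seed)
    tracks = []
    for s in genome:
        L = len(s)
        if mean_depth == 0:
            tracks.append(CoverageTrack(s.id, np.zeros(L, dtype=np.int64)))
            continue
        n_windows = -(-L // 1000)
        mult = rng.gamma(shape=50.0, scale=1.0 / 50.0, size=n_windows)
        mu = mean_depth * np.repeat(mult, 1000)[:L]
        if boost is not None:
            (bid, bstart, bend), bmult = boost
            if bid == s.id:
                if not (0 <= bstart < bend <= L):
                    raise ValueError("boost interval outside scaffold")
                mu[bstart:bend] *= bmult
        r = 1.0 / dispersion
        p = r / (r + mu)
        depth = rng.negative_binomial(r, p).astype(np.int64)
        if zero_end > 0:
            depth[:zero_end] = 0
            depth[L - zero_end:] = 0
        tracks.append(CoverageTrack(s.id, depth))
    return tracks


def coverage_for_contig(
    truth_coverage: Mapping[str, np.ndarray],
    provenance: Sequence[Sequence],
) -> np.ndarray:
    """Coverage array of a derived contig from truth coverage + provenance.

    Flank segments get zero depth (they exist in no read).
    """
    parts = []
    for chrom, start, end, reverse, _d0, _d1 in provenance:
        if chrom == "flank":
            parts.append(np.zeros(end - start, dtype=np.int64))
        else:
            seg = np.asarray(truth_coverage[chrom][start:end])
            parts.append(seg[::-1] if reverse else seg)
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    n_genes: int,
    planted_effects: Mapping[int, float] | np.ndarray | None = None,
    group_sizes: tuple[int, int] = (2, 2),
    nb_mean: float = 200.0,
    nb_dispersion: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted log2 fold changes.

    Returns ``(counts, results)``: counts is genes x samples (control
    columns first); results carries the stand-in statistics — log2 ratio of
    pseudocount-shrunken group means, Welch t-test p-value on log2(count+1),
    and Benjamini-Hochberg adjusted p across genes.  Two replicates per
    group by default.
    """
    if nb_mean <= 0:
        raise ValueError("nb_mean must be positive")
    rng = np.random.default_rng(seed)
    lfc = np.zeros(n_genes)
    if planted_effects is not None:
        if isinstance(planted_effects, Mapping):
            for i, v in planted_effects.items():
                lfc[i] = v
        else:
            lfc = np.asarray(planted_effects, dtype=float)
    base = nb_mean * np.exp(rng.normal(0.0, 0.3, size=n_genes))
    n1, n2 = group_sizes
    if n1 < 1 or n2 < 1:
        raise ValueError("each group needs at least one sample")
    r = 1.0 / nb_dispersion

    def draw(mu: np.ndarray, n: int) -> np.ndarray:
        out = np.empty((len(mu), n), dtype=np.int64)
        for j in range(n):
            p = r / (r + mu)
            out[:, j] = rng.negative_binomial(r, p)
        return out

    counts1 = draw(base, n1)
    counts2 = draw(base * 2.0 ** lfc, n2)
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    samples = [f"ctrl_{j + 1}" for j in range(n1)] + [f"trt_{j + 1}" for j in range(n2)]
    counts = pd.DataFrame(
        np.hstack([counts1, counts2]), index=gene_ids, columns=samples
    )

    m1 = counts1.mean(axis=1)
    m2 = counts2.mean(axis=1)
    est_lfc = np.log2((m2 + 0.5) / (m1 + 0.5))
    log1 = np.log2(counts1 + 1.0)
    log2c = np.log2(counts2 + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _t, pvals = _scipy_stats.ttest_ind(log2c, log1, axis=1, equal_var=False)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    _rej, padj, _a, _b = multipletests(pvals, method="fdr_bh")
    results = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2_fold_change": est_lfc,
            "p_value": pvals,
            "adjusted_p_value": padj,
            "planted_log2fc": lfc,
        }
    )
    return counts, results


# ---------------------------------------------------------------------------
# end-to-end curation benchmark
# ---------------------------------------------------------------------------

@dataclass
class Benchmark:
    """A seeded planted-truth curation scenario.

    The baseline assembly carries one 60 kb terminal-overlap split of the
    first chromosome, one chimera joining the other two chromosomes, a 5 kb
    junk contig, the mitochondrial contig, and 100 bp unsupported flanks at
    every true chromosome end; an identity candidate provides the
    cross-assembly split evidence.
    """

    genome: Assembly
    features: list[GeneFeature]
    truth: TruthRecord
    baseline: Assembly
    alternates: list[Assembly]
    coverage: dict[str, np.ndarray]
    mito_ref: Assembly
    overlap_length: int
    chimera_junction: int


def make_benchmark(
    seed: int,
    overlap_length: int = 60_000,
    flank: int = 100,
) -> Benchmark:
    rng = np.random.default_rng(seed)
    lengths = rng.integers(500_000, 800_001, size=3)
    chroms = []
    for L in lengths:
        chroms.append(
            ChromosomeSpec(
                length=int(L),
                start_telomere_copies=int(rng.integers(12, 18)),
                end_telomere_copies=int(rng.integers(12, 18)),
                centromere_fraction=float(rng.uniform(0.3, 0.7)),
                centromere_width=30_000,
                at_boost=0.25,
            )
        )
    spec = GenomeSpec(
        chromosomes=chroms,
        rrna_cluster=RrnaClusterSpec(chromosome_index=2, copies=7),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    genome, features, truth = generate_genome(spec)
    a, b, c = genome.ids
    la = len(genome[a])
    p = int(0.45 * la)

    baseline_plan = CandidatePlan(
        name="baseline",
        contigs=[
            ContigSpec("utg1", [ContigPiece(a, 0, p)], flank_left=flank),
            ContigSpec("utg2", [ContigPiece(a, p - overlap_length, la)],
                       flank_right=flank),
            ContigSpec(
                "utg3",
                [ContigPiece(b, 0, len(genome[b])), ContigPiece(c, 0, len(genome[c]))],
                flank_left=flank, flank_right=flank,
            ),
        ],
        junk_contigs=[5000],
        include_mito=True,
    )
    alt_plan = identity_plan(genome, "alt1")
    candidates, cand_truth = derive_candidate_assemblies(
        genome, [baseline_plan, alt_plan],
        seed=int(rng.integers(0, 2**31 - 1)),
        mito_sequence=truth.mito_sequence,
    )
    truth.contig_provenance = cand_truth.contig_provenance
    baseline, alternate = candidates

    rrna = truth.chromosomes[c].rrna_span
    cov_tracks = simulate_coverage(
        genome,
        mean_depth=30.0,
        boost=((c, rrna[0], rrna[1]), 50.0) if rrna else None,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    truth_cov = {t.scaffold_id: t.depth for t in cov_tracks}
    coverage = {
        cs.name: coverage_for_contig(
            truth_cov, truth.contig_provenance[f"baseline/{cs.name}"]
        )
        for cs in baseline_plan.contigs
    }

    mito_ref_seq = _apply_noise(rng, truth.mito_sequence, 0.01)
    mito_ref = Assembly("mito_refs", [Scaffold("related_mito", mito_ref_seq)])

    return Benchmark(
        genome=genome,
        features=features,
        truth=truth,
        baseline=baseline,
        alternates=[alternate],
        coverage=coverage,
        mito_ref=mito_ref,
        overlap_length=overlap_length,
        chimera_junction=flank + len(genome[b]),
    )


@dataclass
class BenchmarkOutcome:
    scaffold_count_ok: bool
    all_t2t: bool
    telomere_copies_ok: bool
    sequences_ok: bool
    centromere_ok: bool
    rrna_ok: bool
    replay_ok: bool

    @property
    def all_ok(self) -> bool:
        return all(
            getattr(self, f) for f in (
                "scaffold_count_ok", "all_t2t", "telomere_copies_ok",
                "sequences_ok", "centromere_ok", "rrna_ok", "replay_ok",
            )
        )


def evaluate_benchmark(benchmark: Benchmark, result) -> BenchmarkOutcome:
    """Score a curation result against the planted truth."""
    from .curation import replay_actions
    from .landscape import detect_centromere, detect_tandem_cluster, gc_window_track, gene_count_track

    final = result.assembly
    truth = benchmark.truth
    n_chrom = len(benchmark.genome)
    scaffold_count_ok = len(final) == n_chrom
    all_t2t = bool(result.telomere_reports) and all(
        r.t2t for r in result.telomere_reports
    )

    by_seq = {s.sequence: s.id for s in benchmark.genome}
    mapping = {}  # final id -> truth chromosome id
    for s in final:
        if s.sequence in by_seq:
            mapping[s.id] = by_seq[s.sequence]
    sequences_ok = len(mapping) == n_chrom and scaffold_count_ok

    telomere_copies_ok = sequences_ok
    if sequences_ok:
        for rep in result.telomere_reports:
            t = truth.chromosomes[mapping[rep.scaffold_id]]
            if (rep.start_copies != t.start_telomere_copies
                    or rep.end_copies != t.end_telomere_copies):
                telomere_copies_ok = False

    centromere_ok = sequences_ok
    rrna_ok = sequences_ok
    if sequences_ok:
        window = 1000
        for s in final:
            chrom = mapping[s.id]
            t = truth.chromosomes[chrom]
            gc = gc_window_track(s, window)
            genes = gene_count_track(
                benchmark.features, chrom, len(s), window
            )
            genes.scaffold_id = s.id
            call = detect_centromere(gc, genes, scaffold_length=len(s))
            planted_mid = sum(t.centromere) // 2
            if abs(call.position - planted_mid) > 2 * window:
                centromere_ok = False
            if t.rrna_copies:
                cluster = detect_tandem_cluster(
                    [f for f in benchmark.features
                     if f.scaffold_id == chrom and f.feature_type == "rRNA"]
                )
                if cluster.copies != t.rrna_copies:
                    rrna_ok = False

    replayed = replay_actions(benchmark.baseline, result.actions)
    replay_ok = [s.sequence for s in replayed] == [s.sequence for s in final] and (
        replayed.ids == final.ids
    )

    return BenchmarkOutcome(
        scaffold_count_ok=scaffold_count_ok,
        all_t2t=all_t2t,
        telomere_copies_ok=telomere_copies_ok,
        sequences_ok=sequences_ok,
        centromere_ok=centromere_ok,
        rrna_ok=rrna_ok,
        replay_ok=replay_ok,
    )
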