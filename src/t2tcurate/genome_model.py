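"""Core data types and I/O for assemblies, coverage, alignments and features.

All internal coordinates are 0-based half-open.  1-based inclusive coordinates
appear only at the GFF3 and per-base-coverage file boundaries, where the
formats themselves use them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class Scaffold:
    """A named nucleotide sequence over the uppercase {A,C,G,T,N} alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("scaffold id must be non-empty")
        if not self.sequence:
            raise ValueError(f"scaffold {self.id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"scaffold {self.id!r} contains illegal symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    """Ordered collection of scaffolds with unique ids."""

    name: str
    scaffolds: list[Scaffold] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.scaffolds]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate scaffold ids in assembly {self.name!r}: {dupes}")

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __iter__(self):
        return iter(self.scaffolds)

    def __getitem__(self, key: int | str) -> Scaffold:
        if isinstance(key, str):
            for s in self.scaffolds:
                if s.id == key:
                    return s
            raise KeyError(key)
        return self.scaffolds[key]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.scaffolds]

    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds)


@dataclass
class AssemblyStats:
    """QUAST-style summary statistics of an assembly.

    N50 is the length of the smallest scaffold in the minimal set of largest
    scaffolds whose cumulative length reaches half the total; L50 is the size
    of that set.  GC% is computed over non-N bases only.
    """

    n_scaffolds: int
    total_length: int
    n50: int
    l50: int
    gc_percent: float
    n_bases: int
    lengths: list[int]


@dataclass
class CoverageTrack:
    """Per-base read depth for one scaffold (index 0 = first base)."""

    scaffold_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if (self.depth < 0).any():
            raise ValueError(f"negative depth in coverage track {self.scaffold_id!r}")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class AlignmentRecord:
    """One query-to-target alignment (PAF columns 1-6), 0-based half-open."""

    query_id: str
    query_length: int
    query_start: int
    query_end: int
    target_id: str
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise ValueError(
                f"invalid alignment interval [{self.query_start},{self.query_end}) "
                f"for read {self.query_id!r} of length {self.query_length}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def aligned_fraction(self) -> float:
        return (self.query_end - self.query_start) / self.query_length


@dataclass
class GeneFeature:
    """A genomic feature (gene, rRNA, ...), 0-based half-open internally."""

    scaffold_id: str
    start: int
    end: int
    strand: str
    feature_type: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid feature interval [{self.start},{self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if not self.feature_type:
            raise ValueError("feature_type must be non-empty")

    @property
    def id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def product(self) -> str | None:
        return self.attributes.get("product")


_RRNA_SUBUNIT_RE = re.compile(r"\b(5\.8S|18S|26S|28S|5S)\b", re.IGNORECASE)


def rrna_subunit(product: str) -> str | None:
    """Extract the rRNA subunit label (e.g. '18S') from a product string."""
    m = _RRNA_SUBUNIT_RE.search(product)
    return m.group(1).upper().replace("s", "S") if m else None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, name: str | None = None) -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    Sequences are uppercased and U is mapped to T; any other symbol outside
    {A,C,G,T,N} raises.  Record order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        scaffolds.append(Scaffold(rec.id, seq))
    return Assembly(name or path.stem, scaffolds)


def write_fasta(assembly: Assembly, path: str | Path) -> None:
    """Write an assembly as FASTA with 60-column line wrapping."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in assembly
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------

def compute_assembly_stats(assembly: Assembly) -> AssemblyStats:
    """N50/L50, GC% over non-N bases, N count and total length."""
    if len(assembly) == 0:
        raise ValueError("cannot compute statistics of an empty assembly")
    lengths = [len(s) for s in assembly]
    total = sum(lengths)
    ordered = sorted(lengths, reverse=True)
    cum = 0
    n50 = l50 = 0
    for i, length in enumerate(ordered, start=1):
        cum += length
        if 2 * cum >= total:
            n50, l50 = length, i
            break
    gc = n_count = 0
    for s in assembly:
        gc += s.sequence.count("G") + s.sequence.count("C")
        n_count += s.sequence.count("N")
    denom = total - n_count
    gc_percent = 100.0 * gc / denom if denom else 0.0
    return AssemblyStats(
        n_scaffolds=len(assembly),
        total_length=total,
        n50=n50,
        l50=l50,
        gc_percent=gc_percent,
        n_bases=n_count,
        lengths=lengths,
    )


# ---------------------------------------------------------------------------
# Per-base coverage
# ---------------------------------------------------------------------------

def read_per_base_coverage(path: str | Path) -> list[CoverageTrack]:
    """Read `genomeCoverageBed -d`-style 3-column TSV into coverage tracks.

    Columns are scaffold, 1-based position, depth; positions must be
    consecutive from 1 within each scaffold.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["scaffold", "pos", "depth"],
        dtype={"scaffold": str, "pos": np.int64, "depth": np.int64},
    )
    if df.isna().any().any():
        raise ValueError(f"malformed line in coverage file {path}")
    tracks: list[CoverageTrack] = []
    for scaffold_id, sub in df.groupby("scaffold", sort=False):
        pos = sub["pos"].to_numpy()
        if pos[0] != 1 or not (np.diff(pos) == 1).all():
            raise ValueError(
                f"non-consecutive positions for scaffold {scaffold_id!r} in {path}"
            )
        tracks.append(CoverageTrack(str(scaffold_id), sub["depth"].to_numpy()))
    return tracks


def write_per_base_coverage(tracks: Iterable[CoverageTrack], path: str | Path) -> None:
    """Write coverage tracks as a 3-column, 1-based TSV (inverse of the reader)."""
    with open(path, "w") as fh:
        for t in tracks:
            for i, d in enumerate(t.depth, start=1):
                fh.write(f"{t.scaffold_id}\t{i}\t{int(d)}\n")


def read_bedgraph_coverage(path: str | Path) -> list[CoverageTrack]:
    """Read 4-column bedGraph (0-based half-open intervals) as per-base tracks."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["scaffold", "start", "end", "depth"],
        dtype={"scaffold": str, "start": np.int64, "end": np.int64, "depth": np.int64},
    )
    tracks = []
    for scaffold_id, sub in df.groupby("scaffold", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if starts[0] != 0 or not (starts[1:] == ends[:-1]).all():
            raise ValueError(f"bedGraph intervals not contiguous for {scaffold_id!r}")
        depth = np.repeat(sub["depth"].to_numpy(), ends - starts)
        tracks.append(CoverageTrack(str(scaffold_id), depth))
    return tracks


# ---------------------------------------------------------------------------
# PAF alignments
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Read PAF records (columns 1-6: qname, qlen, qstart, qend, strand, tname).

    Remaining columns are ignored.  Coordinates stay 0-based half-open as in
    the format.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 PAF columns")
            qname, qlen, qstart, qend, strand, tname = cols[:6]
            records.append(
                AlignmentRecord(qname, int(qlen), int(qstart), int(qend), tname, strand)
            )
    return records


def union_aligned_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    ivals = sorted(intervals)
    total = 0
    cur_start: int | None = None
    cur_end = 0
    for s, e in ivals:
        if cur_start is None or s > cur_end:
            if cur_start is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_start is not None:
        total += cur_end - cur_start
    return total


def union_aligned_fraction(records: Iterable[AlignmentRecord]) -> float:
    """Fraction of a read covered by the union of its alignment intervals."""
    records = list(records)
    if not records:
        return 0.0
    qlen = records[0].query_length
    if any(r.query_length != qlen for r in records):
        raise ValueError("records describe reads of differing length")
    return union_aligned_length((r.query_start, r.query_end) for r in records) / qlen


# ---------------------------------------------------------------------------
# GFF3 features
# ---------------------------------------------------------------------------

def read_features(path: str | Path) -> list[GeneFeature]:
    """Read GFF3 features, converting to 0-based half-open coordinates."""
    from gffutils.feature import feature_from_line

    features = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = feature_from_line(line)
            attrs = {k: v[0] if v else "" for k, v in f.attributes.items()}
            if f.end < f.start:
                raise ValueError(f"feature end < start: {line!r}")
            if f.strand not in {"+", "-", "."}:
                raise ValueError(f"unknown strand symbol {f.strand!r}: {line!r}")
            features.append(
                GeneFeature(
                    scaffold_id=f.seqid,
                    start=f.start - 1,
                    end=f.end,
                    strand=f.strand,
                    feature_type=f.featuretype,
                    attributes=attrs,
                )
            )
    return features


def write_features(features: Iterable[GeneFeature], path: str | Path,
                   source: str = "t2tcurate") -> None:
    """Write features as GFF3 (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{f.scaffold_id}\t{source}\t{f.feature_type}\t{f.start + 1}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attrs}\n"
            )


def stats_table(stats: AssemblyStats) -> pd.DataFrame:
    """One-row summary table of assembly statistics (for CLI/TSV output)."""
    return pd.DataFrame(
        [
            {
                "n_scaffolds": stats.n_scaffolds,
                "total_length": stats.total_length,
                "n50": stats.n50,
                "l50": stats.l50,
                "gc_percent": round(stats.gc_percent, 2),
                "n_bases": stats.n_bases,
            }
        ]
    )
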