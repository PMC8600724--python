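"""Genomic landscape tracks and feature localisation.

Windowed GC content, log2 read coverage and gene counts (the circular-map
rings), AT-rich/gene-poor centromere localisation with arm classification,
tandem rRNA cistron counting, and high-coverage peak detection.

Coverage windows use log2(mean depth + 1): the +1 keeps zero-coverage
windows finite, and every plot or table produced from these tracks states
that transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_model import CoverageTrack, GeneFeature, Scaffold, rrna_subunit

ARM_RATIO_METACENTRIC_MAX = 1.7  # standard cytogenetic convention


@dataclass
class WindowTrack:
    """Fixed-window summary values along one scaffold.

    The last window may be partial and is normalised by its actual length.
    Windows consisting only of N bases carry NaN (flagged missing).
    """

    scaffold_id: str
    window_size: int
    values: np.ndarray
    stat_kind: str  # "gc_percent" | "log2_coverage" | "gene_count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CentromereCall:
    """Localised centromere with arm measurements."""

    scaffold_id: str
    position: int  # bp, midpoint of the minimising window
    arm_short: int
    arm_long: int
    arm_ratio: float
    classification: str  # "metacentric" | "submetacentric"
    score: float
    low_confidence: bool


@dataclass
class TandemClusterCall:
    """A tandem repetition of an ordered feature unit (e.g. the rRNA cistron)."""

    scaffold_id: str
    unit: tuple[str, ...]
    copies: int
    span: tuple[int, int]
    member_feature_ids: list[str]


# ---------------------------------------------------------------------------
# window tracks
# ---------------------------------------------------------------------------

def _n_windows(length: int, window_size: int) -> int:
    return -(-length // window_size)


def gc_window_track(scaffold: Scaffold, window_size: int = 1000) -> WindowTrack:
    seq = np.frombuffer(scaffold.sequence.encode("ascii"), dtype=np.uint8)
    is_gc = (seq == ord("G")) | (seq == ord("C"))
    is_n = seq == ord("N")
    nw = _n_windows(len(seq), window_size)
    values = np.empty(nw)
    for i in range(nw):
        lo, hi = i * window_size, min((i + 1) * window_size, len(seq))
        non_n = (hi - lo) - int(is_n[lo:hi].sum())
        values[i] = 100.0 * is_gc[lo:hi].sum() / non_n if non_n else np.nan
    return WindowTrack(scaffold.id, window_size, values, "gc_percent")


def coverage_window_track(track: CoverageTrack, window_size: int = 1000) -> WindowTrack:
    depth = track.depth.astype(float)
    nw = _n_windows(len(depth), window_size)
    values = np.empty(nw)
    for i in range(nw):
        lo, hi = i * window_size, min((i + 1) * window_size, len(depth))
        values[i] = np.log2(depth[lo:hi].mean() + 1.0)
    return WindowTrack(track.scaffold_id, window_size, values, "log2_coverage")


def gene_count_track(
    features: Iterable[GeneFeature],
    scaffold_id: str,
    scaffold_length: int,
    window_size: int = 100_000,
    feature_type: str = "gene",
) -> WindowTrack:
    """Number of features whose start coordinate falls in each window."""
    nw = _n_windows(scaffold_length, window_size)
    values = np.zeros(nw)
    for f in features:
        if f.scaffold_id == scaffold_id and f.feature_type == feature_type:
            values[f.start // window_size] += 1
    return WindowTrack(scaffold_id, window_size, values, "gene_count")


def window_track(
    source,
    window_size: int,
    stat_kind: str,
    *,
    scaffold_id: str | None = None,
    scaffold_length: int | None = None,
    feature_type: str = "gene",
) -> WindowTrack:
    """Dispatching front-end over the three track builders."""
    if window_size < 100:
        raise ValueError("window_size must be >= 100")
    if stat_kind == "gc_percent":
        return gc_window_track(source, window_size)
    if stat_kind == "log2_coverage":
        return coverage_window_track(source, window_size)
    if stat_kind == "gene_count":
        if scaffold_id is None or scaffold_length is None:
            raise ValueError("gene_count tracks need scaffold_id and scaffold_length")
        return gene_count_track(source, scaffold_id, scaffold_length, window_size,
                                feature_type)
    raise ValueError(f"unknown stat_kind {stat_kind!r}")


# ---------------------------------------------------------------------------
# centromere localisation
# ---------------------------------------------------------------------------

def _moving_average(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values.astype(float)
    kernel = np.ones(width) / width
    padded = np.pad(values.astype(float), width // 2, mode="edge")
    out = np.convolve(padded, kernel, mode="same")
    lo = width // 2
    return out[lo:lo + len(values)]


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = float(np.nanstd(values))
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - np.nanmean(values)) / sd


def detect_centromere(
    gc_track: WindowTrack,
    gene_track: WindowTrack,
    exclusion_fraction: float = 0.05,
    smooth_windows: int = 25,
    scaffold_length: int | None = None,
    confidence_cutoff: float = -5.0,
) -> CentromereCall:
    """Locate the centromere as the AT-rich, gene-scarce trough.

    Both tracks are smoothed (moving average over ``smooth_windows``
    windows) and z-scored; the candidate is the region minimising
    z(GC) + z(gene density), with the terminal ``exclusion_fraction`` of
    windows excluded because telomere regions are also AT-rich.  The
    reported position is the centroid of the contiguous trough around the
    minimising window, which is more stable than the raw argmin when the
    trough is wider than the smoothing kernel.

    Arms are measured from the position; arm_ratio = long/short, with the
    metacentric/submetacentric boundary at 1.7.  A trough whose combined
    z-score does not go below ``confidence_cutoff`` is flagged low
    confidence (uniform tracks still return their minimising window).
    """
    if gc_track.scaffold_id != gene_track.scaffold_id:
        raise ValueError("tracks describe different scaffolds")
    n = len(gc_track)
    if n < 100:
        raise ValueError("track too short for centromere detection (< 100 windows)")
    w = gc_track.window_size
    if gene_track.window_size != w:
        if gene_track.window_size % w != 0:
            raise ValueError("gene track window size must be a multiple of the GC one")
        factor = gene_track.window_size // w
        gene_values = np.repeat(gene_track.values / factor, factor)[:n]
    else:
        gene_values = gene_track.values[:n]

    gc = np.nan_to_num(gc_track.values, nan=float(np.nanmean(gc_track.values)))
    z_gc = _zscore(_moving_average(gc, smooth_windows))
    z_gene = _zscore(_moving_average(gene_values, smooth_windows))
    score = z_gc + z_gene
    excl = max(1, int(round(n * exclusion_fraction)))
    interior = score[excl:n - excl]
    arg = int(np.argmin(interior)) + excl
    min_score = float(score[arg])

    # The combined score identifies the trough; the position is refined on
    # the GC component alone, which has per-base resolution, while gene
    # density (sparse features) only confirms gene scarcity.  Centroid of
    # the half-depth GC trough around the argmin:
    gc_min = float(z_gc[arg])
    threshold = gc_min + 0.5 * (float(np.median(z_gc)) - gc_min)
    lo = arg
    while lo > excl and z_gc[lo - 1] <= threshold:
        lo -= 1
    hi = arg
    while hi < n - excl - 1 and z_gc[hi + 1] <= threshold:
        hi += 1
    idx = np.arange(lo, hi + 1)
    weights = threshold - z_gc[lo:hi + 1]
    if weights.sum() > 0:
        centre = int(round(float((idx * weights).sum() / weights.sum())))
    else:
        centre = arg

    length = scaffold_length if scaffold_length is not None else n * w
    position = min(centre * w + w // 2, length - 1)
    arm_a, arm_b = position, length - position
    arm_short, arm_long = min(arm_a, arm_b), max(arm_a, arm_b)
    ratio = arm_long / arm_short if arm_short else float("inf")
    return CentromereCall(
        scaffold_id=gc_track.scaffold_id,
        position=position,
        arm_short=arm_short,
        arm_long=arm_long,
        arm_ratio=ratio,
        classification=(
            "metacentric" if ratio <= ARM_RATIO_METACENTRIC_MAX else "submetacentric"
        ),
        score=min_score,
        low_confidence=min_score > confidence_cutoff,
    )


# ---------------------------------------------------------------------------
# tandem rRNA cluster
# ---------------------------------------------------------------------------

def detect_tandem_cluster(
    features: Sequence[GeneFeature],
    unit: Sequence[str] = ("18S", "5.8S", "26S"),
    max_member_gap: int = 50_000,
) -> TandemClusterCall:
    """Count tandem repetitions of an ordered subunit pattern.

    ``features`` should be the rRNA features of one scaffold; they are
    sorted by position, reduced to subunit labels, and scanned for the
    maximal uninterrupted repetition of ``unit`` (reversed for features on
    the minus strand), with consecutive members no farther apart than
    ``max_member_gap``.  ITS spacers are not part of the pattern.
    """
    unit = tuple(unit)
    labeled = []
    for f in sorted(features, key=lambda f: f.start):
        label = rrna_subunit(f.product or f.attributes.get("Name", "") or "")
        if label is not None:
            labeled.append((f, label))
    if not labeled:
        return TandemClusterCall("" if not features else features[0].scaffold_id,
                                 unit, 0, (0, 0), [])
    scaffold_id = labeled[0][0].scaffold_id

    def run_at(start: int, expected: tuple[str, ...]) -> int:
        """Number of complete unit copies starting at label index ``start``."""
        copies = 0
        i = start
        while i + len(expected) <= len(labeled):
            ok = all(labeled[i + j][1] == expected[j] for j in range(len(expected)))
            if not ok:
                break
            strands = {labeled[i + j][0].strand for j in range(len(expected))}
            if len(strands - {"."}) > 1:
                break
            if copies > 0:
                gap = labeled[i][0].start - labeled[i - 1][0].end
                if gap > max_member_gap:
                    break
            within = [
                labeled[i + j + 1][0].start - labeled[i + j][0].end
                for j in range(len(expected) - 1)
            ]
            if any(g > max_member_gap for g in within):
                break
            copies += 1
            i += len(expected)
        return copies

    best_copies, best_start, best_unit = 0, 0, unit
    for start in range(len(labeled)):
        for expected in (unit, tuple(reversed(unit))):
            if expected == tuple(reversed(unit)) and labeled[start][0].strand != "-":
                continue
            c = run_at(start, expected)
            if c > best_copies:
                best_copies, best_start, best_unit = c, start, expected
    if best_copies == 0:
        return TandemClusterCall(scaffold_id, unit, 0, (0, 0), [])
    members = labeled[best_start:best_start + best_copies * len(unit)]
    span = (members[0][0].start, members[-1][0].end)
    ids = [m[0].id or f"{m[0].scaffold_id}:{m[0].start}" for m in members]
    return TandemClusterCall(scaffold_id, unit, best_copies, span, ids)


# ---------------------------------------------------------------------------
# coverage peaks
# ---------------------------------------------------------------------------

def peak_regions(
    coverage_track: CoverageTrack,
    fold_over_median: float = 10.0,
    merge_gap: int = 1000,
) -> list[tuple[int, int]]:
    """Maximal runs of bases with depth >= fold_over_median x track median.

    Runs separated by gaps of at most ``merge_gap`` bases are merged.  The
    effective threshold is at least 1, so an all-zero track yields no peaks.
    """
    depth = coverage_track.depth
    if depth.size == 0:
        return []
    threshold = max(fold_over_median * float(np.median(depth)), 1.0)
    above = depth >= threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.r_[idx[0], idx[breaks + 1]]
    run_ends = np.r_[idx[breaks], idx[-1]] + 1
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    return [(s, e) for s, e in merged]
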