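"""Whole-assembly comparison via unique k-mer anchors.

Dotplot-grade evidence for contig correspondence, chimera-split support and
terminal-overlap detection between candidate assemblies.  Instead of full
base-level alignment, scaffolds are compared through *anchors*: canonical
k-mers (lexicographic minimum of the k-mer and its reverse complement) that
occur exactly once in each assembly.  Collinear anchors are chained; chains
are the units of evidence for merge/split decisions.

k-mer codes are computed by vectorised base-4 polynomial evaluation, which
keeps desk-scale genomes (a few Mb) well under a second per comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_model import Assembly, Scaffold

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _c

DEFAULT_K = 21
DEFAULT_MAX_GAP = 10_000  # bp; adjacent anchors chain when deltas agree within this


@dataclass
class Anchor:
    """A unique shared k-mer match between two assemblies."""

    __slots__ = ("a_scaffold", "a_pos", "b_scaffold", "b_pos", "orientation")
    a_scaffold: str
    a_pos: int
    b_scaffold: str
    b_pos: int
    orientation: str  # "forward" | "reverse"


@dataclass
class Chain:
    """A maximal collinear run of anchors between one scaffold pair."""

    a_scaffold: str
    b_scaffold: str
    orientation: str
    anchor_count: int
    a_span: tuple[int, int]  # half-open, includes k-mer extent
    b_span: tuple[int, int]

    @property
    def a_length(self) -> int:
        return self.a_span[1] - self.a_span[0]

    @property
    def b_length(self) -> int:
        return self.b_span[1] - self.b_span[0]


@dataclass
class CorrespondenceEntry:
    """Partners of one query scaffold across an assembly comparison."""

    a_scaffold: str
    partners: list[tuple[str, tuple[int, int], tuple[int, int], int, str]]
    is_split_candidate: bool = False
    breakpoints: list[int] = field(default_factory=list)


@dataclass
class OverlapReport:
    """Evidence for a terminal overlap between two contigs."""

    a_scaffold: str
    b_scaffold: str
    a_terminus: str | None  # "start" | "end" | None
    b_terminus: str | None
    overlap_length: int
    orientation: str | None
    is_merge_candidate: bool
    a_span: tuple[int, int] = (0, 0)
    b_span: tuple[int, int] = (0, 0)


# ---------------------------------------------------------------------------
# k-mer encoding
# ---------------------------------------------------------------------------

def _window_codes(sequence: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical k-mer codes for every window of ``sequence``.

    Returns ``(canonical, forward_form, valid)`` where ``forward_form[i]``
    is True when the forward k-mer (not its reverse complement) is the
    canonical form, and ``valid`` masks out windows containing N.
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[raw]
    invalid = codes < 0
    c = np.where(invalid, 0, codes).astype(np.float64)
    n = len(sequence) - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, np.empty(0, dtype=bool), np.empty(0, dtype=bool)
    w = 4.0 ** np.arange(k)
    fwd = np.convolve(c, w, mode="valid").astype(np.int64)
    rc_seq = (3.0 - c)[::-1]
    rc_all = np.convolve(rc_seq, w, mode="valid").astype(np.int64)
    rev = rc_all[::-1]
    canonical = np.minimum(fwd, rev)
    forward_form = fwd <= rev
    bad = np.convolve(invalid.astype(np.float64), np.ones(k), mode="valid") > 0
    return canonical, forward_form, ~bad


def _assembly_kmers(assembly: Assembly, k: int, sample_mod: int):
    """Concatenated canonical k-mer codes of an assembly with provenance."""
    code_parts, form_parts, pos_parts, scaf_parts = [], [], [], []
    for si, scaffold in enumerate(assembly):
        canonical, forward_form, valid = _window_codes(scaffold.sequence, k)
        if sample_mod > 1:
            valid = valid & (canonical % sample_mod == 0)
        idx = np.flatnonzero(valid)
        code_parts.append(canonical[idx])
        form_parts.append(forward_form[idx])
        pos_parts.append(idx.astype(np.int64))
        scaf_parts.append(np.full(idx.size, si, dtype=np.int32))
    if not code_parts:
        z = np.empty(0, dtype=np.int64)
        return z, np.empty(0, bool), z, np.empty(0, np.int32)
    return (
        np.concatenate(code_parts),
        np.concatenate(form_parts),
        np.concatenate(pos_parts),
        np.concatenate(scaf_parts),
    )


def _singleton_mask(codes: np.ndarray):
    """Indices of codes occurring exactly once, with codes sorted ascending."""
    order = np.argsort(codes, kind="stable")
    sc = codes[order]
    first = np.r_[True, sc[1:] != sc[:-1]]
    idx_first = np.flatnonzero(first)
    counts = np.diff(np.r_[idx_first, sc.size])
    singles = idx_first[counts == 1]
    return sc[singles], order[singles]


class _AnchorSet:
    """Array-backed anchor collection (internal fast path)."""

    def __init__(self, a_ids, b_ids, a_scaf, a_pos, b_scaf, b_pos, forward, k):
        self.a_ids = a_ids
        self.b_ids = b_ids
        self.a_scaf = a_scaf
        self.a_pos = a_pos
        self.b_scaf = b_scaf
        self.b_pos = b_pos
        self.forward = forward
        self.k = k

    def __len__(self) -> int:
        return self.a_pos.size

    def to_anchors(self) -> list[Anchor]:
        return [
            Anchor(
                self.a_ids[sa], int(pa), self.b_ids[sb], int(pb),
                "forward" if f else "reverse",
            )
            for sa, pa, sb, pb, f in zip(
                self.a_scaf, self.a_pos, self.b_scaf, self.b_pos, self.forward
            )
        ]


def _anchor_arrays(
    assembly_a: Assembly,
    assembly_b: Assembly,
    k: int = DEFAULT_K,
    sample_mod: int = 1,
) -> _AnchorSet:
    if k % 2 == 0 or not (11 <= k <= 31):
        raise ValueError("k must be odd and within [11, 31]")
    ca, fa, pa, sa = _assembly_kmers(assembly_a, k, sample_mod)
    cb, fb, pb, sb = _assembly_kmers(assembly_b, k, sample_mod)
    ua_codes, ua_idx = _singleton_mask(ca)
    ub_codes, ub_idx = _singleton_mask(cb)
    _, ia, ib = np.intersect1d(
        ua_codes, ub_codes, assume_unique=True, return_indices=True
    )
    ai = ua_idx[ia]
    bi = ub_idx[ib]
    forward = fa[ai] == fb[bi]
    order = np.lexsort((pa[ai], sa[ai]))
    ai, bi, forward = ai[order], bi[order], forward[order]
    return _AnchorSet(
        assembly_a.ids, assembly_b.ids,
        sa[ai], pa[ai], sb[bi], pb[bi], forward, k,
    )


def anchor_matches(
    assembly_a: Assembly,
    assembly_b: Assembly,
    k: int = DEFAULT_K,
    sample_mod: int = 1,
) -> list[Anchor]:
    """Anchors between two assemblies: canonical k-mers unique in each.

    ``sample_mod > 1`` keeps only k-mers whose canonical code is divisible
    by it — deterministic subsampling that trades anchor density for speed.
    Anchors are sorted by (a_scaffold order, a_pos).
    """
    return _anchor_arrays(assembly_a, assembly_b, k, sample_mod).to_anchors()


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _coerce_anchor_set(anchors, k: int | None = None) -> _AnchorSet:
    if isinstance(anchors, _AnchorSet):
        return anchors
    anchors = list(anchors)
    if k is None:
        k = DEFAULT_K
    a_ids = list(dict.fromkeys(a.a_scaffold for a in anchors))
    b_ids = list(dict.fromkeys(a.b_scaffold for a in anchors))
    a_index = {s: i for i, s in enumerate(a_ids)}
    b_index = {s: i for i, s in enumerate(b_ids)}
    n = len(anchors)
    a_scaf = np.fromiter((a_index[a.a_scaffold] for a in anchors), np.int32, n)
    b_scaf = np.fromiter((b_index[a.b_scaffold] for a in anchors), np.int32, n)
    a_pos = np.fromiter((a.a_pos for a in anchors), np.int64, n)
    b_pos = np.fromiter((a.b_pos for a in anchors), np.int64, n)
    fwd = np.fromiter((a.orientation == "forward" for a in anchors), bool, n)
    order = np.lexsort((a_pos, b_scaf.astype(np.int64) * 2 + fwd, a_scaf))
    return _AnchorSet(
        a_ids, b_ids, a_scaf[order], a_pos[order], b_scaf[order],
        b_pos[order], fwd[order], k,
    )


def chain_anchors(anchors, max_gap: int = DEFAULT_MAX_GAP, k: int | None = None) -> list[Chain]:
    """Partition anchors into maximal collinear chains.

    Adjacent anchors (in a-position order within one scaffold pair and
    orientation) join a chain when both coordinate deltas are positive
    (negative in b for reverse orientation), at most ``max_gap``, and agree
    within ``max_gap``.
    """
    aset = _coerce_anchor_set(anchors, k)
    n = len(aset)
    if n == 0:
        return []
    key = (
        aset.a_scaf.astype(np.int64) * (2 * len(aset.b_ids))
        + aset.b_scaf.astype(np.int64) * 2
        + aset.forward
    )
    order = np.lexsort((aset.b_pos, aset.a_pos, key))
    a_scaf = aset.a_scaf[order]
    a_pos = aset.a_pos[order]
    b_scaf = aset.b_scaf[order]
    b_pos = aset.b_pos[order]
    fwd = aset.forward[order]
    okey = key[order]

    da = np.diff(a_pos)
    db = np.diff(b_pos)
    same_group = np.diff(okey) == 0
    f = fwd[1:]
    link_fwd = (db > 0) & (db <= max_gap) & (np.abs(da - db) <= max_gap)
    link_rev = (db < 0) & (-db <= max_gap) & (np.abs(da + db) <= max_gap)
    link = same_group & (da > 0) & (da <= max_gap) & np.where(f, link_fwd, link_rev)
    breaks = np.flatnonzero(~link) + 1
    bounds = np.r_[0, breaks, n]

    chains = []
    kk = aset.k
    for s, e in zip(bounds[:-1], bounds[1:]):
        orient = "forward" if fwd[s] else "reverse"
        a_span = (int(a_pos[s]), int(a_pos[e - 1]) + kk)
        if orient == "forward":
            b_span = (int(b_pos[s]), int(b_pos[e - 1]) + kk)
        else:
            b_span = (int(b_pos[e - 1]), int(b_pos[s]) + kk)
        chains.append(
            Chain(
                a_scaffold=aset.a_ids[a_scaf[s]],
                b_scaffold=aset.b_ids[b_scaf[s]],
                orientation=orient,
                anchor_count=int(e - s),
                a_span=a_span,
                b_span=b_span,
            )
        )
    return chains


def contig_correspondence(
    anchors,
    min_anchors: int = 50,
    min_span: int = 50_000,
    max_gap: int = DEFAULT_MAX_GAP,
    all_a_scaffolds: Sequence[str] | None = None,
    k: int | None = None,
) -> list[CorrespondenceEntry]:
    """Summarise anchor chains into per-scaffold partner lists.

    A scaffold with >= 2 partners on disjoint query spans of at least
    ``min_span`` each, pointing at different target scaffolds, is flagged as
    split evidence with breakpoints at the midpoints between adjacent
    partner spans.
    """
    chains = [c for c in chain_anchors(anchors, max_gap, k) if c.anchor_count >= min_anchors]
    by_a: dict[str, list[Chain]] = {}
    for c in chains:
        by_a.setdefault(c.a_scaffold, []).append(c)
    scaffold_order = list(all_a_scaffolds) if all_a_scaffolds is not None else list(by_a)
    entries = []
    for a_id in scaffold_order:
        partner_chains = sorted(by_a.get(a_id, []), key=lambda c: c.a_span)
        partners = [
            (c.b_scaffold, c.a_span, c.b_span, c.anchor_count, c.orientation)
            for c in partner_chains
        ]
        breakpoints = []
        qualifying = [c for c in partner_chains if c.a_length >= min_span]
        for left, right in zip(qualifying, qualifying[1:]):
            disjoint = right.a_span[0] >= left.a_span[1]
            if disjoint and right.b_scaffold != left.b_scaffold:
                breakpoints.append((left.a_span[1] + right.a_span[0]) // 2)
        entries.append(
            CorrespondenceEntry(
                a_scaffold=a_id,
                partners=partners,
                is_split_candidate=bool(breakpoints),
                breakpoints=breakpoints,
            )
        )
    return entries


# ---------------------------------------------------------------------------
# terminal overlaps
# ---------------------------------------------------------------------------

def detect_terminal_overlap(
    scaffold_a: Scaffold,
    scaffold_b: Scaffold,
    k: int = DEFAULT_K,
    min_overlap: int = 50_000,
    terminal_search: int = 200_000,
    max_gap: int = DEFAULT_MAX_GAP,
    sample_mod: int = 1,
) -> OverlapReport:
    """Estimate a terminal (dovetail) overlap between two contigs.

    The overlap length is the query extent of the largest anchor chain that
    reaches within ``terminal_search`` bp of a terminus of both contigs.
    ``is_merge_candidate`` requires the estimate to be at least
    ``min_overlap`` and the terminus geometry to be consistent with a
    dovetail (opposite termini for forward orientation, same termini for
    reverse).
    """
    aset = _anchor_arrays(
        Assembly("a", [scaffold_a]), Assembly("b", [scaffold_b]), k, sample_mod
    )
    chains = chain_anchors(aset, max_gap)
    a_len, b_len = len(scaffold_a), len(scaffold_b)
    best: tuple[int, Chain, str, str] | None = None
    for c in chains:
        da_start, da_end = c.a_span[0], a_len - c.a_span[1]
        db_start, db_end = c.b_span[0], b_len - c.b_span[1]
        if min(da_start, da_end) > terminal_search or min(db_start, db_end) > terminal_search:
            continue
        a_term = "start" if da_start <= da_end else "end"
        b_term = "start" if db_start <= db_end else "end"
        length = c.a_length
        if best is None or length > best[0]:
            best = (length, c, a_term, b_term)
    if best is None:
        return OverlapReport(
            scaffold_a.id, scaffold_b.id, None, None, 0, None, False
        )
    length, chain, a_term, b_term = best
    if chain.orientation == "forward":
        geometry_ok = a_term != b_term
    else:
        geometry_ok = a_term == b_term
    return OverlapReport(
        a_scaffold=scaffold_a.id,
        b_scaffold=scaffold_b.id,
        a_terminus=a_term,
        b_terminus=b_term,
        overlap_length=length,
        orientation=chain.orientation,
        is_merge_candidate=bool(length >= min_overlap and geometry_ok),
        a_span=chain.a_span,
        b_span=chain.b_span,
    )


def dotplot_matrix(anchors, bin_size: int = 10_000):
    """Binned anchor-count matrix per scaffold pair, for TSV/plot export.

    Returns a dict ``{(a_scaffold, b_scaffold): 2-D count array}``.
    """
    aset = _coerce_anchor_set(anchors)
    out: dict[tuple[str, str], np.ndarray] = {}
    pairs = {}
    for i in range(len(aset)):
        key = (aset.a_ids[aset.a_scaf[i]], aset.b_ids[aset.b_scaf[i]])
        pairs.setdefault(key, []).append(i)
    for key, idx in pairs.items():
        idx = np.asarray(idx)
        ab = aset.a_pos[idx] // bin_size
        bb = aset.b_pos[idx] // bin_size
        mat = np.zeros((int(ab.max()) + 1, int(bb.max()) + 1), dtype=np.int64)
        np.add.at(mat, (ab, bb), 1)
        out[key] = mat
    return out
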