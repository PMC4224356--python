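"""Interval algebra on genome coordinate frames.

All coordinates are 0-based, half-open (BED convention).  An interval covers
bases ``start .. end-1``; abutting intervals share no base and therefore do
not overlap.  :class:`IntervalSet` is array-backed (NumPy columns rather than
per-interval objects) so that operations scale to the millions of control
regions used by the resampling nulls.

The operations here are the universal currency of the pipeline: fixed-size
window tilings, overlap counting, nearest-feature distances, complement,
length-matched control-region sampling from excluded-region-free sequence,
and projection of intervals between two genomes through a block synteny map
(a simplified liftOver: equal-length aligned block pairs, optional negative
strand, no multi-way chains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidMapError,
    InvalidParameterError,
    LayoutMismatchError,
    PlacementError,
)

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "IntervalSet",
    "SyntenyMap",
    "ProjectionResult",
    "tile_windows",
    "count_overlapping",
    "overlaps_any",
    "distance_to_nearest",
    "map_via_synteny",
    "project_intervals",
    "project_pieces",
    "complement",
    "intersect",
    "covered_bp",
    "sample_control_regions",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class GenomeLayout:
    """Ordered chromosome names and lengths; the coordinate frame of a genome.

    Parameters
    ----------
    chromosomes:
        Iterable of ``(name, length)`` pairs.  Names must be unique and
        lengths positive integers.
    """

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = [(str(n), int(l)) for n, l in chromosomes]
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise InvalidParameterError("duplicate chromosome names in layout")
        for n, l in chroms:
            if l <= 0:
                raise InvalidParameterError(f"chromosome {n!r} has non-positive length {l}")
        self._chroms: tuple[tuple[str, int], ...] = tuple(chroms)
        self._lengths = dict(chroms)
        self._order = {n: i for i, (n, _) in enumerate(chroms)}

    @property
    def chromosomes(self) -> tuple[tuple[str, int], ...]:
        return self._chroms

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self._chroms]

    def length_of(self, name: str) -> int:
        return self._lengths[name]

    def order_of(self, name: str) -> int:
        return self._order[name]

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self._chroms)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self._chroms == other._chroms

    def __hash__(self):
        return hash(self._chroms)

    def __repr__(self):
        return f"GenomeLayout({len(self._chroms)} chromosomes, {self.total_bp} bp)"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open region ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    id: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InvalidParameterError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A normalized (chromosome-ordered, start-sorted) collection of intervals.

    Backed by parallel NumPy arrays; intervals within one set may overlap
    unless the caller merged them.  ``layout`` is optional; when present the
    set is validated against chromosome bounds and layout-mismatch is
    detected when two sets are combined.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        layout: GenomeLayout | None = None,
    ):
        ivs = list(intervals)
        chroms = np.array([iv.chrom for iv in ivs], dtype=object)
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        ids = None
        if any(iv.id is not None for iv in ivs):
            ids = np.array([iv.id for iv in ivs], dtype=object)
        scores = None
        if any(iv.score is not None for iv in ivs):
            scores = np.array(
                [np.nan if iv.score is None else iv.score for iv in ivs], dtype=float
            )
        self._init_from_arrays(chroms, starts, ends, ids, scores, layout)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        chroms,
        starts,
        ends,
        ids=None,
        scores=None,
        layout: GenomeLayout | None = None,
    ) -> "IntervalSet":
        obj = cls.__new__(cls)
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if ids is not None:
            ids = np.asarray(ids, dtype=object)
        if scores is not None:
            scores = np.asarray(scores, dtype=float)
        obj._init_from_arrays(chroms, starts, ends, ids, scores, layout)
        return obj

    def _init_from_arrays(self, chroms, starts, ends, ids, scores, layout):
        if not (len(chroms) == len(starts) == len(ends)):
            raise InvalidParameterError("chroms/starts/ends length mismatch")
        if np.any(starts < 0) or np.any(starts >= ends):
            bad = int(np.flatnonzero((starts < 0) | (starts >= ends))[0])
            raise InvalidParameterError(
                f"invalid interval {chroms[bad]}:{starts[bad]}-{ends[bad]}"
            )
        if layout is not None and len(chroms):
            for c in pd.unique(chroms):
                if c not in layout:
                    raise InvalidParameterError(f"chromosome {c!r} not in layout")
            lens = pd.Series(chroms).map(layout._lengths).to_numpy(dtype=np.int64)
            if np.any(ends > lens):
                bad = int(np.flatnonzero(ends > lens)[0])
                raise InvalidParameterError(
                    f"interval {chroms[bad]}:{starts[bad]}-{ends[bad]} exceeds chromosome length"
                )
        # normalize: sort by (chrom order, start, end)
        if len(chroms):
            if layout is not None:
                corder = pd.Series(chroms).map(layout._order).to_numpy(dtype=np.int64)
            else:
                _, corder = np.unique(chroms.astype(str), return_inverse=True)
            order = np.lexsort((ends, starts, corder))
        else:
            order = np.empty(0, dtype=np.intp)
        self.chroms = chroms[order]
        self.starts = starts[order]
        self.ends = ends[order]
        self.ids = ids[order] if ids is not None else None
        self.scores = scores[order] if scores is not None else None
        self.layout = layout
        self._by_chrom_cache: dict | None = None

    # -- basics -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            chrom=self.chroms[i],
            start=int(self.starts[i]),
            end=int(self.ends[i]),
            id=None if self.ids is None else self.ids[i],
            score=None if self.scores is None else float(self.scores[i]),
        )

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_bp(self) -> int:
        return int(self.lengths.sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})
        if self.ids is not None:
            df["id"] = self.ids
        if self.scores is not None:
            df["score"] = self.scores
        return df

    def subset(self, index) -> "IntervalSet":
        index = np.asarray(index)
        return IntervalSet.from_arrays(
            self.chroms[index],
            self.starts[index],
            self.ends[index],
            None if self.ids is None else self.ids[index],
            None if self.scores is None else self.scores[index],
            self.layout,
        )

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends, original_row_indices)``, start-sorted."""
        if self._by_chrom_cache is None:
            out = {}
            idx = np.arange(len(self))
            # rows are already grouped by chromosome after normalization
            if len(self):
                bounds = np.flatnonzero(
                    np.r_[True, self.chroms[1:] != self.chroms[:-1], True]
                )
                for a, b in zip(bounds[:-1], bounds[1:]):
                    out[self.chroms[a]] = (self.starts[a:b], self.ends[a:b], idx[a:b])
            self._by_chrom_cache = out
        return self._by_chrom_cache

    def merged(self) -> "IntervalSet":
        """Union of the set: disjoint, sorted intervals covering the same bases."""
        chroms_out, starts_out, ends_out = [], [], []
        for chrom, (s, e, _) in self.by_chrom().items():
            # s sorted; sweep to merge
            ms, me = [], []
            cur_s, cur_e = None, None
            for a, b in zip(s.tolist(), e.tolist()):
                if cur_s is None:
                    cur_s, cur_e = a, b
                elif a <= cur_e:
                    cur_e = max(cur_e, b)
                else:
                    ms.append(cur_s)
                    me.append(cur_e)
                    cur_s, cur_e = a, b
            if cur_s is not None:
                ms.append(cur_s)
                me.append(cur_e)
            chroms_out.extend([chrom] * len(ms))
            starts_out.extend(ms)
            ends_out.extend(me)
        return IntervalSet.from_arrays(
            np.array(chroms_out, dtype=object),
            np.array(starts_out, dtype=np.int64),
            np.array(ends_out, dtype=np.int64),
            layout=self.layout,
        )

    def expanded(self, margin: int, layout: GenomeLayout | None = None) -> "IntervalSet":
        """Intervals grown by ``margin`` bp on each side, clipped to the layout."""
        layout = layout or self.layout
        starts = np.maximum(self.starts - margin, 0)
        ends = self.ends + margin
        if layout is not None and len(self):
            lens = np.array([layout.length_of(c) for c in self.chroms], dtype=np.int64)
            ends = np.minimum(ends, lens)
        return IntervalSet.from_arrays(self.chroms, starts, ends, layout=layout)

    def __repr__(self):
        return f"IntervalSet({len(self)} intervals, {self.total_bp} bp)"


def concat_sets(sets: Sequence[IntervalSet], layout: GenomeLayout | None = None) -> IntervalSet:
    """Concatenate interval sets (re-normalized); ids/scores dropped."""
    if not sets:
        return IntervalSet(layout=layout)
    layout = layout or sets[0].layout
    return IntervalSet.from_arrays(
        np.concatenate([s.chroms for s in sets]) if sets else np.empty(0, object),
        np.concatenate([s.starts for s in sets]),
        np.concatenate([s.ends for s in sets]),
        layout=layout,
    )


def _check_layouts(a: IntervalSet, b: IntervalSet) -> None:
    if a.layout is not None and b.layout is not None and a.layout != b.layout:
        raise LayoutMismatchError("interval sets are bound to different genome layouts")


# ---------------------------------------------------------------------------
# Window tiling
# ---------------------------------------------------------------------------


def tile_windows(layout: GenomeLayout, size: int) -> IntervalSet:
    """Tile every chromosome with consecutive non-overlapping windows of ``size`` bp.

    The final window of a chromosome may be partial (shorter than ``size``);
    partial windows are recognizable by ``end - start < size`` and are
    excluded from window-scale statistics by default downstream.
    """
    if size <= 0:
        raise InvalidParameterError(f"window size must be positive, got {size}")
    chroms, starts, ends, ids = [], [], [], []
    for name, length in layout.chromosomes:
        edges = list(range(0, length, size)) + [length]
        for a, b in zip(edges[:-1], edges[1:]):
            chroms.append(name)
            starts.append(a)
            ends.append(b)
            ids.append(f"{name}:{a}-{b}")
    return IntervalSet.from_arrays(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        ids=np.array(ids, dtype=object),
        layout=layout,
    )


def full_windows(windows: IntervalSet, size: int) -> IntervalSet:
    """Drop partial terminal windows from a tiling."""
    return windows.subset(windows.lengths == size)


# ---------------------------------------------------------------------------
# Overlap / distance queries
# ---------------------------------------------------------------------------


def overlaps_any(query: IntervalSet, subject: IntervalSet, min_bp: int = 1) -> np.ndarray:
    """Boolean per query interval: does it share >= ``min_bp`` bases with any
    single subject interval?

    For ``min_bp == 1`` the test runs against the merged subject union (an
    equivalent criterion); for larger ``min_bp`` each candidate subject
    interval is checked individually, since merging could conflate adjacent
    subjects.
    """
    _check_layouts(query, subject)
    if min_bp < 1:
        raise InvalidParameterError("min_bp must be >= 1")
    out = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return out
    if min_bp == 1:
        merged = subject.merged().by_chrom()
        for chrom, (qs, qe, qidx) in query.by_chrom().items():
            if chrom not in merged:
                continue
            ms, me, _ = merged[chrom]
            # candidate: last merged interval starting before query end
            i = np.searchsorted(ms, qe, side="left") - 1
            hit = (i >= 0) & (me[np.clip(i, 0, None)] > qs)
            out[qidx] = hit
        return out
    subj = subject.by_chrom()
    for chrom, (qs, qe, qidx) in query.by_chrom().items():
        if chrom not in subj:
            continue
        ss, se, _ = subj[chrom]
        max_len = int((se - ss).max())
        lo = np.searchsorted(ss, qs - max_len + 1, side="left")
        hi = np.searchsorted(ss, qe, side="left")
        for k in range(len(qs)):
            a, b = qs[k], qe[k]
            for j in range(lo[k], hi[k]):
                if min(b, se[j]) - max(a, ss[j]) >= min_bp:
                    out[qidx[k]] = True
                    break
    return out


def count_overlapping(query: IntervalSet, subject: IntervalSet, min_bp: int = 1) -> int:
    """Number of query intervals sharing >= ``min_bp`` bases with >= 1 subject
    interval; each query interval is counted at most once."""
    return int(overlaps_any(query, subject, min_bp=min_bp).sum())


def distance_to_nearest(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per-query distance in bp to the nearest subject interval.

    0 when overlapping; otherwise the gap between the closest ends.  Queries
    on chromosomes without any subject interval get ``nan`` (the undefined
    marker); an entirely empty subject set yields all-``nan`` with a warning.
    """
    _check_layouts(query, subject)
    out = np.full(len(query), np.nan)
    if len(subject) == 0:
        warnings.warn("distance_to_nearest: empty subject set; all distances undefined")
        return out
    merged = subject.merged().by_chrom()
    for chrom, (qs, qe, qidx) in query.by_chrom().items():
        if chrom not in merged:
            continue
        ms, me, _ = merged[chrom]
        i = np.searchsorted(ms, qe, side="left") - 1  # last subject with ms < qe
        overlap = (i >= 0) & (me[np.clip(i, 0, None)] > qs)
        # left neighbor: last subject with me <= qs
        li = np.searchsorted(me, qs, side="right") - 1
        left = np.where(li >= 0, qs - me[np.clip(li, 0, None)], np.inf)
        # right neighbor: first subject with ms >= qe
        ri = np.searchsorted(ms, qe, side="left")
        right = np.where(ri < len(ms), ms[np.clip(ri, 0, len(ms) - 1)] - qe, np.inf)
        d = np.where(overlap, 0.0, np.minimum(left, right))
        out[qidx] = d
    return out


def complement(layout: GenomeLayout, iset: IntervalSet) -> IntervalSet:
    """Maximal intervals covering every base not in ``iset``.

    The union of a set and its complement tiles the genome exactly once.
    """
    merged = iset.merged().by_chrom()
    chroms, starts, ends = [], [], []
    for name, length in layout.chromosomes:
        if name in merged:
            ms, me, _ = merged[name]
            edges_s = np.r_[0, me]
            edges_e = np.r_[ms, length]
        else:
            edges_s = np.array([0])
            edges_e = np.array([length])
        keep = edges_s < edges_e
        chroms.extend([name] * int(keep.sum()))
        starts.extend(edges_s[keep].tolist())
        ends.extend(edges_e[keep].tolist())
    return IntervalSet.from_arrays(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        layout=layout,
    )


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-wise intersection of the unions of two sets (merged output).

    Used e.g. to derive bivalent chromatin regions as the intersection of two
    peak sets.
    """
    _check_layouts(a, b)
    am = a.merged().by_chrom()
    bm = b.merged().by_chrom()
    chroms, starts, ends = [], [], []
    for chrom, (as_, ae, _) in am.items():
        if chrom not in bm:
            continue
        bs, be, _ = bm[chrom]
        i = j = 0
        while i < len(as_) and j < len(bs):
            lo = max(as_[i], bs[j])
            hi = min(ae[i], be[j])
            if lo < hi:
                chroms.append(chrom)
                starts.append(int(lo))
                ends.append(int(hi))
            if ae[i] < be[j]:
                i += 1
            else:
                j += 1
    return IntervalSet.from_arrays(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        layout=a.layout or b.layout,
    )


def covered_bp(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per-query number of bases covered by the union of subject intervals."""
    _check_layouts(query, subject)
    out = np.zeros(len(query), dtype=np.int64)
    if len(query) == 0 or len(subject) == 0:
        return out
    merged = subject.merged().by_chrom()
    for chrom, (qs, qe, qidx) in query.by_chrom().items():
        if chrom not in merged:
            continue
        ms, me, _ = merged[chrom]
        cum = np.r_[0, np.cumsum(me - ms)]

        def cov_before(x):
            # covered bases in [0, x)
            j = np.searchsorted(ms, x, side="left")
            partial = np.zeros(len(x), dtype=np.int64)
            k = j - 1
            valid = k >= 0
            kk = np.clip(k, 0, None)
            partial[valid] = np.maximum(
                0, np.minimum(x[valid], me[kk[valid]]) - ms[kk[valid]]
            )
            return cum[np.clip(k, 0, None)] * (k >= 0) + partial

        out[qidx] = cov_before(qe) - cov_before(qs)
    return out


# ---------------------------------------------------------------------------
# Synteny maps and projection
# ---------------------------------------------------------------------------


class SyntenyMap:
    """Block correspondence between a source and a destination genome.

    Each block pairs a source span ``[src_start, src_end)`` with a
    destination span of identical length, on strand ``+`` (colinear) or ``-``
    (coordinates reversed within the block).  Blocks must not overlap on the
    source genome.  This is the simplified chain model behind the liftOver
    emulation: no gaps within blocks, no multi-way alignments.
    """

    def __init__(
        self,
        blocks: Iterable[tuple[str, int, int, str, int, int, str]],
        src_layout: GenomeLayout | None = None,
        dst_layout: GenomeLayout | None = None,
        min_mapped_fraction: float = 0.95,
    ):
        rows = list(blocks)
        self.src_chrom = np.array([r[0] for r in rows], dtype=object)
        self.src_start = np.array([r[1] for r in rows], dtype=np.int64)
        self.src_end = np.array([r[2] for r in rows], dtype=np.int64)
        self.dst_chrom = np.array([r[3] for r in rows], dtype=object)
        self.dst_start = np.array([r[4] for r in rows], dtype=np.int64)
        self.dst_end = np.array([r[5] for r in rows], dtype=np.int64)
        self.strand = np.array([r[6] for r in rows], dtype=object)
        self.src_layout = src_layout
        self.dst_layout = dst_layout
        self.min_mapped_fraction = float(min_mapped_fraction)
        self._validate()
        self._index = None

    def _validate(self):
        if np.any((self.src_end - self.src_start) != (self.dst_end - self.dst_start)):
            raise InvalidMapError("synteny block source and destination lengths differ")
        if np.any(self.src_start >= self.src_end):
            raise InvalidMapError("empty or inverted synteny block")
        if not np.all(np.isin(self.strand.astype(str), ["+", "-"])):
            raise InvalidMapError("block strand must be '+' or '-'")
        # non-overlap on the source genome
        order = np.lexsort((self.src_start, self.src_chrom.astype(str)))
        sc = self.src_chrom[order]
        ss = self.src_start[order]
        se = self.src_end[order]
        same = sc[1:] == sc[:-1]
        if np.any(same & (ss[1:] < se[:-1])):
            raise InvalidMapError("synteny blocks overlap on the source genome")
        self._order = order

    def __len__(self):
        return len(self.src_start)

    def by_src_chrom(self):
        """Per source chromosome: start-sorted block arrays."""
        if self._index is None:
            idx = {}
            o = self._order
            sc = self.src_chrom[o]
            if len(sc):
                bounds = np.flatnonzero(np.r_[True, sc[1:] != sc[:-1], True])
                for a, b in zip(bounds[:-1], bounds[1:]):
                    sel = o[a:b]
                    idx[sc[a]] = {
                        "ss": self.src_start[sel],
                        "se": self.src_end[sel],
                        "dc": self.dst_chrom[sel],
                        "ds": self.dst_start[sel],
                        "de": self.dst_end[sel],
                        "st": self.strand[sel],
                    }
            self._index = idx
        return self._index

    def invert(self) -> "SyntenyMap":
        """The destination-to-source map.  Valid only if blocks are also
        non-overlapping on the destination genome (true for the maps built
        here and required of invertible maps)."""
        rows = list(
            zip(
                self.dst_chrom,
                self.dst_start,
                self.dst_end,
                self.src_chrom,
                self.src_start,
                self.src_end,
                self.strand,
            )
        )
        return SyntenyMap(
            rows,
            src_layout=self.dst_layout,
            dst_layout=self.src_layout,
            min_mapped_fraction=self.min_mapped_fraction,
        )

    @property
    def aligned_bp(self) -> int:
        return int((self.src_end - self.src_start).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "src_chrom": self.src_chrom,
                "src_start": self.src_start,
                "src_end": self.src_end,
                "dst_chrom": self.dst_chrom,
                "dst_start": self.dst_start,
                "dst_end": self.dst_end,
                "strand": self.strand,
            }
        )


@dataclass
class ProjectionResult:
    """Per-interval projection of an :class:`IntervalSet` through a synteny map.

    ``ok[i]`` is True when >= ``min_fraction`` of interval i's bases lie in
    blocks projecting to a single destination chromosome and strand; then
    ``(chrom[i], start[i], end[i])`` is the min..max span of the projected
    base coordinates.  ``mapped_fraction`` is defined for every interval.
    """

    ok: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    mapped_fraction: np.ndarray

    def mapped_set(self, source: IntervalSet, dst_layout: GenomeLayout | None = None) -> IntervalSet:
        sel = np.flatnonzero(self.ok)
        ids = None
        if source.ids is not None:
            ids = source.ids[sel]
        scores = None
        if source.scores is not None:
            scores = source.scores[sel]
        return IntervalSet.from_arrays(
            self.chrom[sel], self.start[sel], self.end[sel], ids, scores, dst_layout
        )

    @property
    def source_index(self) -> np.ndarray:
        return np.flatnonzero(self.ok)


def project_intervals(
    intervals: IntervalSet, smap: SyntenyMap, min_fraction: float = 0.95
) -> ProjectionResult:
    """Project intervals to the destination genome of ``smap``.

    An interval projects iff at least ``min_fraction`` of its bases fall in
    synteny blocks and all such bases agree on destination chromosome and
    strand; the projected interval is the min..max span of the projected base
    coordinates (destination insertions inside the interval widen the span,
    exactly as liftOver's span semantics do).
    """
    n = len(intervals)
    ok = np.zeros(n, dtype=bool)
    out_chrom = np.empty(n, dtype=object)
    out_start = np.zeros(n, dtype=np.int64)
    out_end = np.zeros(n, dtype=np.int64)
    frac = np.zeros(n, dtype=float)
    index = smap.by_src_chrom()
    for chrom, (qs, qe, qidx) in intervals.by_chrom().items():
        blk = index.get(chrom)
        if blk is None:
            continue
        ss, se = blk["ss"], blk["se"]
        i0 = np.searchsorted(se, qs, side="right")
        i1 = np.searchsorted(ss, qe, side="left")
        for k in range(len(qs)):
            a, b = int(qs[k]), int(qe[k])
            lo_b, hi_b = int(i0[k]), int(i1[k])
            if hi_b <= lo_b:
                continue
            mapped = 0
            dmin, dmax = None, None
            dchrom = None
            dstrand = None
            consistent = True
            for j in range(lo_b, hi_b):
                ov_lo = max(a, int(ss[j]))
                ov_hi = min(b, int(se[j]))
                if ov_lo >= ov_hi:
                    continue
                mapped += ov_hi - ov_lo
                if dchrom is None:
                    dchrom = blk["dc"][j]
                    dstrand = blk["st"][j]
                elif blk["dc"][j] != dchrom or blk["st"][j] != dstrand:
                    consistent = False
                if blk["st"][j] == "+":
                    plo = int(blk["ds"][j]) + (ov_lo - int(ss[j]))
                    phi = int(blk["ds"][j]) + (ov_hi - int(ss[j]))
                else:
                    phi = int(blk["de"][j]) - (ov_lo - int(ss[j]))
                    plo = int(blk["de"][j]) - (ov_hi - int(ss[j]))
                dmin = plo if dmin is None else min(dmin, plo)
                dmax = phi if dmax is None else max(dmax, phi)
            f = mapped / (b - a)
            frac[qidx[k]] = f
            if consistent and f >= min_fraction and mapped > 0:
                ok[qidx[k]] = True
                out_chrom[qidx[k]] = dchrom
                out_start[qidx[k]] = dmin
                out_end[qidx[k]] = dmax
    return ProjectionResult(ok, out_chrom, out_start, out_end, frac)


def project_pieces(intervals: IntervalSet, smap: SyntenyMap) -> IntervalSet:
    """Every per-block projected piece of every interval, regardless of
    mapped fraction or destination consistency.

    This is the conservative footprint of a source set on the destination
    genome; the synthetic generators use it (plus a margin) as a forbidden
    zone so that independently placed destination features can never project
    back onto a source feature.
    """
    chroms, starts, ends = [], [], []
    index = smap.by_src_chrom()
    for chrom, (qs, qe, _) in intervals.by_chrom().items():
        blk = index.get(chrom)
        if blk is None:
            continue
        ss, se = blk["ss"], blk["se"]
        i0 = np.searchsorted(se, qs, side="right")
        i1 = np.searchsorted(ss, qe, side="left")
        for k in range(len(qs)):
            a, b = int(qs[k]), int(qe[k])
            for j in range(int(i0[k]), int(i1[k])):
                ov_lo = max(a, int(ss[j]))
                ov_hi = min(b, int(se[j]))
                if ov_lo >= ov_hi:
                    continue
                if blk["st"][j] == "+":
                    plo = int(blk["ds"][j]) + (ov_lo - int(ss[j]))
                    phi = int(blk["ds"][j]) + (ov_hi - int(ss[j]))
                else:
                    phi = int(blk["de"][j]) - (ov_lo - int(ss[j]))
                    plo = int(blk["de"][j]) - (ov_hi - int(ss[j]))
                chroms.append(blk["dc"][j])
                starts.append(plo)
                ends.append(phi)
    return IntervalSet.from_arrays(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        layout=smap.dst_layout,
    )


def map_via_synteny(
    intervals: IntervalSet, smap: SyntenyMap, min_fraction: float | None = None
) -> tuple[IntervalSet, list[str]]:
    """liftOver-style projection: returns the mapped set and the ids of
    unmapped intervals (interval ``id`` when present, else the row index as a
    string)."""
    if min_fraction is None:
        min_fraction = smap.min_mapped_fraction
    res = project_intervals(intervals, smap, min_fraction=min_fraction)
    mapped = res.mapped_set(intervals, smap.dst_layout)
    unmapped = []
    for i in np.flatnonzero(~res.ok):
        if intervals.ids is not None and intervals.ids[i] is not None:
            unmapped.append(str(intervals.ids[i]))
        else:
            unmapped.append(str(int(i)))
    return mapped, unmapped


# ---------------------------------------------------------------------------
# Length-matched control-region sampling
# ---------------------------------------------------------------------------


def sample_control_regions(
    template: IntervalSet,
    layout: GenomeLayout,
    excluded: IntervalSet,
    n: int = 1_000_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> IntervalSet:
    """Random control regions, length-matched to ``template`` and entirely
    outside ``excluded``.

    Lengths are drawn by resampling the template length multiset (when
    ``n == len(template)`` the multiset is reproduced exactly, in random
    order).  For each length, start positions are sampled uniformly over all
    eligible positions in the complement of ``excluded``, so the placement
    distribution is exactly uniform without rejection retries.  Controls may
    overlap each other, as independent draws do.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(template) == 0:
        raise InvalidParameterError("template set is empty")
    if n <= 0:
        raise InvalidParameterError("n must be positive")
    tlens = template.lengths
    if n == len(tlens):
        lengths = rng.permutation(tlens)
    else:
        lengths = rng.choice(tlens, size=n, replace=True)
    gaps = complement(layout, excluded)
    chroms, starts = place_lengths_uniform(lengths, gaps, rng)
    return IntervalSet.from_arrays(
        chroms, starts, starts + lengths.astype(np.int64), layout=layout
    )


def place_lengths_uniform(
    lengths, gaps: IntervalSet, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Start positions for intervals of the given lengths, each drawn
    uniformly over every eligible start inside the gap set.  Returns
    ``(chroms, starts)`` aligned with ``lengths``."""
    lengths = np.asarray(lengths, dtype=np.int64)
    n = len(lengths)
    gap_chrom = gaps.chroms
    gap_start = gaps.starts
    gap_len = gaps.lengths
    out_chrom = np.empty(n, dtype=object)
    out_start = np.empty(n, dtype=np.int64)
    uniq, inv = np.unique(lengths, return_inverse=True)
    for u_idx, L in enumerate(uniq):
        rows = np.flatnonzero(inv == u_idx)
        caps = np.maximum(gap_len - int(L) + 1, 0)
        total = int(caps.sum())
        if total == 0:
            raise PlacementError(int(L))
        cum = np.cumsum(caps)
        r = rng.integers(0, total, size=len(rows))
        gi = np.searchsorted(cum, r, side="right")
        offset = r - (cum[gi - 1] * (gi > 0))
        out_chrom[rows] = gap_chrom[gi]
        out_start[rows] = gap_start[gi] + offset
    return out_chrom, out_start
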