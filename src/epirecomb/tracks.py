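"""Methylation and sequence-feature tracks.

Bisulfite sequencing reports, for every covered cytosine, the number of reads
supporting methylation ("C" reads, unconverted) and non-methylation ("T"
reads, converted).  The fractional methylation of a site is C/(C+T), and the
methylation level of a region is the unweighted mean of the site fractions of
all covered CpGs inside it.  This module holds the per-site container, the
regional summaries, the standard sequence descriptors used as regression
covariates (G+C content, CpG count, CpG observed/expected), and the assembly
of the per-window feature table that the window-scale correlation and
regression analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidParameterError, LayoutMismatchError, PairingError
from .intervals import GenomeLayout, GenomicInterval, IntervalSet, covered_bp, full_windows, tile_windows

__all__ = [
    "CytosineSite",
    "MethylationTrack",
    "site_fraction",
    "regional_methylation",
    "regional_methylation_many",
    "methylation_difference",
    "gc_content",
    "cpg_count",
    "cpg_oe",
    "repeat_fraction",
    "window_rates",
    "build_window_table",
]


@dataclass(frozen=True)
class CytosineSite:
    """One covered cytosine: 0-based position plus C (methylated) and T
    (unmethylated) read counts."""

    chrom: str
    pos: int
    c_reads: int
    t_reads: int

    def __post_init__(self):
        if self.c_reads < 0 or self.t_reads < 0:
            raise InvalidParameterError("negative read counts")


class MethylationTrack:
    """Per-CpG bisulfite read counts, array-backed per chromosome.

    Sites with total depth below ``min_depth`` are dropped at construction;
    duplicate (chrom, pos) entries are rejected.
    """

    def __init__(self, min_depth: int = 1):
        if min_depth < 1:
            raise InvalidParameterError("min_depth must be >= 1")
        self.min_depth = int(min_depth)
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.dropped_low_depth = 0

    @classmethod
    def from_arrays(cls, chroms, pos, c_reads, t_reads, min_depth: int = 1) -> "MethylationTrack":
        track = cls(min_depth=min_depth)
        chroms = np.asarray(chroms, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        c = np.asarray(c_reads, dtype=np.int64)
        t = np.asarray(t_reads, dtype=np.int64)
        if np.any(c < 0) or np.any(t < 0):
            raise InvalidParameterError("negative read counts")
        keep = (c + t) >= min_depth
        track.dropped_low_depth = int((~keep).sum())
        chroms, pos, c, t = chroms[keep], pos[keep], c[keep], t[keep]
        for chrom in pd.unique(chroms):
            sel = chroms == chrom
            p = pos[sel]
            order = np.argsort(p, kind="stable")
            p = p[order]
            if len(p) > 1 and np.any(p[1:] == p[:-1]):
                raise InvalidParameterError(f"duplicate site positions on {chrom}")
            track._data[chrom] = (p, c[sel][order], t[sel][order])
        return track

    @classmethod
    def from_sites(cls, sites, min_depth: int = 1) -> "MethylationTrack":
        sites = list(sites)
        return cls.from_arrays(
            [s.chrom for s in sites],
            [s.pos for s in sites],
            [s.c_reads for s in sites],
            [s.t_reads for s in sites],
            min_depth=min_depth,
        )

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p, _, _ in self._data.values())

    @property
    def chromosomes(self) -> list[str]:
        return list(self._data)

    def arrays(self, chrom: str):
        """(positions, c_reads, t_reads) for one chromosome (sorted by position)."""
        return self._data.get(chrom, (np.empty(0, np.int64),) * 3)

    def fractions(self, chrom: str) -> np.ndarray:
        p, c, t = self.arrays(chrom)
        return c / (c + t) if len(p) else np.empty(0)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for chrom, (p, c, t) in self._data.items():
            frames.append(pd.DataFrame({"chrom": chrom, "pos": p, "c_reads": c, "t_reads": t}))
        if not frames:
            return pd.DataFrame(columns=["chrom", "pos", "c_reads", "t_reads"])
        return pd.concat(frames, ignore_index=True)

    def __repr__(self):
        return f"MethylationTrack({self.n_sites} sites, min_depth={self.min_depth})"


def site_fraction(c_reads: int, t_reads: int):
    """Fractional methylation of one cytosine: C / (C + T).

    Accepts scalars or aligned arrays; zero total depth raises (a site with
    no reads has no defined methylation level).
    """
    c = np.asarray(c_reads, dtype=float)
    t = np.asarray(t_reads, dtype=float)
    if np.any(c < 0) or np.any(t < 0):
        raise InvalidParameterError("negative read counts")
    total = c + t
    if np.any(total < 1):
        raise DegenerateInputError("site with zero total depth has undefined methylation")
    out = c / total
    return float(out) if out.ndim == 0 else out


def regional_methylation_many(
    track: MethylationTrack,
    regions: IntervalSet,
    min_sites: int = 1,
    weighted: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean fractional methylation per region plus per-region covered-site
    counts.

    Regions with fewer than ``min_sites`` covered cytosines get ``nan``.  The
    default mean is unweighted across sites; ``weighted=True`` pools reads
    instead (sum C / sum (C+T)).
    """
    n = len(regions)
    means = np.full(n, np.nan)
    counts = np.zeros(n, dtype=np.int64)
    for chrom, (qs, qe, qidx) in regions.by_chrom().items():
        p, c, t = track.arrays(chrom)
        if len(p) == 0:
            continue
        frac = c / (c + t)
        cum_f = np.r_[0.0, np.cumsum(frac)]
        cum_c = np.r_[0.0, np.cumsum(c.astype(float))]
        cum_d = np.r_[0.0, np.cumsum((c + t).astype(float))]
        lo = np.searchsorted(p, qs, side="left")
        hi = np.searchsorted(p, qe, side="left")
        k = hi - lo
        counts[qidx] = k
        with np.errstate(invalid="ignore", divide="ignore"):
            if weighted:
                m = (cum_c[hi] - cum_c[lo]) / (cum_d[hi] - cum_d[lo])
            else:
                m = (cum_f[hi] - cum_f[lo]) / k
        m[k < max(min_sites, 1)] = np.nan
        means[qidx] = m
    return means, counts


def regional_methylation(
    track: MethylationTrack,
    region: GenomicInterval,
    min_sites: int = 1,
    weighted: bool = False,
) -> float:
    """Regional methylation of a single region; ``nan`` when fewer than
    ``min_sites`` covered cytosines fall inside it."""
    means, _ = regional_methylation_many(
        track, IntervalSet([region]), min_sites=min_sites, weighted=weighted
    )
    return float(means[0])


def methylation_difference(
    track_a: MethylationTrack,
    track_b: MethylationTrack,
    regions_a: IntervalSet,
    regions_b: IntervalSet | None = None,
    min_sites: int = 1,
    weighted: bool = False,
) -> np.ndarray:
    """Per-region methylation difference (track_a minus track_b) over paired
    regions.

    ``regions_a`` and ``regions_b`` are positionally paired lists, each in
    its own genome's coordinates (pair them via synteny projection first);
    pass a single set when both tracks share coordinates.  A pair with either
    side undefined yields ``nan``.
    """
    if regions_b is None:
        regions_b = regions_a
    if len(regions_a) != len(regions_b):
        raise PairingError(
            f"paired region lists differ in length ({len(regions_a)} vs {len(regions_b)})"
        )
    ma, _ = regional_methylation_many(track_a, regions_a, min_sites=min_sites, weighted=weighted)
    mb, _ = regional_methylation_many(track_b, regions_b, min_sites=min_sites, weighted=weighted)
    return ma - mb


# ---------------------------------------------------------------------------
# Sequence descriptors
# ---------------------------------------------------------------------------

_ACGT = frozenset("ACGT")


def _counts(seq: str):
    s = seq.upper()
    nA = s.count("A")
    nC = s.count("C")
    nG = s.count("G")
    nT = s.count("T")
    return nA, nC, nG, nT


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); ambiguous bases are excluded from both
    numerator and denominator.  All-ambiguous input yields ``nan``."""
    if not seq:
        raise InvalidParameterError("empty sequence")
    nA, nC, nG, nT = _counts(seq)
    denom = nA + nC + nG + nT
    if denom == 0:
        return float("nan")
    return (nG + nC) / denom


def cpg_count(seq: str) -> int:
    """Number of CpG dinucleotides (plus strand, exact 'CG' matches)."""
    if not seq:
        raise InvalidParameterError("empty sequence")
    return seq.upper().count("CG")


def cpg_oe(seq: str) -> float:
    """Normalized CpG content (CpG observed/expected): nCpG * L / (nC * nG),
    with L the number of unambiguous bases; ``nan`` when the sequence has no
    C or no G."""
    if not seq:
        raise InvalidParameterError("empty sequence")
    nA, nC, nG, nT = _counts(seq)
    L = nA + nC + nG + nT
    if nC == 0 or nG == 0:
        return float("nan")
    return cpg_count(seq) * L / (nC * nG)


def repeat_fraction(region: GenomicInterval, repeats: IntervalSet) -> float:
    """Fraction of region bases covered by the union of repeat annotations."""
    cov = covered_bp(IntervalSet([region]), repeats)
    return float(cov[0]) / region.length


# ---------------------------------------------------------------------------
# Window feature table
# ---------------------------------------------------------------------------


def window_rates(windows: IntervalSet, rate_segments: IntervalSet) -> np.ndarray:
    """Per-window recombination rate: bp-weighted mean of the rates of map
    segments overlapping each window.

    ``rate_segments`` is a piecewise-constant scored track (disjoint
    segments).  Windows with no covered base get ``nan``.  Splitting any
    segment into abutting equal-rate pieces leaves the result unchanged.
    """
    if rate_segments.scores is None:
        raise InvalidParameterError("rate track has no scores")
    segs = rate_segments.by_chrom()
    out = np.full(len(windows), np.nan)
    for chrom, (qs, qe, qidx) in windows.by_chrom().items():
        if chrom not in segs:
            continue
        ss, se, sidx = segs[chrom]
        if len(ss) > 1 and np.any(ss[1:] < se[:-1]):
            raise InvalidParameterError(f"overlapping rate segments on {chrom}")
        rate = rate_segments.scores[sidx]
        seg_len = (se - ss).astype(float)
        cum_wlen = np.r_[0.0, np.cumsum(seg_len)]
        cum_wsum = np.r_[0.0, np.cumsum(rate * seg_len)]

        def upto(x):
            # (covered bp, rate*bp) over segment bases in [0, x)
            j = np.searchsorted(ss, x, side="left")
            k = j - 1
            kk = np.clip(k, 0, None)
            part = np.clip(np.minimum(x, se[kk]) - ss[kk], 0, None).astype(float)
            part[k < 0] = 0.0
            wl = cum_wlen[kk] * (k >= 0) + part
            wsum = cum_wsum[kk] * (k >= 0) + part * rate[kk]
            return wl, wsum

        wl_hi, wsum_hi = upto(qe)
        wl_lo, wsum_lo = upto(qs)
        bp = wl_hi - wl_lo
        with np.errstate(invalid="ignore", divide="ignore"):
            out[qidx] = (wsum_hi - wsum_lo) / bp
    return out


def _fetch_seq(seq_source, chrom: str, start: int, end: int) -> str:
    """Sequence accessor tolerant of pyfaidx.Fasta objects and plain dicts."""
    obj = seq_source[chrom]
    piece = obj[start:end]
    return piece if isinstance(piece, str) else str(piece.seq)


def build_window_table(
    layout: GenomeLayout,
    size: int,
    rec_map: IntervalSet,
    meth_track: MethylationTrack,
    seq_source=None,
    repeats: IntervalSet | None = None,
    min_sites: int = 5,
    include_partial: bool = False,
    weighted_methylation: bool = False,
) -> pd.DataFrame:
    """One row per genomic window with the response and all predictors.

    Columns: window coordinates, ``recombination_rate`` (bp-weighted mean of
    overlapping map segments, cM/Mb), ``methylation`` (mean site fraction,
    ``nan`` below ``min_sites`` covered cytosines), ``covered_sites``, and —
    when a sequence source / repeat annotation is supplied — ``gc``,
    ``cpg_count``, ``cpg_oe`` and ``repeat_fraction``.  Partial terminal
    windows are excluded unless ``include_partial``.
    """
    if rec_map.layout is not None and rec_map.layout != layout:
        raise LayoutMismatchError("recombination map layout differs from window layout")
    if repeats is not None and repeats.layout is not None and repeats.layout != layout:
        raise LayoutMismatchError("repeat annotation layout differs from window layout")
    windows = tile_windows(layout, size)
    if not include_partial:
        windows = full_windows(windows, size)
    rate = window_rates(windows, rec_map)
    meth, nsites = regional_methylation_many(
        meth_track, windows, min_sites=min_sites, weighted=weighted_methylation
    )
    df = windows.to_dataframe()[["chrom", "start", "end"]].copy()
    df["recombination_rate"] = rate
    df["methylation"] = meth
    df["covered_sites"] = nsites
    if seq_source is not None:
        gc = np.empty(len(windows))
        ncpg = np.empty(len(windows), dtype=np.int64)
        oe = np.empty(len(windows))
        for i in range(len(windows)):
            seq = _fetch_seq(seq_source, df["chrom"].iat[i], int(df["start"].iat[i]), int(df["end"].iat[i]))
            gc[i] = gc_content(seq)
            ncpg[i] = cpg_count(seq)
            oe[i] = cpg_oe(seq)
        df["gc"] = gc
        df["cpg_count"] = ncpg
        df["cpg_oe"] = oe
    if repeats is not None:
        cov = covered_bp(windows, repeats)
        df["repeat_fraction"] = cov / windows.lengths
    return df
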