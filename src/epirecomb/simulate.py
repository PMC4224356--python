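"""Synthetic-data generators with the statistical structure the pipeline assumes.

Every generator is seed-reproducible and constructed so that the quantity the
pipeline estimates is *planted* with a known value:

* paired hotspot sets whose cross-genome classification counts are exact by
  construction (including the published-scale presets);
* a window-scale methylation/recombination pair built on a shared latent
  bivariate-Gaussian field, with the latent correlation analytically
  corrected for binomial read noise so the measured window correlation
  targets the configured rho;
* peak sets with a planted fold enrichment over hotspots, where the expected
  (control-region) overlap probability is computed exactly from the gap
  geometry rather than approximated;
* colinear synteny maps with indels whose forward and reverse maps are
  mutually inverse on aligned bases.

The generators emulate the statistical shape of bisulfite methylomes,
LD-based recombination maps and ChIP peak sets — not sequence evolution,
motif content, or read-level error processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, InvalidParameterError
from .intervals import (
    GenomeLayout,
    IntervalSet,
    SyntenyMap,
    complement,
    concat_sets,
    project_intervals,
    project_pieces,
    tile_windows,
)
from .tracks import MethylationTrack

__all__ = [
    "GeneratorConfig",
    "PRESETS",
    "make_genome",
    "make_synteny_map",
    "make_paired_hotspots",
    "make_snp_dsb_hotspots",
    "make_recombination_map",
    "make_methylome",
    "make_peaks",
    "make_window_fields",
    "simulate_window_study",
    "generate_preset",
]


@dataclass
class GeneratorConfig:
    """Default study conditions for the self-contained synthetic run.

    Lengths are in bp, depth in mean reads per CpG, rates in cM/Mb.
    ``window_corr`` is the target Pearson correlation between window-mean
    methylation and window recombination rate at ``window_size``.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 10_000_000
    window_size: int = 250_000
    window_corr: float = 0.3
    hotspot_counts: tuple[int, int, int] = (400, 250, 40)
    hotspot_length_range: tuple[int, int] = (1_000, 3_000)
    peak_fold: float = 3.0
    peak_length: int = 1_000
    n_peaks: int = 1_000
    read_depth: float = 30.0
    site_spacing: int = 5_000
    indel_rate: float = 1e-5
    indel_size: tuple[int, int] = (1, 50)
    gc: float = 0.42
    m_mean: float = 0.7
    m_sd: float = 0.08
    rate_mean: float = 1.0
    rate_cv: float = 0.35
    hotspot_multiplier: float = 10.0

    def __post_init__(self):
        n_a, n_b, n_shared = self.hotspot_counts
        if n_shared > min(n_a, n_b):
            raise InvalidParameterError("n_shared exceeds min(n_a, n_b)")
        if not (-1 < self.window_corr < 1):
            raise InvalidParameterError("|window_corr| must be < 1")
        if self.read_depth < 1:
            raise InvalidParameterError("read depth must be >= 1")


#: Published-scale preset conditions.  The human/chimp counts reproduce the
#: species-specific/common hotspot partition (9,300 human and 5,037 chimp
#: hotspots, 131 shared); the mouse preset reproduces the SNP/DSB partition
#: (47,068 SNP and 9,874 DSB hotspots, 2,571 DSB hotspots overlapping 2,570
#: distinct SNP hotspots — the published class sizes are only consistent if
#: one SNP hotspot carries two DSB hotspots).
PRESETS: dict[str, dict] = {
    "humanchimp_paper": dict(
        kind="cross_species",
        n_chrom=2,
        chrom_length=50_000_000,
        counts=(9_300, 5_037, 131),
        length_range=(1_000, 3_000),
        indel_rate=1e-5,
        indel_size=(1, 50),
    ),
    "mouse_paper": dict(
        kind="snp_dsb",
        n_chrom=5,
        chrom_length=100_000_000,
        n_snp=47_068,
        n_dsb=9_874,
        n_shared_dsb=2_571,
        n_snp_overlapped=2_570,
        length_range=(1_000, 3_000),
    ),
    "window_corr": dict(
        kind="window_study",
        n_chrom=5,
        chrom_length=500_000_000,
        window_size=500_000,
        rho=0.2,
        depth=30.0,
        site_spacing=10_000,
        m_mean=0.7,
        m_sd=0.08,
        rate_mean=1.0,
        rate_cv=0.35,
    ),
    "enrichment": dict(
        kind="enrichment",
        n_chrom=5,
        chrom_length=100_000_000,
        n_hotspots=5_000,
        length_range=(1_000, 3_000),
        fold=3.5,
        peak_length=1_000,
        n_peaks=20_000,
    ),
}


def _rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Genome and synteny
# ---------------------------------------------------------------------------


def make_genome(
    n_chrom: int,
    chrom_length: int,
    gc: float = 0.41,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    with_sequence: bool = False,
    prefix: str = "chr",
):
    """A genome layout of ``n_chrom`` equal-length chromosomes, optionally
    with i.i.d. random sequence at the given G+C fraction.

    Returns ``(layout, sequences)`` where ``sequences`` is ``None`` or a dict
    of chromosome name to string.
    """
    rng = _rng(seed, rng)
    layout = GenomeLayout([(f"{prefix}{i + 1}", chrom_length) for i in range(n_chrom)])
    seqs = None
    if with_sequence:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seqs = {
            name: bases[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")
            for name, length in layout.chromosomes
        }
    return layout, seqs


def make_synteny_map(
    layout_a: GenomeLayout,
    indel_rate: float = 1e-5,
    indel_size: tuple[int, int] = (1, 50),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """A colinear two-genome alignment: aligned blocks separated by indels.

    Aligned block lengths are geometric with mean ``1/indel_rate``; each
    indel is, with equal probability, an insertion in the destination genome
    or a deletion (unaligned source bases), with size uniform in
    ``indel_size``.  Returns ``(forward, reverse, layout_b)``; forward and
    reverse are mutually inverse on aligned bases.  ``indel_rate=0`` yields
    the identity map.
    """
    rng = _rng(seed, rng)
    if indel_rate < 0:
        raise InvalidParameterError("indel_rate must be >= 0")
    blocks = []
    b_lengths = []
    lo, hi = indel_size
    for name, length in layout_a.chromosomes:
        pos_a = 0
        pos_b = 0
        while pos_a < length:
            if indel_rate > 0:
                bl = int(min(rng.geometric(indel_rate), length - pos_a))
            else:
                bl = length - pos_a
            blocks.append((name, pos_a, pos_a + bl, name, pos_b, pos_b + bl, "+"))
            pos_a += bl
            pos_b += bl
            if pos_a >= length:
                break
            d = int(rng.integers(lo, hi + 1))
            if rng.random() < 0.5:
                pos_b += d  # insertion in genome B
            else:
                pos_a = min(pos_a + d, length)  # deletion relative to B
        b_lengths.append((name, max(pos_b, 1)))
    layout_b = GenomeLayout(b_lengths)
    fwd = SyntenyMap(blocks, src_layout=layout_a, dst_layout=layout_b)
    return fwd, fwd.invert(), layout_b


# ---------------------------------------------------------------------------
# Disjoint interval placement
# ---------------------------------------------------------------------------


def _place_disjoint(
    lengths,
    layout: GenomeLayout,
    rng: np.random.Generator,
    forbidden: IntervalSet | None = None,
    max_rounds: int = 500,
) -> IntervalSet:
    """Place intervals of the given lengths uniformly at random, mutually
    disjoint and disjoint from ``forbidden``.

    Batch rejection: each round proposes positions for all still-unplaced
    intervals, accepts the non-conflicting ones, and retries the rest.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    names = layout.names
    clens = np.array([layout.length_of(n) for n in names], dtype=np.int64)
    weights = clens / clens.sum()
    occ: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if forbidden is not None and len(forbidden):
        for chrom, (s, e, _) in forbidden.merged().by_chrom().items():
            occ[chrom] = (s.copy(), e.copy())
    placed_chrom = np.empty(len(lengths), dtype=object)
    placed_start = np.empty(len(lengths), dtype=np.int64)
    pending = np.arange(len(lengths))
    for _ in range(max_rounds):
        if len(pending) == 0:
            break
        L = lengths[pending]
        ci = rng.choice(len(names), size=len(pending), p=weights)
        span = clens[ci] - L
        if np.any(span < 0):
            raise GenerationError("interval longer than chromosome")
        st = rng.integers(0, span + 1)
        order = np.lexsort((st, ci))
        accepted = []
        prev_end: dict[int, int] = {}
        for k in order:
            c = int(ci[k])
            s = int(st[k])
            e = s + int(L[k])
            if c in prev_end and s < prev_end[c]:
                continue
            name = names[c]
            if name in occ:
                os_, oe_ = occ[name]
                i = np.searchsorted(os_, e, side="left") - 1
                if i >= 0 and oe_[i] > s:
                    continue
            accepted.append((k, c, s, e))
            prev_end[c] = e
        if accepted:
            acc_idx = np.array([a[0] for a in accepted])
            rows = pending[acc_idx]
            placed_chrom[rows] = [names[a[1]] for a in accepted]
            placed_start[rows] = [a[2] for a in accepted]
            for name in {names[a[1]] for a in accepted}:
                new_s = np.array([a[2] for a in accepted if names[a[1]] == name], dtype=np.int64)
                new_e = np.array([a[3] for a in accepted if names[a[1]] == name], dtype=np.int64)
                if name in occ:
                    os_, oe_ = occ[name]
                    os_ = np.concatenate([os_, new_s])
                    oe_ = np.concatenate([oe_, new_e])
                else:
                    os_, oe_ = new_s, new_e
                o = np.argsort(os_, kind="stable")
                occ[name] = (os_[o], oe_[o])
            mask = np.ones(len(pending), dtype=bool)
            mask[acc_idx] = False
            pending = pending[mask]
    if len(pending):
        raise GenerationError(
            f"could not place {len(pending)} intervals after {max_rounds} rounds; "
            "genome too crowded for the requested counts"
        )
    return IntervalSet.from_arrays(
        placed_chrom, placed_start, placed_start + lengths, layout=layout
    )


# ---------------------------------------------------------------------------
# Hotspot sets
# ---------------------------------------------------------------------------


def make_paired_hotspots(
    layout_a: GenomeLayout,
    layout_b: GenomeLayout,
    map_ab: SyntenyMap,
    map_ba: SyntenyMap,
    counts: tuple[int, int, int],
    length_range: tuple[int, int] = (1_000, 3_000),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    margin: int = 100,
) -> tuple[IntervalSet, IntervalSet]:
    """Hotspot sets for two genomes with exactly ``n_shared`` cross-genome
    pairs.

    Exactly ``n_shared`` genome-A hotspots project (through ``map_ab``) onto
    a genome-B hotspot, reciprocally; every other hotspot's projection is
    overlap-free by construction (B-specific hotspots are placed outside the
    margin-expanded footprint of all A hotspots, which — for a colinear map —
    guarantees their back-projections avoid A hotspots).  Within-set
    intervals are disjoint; lengths are uniform over ``length_range``.
    """
    rng = _rng(seed, rng)
    n_a, n_b, n_shared = counts
    if n_shared > min(n_a, n_b):
        raise GenerationError("n_shared exceeds min(n_a, n_b)")
    lo, hi = length_range
    hs_a = _place_disjoint(rng.integers(lo, hi + 1, size=n_a), layout_a, rng)
    proj = project_intervals(hs_a, map_ab, min_fraction=map_ab.min_mapped_fraction)
    candidates = rng.permutation(np.flatnonzero(proj.ok))
    shared_a: list[int] = []
    for i in candidates:
        if len(shared_a) == n_shared:
            break
        piv = IntervalSet.from_arrays(
            np.array([proj.chrom[i]], dtype=object),
            np.array([proj.start[i]]),
            np.array([proj.end[i]]),
            layout=layout_b,
        )
        back = project_intervals(piv, map_ba, min_fraction=map_ba.min_mapped_fraction)
        if not back.ok[0]:
            continue
        if back.chrom[0] != hs_a.chroms[i]:
            continue
        if back.start[0] < hs_a.ends[i] and back.end[0] > hs_a.starts[i]:
            shared_a.append(int(i))
    if len(shared_a) < n_shared:
        raise GenerationError(
            f"only {len(shared_a)} of {n_shared} shared hotspots are cleanly mappable; "
            "reduce indel rate or hotspot count"
        )
    shared_a = np.array(shared_a, dtype=np.intp)
    hs_b_shared = IntervalSet.from_arrays(
        proj.chrom[shared_a], proj.start[shared_a], proj.end[shared_a], layout=layout_b
    )
    footprint = project_pieces(hs_a, map_ab).expanded(margin, layout_b).merged()
    hs_b_specific = _place_disjoint(
        rng.integers(lo, hi + 1, size=n_b - n_shared), layout_b, rng, forbidden=footprint
    )
    hs_b = concat_sets([hs_b_shared, hs_b_specific], layout=layout_b)
    return hs_a, hs_b


def make_snp_dsb_hotspots(
    layout: GenomeLayout,
    n_snp: int,
    n_dsb: int,
    n_shared_dsb: int,
    n_snp_overlapped: int | None = None,
    length_range: tuple[int, int] = (1_000, 3_000),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[IntervalSet, IntervalSet]:
    """Historical (SNP-map) and current (DSB-map) hotspot sets on one genome.

    Exactly ``n_shared_dsb`` DSB hotspots overlap a SNP hotspot, landing on
    ``n_snp_overlapped`` distinct SNP hotspots (default: one DSB per
    overlapped SNP hotspot; fewer overlapped hosts than shared DSBs means
    some hosts carry two).  Overlapping DSB hotspots are placed fully inside
    their host so that all remaining pairs are overlap-free by construction.
    """
    rng = _rng(seed, rng)
    if n_snp_overlapped is None:
        n_snp_overlapped = n_shared_dsb
    n_double = n_shared_dsb - n_snp_overlapped
    if n_double < 0 or n_double > n_snp_overlapped:
        raise GenerationError("need n_snp_overlapped <= n_shared_dsb <= 2 * n_snp_overlapped")
    if n_snp_overlapped > n_snp or n_shared_dsb > n_dsb:
        raise GenerationError("shared counts exceed set sizes")
    lo, hi = length_range
    snp = _place_disjoint(rng.integers(lo, hi + 1, size=n_snp), layout, rng)
    snp_lens = snp.lengths
    long_enough = np.flatnonzero(snp_lens >= 2 * lo + 2)
    if n_double > len(long_enough):
        raise GenerationError("not enough long SNP hotspots to host double DSB overlaps")
    hosts_double = rng.choice(long_enough, size=n_double, replace=False) if n_double else np.empty(0, np.intp)
    rest = np.setdiff1d(np.arange(n_snp), hosts_double)
    hosts_single = rng.choice(rest, size=n_snp_overlapped - n_double, replace=False)
    dsb_chrom, dsb_start, dsb_end = [], [], []
    for h in hosts_single:
        s, e = int(snp.starts[h]), int(snp.ends[h])
        L = int(min(rng.integers(lo, hi + 1), e - s))
        st = int(rng.integers(s, e - L + 1))
        dsb_chrom.append(snp.chroms[h])
        dsb_start.append(st)
        dsb_end.append(st + L)
    for h in hosts_double:
        s, e = int(snp.starts[h]), int(snp.ends[h])
        mid = (s + e) // 2
        st1 = int(rng.integers(s, mid - lo + 1))
        st2 = int(rng.integers(mid, e - lo + 1))
        for st in (st1, st2):
            dsb_chrom.append(snp.chroms[h])
            dsb_start.append(st)
            dsb_end.append(st + lo)
    dsb_shared = IntervalSet.from_arrays(
        np.array(dsb_chrom, dtype=object),
        np.array(dsb_start, dtype=np.int64),
        np.array(dsb_end, dtype=np.int64),
        layout=layout,
    )
    forbidden = concat_sets([snp, dsb_shared], layout=layout).merged()
    dsb_only = _place_disjoint(
        rng.integers(lo, hi + 1, size=n_dsb - n_shared_dsb), layout, rng, forbidden=forbidden
    )
    dsb = concat_sets([dsb_shared, dsb_only], layout=layout)
    return snp, dsb


# ---------------------------------------------------------------------------
# Window-scale latent fields, methylome, recombination map
# ---------------------------------------------------------------------------


def make_window_fields(
    n_windows: int, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """A bivariate standard-normal latent field pair with correlation rho."""
    if not (-1 < rho < 1):
        raise InvalidParameterError("|rho| must be < 1")
    z = rng.standard_normal((n_windows, 2))
    z1 = z[:, 0]
    z2 = rho * z1 + np.sqrt(1 - rho**2) * z[:, 1]
    return z1, z2


def _window_values(layout: GenomeLayout, window_size: int, values: np.ndarray):
    """Group per-window values by chromosome; returns dict chrom -> (starts, vals)."""
    windows = tile_windows(layout, window_size)
    out = {}
    i = 0
    for chrom, (ws, we, idx) in windows.by_chrom().items():
        out[chrom] = (ws, values[idx])
    return windows, out


def make_methylome(
    layout: GenomeLayout,
    window_size: int,
    window_m: np.ndarray,
    site_spacing: int = 5_000,
    depth: float = 30.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MethylationTrack:
    """A per-CpG bisulfite track whose true regional methylation is the given
    per-window value.

    CpG sites sit on a jittered grid with mean spacing ``site_spacing``; the
    read depth of a site is Poisson(``depth``) floored at 1, and its C count
    is Binomial(depth, m) with m the value of the containing window.
    """
    rng = _rng(seed, rng)
    windows, per_chrom = _window_values(layout, window_size, np.asarray(window_m, dtype=float))
    chroms, positions, cs, ts = [], [], [], []
    for name, length in layout.chromosomes:
        grid = np.arange(site_spacing // 2, length, site_spacing, dtype=np.int64)
        jitter = rng.integers(-(site_spacing // 4), site_spacing // 4 + 1, size=len(grid))
        pos = np.clip(grid + jitter, 0, length - 1)
        ws, vals = per_chrom[name]
        m = vals[np.searchsorted(ws, pos, side="right") - 1]
        d = np.maximum(1, rng.poisson(depth, size=len(pos)))
        c = rng.binomial(d, m)
        chroms.append(np.full(len(pos), name, dtype=object))
        positions.append(pos)
        cs.append(c)
        ts.append(d - c)
    return MethylationTrack.from_arrays(
        np.concatenate(chroms),
        np.concatenate(positions),
        np.concatenate(cs),
        np.concatenate(ts),
        min_depth=1,
    )


def make_recombination_map(
    layout: GenomeLayout,
    window_size: int,
    window_rates: np.ndarray | None = None,
    background_rate: float = 1.0,
    hotspots: IntervalSet | None = None,
    hotspot_multiplier: float = 1.0,
) -> IntervalSet:
    """A piecewise-constant recombination map (scored segment set, cM/Mb).

    The per-window background is ``window_rates`` (or a flat
    ``background_rate``); bases inside hotspots are multiplied by
    ``hotspot_multiplier``, splitting segments at hotspot boundaries.
    """
    if background_rate <= 0:
        raise InvalidParameterError("background_rate must be positive")
    windows = tile_windows(layout, window_size)
    if window_rates is None:
        window_rates = np.full(len(windows), float(background_rate))
    window_rates = np.asarray(window_rates, dtype=float)
    if len(window_rates) != len(windows):
        raise InvalidParameterError("window_rates length does not match the tiling")
    hot = hotspots.merged().by_chrom() if hotspots is not None and len(hotspots) else {}
    chroms, starts, ends, scores = [], [], [], []
    _, per_chrom = _window_values(layout, window_size, window_rates)
    for name, length in layout.chromosomes:
        ws, vals = per_chrom[name]
        edges = set(ws.tolist())
        edges.add(length)
        if name in hot:
            hs, he, _ = hot[name]
            edges.update(int(x) for x in hs)
            edges.update(int(x) for x in he)
        edges = np.array(sorted(e for e in edges if 0 <= e <= length), dtype=np.int64)
        seg_s = edges[:-1]
        seg_e = edges[1:]
        rate = vals[np.searchsorted(ws, seg_s, side="right") - 1].copy()
        if name in hot:
            hs, he, _ = hot[name]
            j = np.searchsorted(hs, seg_s, side="right") - 1
            inside = (j >= 0) & (he[np.clip(j, 0, None)] > seg_s)
            rate[inside] *= hotspot_multiplier
        chroms.append(np.full(len(seg_s), name, dtype=object))
        starts.append(seg_s)
        ends.append(seg_e)
        scores.append(rate)
    return IntervalSet.from_arrays(
        np.concatenate(chroms),
        np.concatenate(starts),
        np.concatenate(ends),
        scores=np.concatenate(scores),
        layout=layout,
    )


def planted_correlation_attenuation(
    m_mean: float, m_sd: float, depth: float, sites_per_window: float
) -> float:
    """Attenuation of the window-level methylation/rate correlation caused by
    binomial read noise: sd(true) / sd(measured)."""
    v_noise = m_mean * (1 - m_mean) / (depth * sites_per_window)
    return m_sd / np.sqrt(m_sd**2 + v_noise)


def simulate_window_study(
    n_chrom: int = 5,
    chrom_length: int = 500_000_000,
    window_size: int = 500_000,
    rho: float = 0.2,
    depth: float = 30.0,
    site_spacing: int = 10_000,
    m_mean: float = 0.7,
    m_sd: float = 0.08,
    rate_mean: float = 1.0,
    rate_cv: float = 0.35,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Generate a matched methylome + recombination map whose window-scale
    Pearson correlation targets ``rho``.

    True window methylation is ``clip(m_mean + m_sd * z1, 0.01, 0.99)`` and
    the window rate ``max(0.05 * rate_mean, rate_mean * (1 + rate_cv * z2))``
    for a latent bivariate-normal ``(z1, z2)``.  Both links are affine except
    in the far tails, so the measured correlation equals the latent one up to
    read-noise attenuation, which is corrected analytically from depth and
    CpG density.  Returns a dict with layout, windows, rate map, methylation
    track and the latent correlation actually used.
    """
    rng = _rng(seed, rng)
    layout, _ = make_genome(n_chrom, chrom_length, rng=rng)
    windows = tile_windows(layout, window_size)
    att = planted_correlation_attenuation(
        m_mean, m_sd, depth, sites_per_window=window_size / site_spacing
    )
    rho_latent = rho / att
    if not (-1 < rho_latent < 1):
        raise GenerationError("target correlation unattainable at this depth/density")
    z1, z2 = make_window_fields(len(windows), rho_latent, rng)
    window_m = np.clip(m_mean + m_sd * z1, 0.01, 0.99)
    window_r = np.maximum(0.05 * rate_mean, rate_mean * (1 + rate_cv * z2))
    rec_map = make_recombination_map(layout, window_size, window_rates=window_r)
    meth = make_methylome(
        layout, window_size, window_m, site_spacing=site_spacing, depth=depth, rng=rng
    )
    return {
        "layout": layout,
        "windows": windows,
        "rec_map": rec_map,
        "meth_track": meth,
        "window_m": window_m,
        "window_rate": window_r,
        "rho_target": rho,
        "rho_latent": rho_latent,
    }


# ---------------------------------------------------------------------------
# Peak sets with planted fold enrichment
# ---------------------------------------------------------------------------


def _gap_overlap_probability(
    gap_lengths: np.ndarray, control_len: int, peak_len: int
) -> tuple[float, float, float]:
    """Exact probability that one uniformly placed control of ``control_len``
    and one uniformly placed peak of ``peak_len`` (both confined to the gaps)
    overlap; returns (q, total_control_starts, total_peak_starts)."""
    g = gap_lengths.astype(np.int64)
    A = np.maximum(g - control_len + 1, 0).astype(float)
    B = np.maximum(g - peak_len + 1, 0).astype(float)
    M = B - control_len
    m = np.minimum(A, np.maximum(M, 0.0))
    right = m * M - m * (m - 1) / 2
    M2 = A - peak_len
    m2 = np.minimum(B, np.maximum(M2, 0.0))
    left = m2 * M2 - m2 * (m2 - 1) / 2
    pairs = A * B - np.maximum(right, 0) - np.maximum(left, 0)
    tot_A = A.sum()
    tot_B = B.sum()
    if tot_A == 0 or tot_B == 0:
        return 0.0, tot_A, tot_B
    return float(pairs.sum() / (tot_A * tot_B)), tot_A, tot_B


def expected_control_overlaps(
    hotspots: IntervalSet, layout: GenomeLayout, peak_length: int, n_free_peaks: int
) -> float:
    """Analytic expected number of length-matched hotspot-free control
    regions (one per hotspot) overlapping at least one of ``n_free_peaks``
    peaks placed uniformly in the hotspot-free genome."""
    gaps = complement(layout, hotspots)
    g = gaps.lengths
    uniq, counts = np.unique(hotspots.lengths, return_counts=True)
    total = 0.0
    for L, k in zip(uniq, counts):
        q, _, _ = _gap_overlap_probability(g, int(L), peak_length)
        total += k * (1.0 - (1.0 - q) ** n_free_peaks)
    return total


def _uniform_gap_placements(
    gaps: IntervalSet, length: int, k: int, rng: np.random.Generator
) -> IntervalSet:
    caps = np.maximum(gaps.lengths - length + 1, 0)
    total = int(caps.sum())
    if total == 0:
        raise GenerationError(f"no room for intervals of length {length} outside excluded regions")
    cum = np.cumsum(caps)
    r = rng.integers(0, total, size=k)
    gi = np.searchsorted(cum, r, side="right")
    offset = r - (cum[gi - 1] * (gi > 0))
    starts = gaps.starts[gi] + offset
    return IntervalSet.from_arrays(
        gaps.chroms[gi], starts, starts + length, layout=gaps.layout
    )


def make_peaks(
    layout: GenomeLayout,
    hotspots: IntervalSet,
    fold: float,
    peak_length: int = 1_000,
    n_peaks: int = 20_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> IntervalSet:
    """A peak set with planted fold enrichment over hotspots.

    The target is fold = observed / expected where "expected" is the number
    of length-matched hotspot-free controls overlapping a peak (the control-
    resampling definition used by the enrichment analysis).  The construction
    places ``n_in`` peaks fully inside ``n_in`` distinct hotspots (so the
    observed overlap count is exactly ``n_in``) and the remaining peaks
    uniformly over the hotspot-free genome; ``n_in = round(fold * E)`` with E
    the exact analytic expectation for the free peaks, solved by fixed-point
    iteration since E depends on how many peaks remain free.
    """
    rng = _rng(seed, rng)
    if fold < 0:
        raise InvalidParameterError("fold must be >= 0")
    n_hs = len(hotspots)
    if n_hs == 0:
        raise InvalidParameterError("empty hotspot set")
    gaps = complement(layout, hotspots)
    cap = min(n_hs, n_peaks)

    def _unattainable():
        e_min = expected_control_overlaps(
            hotspots, layout, peak_length, max(n_peaks - cap, 0)
        )
        attainable = cap / e_min if e_min > 0 else float("inf")
        raise GenerationError(
            f"requested fold {fold} unattainable; maximum attainable is about {attainable:.2f}"
        )

    n_in = 0
    for _ in range(12):
        E = expected_control_overlaps(hotspots, layout, peak_length, n_peaks - n_in)
        new_n_in = int(round(fold * E))
        if new_n_in > cap:
            _unattainable()
        if new_n_in == n_in:
            break
        n_in = new_n_in
    hosts = rng.choice(n_hs, size=n_in, replace=False) if n_in else np.empty(0, np.intp)
    in_chrom, in_start, in_end = [], [], []
    for h in hosts:
        s, e = int(hotspots.starts[h]), int(hotspots.ends[h])
        L = min(peak_length, e - s)
        st = int(rng.integers(s, e - L + 1))
        in_chrom.append(hotspots.chroms[h])
        in_start.append(st)
        in_end.append(st + L)
    inside = IntervalSet.from_arrays(
        np.array(in_chrom, dtype=object),
        np.array(in_start, dtype=np.int64),
        np.array(in_end, dtype=np.int64),
        layout=layout,
    )
    outside = _uniform_gap_placements(gaps, peak_length, n_peaks - n_in, rng)
    return concat_sets([inside, outside], layout=layout)


# ---------------------------------------------------------------------------
# Preset dispatch
# ---------------------------------------------------------------------------


def generate_preset(name: str, seed: int | None = None) -> dict:
    """Generate the named preset's full input bundle.

    ``humanchimp_paper`` returns layouts, synteny maps and the paired hotspot
    sets; ``mouse_paper`` the SNP/DSB sets; ``window_corr`` the matched
    methylome/rate pair; ``enrichment`` hotspots plus peaks with planted
    fold.
    """
    if name not in PRESETS:
        raise InvalidParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = dict(PRESETS[name])
    kind = cfg.pop("kind")
    rng = _rng(seed)
    if kind == "cross_species":
        layout_a, _ = make_genome(cfg["n_chrom"], cfg["chrom_length"], rng=rng)
        map_ab, map_ba, layout_b = make_synteny_map(
            layout_a, indel_rate=cfg["indel_rate"], indel_size=cfg["indel_size"], rng=rng
        )
        hs_a, hs_b = make_paired_hotspots(
            layout_a, layout_b, map_ab, map_ba, cfg["counts"], cfg["length_range"], rng=rng
        )
        return {
            "layout_a": layout_a,
            "layout_b": layout_b,
            "map_ab": map_ab,
            "map_ba": map_ba,
            "hs_a": hs_a,
            "hs_b": hs_b,
            "counts": cfg["counts"],
        }
    if kind == "snp_dsb":
        layout, _ = make_genome(cfg["n_chrom"], cfg["chrom_length"], rng=rng)
        snp, dsb = make_snp_dsb_hotspots(
            layout,
            cfg["n_snp"],
            cfg["n_dsb"],
            cfg["n_shared_dsb"],
            cfg["n_snp_overlapped"],
            cfg["length_range"],
            rng=rng,
        )
        return {"layout": layout, "snp": snp, "dsb": dsb}
    if kind == "window_study":
        params = {k: v for k, v in cfg.items()}
        return simulate_window_study(rng=rng, **params)
    if kind == "enrichment":
        layout, _ = make_genome(cfg["n_chrom"], cfg["chrom_length"], rng=rng)
        lo, hi = cfg["length_range"]
        hotspots = _place_disjoint(
            rng.integers(lo, hi + 1, size=cfg["n_hotspots"]), layout, rng
        )
        peaks = make_peaks(
            layout,
            hotspots,
            fold=cfg["fold"],
            peak_length=cfg["peak_length"],
            n_peaks=cfg["n_peaks"],
            rng=rng,
        )
        return {"layout": layout, "hotspots": hotspots, "peaks": peaks, "fold": cfg["fold"]}
    raise InvalidParameterError(f"unknown preset kind {kind!r}")
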