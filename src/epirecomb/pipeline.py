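"""Fine-scale hotspot analyses.

Cross-species hotspot classification through synteny projection, historical
(SNP-map) versus current (DSB-map) hotspot classification in one genome,
overlap enrichment of hotspots in chromatin-mark peak sets against
length-matched control-region resampling, the bootstrap null for
interspecies methylation divergence at hotspots, recombination-rate profiles
as a function of distance to the nearest peak, grouped feature comparisons,
and the end-to-end synthetic run.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, StageError
from .intervals import (
    GenomeLayout,
    IntervalSet,
    SyntenyMap,
    complement,
    concat_sets,
    count_overlapping,
    distance_to_nearest,
    intersect,
    overlaps_any,
    place_lengths_uniform,
    project_intervals,
)
from .stats import fisher_exact_2x2, one_way_anova, two_sample_t
from .tracks import MethylationTrack, regional_methylation_many

logger = logging.getLogger("epirecomb")

__all__ = [
    "CrossSpeciesClassification",
    "MouseClassification",
    "EnrichmentResult",
    "BootstrapNull",
    "GroupComparison",
    "classify_cross_species",
    "classify_mouse",
    "overlap_enrichment",
    "methylation_divergence_null",
    "recombination_distance_profile",
    "group_feature_comparison",
    "default_config",
    "run_full_analysis",
]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass
class CrossSpeciesClassification:
    """Hotspot classes for a two-genome comparison.

    ``labels_*`` holds ``"common"`` or ``"species_specific"`` per input
    hotspot; unmappable hotspots (synteny projection failed) are flagged
    separately and counted as species-specific by default — they cannot be
    shared — but never silently dropped.  ``syntenic_*`` are the projections
    of the partner genome's specific hotspots, the third region class used in
    the grouped comparisons.
    """

    labels_a: np.ndarray
    labels_b: np.ndarray
    unmappable_a: np.ndarray
    unmappable_b: np.ndarray
    syntenic_b_of_a_specific: IntervalSet
    syntenic_a_of_b_specific: IntervalSet
    proj_a: object = None
    proj_b: object = None

    @property
    def n_common_a(self) -> int:
        return int((self.labels_a == "common").sum())

    @property
    def n_common_b(self) -> int:
        return int((self.labels_b == "common").sum())

    @property
    def n_specific_a(self) -> int:
        return int((self.labels_a == "species_specific").sum())

    @property
    def n_specific_b(self) -> int:
        return int((self.labels_b == "species_specific").sum())

    @property
    def n_unmappable_a(self) -> int:
        return int(self.unmappable_a.sum())

    @property
    def n_unmappable_b(self) -> int:
        return int(self.unmappable_b.sum())

    def summary(self) -> dict[str, int]:
        return {
            "species_specific_a": self.n_specific_a,
            "species_specific_b": self.n_specific_b,
            "common_a": self.n_common_a,
            "common_b": self.n_common_b,
            "unmappable_a": self.n_unmappable_a,
            "unmappable_b": self.n_unmappable_b,
        }


def classify_cross_species(
    hs_a: IntervalSet,
    hs_b: IntervalSet,
    map_ab: SyntenyMap,
    map_ba: SyntenyMap,
    reciprocal: bool = True,
    min_fraction: float | None = None,
) -> CrossSpeciesClassification:
    """Classify each genome's hotspots as common (shared) or species-specific.

    A hotspot is common iff its synteny projection overlaps (>= 1 bp) a
    hotspot of the partner genome; with ``reciprocal`` (default) the overlap
    must also hold in the opposite direction, i.e. the hotspot must itself be
    overlapped by the projection of some partner hotspot.  Hotspots whose
    projection fails (below ``min_fraction`` mapped bases, or inconsistent
    destination) are flagged unmappable and classified species-specific.
    """
    fa = min_fraction if min_fraction is not None else map_ab.min_mapped_fraction
    fb = min_fraction if min_fraction is not None else map_ba.min_mapped_fraction
    proj_a = project_intervals(hs_a, map_ab, min_fraction=fa)
    proj_b = project_intervals(hs_b, map_ba, min_fraction=fb)
    proj_a_set = proj_a.mapped_set(hs_a, map_ab.dst_layout)
    proj_b_set = proj_b.mapped_set(hs_b, map_ba.dst_layout)

    fwd_a = np.zeros(len(hs_a), dtype=bool)
    if len(proj_a_set):
        fwd_a[proj_a.source_index] = overlaps_any(proj_a_set, hs_b)
    fwd_b = np.zeros(len(hs_b), dtype=bool)
    if len(proj_b_set):
        fwd_b[proj_b.source_index] = overlaps_any(proj_b_set, hs_a)

    if reciprocal:
        common_a = fwd_a & overlaps_any(hs_a, proj_b_set)
        common_b = fwd_b & overlaps_any(hs_b, proj_a_set)
    else:
        common_a, common_b = fwd_a, fwd_b

    labels_a = np.where(common_a, "common", "species_specific").astype(object)
    labels_b = np.where(common_b, "common", "species_specific").astype(object)

    spec_a = proj_a.ok & ~common_a
    syntenic_b = IntervalSet.from_arrays(
        proj_a.chrom[spec_a],
        proj_a.start[spec_a],
        proj_a.end[spec_a],
        layout=map_ab.dst_layout,
    )
    spec_b = proj_b.ok & ~common_b
    syntenic_a = IntervalSet.from_arrays(
        proj_b.chrom[spec_b],
        proj_b.start[spec_b],
        proj_b.end[spec_b],
        layout=map_ba.dst_layout,
    )
    return CrossSpeciesClassification(
        labels_a=labels_a,
        labels_b=labels_b,
        unmappable_a=~proj_a.ok,
        unmappable_b=~proj_b.ok,
        syntenic_b_of_a_specific=syntenic_b,
        syntenic_a_of_b_specific=syntenic_a,
        proj_a=proj_a,
        proj_b=proj_b,
    )


@dataclass
class MouseClassification:
    """SNP-only / DSB-only / SNP-DSB hotspot classes on one genome.

    ``snp_dsb`` counts DSB hotspots overlapping >= 1 SNP hotspot (the class
    is defined on the DSB side); ``snp_overlapped`` counts the distinct SNP
    hotspots they land on, which can be smaller when one SNP hotspot carries
    several DSB hotspots.  Each input set is partitioned exactly:
    snp_only + snp_overlapped == |SNP| and dsb_only + snp_dsb == |DSB|.
    """

    snp_overlaps_dsb: np.ndarray
    dsb_overlaps_snp: np.ndarray

    @property
    def n_snp_only(self) -> int:
        return int((~self.snp_overlaps_dsb).sum())

    @property
    def n_dsb_only(self) -> int:
        return int((~self.dsb_overlaps_snp).sum())

    @property
    def n_snp_dsb(self) -> int:
        return int(self.dsb_overlaps_snp.sum())

    @property
    def n_snp_overlapped(self) -> int:
        return int(self.snp_overlaps_dsb.sum())

    def summary(self) -> dict[str, int]:
        return {
            "snp_only": self.n_snp_only,
            "dsb_only": self.n_dsb_only,
            "snp_dsb": self.n_snp_dsb,
            "snp_overlapped": self.n_snp_overlapped,
        }


def classify_mouse(snp_hs: IntervalSet, dsb_hs: IntervalSet) -> MouseClassification:
    """Classify same-genome hotspot sets by mutual overlap (>= 1 bp)."""
    return MouseClassification(
        snp_overlaps_dsb=overlaps_any(snp_hs, dsb_hs),
        dsb_overlaps_snp=overlaps_any(dsb_hs, snp_hs),
    )


# ---------------------------------------------------------------------------
# Overlap enrichment with control resampling
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """Observed versus expected feature/peak overlap.

    ``expected`` is the mean overlap count over ``n_controls`` control sets,
    each a length-matched resample of the feature set placed uniformly in
    the excluded-region-free genome.  ``p`` is the two-sided Fisher exact
    p-value on the observed-vs-rounded-expected 2x2 table (an approximation,
    since the expected count is an average, not a single draw);
    ``mc_p`` is the direct Monte-Carlo upper-tail p: the fraction of control
    sets with at least the observed overlap (with +1 correction).
    ``expected_genome`` is the analytic whole-genome-placement expectation
    reported for comparison.
    """

    observed: int
    expected: float
    fold: float
    p: float
    mc_p: float
    n_controls: int
    seed: int | None
    n_features: int
    expected_genome: float = float("nan")
    fold_undefined: bool = False

    def to_row(self) -> dict:
        return {
            "observed": self.observed,
            "expected": self.expected,
            "fold": self.fold,
            "fisher_p": self.p,
            "mc_p": self.mc_p,
            "n_controls": self.n_controls,
            "n_features": self.n_features,
            "expected_genome": self.expected_genome,
        }


def _expected_overlap_genomewide(
    features: IntervalSet, peaks: IntervalSet, layout: GenomeLayout
) -> float:
    """Analytic expected overlap count if each feature were placed uniformly
    on its genome (whole-genome placement, no exclusion): for a feature of
    length L, the overlapping start positions near the merged peaks are
    counted exactly, including adjacent-peak double-count and chromosome-edge
    corrections."""
    merged = peaks.merged().by_chrom()
    per_chrom = {}
    for chrom, (ps, pe, _) in merged.items():
        gaps = ps[1:] - pe[:-1]
        per_chrom[chrom] = {
            "total_len": float((pe - ps).sum()),
            "n": len(ps),
            "gaps_sorted": np.sort(gaps.astype(float)),
            "first_start": float(ps[0]),
            "last_end": float(pe[-1]),
        }
        per_chrom[chrom]["gap_cumsum"] = np.r_[0.0, np.cumsum(per_chrom[chrom]["gaps_sorted"])]
    clens = {n: layout.length_of(n) for n in layout.names}
    uniq, counts = np.unique(features.lengths, return_counts=True)
    expected = 0.0
    for L, k in zip(uniq, counts):
        L = int(L)
        hit_starts = 0.0
        total_starts = 0.0
        for chrom, clen in clens.items():
            total_starts += max(clen - L + 1, 0)
            info = per_chrom.get(chrom)
            if info is None:
                continue
            ext = L - 1
            n_int = info["n"]
            raw = info["total_len"] + n_int * ext
            # adjacent expanded intervals overlap when the gap is < ext
            g = info["gaps_sorted"]
            j = np.searchsorted(g, ext, side="left")
            over = j * ext - info["gap_cumsum"][j]
            # clip at the chromosome edges
            left_clip = max(0.0, ext - info["first_start"])
            right_clip = max(0.0, info["last_end"] - (clen - L + 1))
            hit_starts += max(raw - over - left_clip - right_clip, 0.0)
        if total_starts > 0:
            expected += k * hit_starts / total_starts
    return expected


def overlap_enrichment(
    features: IntervalSet,
    peaks: IntervalSet,
    layout: GenomeLayout,
    excluded: IntervalSet | None = None,
    n_controls: int = 1_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_bp: int = 1,
) -> EnrichmentResult:
    """Observed/expected overlap of ``features`` with ``peaks``.

    ``expected`` comes from ``n_controls`` control sets, each one a
    length-matched copy of the feature set placed uniformly over the genome
    excluding ``excluded`` (default: the features themselves, i.e. controls
    are sampled from hotspot-free sequence).
    """
    if n_controls < 100:
        raise InvalidParameterError("n_controls must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    if excluded is None:
        excluded = features
    observed = count_overlapping(features, peaks, min_bp=min_bp)
    nf = len(features)
    template = features.lengths
    lengths = np.tile(template, n_controls)
    set_id = np.repeat(np.arange(n_controls, dtype=float), nf)
    gaps = complement(layout, excluded)
    chroms, starts = place_lengths_uniform(lengths, gaps, rng)
    controls = IntervalSet.from_arrays(
        chroms, starts, starts + lengths, scores=set_id, layout=layout
    )
    flags = overlaps_any(controls, peaks, min_bp=min_bp)
    counts = np.bincount(
        controls.scores.astype(np.int64), weights=flags.astype(float), minlength=n_controls
    )
    expected = float(counts.mean())
    mc_p = float((1 + (counts >= observed).sum()) / (n_controls + 1))
    expected_genome = _expected_overlap_genomewide(features, peaks, layout)
    if expected <= 0:
        return EnrichmentResult(
            observed, expected, float("nan"), float("nan"), mc_p,
            n_controls, seed, nf, expected_genome, fold_undefined=True,
        )
    fold = observed / expected
    r_exp = int(round(expected))
    table = [[observed, nf - observed], [r_exp, nf - r_exp]]
    try:
        p = fisher_exact_2x2(table)
    except Exception:
        p = float("nan")
    return EnrichmentResult(
        observed, expected, fold, p, mc_p, n_controls, seed, nf, expected_genome
    )


# ---------------------------------------------------------------------------
# Bootstrap divergence null
# ---------------------------------------------------------------------------


@dataclass
class BootstrapNull:
    """Bootstrap null for a mean difference: ``draws`` are B bootstrap means
    of control differences at the hotspot sample size; ``empirical_p`` is the
    two-sided tail fraction |draw| >= |observed| with +1 correction."""

    draws: np.ndarray
    observed: float
    empirical_p: float
    B: int
    seed: int | None

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "empirical_p": self.empirical_p,
            "B": self.B,
            "null_mean": float(np.mean(self.draws)),
            "null_sd": float(np.std(self.draws, ddof=1)),
        }


def methylation_divergence_null(
    diffs_hotspots,
    diffs_controls,
    B: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapNull:
    """Is the mean interspecies methylation difference at hotspots compatible
    with the control-region distribution?

    Draws B bootstrap samples (size = number of hotspot differences, with
    replacement) from the control differences, records their means, and
    reports the two-sided empirical p-value of the observed hotspot mean.
    NaN differences (regions undefined on either side) are dropped first.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    dh = np.asarray(diffs_hotspots, dtype=float)
    dc = np.asarray(diffs_controls, dtype=float)
    dh = dh[np.isfinite(dh)]
    dc = dc[np.isfinite(dc)]
    if len(dh) == 0 or len(dc) == 0:
        raise InvalidParameterError("empty difference vector after dropping undefined values")
    if B < 1_000:
        warnings.warn(f"B={B} bootstrap draws is low; >= 1000 recommended")
    n = len(dh)
    observed = float(dh.mean())
    draws = np.empty(B)
    chunk = max(1, int(2e7 // max(n, 1)))
    for lo in range(0, B, chunk):
        hi = min(B, lo + chunk)
        idx = rng.integers(0, len(dc), size=(hi - lo, n))
        draws[lo:hi] = dc[idx].mean(axis=1)
    p = float((1 + (np.abs(draws) >= abs(observed)).sum()) / (B + 1))
    return BootstrapNull(draws=draws, observed=observed, empirical_p=p, B=B, seed=seed)


# ---------------------------------------------------------------------------
# Distance profiles and grouped comparisons
# ---------------------------------------------------------------------------


DEFAULT_DISTANCE_BINS = list(range(0, 100_001, 5_000))


def recombination_distance_profile(
    rec_map: IntervalSet,
    peaks: IntervalSet,
    bin_edges: list[int] | None = None,
) -> pd.DataFrame:
    """Mean recombination rate as a function of distance to the nearest peak.

    Each map segment is assigned to a distance bin by its midpoint; the
    per-bin rate is the bp-weighted mean over assigned segments.  Bins are
    ``[e0,e1), [e1,e2), ...`` plus a final open-ended bin; segments on
    chromosomes without peaks are excluded.
    """
    if rec_map.scores is None:
        raise InvalidParameterError("rate track has no scores")
    edges = DEFAULT_DISTANCE_BINS if bin_edges is None else list(bin_edges)
    if edges[0] != 0 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise InvalidParameterError("bin edges must be strictly increasing and start at 0")
    mid = (rec_map.starts + rec_map.ends) // 2
    seg_len_all = (rec_map.ends - rec_map.starts).astype(float)
    # carry segment lengths through the point set's normalization via ids
    mids = IntervalSet.from_arrays(
        rec_map.chroms, mid, mid + 1,
        ids=np.array([float(x) for x in seg_len_all], dtype=object),
        scores=rec_map.scores,
        layout=rec_map.layout,
    )
    dist = distance_to_nearest(mids, peaks)
    ok = np.isfinite(dist)
    bins = np.searchsorted(edges, dist[ok], side="right") - 1
    seg_len = mids.ids[ok].astype(float)
    rate = mids.scores[ok]
    nb = len(edges)
    wsum = np.bincount(bins, weights=rate * seg_len, minlength=nb)
    wlen = np.bincount(bins, weights=seg_len, minlength=nb)
    cnt = np.bincount(bins, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_rate = wsum / wlen
    lo = np.array(edges, dtype=float)
    hi = np.r_[np.array(edges[1:], dtype=float), np.inf]
    return pd.DataFrame(
        {
            "bin_lo": lo,
            "bin_hi": hi,
            "mean_rate": mean_rate,
            "n_segments": cnt,
            "bp": wlen,
        }
    )


@dataclass
class GroupComparison:
    """Group means with 95% normal-approximation confidence intervals plus an
    overall test (one-way ANOVA) or all pairwise Welch t tests."""

    groups: list[str]
    means: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n: dict[str, int]
    test: str
    statistic: float
    p: float
    pairwise: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "mean": [self.means[g] for g in self.groups],
                "ci_low": [self.ci_low[g] for g in self.groups],
                "ci_high": [self.ci_high[g] for g in self.groups],
                "n": [self.n[g] for g in self.groups],
            }
        )


def group_feature_comparison(values_by_group: dict, test: str = "anova") -> GroupComparison:
    """Compare a per-region feature (methylation, rate, ...) across named
    region groups; NaN values are dropped per group."""
    if len(values_by_group) < 2:
        raise InvalidParameterError("need at least 2 groups")
    if test not in ("anova", "t"):
        raise InvalidParameterError("test must be 'anova' or 't'")
    clean = {}
    for name, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        clean[str(name)] = v[np.isfinite(v)]
    names = list(clean)
    means, lo, hi, ns = {}, {}, {}, {}
    for g, v in clean.items():
        m = float(v.mean()) if len(v) else float("nan")
        se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        means[g] = m
        lo[g] = m - 1.96 * se
        hi[g] = m + 1.96 * se
        ns[g] = int(len(v))
    pairwise = {}
    if test == "anova":
        stat, p = one_way_anova([clean[g] for g in names])
    else:
        stat, p = float("nan"), float("nan")
        for i, gi in enumerate(names):
            for gj in names[i + 1 :]:
                pairwise[(gi, gj)] = two_sample_t(clean[gi], clean[gj])
        if len(names) == 2:
            stat, p = pairwise[(names[0], names[1])]
    return GroupComparison(
        groups=names, means=means, ci_low=lo, ci_high=hi, n=ns,
        test=test, statistic=stat, p=p, pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------


def default_config() -> dict:
    """The default self-contained synthetic study: a small two-chromosome
    genome with planted window correlation, cross-species hotspot structure
    and peak enrichment, sized to run in seconds."""
    return {
        "seed": 0,
        "generator": {
            "n_chrom": 2,
            "chrom_length": 10_000_000,
            "window_size": 250_000,
            "window_corr": 0.3,
            "hotspot_counts": [400, 250, 40],
            "hotspot_length_range": [1_000, 3_000],
            "peak_fold": 3.0,
            "peak_fold_k27": 2.0,
            "peak_length": 1_000,
            "n_peaks": 1_000,
            "read_depth": 30,
            "site_spacing": 5_000,
            "indel_rate": 1e-5,
            "indel_size": [1, 50],
            "gc": 0.42,
            "m_mean": 0.7,
            "m_sd": 0.08,
            "rate_mean": 1.0,
            "rate_cv": 0.35,
            "hotspot_multiplier": 10.0,
        },
        "analysis": {
            "min_sites": 5,
            "n_controls": 200,
            "bootstrap_B": 2_000,
            "distance_bins": DEFAULT_DISTANCE_BINS,
            "stepwise_alpha": 0.05,
        },
    }


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_full_analysis(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "epirecomb_run",
    seed: int | None = None,
) -> dict:
    """Run the whole pipeline on synthetic inputs (or configured files) and
    write per-stage TSV tables plus a reproducibility manifest.

    Stages: ``simulate`` (build all inputs), ``windows`` (feature table,
    correlations, Box-Cox + backward-stepwise regression), ``hotspots``
    (classification, enrichment incl. bivalent regions, divergence null,
    distance profile, grouped comparisons).  A fixed seed makes the output
    tables byte-identical across runs.  Returns a dict of output paths.
    """
    from . import io as eio
    from . import simulate as sim
    from .stats import backward_stepwise, boxcox, pearson

    if config is None:
        config = default_config()
    elif isinstance(config, (str, Path)):
        config = eio.read_config(config)
    cfg = json.loads(json.dumps(config))  # deep copy, JSON-typed
    base = default_config()
    for section in ("generator", "analysis"):
        merged = dict(base[section])
        merged.update(cfg.get(section, {}))
        cfg[section] = merged
    if seed is None:
        seed = int(cfg.get("seed", 0))
    cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rng = np.random.default_rng(seed)
    g = cfg["generator"]
    a = cfg["analysis"]

    if "inputs" in cfg:
        return _run_from_inputs(cfg, out, seed)

    # ---- stage: simulate --------------------------------------------------
    try:
        logger.info("stage simulate: building synthetic inputs (seed=%d)", seed)
        layout_a, seqs_a = sim.make_genome(
            g["n_chrom"], g["chrom_length"], gc=g["gc"], rng=rng, with_sequence=True
        )
        map_ab, map_ba, layout_b = sim.make_synteny_map(
            layout_a, indel_rate=g["indel_rate"], indel_size=tuple(g["indel_size"]), rng=rng
        )
        hs_a, hs_b = sim.make_paired_hotspots(
            layout_a, layout_b, map_ab, map_ba,
            tuple(g["hotspot_counts"]), tuple(g["hotspot_length_range"]), rng=rng,
        )
        ws = int(g["window_size"])
        from .intervals import tile_windows

        windows_a = tile_windows(layout_a, ws)
        att = sim.planted_correlation_attenuation(
            g["m_mean"], g["m_sd"], g["read_depth"], ws / g["site_spacing"]
        )
        z1, z2 = sim.make_window_fields(len(windows_a), g["window_corr"] / att, rng)
        window_m = np.clip(g["m_mean"] + g["m_sd"] * z1, 0.01, 0.99)
        window_r = np.maximum(0.05 * g["rate_mean"], g["rate_mean"] * (1 + g["rate_cv"] * z2))
        rec_map = sim.make_recombination_map(
            layout_a, ws, window_rates=window_r,
            hotspots=hs_a, hotspot_multiplier=g["hotspot_multiplier"],
        )
        meth_a = sim.make_methylome(
            layout_a, ws, window_m, site_spacing=g["site_spacing"],
            depth=g["read_depth"], rng=rng,
        )
        # partner methylome: same regional levels transferred through synteny
        # (no planted divergence), independent read noise
        windows_b = tile_windows(layout_b, ws)
        m_b = np.full(len(windows_b), g["m_mean"])
        meth_b = sim.make_methylome(
            layout_b, ws, m_b, site_spacing=g["site_spacing"], depth=g["read_depth"], rng=rng
        )
        # a second methylome for genome A drawn around the same mean, so
        # control differences have comparable spread
        repeats = sim._place_disjoint(
            rng.integers(500, 5_001, size=max(4, int(layout_a.total_bp // 100_000))),
            layout_a, rng,
        )
        peaks_k4 = sim.make_peaks(
            layout_a, hs_a, fold=g["peak_fold"], peak_length=g["peak_length"],
            n_peaks=g["n_peaks"], rng=rng,
        )
        peaks_k27 = sim.make_peaks(
            layout_a, hs_a, fold=g["peak_fold_k27"], peak_length=g["peak_length"],
            n_peaks=g["n_peaks"], rng=rng,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    # ---- stage: windows ---------------------------------------------------
    try:
        logger.info("stage windows: feature table, correlations, regression")
        from .tracks import build_window_table

        table = build_window_table(
            layout_a, ws, rec_map, meth_a, seq_source=seqs_a, repeats=repeats,
            min_sites=a["min_sites"],
        )
        paths["window_table"] = out / "window_table.tsv"
        _write_tsv(table, paths["window_table"])

        used = table.dropna(subset=["recombination_rate", "methylation"])
        corr_rows = []
        r_raw = pearson(used["methylation"], used["recombination_rate"])
        corr_rows.append({"variables": "methylation~rate", "transform": "raw",
                          "r": r_raw.r, "p": r_raw.p, "n": r_raw.n})
        rate_bc, spec = boxcox(used["recombination_rate"].to_numpy())
        r_bc = pearson(used["methylation"], rate_bc)
        corr_rows.append({"variables": "methylation~rate", "transform": f"boxcox(lambda={spec.lmbda:g})",
                          "r": r_bc.r, "p": r_bc.p, "n": r_bc.n})
        paths["window_correlations"] = out / "window_correlations.tsv"
        _write_tsv(pd.DataFrame(corr_rows), paths["window_correlations"])

        predictors = used[["gc", "repeat_fraction", "methylation", "cpg_count"]]
        reg = backward_stepwise(rate_bc, predictors, alpha=a["stepwise_alpha"])
        reg_df = reg.to_frame()
        reg_df["adjusted_r2"] = reg.adjusted_r2
        reg_df["n"] = reg.nobs
        paths["window_regression"] = out / "window_regression.tsv"
        _write_tsv(reg_df, paths["window_regression"])
    except StageError:
        raise
    except Exception as exc:
        raise StageError("windows", str(exc)) from exc

    # ---- stage: hotspots --------------------------------------------------
    try:
        logger.info("stage hotspots: classification, enrichment, nulls")
        cls = classify_cross_species(hs_a, hs_b, map_ab, map_ba)
        cls_df = pd.DataFrame(sorted(cls.summary().items()), columns=["class", "count"])
        paths["classification"] = out / "classification_counts.tsv"
        _write_tsv(cls_df, paths["classification"])

        child = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
        bivalent = intersect(peaks_k4, peaks_k27)
        enr_rows = []
        for name, pk in (("H3K4me3", peaks_k4), ("H3K27me3", peaks_k27), ("bivalent", bivalent)):
            res = overlap_enrichment(
                hs_a, pk, layout_a, n_controls=a["n_controls"], seed=child()
            )
            row = {"peaks": name}
            row.update(res.to_row())
            enr_rows.append(row)
        paths["enrichment"] = out / "enrichment.tsv"
        _write_tsv(pd.DataFrame(enr_rows), paths["enrichment"])

        spec_a_mask = (cls.labels_a == "species_specific") & ~cls.unmappable_a
        spec_set_a = hs_a.subset(np.flatnonzero(spec_a_mask))
        proj_ok = cls.proj_a
        sel = np.flatnonzero(spec_a_mask & proj_ok.ok)
        regions_a = hs_a.subset(sel)
        regions_b = IntervalSet.from_arrays(
            proj_ok.chrom[sel], proj_ok.start[sel], proj_ok.end[sel], layout=layout_b
        )
        from .tracks import methylation_difference

        diffs_hot = methylation_difference(meth_a, meth_b, regions_a, regions_b, min_sites=1)
        ctl = sim._place_disjoint(
            rng.permutation(regions_a.lengths), layout_a, rng,
            forbidden=concat_sets([hs_a], layout=layout_a).merged(),
        )
        proj_ctl = project_intervals(ctl, map_ab, min_fraction=map_ab.min_mapped_fraction)
        keep = np.flatnonzero(proj_ctl.ok)
        ctl_a = ctl.subset(keep)
        ctl_b = IntervalSet.from_arrays(
            proj_ctl.chrom[keep], proj_ctl.start[keep], proj_ctl.end[keep], layout=layout_b
        )
        diffs_ctl = methylation_difference(meth_a, meth_b, ctl_a, ctl_b, min_sites=1)
        null = methylation_divergence_null(diffs_hot, diffs_ctl, B=a["bootstrap_B"], seed=child())
        null_df = pd.DataFrame([null.summary()])
        paths["divergence_null"] = out / "divergence_null.tsv"
        _write_tsv(null_df, paths["divergence_null"])

        prof = recombination_distance_profile(rec_map, peaks_k4, bin_edges=a["distance_bins"])
        paths["distance_profile"] = out / "distance_profile.tsv"
        _write_tsv(prof, paths["distance_profile"])

        common_set_a = hs_a.subset(np.flatnonzero(cls.labels_a == "common"))
        groups = {
            "species_specific": regional_methylation_many(meth_a, spec_set_a, min_sites=1)[0],
            "common": regional_methylation_many(meth_a, common_set_a, min_sites=1)[0],
            "syntenic_of_partner_specific": regional_methylation_many(
                meth_a, cls.syntenic_a_of_b_specific, min_sites=1
            )[0] if len(cls.syntenic_a_of_b_specific) else np.array([np.nan]),
            "control": regional_methylation_many(meth_a, ctl_a, min_sites=1)[0],
        }
        groups = {k: v for k, v in groups.items() if np.isfinite(v).sum() >= 2}
        cmp_res = group_feature_comparison(groups, test="anova")
        cmp_df = cmp_res.to_frame()
        cmp_df["anova_F"] = cmp_res.statistic
        cmp_df["anova_p"] = cmp_res.p
        paths["group_comparison"] = out / "group_methylation.tsv"
        _write_tsv(cmp_df, paths["group_comparison"])
    except StageError:
        raise
    except Exception as exc:
        raise StageError("hotspots", str(exc)) from exc

    manifest = eio.build_manifest(cfg, {k: str(v) for k, v in paths.items()})
    paths["manifest"] = out / "manifest.json"
    eio.write_manifest(manifest, paths["manifest"])
    logger.info("run complete: %d output tables in %s", len(paths) - 1, out)
    return {k: str(v) for k, v in paths.items()}


def _run_from_inputs(cfg: dict, out: Path, seed: int) -> dict:
    """File-driven run: window-scale stage from user-supplied tracks, plus
    the hotspot stage when hotspot/synteny/peak files are configured."""
    from . import io as eio
    from .stats import backward_stepwise, boxcox, pearson
    from .tracks import build_window_table

    inputs = cfg["inputs"]
    a = cfg["analysis"]
    paths: dict[str, Path] = {}
    rng = np.random.default_rng(seed)

    def need(key: str, stage: str) -> str:
        if key not in inputs:
            raise StageError(stage, f"missing input {key!r} in config")
        return inputs[key]

    try:
        layout = eio.read_chrom_sizes(need("chrom_sizes", "windows"))
        rec_map = eio.read_bedgraph(need("rec_map", "windows"), layout=layout)
        meth = eio.read_cytosine_report(need("cytosine_report", "windows"))
        ws = int(cfg.get("generator", {}).get("window_size", 500_000))
        table = build_window_table(layout, ws, rec_map, meth, min_sites=a["min_sites"])
        paths["window_table"] = out / "window_table.tsv"
        _write_tsv(table, paths["window_table"])
        used = table.dropna(subset=["recombination_rate", "methylation"])
        rate_bc, spec = boxcox(used["recombination_rate"].to_numpy())
        r = pearson(used["methylation"], rate_bc)
        _write_tsv(
            pd.DataFrame(
                [{"variables": "methylation~rate",
                  "transform": f"boxcox(lambda={spec.lmbda:g})",
                  "r": r.r, "p": r.p, "n": r.n}]
            ),
            out / "window_correlations.tsv",
        )
        paths["window_correlations"] = out / "window_correlations.tsv"
        pred_cols = [c for c in ("gc", "repeat_fraction", "methylation", "cpg_count") if c in used]
        if len(pred_cols) >= 1 and len(used) > len(pred_cols) + 2:
            reg = backward_stepwise(rate_bc, used[pred_cols], alpha=a["stepwise_alpha"])
            reg_df = reg.to_frame()
            reg_df["adjusted_r2"] = reg.adjusted_r2
            reg_df["n"] = reg.nobs
            paths["window_regression"] = out / "window_regression.tsv"
            _write_tsv(reg_df, paths["window_regression"])
    except StageError:
        raise
    except Exception as exc:
        raise StageError("windows", str(exc)) from exc

    if "hotspots_a" in inputs:
        try:
            hs_a = eio.read_bed(need("hotspots_a", "hotspots"), layout=layout)
            if "peaks" in inputs:
                pk = eio.read_bed(inputs["peaks"], layout=layout)
                res = overlap_enrichment(
                    hs_a, pk, layout, n_controls=a["n_controls"],
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                paths["enrichment"] = out / "enrichment.tsv"
                _write_tsv(pd.DataFrame([res.to_row()]), paths["enrichment"])
            if "hotspots_b" in inputs and "synteny_ab" in inputs and "synteny_ba" in inputs:
                map_ab = eio.read_synteny(inputs["synteny_ab"], src_layout=layout)
                map_ba = eio.read_synteny(inputs["synteny_ba"], dst_layout=layout)
                hs_b = eio.read_bed(inputs["hotspots_b"], layout=map_ab.dst_layout)
                cls = classify_cross_species(hs_a, hs_b, map_ab, map_ba)
                cls_df = pd.DataFrame(sorted(cls.summary().items()), columns=["class", "count"])
                paths["classification"] = out / "classification_counts.tsv"
                _write_tsv(cls_df, paths["classification"])
        except StageError:
            raise
        except Exception as exc:
            raise StageError("hotspots", str(exc)) from exc

    manifest = eio.build_manifest(cfg, {k: str(v) for k, v in paths.items()})
    paths["manifest"] = out / "manifest.json"
    eio.write_manifest(manifest, paths["manifest"])
    return {k: str(v) for k, v in paths.items()}
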