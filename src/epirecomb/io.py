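"""Readers and writers for the plain-text genomics formats the pipeline touches.

BED3/BED6 and bedGraph intervals are 0-based half-open on disk and in
memory.  Cytosine reports follow the Bismark-style dialect — tab-separated
``chrom, 1-based position, strand, count_methylated, count_unmethylated,
context`` — and are converted to 0-based on ingestion, keeping CpG-context
rows only.  Synteny maps are 7-column TSV (src_chrom, src_start, src_end,
dst_chrom, dst_start, dst_end, strand).  Run manifests are JSON with the
configuration, seeds and SHA-256 digests of every output table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ValidationError
from .intervals import GenomeLayout, IntervalSet, SyntenyMap
from .tracks import MethylationTrack

logger = logging.getLogger("epirecomb")

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_synteny",
    "write_synteny",
    "read_fasta",
    "write_fasta",
    "read_config",
    "build_manifest",
    "write_manifest",
    "sha256_of",
]


def read_chrom_sizes(path) -> GenomeLayout:
    """Two-column ``name<TAB>length`` file -> layout (order preserved)."""
    chroms = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError("expected 'name<TAB>length'", path, ln)
            try:
                chroms.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise ValidationError(f"bad chromosome length {parts[1]!r}", path, ln) from exc
    return GenomeLayout(chroms)


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


def _skippable(line: str) -> bool:
    return (
        not line.strip()
        or line.startswith("#")
        or line.startswith("track")
        or line.startswith("browser")
    )


def read_bed(path, layout: GenomeLayout | None = None) -> IntervalSet:
    """BED3-BED6 reader (extra columns ignored; column 4 = name, 5 = score)."""
    chroms, starts, ends, ids, scores = [], [], [], [], []
    any_id = any_score = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if _skippable(line):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError("fewer than 3 columns", path, ln)
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError("non-integer coordinates", path, ln) from exc
            if not (0 <= s < e):
                raise ValidationError(f"invalid interval {parts[0]}:{s}-{e}", path, ln)
            chroms.append(parts[0])
            starts.append(s)
            ends.append(e)
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            ids.append(name)
            any_id = any_id or name is not None
            sc = None
            if len(parts) > 4 and parts[4] != ".":
                try:
                    sc = float(parts[4])
                except ValueError as exc:
                    raise ValidationError(f"non-numeric score {parts[4]!r}", path, ln) from exc
            scores.append(np.nan if sc is None else sc)
            any_score = any_score or sc is not None
    try:
        return IntervalSet.from_arrays(
            np.array(chroms, dtype=object),
            np.array(starts, dtype=np.int64),
            np.array(ends, dtype=np.int64),
            ids=np.array(ids, dtype=object) if any_id else None,
            scores=np.array(scores, dtype=float) if any_score else None,
            layout=layout,
        )
    except Exception as exc:
        raise ValidationError(str(exc), path) from exc


def write_bed(iset: IntervalSet, path) -> None:
    """BED3 plus name/score columns when present."""
    with open(path, "w") as fh:
        for i in range(len(iset)):
            cols = [str(iset.chroms[i]), str(int(iset.starts[i])), str(int(iset.ends[i]))]
            if iset.ids is not None or iset.scores is not None:
                cols.append("." if iset.ids is None or iset.ids[i] is None else str(iset.ids[i]))
            if iset.scores is not None:
                cols.append(f"{iset.scores[i]:.10g}")
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path, layout: GenomeLayout | None = None) -> IntervalSet:
    """4-column bedGraph -> scored segment set; overlapping segments are an
    error (the track must be piecewise-constant); empty input warns."""
    chroms, starts, ends, scores = [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if _skippable(line):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError("bedGraph needs 4 columns", path, ln)
            try:
                s, e = int(parts[1]), int(parts[2])
                v = float(parts[3])
            except ValueError as exc:
                raise ValidationError("non-numeric bedGraph row", path, ln) from exc
            if not (0 <= s < e):
                raise ValidationError(f"invalid interval {parts[0]}:{s}-{e}", path, ln)
            chroms.append(parts[0])
            starts.append(s)
            ends.append(e)
            scores.append(v)
    if not chroms:
        logger.warning("empty bedGraph %s", path)
    iset = IntervalSet.from_arrays(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        scores=np.array(scores, dtype=float),
        layout=layout,
    )
    for chrom, (s, e, _) in iset.by_chrom().items():
        if len(s) > 1 and np.any(s[1:] < e[:-1]):
            raise ValidationError(f"overlapping segments on {chrom}", path)
    return iset


def write_bedgraph(iset: IntervalSet, path) -> None:
    if iset.scores is None:
        raise ValidationError("interval set has no scores to write as bedGraph")
    with open(path, "w") as fh:
        for i in range(len(iset)):
            fh.write(
                f"{iset.chroms[i]}\t{int(iset.starts[i])}\t{int(iset.ends[i])}\t"
                f"{iset.scores[i]:.10g}\n"
            )


def read_cytosine_report(
    path, min_depth: int = 1, merge_strands: bool = False
) -> MethylationTrack:
    """Bismark-style cytosine report -> methylation track.

    Columns: chrom, 1-based position, strand, count_methylated,
    count_unmethylated, context.  Non-CpG rows (CHG/CHH/...) are dropped and
    counted; with ``merge_strands`` the minus-strand call of a CpG (position
    p+1, strand '-') is pooled into the plus-strand site at p.
    """
    chroms, pos, cm, cu = [], [], [], []
    strands = []
    dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if _skippable(line):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValidationError("cytosine report needs 6 columns", path, ln)
            ctx = parts[5].upper()
            if ctx not in ("CG", "CPG"):
                dropped += 1
                continue
            try:
                p = int(parts[1]) - 1
                c = int(parts[3])
                t = int(parts[4])
            except ValueError as exc:
                raise ValidationError("non-integer cytosine-report row", path, ln) from exc
            if c < 0 or t < 0:
                raise ValidationError("negative read counts", path, ln)
            if p < 0:
                raise ValidationError("position must be >= 1 (1-based)", path, ln)
            chroms.append(parts[0])
            pos.append(p)
            cm.append(c)
            cu.append(t)
            strands.append(parts[2])
    if dropped:
        logger.info("read_cytosine_report: dropped %d non-CpG rows from %s", dropped, path)
    chroms = np.array(chroms, dtype=object)
    pos = np.array(pos, dtype=np.int64)
    cm = np.array(cm, dtype=np.int64)
    cu = np.array(cu, dtype=np.int64)
    strands = np.array(strands, dtype=object)
    if merge_strands:
        # map minus-strand G of the CpG (at p) onto the plus-strand C (p-1)
        pos = np.where(strands == "-", pos - 1, pos)
        key = np.char.add(np.char.add(chroms.astype(str), ":"), pos.astype(str))
        uniq, inv = np.unique(key, return_inverse=True)
        cm = np.bincount(inv, weights=cm).astype(np.int64)
        cu = np.bincount(inv, weights=cu).astype(np.int64)
        first = np.full(len(uniq), -1, dtype=np.int64)
        seen_at = {}
        for i, k in enumerate(inv):
            if k not in seen_at:
                seen_at[k] = i
        order = np.array([seen_at[k] for k in range(len(uniq))])
        chroms = chroms[order]
        pos = pos[order]
    track = MethylationTrack.from_arrays(chroms, pos, cm, cu, min_depth=min_depth)
    track.dropped_non_cpg = dropped
    return track


def write_cytosine_report(track: MethylationTrack, path) -> None:
    """Write a track back out in the 6-column dialect (plus strand, CG context)."""
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            p, c, t = track.arrays(chrom)
            for i in range(len(p)):
                fh.write(f"{chrom}\t{p[i] + 1}\t+\t{c[i]}\t{t[i]}\tCG\n")


def read_synteny(
    path,
    src_layout: GenomeLayout | None = None,
    dst_layout: GenomeLayout | None = None,
    min_mapped_fraction: float = 0.95,
) -> SyntenyMap:
    """7-column synteny TSV -> :class:`SyntenyMap`."""
    blocks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if _skippable(line):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValidationError("synteny map needs 7 columns", path, ln)
            try:
                blocks.append(
                    (
                        parts[0], int(parts[1]), int(parts[2]),
                        parts[3], int(parts[4]), int(parts[5]), parts[6],
                    )
                )
            except ValueError as exc:
                raise ValidationError("non-integer synteny coordinates", path, ln) from exc
    try:
        return SyntenyMap(
            blocks, src_layout=src_layout, dst_layout=dst_layout,
            min_mapped_fraction=min_mapped_fraction,
        )
    except Exception as exc:
        raise ValidationError(str(exc), path) from exc


def write_synteny(smap: SyntenyMap, path) -> None:
    with open(path, "w") as fh:
        for i in range(len(smap)):
            fh.write(
                f"{smap.src_chrom[i]}\t{int(smap.src_start[i])}\t{int(smap.src_end[i])}\t"
                f"{smap.dst_chrom[i]}\t{int(smap.dst_start[i])}\t{int(smap.dst_end[i])}\t"
                f"{smap.strand[i]}\n"
            )


def read_fasta(path):
    """FASTA access through pyfaidx (sequences fetched lazily by region)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_config(path) -> dict:
    """YAML (or JSON, a YAML subset) key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping", path)
    return cfg


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(config: dict, outputs: dict[str, str]) -> dict:
    """Reproducibility manifest: version, config (with seeds) and per-output
    SHA-256 digests; no volatile fields, so reruns reproduce it bit-for-bit."""
    cfg_json = json.dumps(config, sort_keys=True)
    return {
        "tool": "epirecomb",
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "outputs": {
            name: {"path": p, "sha256": sha256_of(p)} for name, p in sorted(outputs.items())
        },
    }


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
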