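"""Read 5'-end count tracks: SAM/BAM ingestion, bedGraph I/O, replicate pooling.

A dRNA-seq library is reduced to a strand-specific sparse map of read 5'-end
("read start") counts per genomic position.  For a forward-strand alignment the
5' end is the leftmost aligned reference base; for a reverse-strand alignment it
is the rightmost aligned base.  Soft-clipped bases do not shift the counted
coordinate.  Positions are 1-based inclusive throughout; bedGraph files use the
format's native 0-based half-open intervals and are converted on the fly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

logger = logging.getLogger(__name__)

TEX_PLUS = "TEX_PLUS"
TEX_MINUS = "TEX_MINUS"
TREATMENTS = (TEX_PLUS, TEX_MINUS)

STRANDS = ("+", "-")


@dataclass
class LibraryMeta:
    """Identity and bookkeeping for one sequencing library (or pooled set)."""

    library_id: str
    treatment: str
    condition: str = ""
    replicate: int = 1
    total_readstarts: int = 0

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )


@dataclass
class ReadStartTrack:
    """Sparse per-position counts of read 5' ends, per replicon and strand.

    ``counts[replicon][strand]`` maps 1-based position -> count.  Zero counts
    are implicit (never stored).  ``lengths`` records replicon lengths where
    known (None = unknown; bounds checks are then relaxed).
    """

    meta: LibraryMeta
    counts: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)
    lengths: dict[str, int | None] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------
    def add(self, replicon: str, strand: str, position: int, count: float = 1) -> None:
        if strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        if position < 1:
            raise ValueError(f"positions are 1-based; got {position}")
        if count < 0:
            raise ValueError(f"negative count {count} at {replicon}:{position}")
        if count == 0:
            return
        strands = self.counts.setdefault(replicon, {"+": {}, "-": {}})
        strands[strand][position] = strands[strand].get(position, 0) + count

    def get(self, replicon: str, strand: str, position: int) -> float:
        return self.counts.get(replicon, {}).get(strand, {}).get(position, 0)

    # -- views ----------------------------------------------------------------
    def replicons(self) -> list[str]:
        return sorted(set(self.counts) | set(self.lengths))

    def positions(self, replicon: str, strand: str) -> list[int]:
        return sorted(self.counts.get(replicon, {}).get(strand, {}))

    def total(self) -> float:
        return sum(
            c
            for strands in self.counts.values()
            for sparse in strands.values()
            for c in sparse.values()
        )

    def sync_total(self) -> None:
        """Recompute ``meta.total_readstarts`` from the stored counts."""
        t = self.total()
        self.meta.total_readstarts = int(t) if float(t).is_integer() else t

    def max_position(self, replicon: str) -> int:
        strands = self.counts.get(replicon, {})
        mx = 0
        for sparse in strands.values():
            if sparse:
                mx = max(mx, max(sparse))
        return mx

    def scaled(self, factor: float, library_id: str | None = None) -> "ReadStartTrack":
        """Return a copy with every count multiplied by ``factor``."""
        meta = LibraryMeta(
            library_id=library_id or f"{self.meta.library_id}_scaled",
            treatment=self.meta.treatment,
            condition=self.meta.condition,
            replicate=self.meta.replicate,
        )
        out = ReadStartTrack(meta=meta, lengths=dict(self.lengths))
        for replicon, strands in self.counts.items():
            for strand, sparse in strands.items():
                for pos, c in sparse.items():
                    out.add(replicon, strand, pos, c * factor)
        out.meta.total_readstarts = self.meta.total_readstarts * factor
        return out


@dataclass
class CoverageTrack:
    """Per-position sequencing depth (read coverage), possibly unstranded.

    Strand key "." holds unstranded coverage.  Values are non-negative reals.
    """

    counts: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)
    lengths: dict[str, int | None] = field(default_factory=dict)

    def add(self, replicon: str, strand: str, position: int, depth: float) -> None:
        if depth < 0:
            raise ValueError(f"negative depth {depth} at {replicon}:{position}")
        if depth == 0:
            return
        strands = self.counts.setdefault(replicon, {})
        sparse = strands.setdefault(strand, {})
        sparse[position] = sparse.get(position, 0.0) + depth

    def get(self, replicon: str, strand: str, position: int) -> float:
        return self.counts.get(replicon, {}).get(strand, {}).get(position, 0.0)

    def replicons(self) -> list[str]:
        return sorted(set(self.counts) | set(self.lengths))


# ---------------------------------------------------------------------------
# SAM/BAM ingestion
# ---------------------------------------------------------------------------

def count_read_starts(
    alignment_path: str | Path,
    *,
    meta: LibraryMeta | None = None,
    r1_only: bool = False,
    min_mapq: int = 0,
    keep_secondary: bool = False,
) -> ReadStartTrack:
    """Count read 5' ends from a SAM/BAM file.

    Unmapped records are always skipped; secondary and supplementary records
    are skipped unless ``keep_secondary``.  With ``r1_only``, second-in-pair
    records are skipped as well (the dRNA-seq 5' end lives on R1).  Reads with
    mapping quality below ``min_mapq`` are dropped.
    """
    alignment_path = str(alignment_path)
    if meta is None:
        meta = LibraryMeta(library_id=Path(alignment_path).stem, treatment=TEX_MINUS)
    track = ReadStartTrack(meta=meta)
    with pysam.AlignmentFile(alignment_path, check_sq=False) as af:
        if af.header.get("SQ"):
            for sq in af.header["SQ"]:
                track.lengths[sq["SN"]] = sq.get("LN")
        else:
            logger.warning(
                "%s: no sequence dictionary; replicon lengths unknown, bounds checks relaxed",
                alignment_path,
            )
        for rec in af:
            if rec.is_unmapped:
                continue
            if not keep_secondary and (rec.is_secondary or rec.is_supplementary):
                continue
            if r1_only and rec.is_paired and rec.is_read2:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.is_reverse:
                # rightmost aligned reference base = biological 5' end on '-'
                track.add(rec.reference_name, "-", rec.reference_end)  # reference_end is 0-based excl == 1-based incl
            else:
                track.add(rec.reference_name, "+", rec.reference_start + 1)
    track.sync_total()
    return track


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def _parse_bedgraph(path: str | Path) -> tuple[dict[str, dict[int, float]], int]:
    """Parse one bedGraph file into replicon -> {1-based position: value}.

    Validates non-negative values and non-overlapping intervals; an overlap
    error names the first offending line.
    """
    sparse: dict[str, dict[int, float]] = {}
    seen: dict[str, list[tuple[int, int, int]]] = {}
    n_values = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}")
            chrom, start_s, end_s, value_s = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
                value = float(value_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line: {line!r}") from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval [{start},{end})")
            seen.setdefault(chrom, []).append((start, end, lineno))
            if value == 0:
                continue
            chrom_map = sparse.setdefault(chrom, {})
            for pos0 in range(start, end):
                chrom_map[pos0 + 1] = value  # 0-based half-open -> 1-based
                n_values += 1
    for chrom, ivals in seen.items():
        ivals.sort()
        for (s1, e1, _l1), (s2, _e2, l2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{path}: overlapping intervals on {chrom}; first offending line {l2}"
                )
    return sparse, n_values


def read_bedgraph_pair(
    plus_path: str | Path,
    minus_path: str | Path,
    *,
    meta: LibraryMeta | None = None,
    lengths: dict[str, int | None] | None = None,
) -> ReadStartTrack:
    """Load a strand pair of bedGraph files into one ReadStartTrack."""
    if meta is None:
        meta = LibraryMeta(library_id=Path(plus_path).stem, treatment=TEX_MINUS)
    track = ReadStartTrack(meta=meta, lengths=dict(lengths or {}))
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        sparse, _ = _parse_bedgraph(path)
        for chrom, posmap in sparse.items():
            for pos, value in posmap.items():
                track.add(chrom, strand, pos, value)
    track.sync_total()
    return track


def _format_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _write_bedgraph(sparse_by_replicon: dict[str, dict[int, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tvalue\n")
        for chrom in sorted(sparse_by_replicon):
            posmap = sparse_by_replicon[chrom]
            run_start = run_end = None
            run_val = None
            for pos in sorted(posmap):
                val = posmap[pos]
                if run_start is not None and pos == run_end + 1 and val == run_val:
                    run_end = pos
                    continue
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start - 1}\t{run_end}\t{_format_value(run_val)}\n")
                run_start = run_end = pos
                run_val = val
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start - 1}\t{run_end}\t{_format_value(run_val)}\n")


def write_bedgraph_pair(track: ReadStartTrack, plus_path: str | Path, minus_path: str | Path) -> None:
    """Write one bedGraph file per strand, merging equal-valued adjacent runs."""
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        by_rep = {
            replicon: strands.get(strand, {})
            for replicon, strands in track.counts.items()
            if strands.get(strand)
        }
        _write_bedgraph(by_rep, path)


def read_bedgraph_coverage(path: str | Path, *, strand: str = ".") -> CoverageTrack:
    cov = CoverageTrack()
    sparse, _ = _parse_bedgraph(path)
    for chrom, posmap in sparse.items():
        for pos, value in posmap.items():
            cov.add(chrom, strand, pos, value)
    return cov


def write_bedgraph_coverage(cov: CoverageTrack, path: str | Path, *, strand: str = ".") -> None:
    by_rep = {
        replicon: strands.get(strand, {})
        for replicon, strands in cov.counts.items()
        if strands.get(strand)
    }
    _write_bedgraph(by_rep, path)


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

def pool(tracks: list[ReadStartTrack], *, library_id: str | None = None) -> ReadStartTrack:
    """Position-wise sum of replicate tracks of the same treatment.

    Pooling across treatments is forbidden: TEX+ and TEX- answer different
    questions and must stay separate.
    """
    if not tracks:
        raise ValueError("pool() requires at least one track")
    treatments = {t.meta.treatment for t in tracks}
    if len(treatments) > 1:
        raise ValueError(f"refusing to pool across treatments: {sorted(treatments)}")
    meta = LibraryMeta(
        library_id=library_id or "pooled_" + "_".join(t.meta.library_id for t in tracks),
        treatment=tracks[0].meta.treatment,
        condition=tracks[0].meta.condition,
    )
    out = ReadStartTrack(meta=meta)
    for t in tracks:
        for replicon, length in t.lengths.items():
            if length is not None:
                out.lengths[replicon] = length
            else:
                out.lengths.setdefault(replicon, None)
        for replicon, strands in t.counts.items():
            for strand, sparse in strands.items():
                for pos, c in sparse.items():
                    out.add(replicon, strand, pos, c)
    out.sync_total()
    return out
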