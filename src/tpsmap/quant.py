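"""Condition comparisons at site resolution and Ribo-seq peak overlap.

Library normalization follows two conventions: ``per_million`` rescales each
library so its read-start integral is 1e6; ``match_max`` rescales shallower
libraries up to the most deeply sequenced one (which keeps factor 1).  Site
and gene signals from the normalized tracks are compared between exactly two
conditions with a pseudocount log2 ratio; a site is flagged discordant when
its fold-change opposes the cognate gene's fold-change and both exceed an
effect floor.  Ribo-seq peaks are local coverage maxima passing a z-score
rule, and site/peak overlap is summit distance within an adjacency margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import GeneModel, TPSAnnotation
from .caller import TPSCall
from .ingest import CoverageTrack, LibraryMeta, ReadStartTrack

logger = logging.getLogger(__name__)

MODE_MATCH_MAX = "match_max"
MODE_PER_MILLION = "per_million"


@dataclass
class DifferentialRecord:
    tps_id: str
    locus_tag: str | None
    signal_a: float
    signal_b: float
    gene_a: float
    gene_b: float
    log2fc_site: float
    log2fc_gene: float
    discordant: bool


@dataclass
class RiboPeak:
    replicon: str
    strand: str     # "." for unstranded coverage
    position: int   # summit
    height: float
    z_score: float


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def scale_factors(libs: list[LibraryMeta], mode: str = MODE_MATCH_MAX) -> dict[str, float]:
    """Per-library multiplicative factors for the chosen normalization."""
    totals = {lib.library_id: lib.total_readstarts for lib in libs}
    for lid, tot in totals.items():
        if tot <= 0:
            raise ValueError(f"library {lid!r} has zero total read starts")
    if mode == MODE_PER_MILLION:
        return {lid: 1e6 / tot for lid, tot in totals.items()}
    if mode == MODE_MATCH_MAX:
        top = max(totals.values())
        return {lid: top / tot for lid, tot in totals.items()}
    raise ValueError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# Signals
# ---------------------------------------------------------------------------

def site_signal(track: ReadStartTrack, call: TPSCall, halfwidth: int = 2) -> float:
    """Strand-matched read-start signal in [position - halfwidth, position + halfwidth]."""
    return float(
        sum(
            track.get(call.replicon, call.strand, p)
            for p in range(call.position - halfwidth, call.position + halfwidth + 1)
        )
    )


def gene_signal(track: ReadStartTrack, gene: GeneModel) -> float:
    """Mean strand-matched read-start count over the CDS interval."""
    return gene_total(track, gene) / gene.length


def gene_total(track: ReadStartTrack, gene: GeneModel) -> float:
    """Total strand-matched read-start count over the CDS interval."""
    sparse = track.counts.get(gene.replicon, {}).get(gene.strand, {})
    return float(sum(c for p, c in sparse.items() if gene.start <= p <= gene.end))


def differential_sites(
    tracks_by_condition: dict[str, ReadStartTrack],
    annotations: list[TPSAnnotation],
    calls: list[TPSCall],
    genes: list[GeneModel],
    *,
    pseudocount: float = 1.0,
    effect_floor: float = 1.0,
    halfwidth: int = 2,
) -> list[DifferentialRecord]:
    """Site-level vs gene-level log2 fold-changes between two conditions.

    ``tracks_by_condition`` maps condition label -> normalized (same mode)
    TEX- track; the two conditions are taken in insertion order (a, b).
    log2fc = log2((b + pseudocount) / (a + pseudocount)).  Discordance:
    opposite fold-change signs at site and gene, both magnitudes >= the floor.
    """
    if len(tracks_by_condition) != 2:
        raise ValueError(
            f"exactly two conditions required, got {sorted(tracks_by_condition)}"
        )
    (cond_a, track_a), (cond_b, track_b) = tracks_by_condition.items()
    logger.debug("differential: %s (a) vs %s (b)", cond_a, cond_b)
    call_index = {c.tps_id: c for c in calls}
    gene_index = {g.locus_tag: g for g in genes}
    records: list[DifferentialRecord] = []
    for a in annotations:
        if a.orientation != "sense" or a.locus_tag is None:
            continue
        call = call_index.get(a.tps_id)
        gene = gene_index.get(a.locus_tag)
        if call is None or gene is None:
            continue
        s_a = site_signal(track_a, call, halfwidth)
        s_b = site_signal(track_b, call, halfwidth)
        g_a = gene_signal(track_a, gene)
        g_b = gene_signal(track_b, gene)
        fc_site = float(np.log2((s_b + pseudocount) / (s_a + pseudocount)))
        # the gene ratio uses CDS totals so the pseudocount acts on the same
        # count scale as the site window sum
        fc_gene = float(
            np.log2(
                (gene_total(track_b, gene) + pseudocount)
                / (gene_total(track_a, gene) + pseudocount)
            )
        )
        discordant = (
            fc_site * fc_gene < 0
            and abs(fc_site) >= effect_floor
            and abs(fc_gene) >= effect_floor
        )
        records.append(
            DifferentialRecord(
                tps_id=a.tps_id,
                locus_tag=a.locus_tag,
                signal_a=s_a,
                signal_b=s_b,
                gene_a=g_a,
                gene_b=g_b,
                log2fc_site=fc_site,
                log2fc_gene=fc_gene,
                discordant=discordant,
            )
        )
    return records


def differential_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    cols = [
        "tps_id", "locus_tag", "signal_a", "signal_b", "gene_a", "gene_b",
        "log2fc_site", "log2fc_gene", "discordant",
    ]
    return pd.DataFrame([{k: getattr(r, k) for k in cols} for r in records], columns=cols)


# ---------------------------------------------------------------------------
# Ribo-seq peaks
# ---------------------------------------------------------------------------

def call_ribo_peaks(
    coverage: CoverageTrack,
    *,
    window: int = 200,
    min_z: float = 2.0,
    min_height: float = 5.0,
) -> list[RiboPeak]:
    """Local-maximum peak calling with a windowed z-score rule.

    A position is a summit when its depth is >= ``min_height``, exceeds every
    depth strictly to its left and every depth to its right within
    +/- window/2 (ties to the right allowed, so the leftmost of a tied run is
    the summit), and z = (height - window mean) / max(window SD, 1) >= min_z.
    """
    half = window // 2
    peaks: list[RiboPeak] = []
    for replicon in coverage.replicons():
        strands = coverage.counts.get(replicon, {})
        for strand, sparse in sorted(strands.items()):
            if not sparse:
                continue
            length = coverage.lengths.get(replicon) or max(sparse)
            dense = np.zeros(length, dtype=float)
            pos = np.fromiter(sparse.keys(), dtype=np.int64, count=len(sparse))
            val = np.fromiter(sparse.values(), dtype=float, count=len(sparse))
            dense[pos - 1] = val
            order = np.flatnonzero(dense >= min_height)
            for i in order:
                h = dense[i]
                lo = max(0, i - half)
                hi = min(length, i + half + 1)
                left = dense[lo:i]
                right = dense[i + 1:hi]
                if left.size and left.max() >= h:
                    continue
                if right.size and right.max() > h:
                    continue
                win = dense[lo:hi]
                z = (h - win.mean()) / max(win.std(), 1.0)
                if z >= min_z:
                    peaks.append(
                        RiboPeak(
                            replicon=replicon,
                            strand=strand,
                            position=int(i + 1),
                            height=float(h),
                            z_score=float(z),
                        )
                    )
    peaks.sort(key=lambda p: (p.replicon, p.position))
    return peaks


def peaks_to_frame(peaks: list[RiboPeak]) -> pd.DataFrame:
    cols = ["replicon", "strand", "position", "height", "z_score"]
    return pd.DataFrame([{k: getattr(p, k) for k in cols} for p in peaks], columns=cols)


# ---------------------------------------------------------------------------
# Overlap fraction
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    n_total: int
    n_overlapping: int
    fraction: float | None
    percent: int | None
    table: pd.DataFrame


def overlap_fraction(
    calls: list[TPSCall], peaks: list[RiboPeak], adjacency: int = 10
) -> OverlapResult:
    """Fraction of sites with a peak summit within +/- adjacency nt.

    Reported as the raw ratio and as a percentage rounded to the nearest
    integer; the per-site table carries the distance to the nearest summit so
    the sensitivity to the adjacency margin can be examined.
    """
    summit_by_rep: dict[str, np.ndarray] = {}
    for p in peaks:
        summit_by_rep.setdefault(p.replicon, [])
    for p in peaks:
        summit_by_rep[p.replicon].append(p.position)
    summit_by_rep = {r: np.sort(np.array(v)) for r, v in summit_by_rep.items()}
    rows = []
    n_over = 0
    for c in calls:
        summits = summit_by_rep.get(c.replicon)
        if summits is None or summits.size == 0:
            dist = None
        else:
            j = np.searchsorted(summits, c.position)
            cand = summits[max(0, j - 1): j + 1]
            dist = int(np.min(np.abs(cand - c.position)))
        overlapping = dist is not None and dist <= adjacency
        n_over += overlapping
        rows.append(
            {
                "tps_id": c.tps_id,
                "replicon": c.replicon,
                "position": c.position,
                "nearest_summit_distance": dist,
                "overlapping": overlapping,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["tps_id", "replicon", "position", "nearest_summit_distance", "overlapping"],
    )
    if not calls:
        return OverlapResult(0, 0, None, None, table)
    frac = n_over / len(calls)
    return OverlapResult(len(calls), n_over, frac, int(round(100 * frac)), table)
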