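"""Cross-species layers: conserved TPS, species-specific internal sites,
sense/antisense coincidence.

Conservation is defined on the normalized position D: a site pair in an
orthologous gene pair is conserved when |D_a - D_b| < threshold (default 3,
strict).  Only sense annotations enter the conservation test; antisense
conservation is the separate presence-only question (both orthologs carry at
least one aTPS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotate import CATEGORY_INTERNAL, TPSAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologPair:
    locus_a: str
    locus_b: str


@dataclass
class ConservedTPS:
    pair: OrthologPair
    tps_a: str
    tps_b: str
    d_a: float
    d_b: float

    @property
    def delta(self) -> float:
        return abs(self.d_a - self.d_b)


def read_ortholog_pairs(path: str | Path) -> list[OrthologPair]:
    """Two-column TSV with header; one-to-one mapping enforced."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two locus-tag columns")
    pairs = [OrthologPair(str(a), str(b)) for a, b in frame.iloc[:, :2].itertuples(index=False)]
    _check_one_to_one(pairs)
    return pairs


def write_ortholog_pairs(pairs: list[OrthologPair], path: str | Path) -> None:
    pd.DataFrame(
        [(p.locus_a, p.locus_b) for p in pairs], columns=["locus_a", "locus_b"]
    ).to_csv(path, sep="\t", index=False)


def _check_one_to_one(pairs: list[OrthologPair]) -> None:
    for col, loci in (("a", [p.locus_a for p in pairs]), ("b", [p.locus_b for p in pairs])):
        if len(loci) != len(set(loci)):
            dup = sorted({x for x in loci if loci.count(x) > 1})
            raise ValueError(f"ortholog table is not one-to-one in species {col}: {dup[:5]}")


def _sense_by_locus(annotations: list[TPSAnnotation]) -> dict[str, list[TPSAnnotation]]:
    idx: dict[str, list[TPSAnnotation]] = {}
    for a in annotations:
        if a.orientation == "sense" and a.locus_tag is not None and a.d is not None:
            idx.setdefault(a.locus_tag, []).append(a)
    return idx


def _antisense_loci(annotations: list[TPSAnnotation]) -> set[str]:
    return {
        a.locus_tag
        for a in annotations
        if a.orientation == "antisense" and a.locus_tag is not None
    }


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

def conserved(
    annot_a: list[TPSAnnotation],
    annot_b: list[TPSAnnotation],
    pairs: list[OrthologPair],
    threshold: float = 3.0,
) -> list[ConservedTPS]:
    """All cross combinations of sense sites in orthologous genes with
    |D_a - D_b| strictly below the threshold.

    A site may participate in several conserved combinations; a gene pair may
    contribute several.  Output is sorted by pair, then delta.
    """
    _check_one_to_one(pairs)
    idx_a = _sense_by_locus(annot_a)
    idx_b = _sense_by_locus(annot_b)
    out: list[ConservedTPS] = []
    n_skipped = 0
    for pair in pairs:
        in_a = idx_a.get(pair.locus_a)
        in_b = idx_b.get(pair.locus_b)
        if not in_a or not in_b:
            n_skipped += 1
            continue
        for sa in in_a:
            for sb in in_b:
                if abs(sa.d - sb.d) < threshold:
                    out.append(
                        ConservedTPS(
                            pair=pair, tps_a=sa.tps_id, tps_b=sb.tps_id,
                            d_a=sa.d, d_b=sb.d,
                        )
                    )
    logger.debug("conserved(): %d/%d pairs without sites in one species", n_skipped, len(pairs))
    out.sort(key=lambda c: (c.pair.locus_a, c.pair.locus_b, c.delta, c.tps_a, c.tps_b))
    return out


def conserved_to_frame(records: list[ConservedTPS]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_a": r.pair.locus_a,
                "locus_b": r.pair.locus_b,
                "tps_a": r.tps_a,
                "tps_b": r.tps_b,
                "d_a": r.d_a,
                "d_b": r.d_b,
                "delta": r.delta,
            }
            for r in records
        ],
        columns=["locus_a", "locus_b", "tps_a", "tps_b", "d_a", "d_b", "delta"],
    )


def conservation_counts(records: list[ConservedTPS]) -> dict[str, int]:
    """Pair-count and distinct-site counts (both species) for a conserved set."""
    return {
        "n_combinations": len(records),
        "n_gene_pairs": len({(r.pair.locus_a, r.pair.locus_b) for r in records}),
        "n_distinct_tps_a": len({r.tps_a for r in records}),
        "n_distinct_tps_b": len({r.tps_b for r in records}),
    }


# ---------------------------------------------------------------------------
# Species-specific internal sites
# ---------------------------------------------------------------------------

def _internal_loci(idx: dict[str, list[TPSAnnotation]]) -> set[str]:
    return {
        locus
        for locus, sites in idx.items()
        if any(s.category == CATEGORY_INTERNAL for s in sites)
    }


def specific_internal(
    annot_a: list[TPSAnnotation],
    annot_b: list[TPSAnnotation],
    pairs: list[OrthologPair],
) -> tuple[list[str], list[str]]:
    """Orthologous genes with an internal site (25 < D < 75) in one species and
    none in the partner; returned as (A-specific loci, B-specific loci)."""
    idx_a = _sense_by_locus(annot_a)
    idx_b = _sense_by_locus(annot_b)
    internal_a = _internal_loci(idx_a)
    internal_b = _internal_loci(idx_b)
    only_a = sorted(
        p.locus_a for p in pairs if p.locus_a in internal_a and p.locus_b not in internal_b
    )
    only_b = sorted(
        p.locus_b for p in pairs if p.locus_b in internal_b and p.locus_a not in internal_a
    )
    return only_a, only_b


# ---------------------------------------------------------------------------
# Sense/antisense coincidence
# ---------------------------------------------------------------------------

def coincidences(
    annotations: list[TPSAnnotation], window: int = 5
) -> list[tuple[str, str]]:
    """Unordered (sense TPS, antisense aTPS) site pairs on the same replicon,
    opposite strands, within ``window`` nt — the positional signature of
    sense/antisense duplex cleavage.  Each pair is reported once."""
    sense_sites: dict[str, tuple[str, str, int]] = {}
    anti_sites: dict[str, tuple[str, str, int]] = {}
    for a in annotations:
        if a.orientation == "sense":
            sense_sites[a.tps_id] = (a.replicon, a.strand, a.x_tps)
        elif a.orientation == "antisense":
            anti_sites[a.tps_id] = (a.replicon, a.strand, a.x_tps)
    found: set[tuple[str, str]] = set()
    for sid, (rep_s, strand_s, pos_s) in sense_sites.items():
        for aid, (rep_a, strand_a, pos_a) in anti_sites.items():
            if sid == aid:
                continue
            if rep_s != rep_a or strand_s == strand_a:
                continue
            if abs(pos_s - pos_a) <= window:
                found.add((sid, aid))
    return sorted(found)


def conserved_atps(
    annot_a: list[TPSAnnotation],
    annot_b: list[TPSAnnotation],
    pairs: list[OrthologPair],
) -> list[OrthologPair]:
    """Ortholog pairs where both genes carry at least one antisense site
    (presence only; no positional requirement)."""
    anti_a = _antisense_loci(annot_a)
    anti_b = _antisense_loci(annot_b)
    return [p for p in pairs if p.locus_a in anti_a and p.locus_b in anti_b]
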