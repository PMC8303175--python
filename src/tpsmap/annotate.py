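"""Gene-model loading and CDS-relative placement of processing sites.

Each called site is mapped onto annotated coding sequences and given a
normalized position

    D = 100 * sigma * (x_TPS - x_CDSstart) / |x_CDSstart - x_CDSend|

with sigma = +1 for forward genes and -1 for reverse genes, so that D = 0 at
the first base of the start codon and D = 100 at the last CDS base regardless
of strand.  D < 0 marks sites upstream of the start (5' UTR side) and D > 100
sites downstream of the CDS (3' side).  Sites on the strand opposite to the
gene are antisense (aTPS) and are assigned only within the unextended gene
interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .caller import TPSCall

logger = logging.getLogger(__name__)

CATEGORY_UPSTREAM = "UPSTREAM"
CATEGORY_START = "START_PROXIMAL"
CATEGORY_INTERNAL = "INTERNAL"
CATEGORY_STOP = "STOP_PROXIMAL"
CATEGORY_DOWNSTREAM = "DOWNSTREAM"


@dataclass
class GeneModel:
    """One CDS with strand-aware start/end codon coordinates (1-based inclusive)."""

    locus_tag: str
    replicon: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.locus_tag}: start > end")
        if self.end - self.start + 1 < 6:
            raise ValueError(f"{self.locus_tag}: CDS shorter than 6 nt")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")

    @property
    def x_cds_start(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end

    @property
    def x_cds_end(self) -> int:
        """Genomic coordinate of the last CDS base."""
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TPSAnnotation:
    """One site assigned to one gene (a site may annotate several genes)."""

    tps_id: str
    locus_tag: str | None
    orientation: str | None      # "sense" | "antisense" | None for unassigned
    replicon: str
    strand: str                  # strand of the site itself
    x_tps: int
    d: float | None
    category: str | None
    p_value: float | None = None


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def load_annotation(gff3_path: str | Path, feature_type: str = "CDS") -> list[GeneModel]:
    """Load gene models of one feature type from GFF3.

    Locus tags come from the ``locus_tag`` attribute, falling back to ``ID``.
    Records without a strand are skipped with a warning; duplicate locus tags
    are an error.
    """
    with open(gff3_path) as fh:
        has_features = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_features:
        return []
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise ValueError(f"malformed GFF3 {gff3_path}: {exc}") from exc
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        tags = feat.attributes.get("locus_tag") or feat.attributes.get("ID")
        if not tags:
            logger.warning("%s:%d-%d: no locus_tag/ID; skipped", feat.seqid, feat.start, feat.end)
            continue
        tag = tags[0]
        if feat.strand not in ("+", "-"):
            logger.warning("%s (%s): missing strand; skipped", tag, feat.seqid)
            continue
        if tag in seen:
            raise ValueError(f"duplicate locus tag {tag!r} in {gff3_path}")
        seen.add(tag)
        genes.append(
            GeneModel(
                locus_tag=tag,
                replicon=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Normalized position
# ---------------------------------------------------------------------------

def normalized_position(gene: GeneModel, x_tps: int) -> float:
    """CDS-relative position D of a genomic coordinate (0 = start codon,
    100 = last CDS base; out-of-bound values allowed)."""
    sigma = 1.0 if gene.strand == "+" else -1.0
    denom = abs(gene.x_cds_start - gene.x_cds_end)
    return 100.0 * sigma * (x_tps - gene.x_cds_start) / denom


def categorize(d: float) -> str:
    """Positional category of a normalized position.

    Internal sites are the strict band 25 < D < 75; the boundaries belong to
    the start-/stop-proximal classes.
    """
    if d < 0:
        return CATEGORY_UPSTREAM
    if d <= 25:
        return CATEGORY_START
    if d < 75:
        return CATEGORY_INTERNAL
    if d <= 100:
        return CATEGORY_STOP
    return CATEGORY_DOWNSTREAM


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def assign(
    calls: list[TPSCall],
    genes: list[GeneModel],
    *,
    max_upstream_ext: int = 150,
    max_downstream_ext: int = 150,
) -> list[TPSAnnotation]:
    """Assign calls to genes, sense within strand-aware extended intervals and
    antisense within unextended intervals.

    A call may annotate several (possibly overlapping) genes; calls matching
    no gene are retained with a null locus so the inventory stays complete.
    """
    sense_trees: dict[tuple[str, str], IntervalTree] = {}
    anti_trees: dict[tuple[str, str], IntervalTree] = {}
    for gene in genes:
        if gene.strand == "+":
            ext_start = gene.start - max_upstream_ext
            ext_end = gene.end + max_downstream_ext
        else:
            ext_start = gene.start - max_downstream_ext
            ext_end = gene.end + max_upstream_ext
        sense_trees.setdefault((gene.replicon, gene.strand), IntervalTree()).addi(
            ext_start, ext_end + 1, gene
        )
        anti_trees.setdefault((gene.replicon, gene.strand), IntervalTree()).addi(
            gene.start, gene.end + 1, gene
        )
    out: list[TPSAnnotation] = []
    for call in calls:
        hits = 0
        sense_tree = sense_trees.get((call.replicon, call.strand))
        if sense_tree is not None:
            for iv in sorted(sense_tree[call.position], key=lambda iv: iv.data.locus_tag):
                gene: GeneModel = iv.data
                d = normalized_position(gene, call.position)
                out.append(
                    TPSAnnotation(
                        tps_id=call.tps_id,
                        locus_tag=gene.locus_tag,
                        orientation="sense",
                        replicon=call.replicon,
                        strand=call.strand,
                        x_tps=call.position,
                        d=d,
                        category=categorize(d),
                        p_value=call.p_value,
                    )
                )
                hits += 1
        opposite = "-" if call.strand == "+" else "+"
        anti_tree = anti_trees.get((call.replicon, opposite))
        if anti_tree is not None:
            for iv in sorted(anti_tree[call.position], key=lambda iv: iv.data.locus_tag):
                gene = iv.data
                d = normalized_position(gene, call.position)
                out.append(
                    TPSAnnotation(
                        tps_id=call.tps_id,
                        locus_tag=gene.locus_tag,
                        orientation="antisense",
                        replicon=call.replicon,
                        strand=call.strand,
                        x_tps=call.position,
                        d=d,
                        category=categorize(d),
                        p_value=call.p_value,
                    )
                )
                hits += 1
        if hits == 0:
            out.append(
                TPSAnnotation(
                    tps_id=call.tps_id,
                    locus_tag=None,
                    orientation=None,
                    replicon=call.replicon,
                    strand=call.strand,
                    x_tps=call.position,
                    d=None,
                    category=None,
                    p_value=call.p_value,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(
    annotations: list[TPSAnnotation],
    *,
    histogram_bin: float = 3.0,
    density_window: int = 200,
) -> dict[str, pd.DataFrame]:
    """Per-gene multiplicity, D histogram (bin width 3), and densest-window report.

    The densest window scans, per replicon, all windows of ``density_window``
    nt over distinct annotated site positions and reports the maximum count and
    its density (count / window length per nt).
    """
    sense = [a for a in annotations if a.orientation == "sense"]
    # multiplicity: distinct sites per gene
    mult_rows = []
    per_gene: dict[str, set[str]] = {}
    for a in sense:
        per_gene.setdefault(a.locus_tag, set()).add(a.tps_id)
    for locus, ids in sorted(per_gene.items()):
        mult_rows.append({"locus_tag": locus, "n_tps": len(ids)})
    multiplicity = pd.DataFrame(mult_rows, columns=["locus_tag", "n_tps"])

    if multiplicity.empty:
        mult_dist = pd.DataFrame(columns=["n_tps", "n_genes", "fraction"])
    else:
        counts = multiplicity["n_tps"].value_counts().sort_index()
        mult_dist = pd.DataFrame(
            {
                "n_tps": counts.index,
                "n_genes": counts.values,
                "fraction": counts.values / counts.values.sum(),
            }
        )

    d_values = [a.d for a in sense if a.d is not None]
    if d_values:
        import numpy as np

        lo = float(np.floor(min(d_values) / histogram_bin) * histogram_bin)
        hi = float(np.ceil(max(d_values) / histogram_bin) * histogram_bin)
        if hi <= lo:
            hi = lo + histogram_bin
        edges = np.arange(lo, hi + histogram_bin / 2, histogram_bin)
        hist, _ = np.histogram(d_values, bins=edges)
        d_hist = pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}
        )
    else:
        d_hist = pd.DataFrame(columns=["bin_left", "bin_right", "count"])

    dens_rows = []
    by_rep: dict[str, list[int]] = {}
    for a in sense:
        by_rep.setdefault(a.replicon, []).append(a.x_tps)
    for replicon, raw in sorted(by_rep.items()):
        pos = sorted(set(raw))
        best_count, best_start = 0, pos[0] if pos else 0
        j = 0
        for i in range(len(pos)):
            while pos[i] - pos[j] >= density_window:
                j += 1
            if i - j + 1 > best_count:
                best_count = i - j + 1
                best_start = pos[j]
        dens_rows.append(
            {
                "replicon": replicon,
                "window_start": best_start,
                "window_length": density_window,
                "count": best_count,
                "density_per_nt": best_count / density_window,
            }
        )
    densest = pd.DataFrame(
        dens_rows,
        columns=["replicon", "window_start", "window_length", "count", "density_per_nt"],
    )
    return {
        "multiplicity": multiplicity,
        "multiplicity_distribution": mult_dist,
        "d_histogram": d_hist,
        "densest_window": densest,
    }


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = [
    "tps_id", "locus_tag", "orientation", "replicon", "strand",
    "x_tps", "d", "category", "p_value",
]


def annotations_to_frame(annotations: list[TPSAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [{k: getattr(a, k) for k in _ANNOT_COLUMNS} for a in annotations],
        columns=_ANNOT_COLUMNS,
    )


def frame_to_annotations(frame: pd.DataFrame) -> list[TPSAnnotation]:
    out = []
    for row in frame.itertuples(index=False):
        d = None if pd.isna(row.d) else float(row.d)
        out.append(
            TPSAnnotation(
                tps_id=row.tps_id,
                locus_tag=None if pd.isna(row.locus_tag) or row.locus_tag == "" else str(row.locus_tag),
                orientation=None if pd.isna(row.orientation) or row.orientation == "" else row.orientation,
                replicon=str(row.replicon),
                strand=row.strand,
                x_tps=int(row.x_tps),
                d=d,
                category=None if pd.isna(row.category) or row.category == "" else row.category,
                p_value=None if pd.isna(row.p_value) else float(row.p_value),
            )
        )
    return out


def write_annotations(annotations: list[TPSAnnotation], tsv_path) -> None:
    annotations_to_frame(annotations).to_csv(tsv_path, sep="\t", index=False)


def read_annotations(tsv_path) -> list[TPSAnnotation]:
    return frame_to_annotations(pd.read_csv(tsv_path, sep="\t"))
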