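"""Synthetic dRNA-seq studies with planted ground truth.

The generator emulates the statistical structure the caller assumes: per
position and library, read-start counts are Poisson with a background rate
``lambda_bg``, plus a site contribution at planted positions.  A planted
processing site (TPS, a 5'-monophosphorylated end) contributes mean ``mu`` to
the TEX- library and ``mu * tex_plus_leak`` to TEX+ (incomplete exonuclease
digestion); a planted transcription start site (TSS, 5'-triphosphorylated)
contributes ``mu * tex_enrichment`` to TEX+ and ``mu * tss_minus_fraction`` to
TEX-.  Same-strand, same-kind sites are kept at least one nucleotide further
apart than the caller's clustering gap so the planted truth is unambiguous at
evaluation time.

Everything is deterministic given the seed; the two-species study additionally
plants non-conserved ortholog sites with a guaranteed normalized-position
separation so the conserved truth set is exactly recoverable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel, normalized_position
from .caller import TPSCall
from .comparative import OrthologPair
from .ingest import (
    TEX_MINUS,
    TEX_PLUS,
    CoverageTrack,
    LibraryMeta,
    ReadStartTrack,
)

logger = logging.getLogger(__name__)

KIND_TSS = "TSS"
KIND_TPS = "TPS"


@dataclass
class SiteRecord:
    replicon: str
    position: int
    strand: str
    kind: str           # TSS | TPS
    strength: float     # mu = expected extra read starts in the favored library
    locus_tag: str | None = None


@dataclass
class SiteTruth:
    sites: list[SiteRecord]
    seed: int

    def of_kind(self, kind: str) -> list[SiteRecord]:
        return [s for s in self.sites if s.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        cols = ["replicon", "position", "strand", "kind", "strength", "locus_tag"]
        return pd.DataFrame(
            [{k: getattr(s, k) for k in cols} for s in self.sites], columns=cols
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SimDesign:
    """Parameters of a single-replicon synthetic study."""

    n_genes: int = 50
    replicon_length: int = 100_000
    gene_length_range: tuple[int, int] = (300, 1500)
    strand_balance: float = 0.5
    lambda_bg: float = 1.0
    tex_plus_leak: float = 0.02
    tss_minus_fraction: float = 1.0
    tex_enrichment: float = 3.0
    replicon_id: str = "chr"
    locus_prefix: str = "GENE"
    min_gene_gap: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_bg < 0:
            raise ValueError("lambda_bg must be >= 0")
        if not 0 <= self.tex_plus_leak < 1:
            raise ValueError("tex_plus_leak must be in [0, 1)")
        if not 0 <= self.strand_balance <= 1:
            raise ValueError("strand_balance must be in [0, 1]")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range must be (lo, hi) with lo <= hi")
        if self.gene_length_range[0] < 6:
            raise ValueError("genes must be at least 6 nt")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(design: SimDesign) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping CDS (no overlaps on either strand)
    with random lengths, gaps, and strands; deterministic given the seed."""
    rng = _rng(design.seed, 1)
    n = design.n_genes
    if n == 0:
        return []
    lo, hi = design.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    needed = int(lengths.sum()) + design.min_gene_gap * (n + 1)
    if needed > design.replicon_length:
        raise ValueError(
            f"replicon of {design.replicon_length} nt too short for {n} genes "
            f"(need >= {needed} nt); shorten genes or extend the replicon"
        )
    slack = design.replicon_length - needed
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1))) if slack > 0 else np.zeros(n + 1, dtype=int)
    strands = np.where(rng.random(n) < design.strand_balance, "+", "-")
    genes: list[GeneModel] = []
    cursor = 1
    width = max(4, len(str(n)))
    for i in range(n):
        cursor += design.min_gene_gap + int(extra[i])
        start = cursor
        end = start + int(lengths[i]) - 1
        genes.append(
            GeneModel(
                locus_tag=f"{design.locus_prefix}_{i + 1:0{width}d}",
                replicon=design.replicon_id,
                start=start,
                end=end,
                strand=str(strands[i]),
            )
        )
        cursor = end + 1
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path, lengths: dict[str, int] | None = None) -> None:
    """Deterministic GFF3 with CDS features carrying locus_tag attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for replicon, length in sorted((lengths or {}).items()):
            fh.write(f"##sequence-region {replicon} 1 {length}\n")
        for g in sorted(genes, key=lambda g: (g.replicon, g.start, g.locus_tag)):
            fh.write(
                f"{g.replicon}\ttpsmap_sim\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.locus_tag};locus_tag={g.locus_tag}\n"
            )


# ---------------------------------------------------------------------------
# Distribution specs
# ---------------------------------------------------------------------------

def _draw_count(spec, rng: np.random.Generator) -> int:
    """Per-gene site multiplicity: a constant int, or a {count: probability}
    categorical (e.g. {1: 0.59, 2: 0.25, 3: 0.16} for a mostly-single-site
    genome)."""
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    if isinstance(spec, dict):
        values = sorted(spec)
        probs = np.array([spec[v] for v in values], dtype=float)
        probs = probs / probs.sum()
        return int(rng.choice(values, p=probs))
    raise ValueError(f"bad count spec {spec!r}")


def _draw_strength(spec, rng: np.random.Generator) -> float:
    """Site strength mu: constant, ("uniform", lo, hi), or ("lognormal", mu, sigma)."""
    if isinstance(spec, (int, float, np.floating, np.integer)):
        v = float(spec)
    elif isinstance(spec, (tuple, list)) and spec and spec[0] == "uniform":
        v = float(rng.uniform(spec[1], spec[2]))
    elif isinstance(spec, (tuple, list)) and spec and spec[0] == "lognormal":
        v = float(rng.lognormal(spec[1], spec[2]))
    else:
        raise ValueError(f"bad strength spec {spec!r}")
    if v < 0:
        raise ValueError("strengths must be >= 0")
    return v


# ---------------------------------------------------------------------------
# Truth planting
# ---------------------------------------------------------------------------

def plant_truth(
    genes: list[GeneModel],
    *,
    tps_per_gene=1,
    tss_per_gene=1,
    atps_per_gene=0,
    strength=50.0,
    min_spacing: int = 6,
    max_tries: int = 200,
    seed: int = 0,
) -> SiteTruth:
    """Plant TSS/TPS (and optionally antisense TPS) in each gene.

    TSS go at the gene 5' end (0-5 nt upstream of the start codon, the
    leaderless-dominated regime of halophilic archaea); TPS are uniform within
    the CDS; antisense TPS are uniform within the CDS on the opposite strand.
    Same-strand same-kind sites anywhere on the replicon are kept
    >= min_spacing nt apart by rejection; a site that cannot be placed is
    skipped with a warning, never silently dropped from an already-recorded
    truth table.
    """
    rng = _rng(seed, 2)
    occupied: dict[tuple[str, str, str], list[int]] = {}
    sites: list[SiteRecord] = []

    def _try_place(replicon: str, strand: str, kind: str, sampler, locus: str) -> None:
        key = (replicon, strand, kind)
        taken = occupied.setdefault(key, [])
        for _ in range(max_tries):
            pos = sampler()
            if all(abs(pos - q) >= min_spacing for q in taken):
                taken.append(pos)
                sites.append(
                    SiteRecord(
                        replicon=replicon,
                        position=pos,
                        strand=strand,
                        kind=kind,
                        strength=_draw_strength(strength, rng),
                        locus_tag=locus,
                    )
                )
                return
        logger.warning(
            "could not place a %s in %s within %d tries (spacing %d nt); site skipped",
            kind, locus, max_tries, min_spacing,
        )

    for gene in genes:
        anti = "-" if gene.strand == "+" else "+"
        for _ in range(_draw_count(tss_per_gene, rng)):
            offset = int(rng.integers(0, 6))
            pos0 = gene.x_cds_start - offset if gene.strand == "+" else gene.x_cds_start + offset
            _try_place(gene.replicon, gene.strand, KIND_TSS, lambda p=pos0: p, gene.locus_tag)
        for _ in range(_draw_count(tps_per_gene, rng)):
            _try_place(
                gene.replicon, gene.strand, KIND_TPS,
                lambda g=gene: int(rng.integers(g.start, g.end + 1)),
                gene.locus_tag,
            )
        for _ in range(_draw_count(atps_per_gene, rng)):
            _try_place(
                gene.replicon, anti, KIND_TPS,
                lambda g=gene: int(rng.integers(g.start, g.end + 1)),
                gene.locus_tag,
            )
    return SiteTruth(sites=sites, seed=seed)


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def simulate_library(
    truth: SiteTruth,
    design: SimDesign,
    treatment: str,
    replicate: int = 1,
    seed: int | None = None,
) -> ReadStartTrack:
    """One library's read-start track: Poisson background plus Poisson site
    contributions whose means depend on treatment and site kind."""
    if treatment not in (TEX_PLUS, TEX_MINUS):
        raise ValueError(f"unknown treatment {treatment!r}")
    base_seed = design.seed if seed is None else seed
    tcode = 0 if treatment == TEX_MINUS else 1
    rng = _rng(base_seed, 3, tcode, replicate)
    L = design.replicon_length
    replicon = design.replicon_id
    meta = LibraryMeta(
        library_id=f"{replicon}_{treatment}_rep{replicate}",
        treatment=treatment,
        replicate=replicate,
    )
    track = ReadStartTrack(meta=meta, lengths={replicon: L})
    for strand in ("+", "-"):
        dense = (
            rng.poisson(design.lambda_bg, size=L).astype(np.int64)
            if design.lambda_bg > 0
            else np.zeros(L, dtype=np.int64)
        )
        for site in truth.sites:
            if site.strand != strand or site.replicon != replicon:
                continue
            if not 1 <= site.position <= L:
                raise ValueError(f"planted site at {site.position} outside replicon of {L} nt")
            if site.kind == KIND_TPS:
                mu = site.strength if treatment == TEX_MINUS else site.strength * design.tex_plus_leak
            else:
                mu = (
                    site.strength * design.tex_enrichment
                    if treatment == TEX_PLUS
                    else site.strength * design.tss_minus_fraction
                )
            if mu > 0:
                dense[site.position - 1] += rng.poisson(mu)
        for idx in np.flatnonzero(dense):
            track.add(replicon, strand, int(idx + 1), int(dense[idx]))
    track.sync_total()
    return track


# ---------------------------------------------------------------------------
# Two-species ortholog study
# ---------------------------------------------------------------------------

@dataclass
class ConservedTruth:
    pair: OrthologPair
    position_a: int
    position_b: int
    d_a: float
    d_b: float


@dataclass
class OrthologStudy:
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    pairs: list[OrthologPair]
    truth_a: SiteTruth
    truth_b: SiteTruth
    conserved: list[ConservedTruth]
    atps_pairs: list[OrthologPair] = field(default_factory=list)


def simulate_ortholog_study(
    design_a: SimDesign,
    design_b: SimDesign,
    n_pairs: int,
    conserved_fraction: float,
    jitter: float,
    *,
    threshold: float = 3.0,
    margin: float = 2.0,
    strength=50.0,
    n_atps_pairs: int = 0,
    seed: int = 0,
) -> OrthologStudy:
    """Two annotated replicons with one sense TPS per paired gene.

    A controllable fraction of pairs is positionally conserved: the site in
    gene B sits at D_B = D_A + U(-jitter, +jitter) after rounding to integer
    coordinates (re-drawn if rounding pushes |dD| past the threshold).
    Non-conserved pairs get independent positions rejection-sampled to
    |D_A - D_B| >= threshold + margin, so the planted conserved set is exactly
    the set recoverable under the criterion.  Optionally the first
    ``n_atps_pairs`` pairs also get one antisense TPS in each gene.
    """
    if not 0 <= conserved_fraction <= 1:
        raise ValueError("conserved_fraction must be in [0, 1]")
    if jitter >= threshold:
        raise ValueError(
            f"jitter ({jitter}) must be below the conservation threshold ({threshold}); "
            "otherwise the planted truth is ambiguous"
        )
    if design_a.replicon_id == design_b.replicon_id:
        raise ValueError("the two designs must use distinct replicon ids")
    genes_a = generate_annotation(design_a)
    genes_b = generate_annotation(design_b)
    if n_pairs > min(len(genes_a), len(genes_b)):
        raise ValueError(f"n_pairs={n_pairs} exceeds available genes")
    if n_atps_pairs > n_pairs:
        raise ValueError("n_atps_pairs cannot exceed n_pairs")
    rng = _rng(seed, 4)
    pairs = [
        OrthologPair(genes_a[i].locus_tag, genes_b[i].locus_tag) for i in range(n_pairs)
    ]
    n_cons = int(round(n_pairs * conserved_fraction))
    cons_idx = set(rng.choice(n_pairs, size=n_cons, replace=False).tolist()) if n_cons else set()

    def _coord(gene: GeneModel, d: float) -> int:
        sigma = 1 if gene.strand == "+" else -1
        return gene.x_cds_start + sigma * int(round(d / 100.0 * (gene.length - 1)))

    sites_a: list[SiteRecord] = []
    sites_b: list[SiteRecord] = []
    conserved_truth: list[ConservedTruth] = []
    for i in range(n_pairs):
        ga, gb = genes_a[i], genes_b[i]
        d_target_a = float(rng.uniform(5.0, 95.0))
        xa = _coord(ga, d_target_a)
        da = normalized_position(ga, xa)
        if i in cons_idx:
            for _ in range(1000):
                db_target = da + float(rng.uniform(-jitter, jitter))
                xb = _coord(gb, db_target)
                db = normalized_position(gb, xb)
                if abs(da - db) < threshold:
                    break
            else:  # pragma: no cover - cannot happen for sane gene lengths
                raise RuntimeError("failed to realize a conserved pair within threshold")
            conserved_truth.append(ConservedTruth(pairs[i], xa, xb, da, db))
        else:
            for _ in range(1000):
                db_target = float(rng.uniform(5.0, 95.0))
                xb = _coord(gb, db_target)
                db = normalized_position(gb, xb)
                if abs(da - db) >= threshold + margin:
                    break
            else:  # pragma: no cover
                raise RuntimeError("failed to place a non-conserved pair")
        mu_a = _draw_strength(strength, rng)
        mu_b = _draw_strength(strength, rng)
        sites_a.append(SiteRecord(ga.replicon, xa, ga.strand, KIND_TPS, mu_a, ga.locus_tag))
        sites_b.append(SiteRecord(gb.replicon, xb, gb.strand, KIND_TPS, mu_b, gb.locus_tag))

    atps_pairs: list[OrthologPair] = []
    for i in range(n_atps_pairs):
        ga, gb = genes_a[i], genes_b[i]
        for gene, bucket in ((ga, sites_a), (gb, sites_b)):
            anti = "-" if gene.strand == "+" else "+"
            pos = int(rng.integers(gene.start, gene.end + 1))
            bucket.append(
                SiteRecord(gene.replicon, pos, anti, KIND_TPS, _draw_strength(strength, rng), gene.locus_tag)
            )
        atps_pairs.append(pairs[i])

    return OrthologStudy(
        genes_a=genes_a,
        genes_b=genes_b,
        pairs=pairs,
        truth_a=SiteTruth(sites=sites_a, seed=seed),
        truth_b=SiteTruth(sites=sites_b, seed=seed),
        conserved=conserved_truth,
        atps_pairs=atps_pairs,
    )


# ---------------------------------------------------------------------------
# Ribo-seq coverage
# ---------------------------------------------------------------------------

def simulate_riboseq(
    genes: list[GeneModel],
    truth: SiteTruth,
    peak_fraction: float,
    *,
    peak_height: float = 50.0,
    base: float = 10.0,
    half_width: int = 15,
    seed: int = 0,
) -> tuple[CoverageTrack, list[int]]:
    """Unstranded coverage: ``base`` within each CDS (0 outside) plus a
    triangular peak of summit height ``peak_height`` centered at a randomly
    chosen ``peak_fraction`` of planted TPS.  Returns the track and the
    positions that received peaks."""
    if not 0 <= peak_fraction <= 1:
        raise ValueError("peak_fraction must be in [0, 1]")
    rng = _rng(seed, 5)
    dense_by_rep: dict[str, np.ndarray] = {}
    length_by_rep: dict[str, int] = {}
    for g in genes:
        length_by_rep[g.replicon] = max(length_by_rep.get(g.replicon, 0), g.end + half_width + 1)
    tps = [s for s in truth.sites if s.kind == KIND_TPS]
    for s in tps:
        length_by_rep[s.replicon] = max(length_by_rep.get(s.replicon, 0), s.position + half_width + 1)
    for rep, L in length_by_rep.items():
        dense_by_rep[rep] = np.zeros(L, dtype=float)
    for g in genes:
        dense_by_rep[g.replicon][g.start - 1:g.end] += base
    n_peaked = int(round(peak_fraction * len(tps)))
    order = rng.permutation(len(tps))[:n_peaked] if n_peaked else np.array([], dtype=int)
    peaked_positions: list[int] = []
    for idx in sorted(order.tolist()):
        s = tps[idx]
        dense = dense_by_rep[s.replicon]
        center = s.position - 1
        for o in range(-half_width, half_width + 1):
            j = center + o
            if 0 <= j < dense.shape[0]:
                dense[j] += peak_height * (1.0 - abs(o) / (half_width + 1))
        peaked_positions.append(s.position)
    cov = CoverageTrack(lengths={r: int(L) for r, L in length_by_rep.items()})
    for rep, dense in dense_by_rep.items():
        for idx in np.flatnonzero(dense):
            cov.add(rep, ".", int(idx + 1), float(dense[idx]))
    return cov, sorted(peaked_positions)


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

@dataclass
class Recovery:
    n_truth: int
    n_called: int
    true_positives: int

    @property
    def recall(self) -> float:
        return self.true_positives / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.true_positives / self.n_called if self.n_called else float("nan")


def match_sites(
    calls: list[TPSCall], truth: SiteTruth, kind: str = KIND_TPS, tolerance: int = 2
) -> Recovery:
    """Greedy one-to-one match of calls to planted sites of one kind within a
    positional tolerance (same replicon and strand)."""
    remaining: dict[tuple[str, str], list[int]] = {}
    for s in truth.of_kind(kind):
        remaining.setdefault((s.replicon, s.strand), []).append(s.position)
    n_truth = sum(len(v) for v in remaining.values())
    tp = 0
    for c in sorted(calls, key=lambda c: (c.replicon, c.strand, c.position)):
        pool = remaining.get((c.replicon, c.strand), [])
        best = None
        for j, pos in enumerate(pool):
            d = abs(pos - c.position)
            if d <= tolerance and (best is None or d < abs(pool[best] - c.position)):
                best = j
        if best is not None:
            pool.pop(best)
            tp += 1
    return Recovery(n_truth=n_truth, n_called=len(calls), true_positives=tp)
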