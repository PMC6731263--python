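"""Genome compactness and density statistics.

Covers the headline descriptive numbers of a small, gene-dense genome:
variant density (per kb and as percent divergence), per-region-class
variant densities with fold ratios, gene/intron summary statistics,
the fraction of genes expressed above an RNA-seq exon-depth threshold,
GC-anomaly window scans, telomere-repeat detection at chromosome ends,
and shared-protein (Venn) arithmetic against a panel of other genomes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

# Region-class codes used in RegionClassMap arrays.
CODING = 0
INTRON = 1
INTERGENIC = 2
CLASS_NAMES = {CODING: "coding", INTRON: "intron", INTERGENIC: "intergenic"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A protein-coding gene: its span, strand and exon structure.

    Coordinates are 1-based inclusive.  Introns are derived as the gaps
    between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ParameterError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.end < self.start:
            raise ParameterError(f"gene {self.gene_id}: end < start")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e < s or s < self.start or e > self.end:
                raise ParameterError(f"gene {self.gene_id}: exon ({s},{e}) outside span")
            if prev_end is not None and s <= prev_end:
                raise ParameterError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


class RegionClassMap:
    """Per-chromosome partition of every base into coding / intron / intergenic.

    Stored as one ``int8`` array per chromosome (index 0 = position 1).
    The three classes are disjoint and cover each chromosome by construction.
    """

    def __init__(self, class_arrays: Mapping[str, np.ndarray]):
        self.arrays: dict[str, np.ndarray] = {}
        for chrom, arr in class_arrays.items():
            arr = np.asarray(arr, dtype=np.int8)
            if arr.ndim != 1 or not np.isin(arr, list(CLASS_NAMES)).all():
                raise ParameterError(f"{chrom}: class array is not a partition into known classes")
            self.arrays[chrom] = arr

    @classmethod
    def from_genes(cls, chrom_lengths: Mapping[str, int], genes: Iterable[GeneModel]) -> "RegionClassMap":
        arrays = {c: np.full(length, INTERGENIC, dtype=np.int8) for c, length in chrom_lengths.items()}
        for g in genes:
            arr = arrays[g.chrom]
            for s, e in g.introns:
                arr[s - 1 : e] = INTRON
            for s, e in g.exons:
                arr[s - 1 : e] = CODING
        return cls(arrays)

    def class_at(self, chrom: str, pos: int) -> int:
        """Class code at a 1-based position."""
        return int(self.arrays[chrom][pos - 1])

    def span_bp(self) -> dict[str, int]:
        """Total bases per class over all chromosomes."""
        out = {name: 0 for name in CLASS_NAMES.values()}
        for arr in self.arrays.values():
            counts = np.bincount(arr, minlength=3)
            for code, name in CLASS_NAMES.items():
                out[name] += int(counts[code])
        return out


def _sites_frame(sites) -> pd.DataFrame:
    """Coerce a site collection (DataFrame or VariantSite list) to a frame."""
    if isinstance(sites, pd.DataFrame):
        return sites
    rows = [(s.chrom, s.pos) for s in sites]
    return pd.DataFrame(rows, columns=["chrom", "pos"])


@dataclass(frozen=True)
class DensityResult:
    per_kb: float
    pct_divergence: float


def variant_density(n_sites: int, span_bp: int) -> DensityResult:
    """Variant density over a span: sites per kb and percent divergence.

    ``per_kb = n / (span/1000)``; ``pct_divergence = 100 * n / span``.
    """
    if span_bp <= 0:
        raise ParameterError("span must be positive")
    return DensityResult(n_sites / (span_bp / 1000.0), 100.0 * n_sites / span_bp)


def chromosome_densities(sites, chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Per-chromosome variant counts and densities (sites per kb)."""
    frame = _sites_frame(sites)
    counts = frame.groupby("chrom").size() if len(frame) else pd.Series(dtype=int)
    rows = []
    for chrom, length in chrom_lengths.items():
        n = int(counts.get(chrom, 0))
        rows.append((chrom, length, n, n / (length / 1000.0)))
    return pd.DataFrame(rows, columns=["chrom", "length", "n_sites", "per_kb"])


def density_by_class(sites, class_map: RegionClassMap) -> pd.DataFrame:
    """Variant density per region class, with fold ratios relative to coding.

    Each site is assigned to exactly one class — the class of its 1-based
    start position.  The returned frame has one row per class plus
    ``fold_vs_coding`` (``inf`` when the coding density is zero).
    """
    frame = _sites_frame(sites)
    counts = {name: 0 for name in CLASS_NAMES.values()}
    for chrom, pos in zip(frame["chrom"], frame["pos"]):
        counts[CLASS_NAMES[class_map.class_at(chrom, int(pos))]] += 1
    spans = class_map.span_bp()
    rows = []
    for name in CLASS_NAMES.values():
        span = spans[name]
        dens = counts[name] / (span / 1000.0) if span else math.nan
        rows.append((name, counts[name], span, dens))
    out = pd.DataFrame(rows, columns=["region_class", "n_sites", "span_bp", "per_kb"])
    coding = float(out.loc[out.region_class == "coding", "per_kb"].iloc[0])
    folds = []
    for dens in out["per_kb"]:
        folds.append(math.inf if coding == 0 else dens / coding)
    out["fold_vs_coding"] = folds
    return out


@dataclass(frozen=True)
class GeneStats:
    genes_per_kb: float
    introns_per_gene: float
    mean_intron_length: float | None


def gene_stats(genes: Sequence[GeneModel], genome_length: int) -> GeneStats:
    """Gene density per kb, introns per gene and mean intron length.

    Mean intron length is ``None`` for an intronless gene set.
    """
    if not genes:
        raise ParameterError("need at least one gene")
    intron_lengths = [e - s + 1 for g in genes for s, e in g.introns]
    mean_len = float(np.mean(intron_lengths)) if intron_lengths else None
    return GeneStats(
        genes_per_kb=len(genes) / (genome_length / 1000.0),
        introns_per_gene=len(intron_lengths) / len(genes),
        mean_intron_length=mean_len,
    )


@dataclass(frozen=True)
class ExpressionSummary:
    n_expressed: int
    n_genes: int
    percent: float


def expression_fraction(
    exon_depth: Mapping[str, np.ndarray],
    genes: Sequence[GeneModel],
    threshold: float = 1.0,
) -> ExpressionSummary:
    """Count genes whose mean RNA-seq depth over all exon bases is >= threshold.

    ``exon_depth`` maps chromosome -> per-base depth array (index 0 =
    position 1); positions beyond the array are treated as depth 0.
    """
    n_expr = 0
    for g in genes:
        if g.exon_length == 0:
            raise ParameterError(f"gene {g.gene_id} has zero exon length")
        track = np.asarray(exon_depth.get(g.chrom, ()), dtype=float)
        total = 0.0
        for s, e in g.exons:
            lo, hi = s - 1, e  # clip to the available track; missing = 0
            if lo < len(track):
                total += float(track[lo : min(hi, len(track))].sum())
        if total / g.exon_length >= threshold:
            n_expr += 1
    return ExpressionSummary(n_expr, len(genes), 100.0 * n_expr / len(genes))


def gc_anomaly_windows(
    sequence: str,
    window: int = 1000,
    step: int = 500,
    low: float = 0.48,
    high: float = 0.70,
) -> tuple[pd.DataFrame, list[tuple[int, int, str]]]:
    """Sliding-window GC scan flagging windows outside [low, high].

    Ns are excluded from both numerator and denominator; windows with more
    than 50% N are reported as ``no-data`` and never flagged.  Adjacent or
    overlapping flagged windows of the same polarity merge into intervals
    (0-based half-open).  Case-insensitive.
    """
    if window < step:
        raise ParameterError("window must be >= step")
    codes = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    is_gc = (codes == ord("G")) | (codes == ord("C"))
    is_n = ~np.isin(codes, np.frombuffer(b"ACGT", dtype=np.uint8))
    rows = []
    for start in range(0, max(len(codes), 1), step):
        end = min(start + window, len(codes))
        if start >= len(codes):
            break
        n_n = int(is_n[start:end].sum())
        denom = (end - start) - n_n
        if n_n > (end - start) / 2 or denom == 0:
            rows.append((start, end, math.nan, "no-data"))
        else:
            gc = float(is_gc[start:end].sum()) / denom
            flag = "low" if gc < low else "high" if gc > high else ""
            rows.append((start, end, gc, flag))
        if end == len(codes):
            break
    track = pd.DataFrame(rows, columns=["start", "end", "gc", "flag"])
    intervals: list[tuple[int, int, str]] = []
    for _, row in track.iterrows():
        if row.flag not in ("low", "high"):
            continue
        if intervals and intervals[-1][2] == row.flag and row.start <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], int(row.end), row.flag)
        else:
            intervals.append((int(row.start), int(row.end), row.flag))
    return track, intervals


@dataclass(frozen=True)
class TelomereHit:
    present: bool
    copies: int


def _max_tandem_run(seq: str, unit: str, max_mismatch: int) -> int:
    """Longest run of consecutive unit copies (each with <= max_mismatch)."""
    u = len(unit)
    best = 0
    for offset in range(len(seq) - u + 1):
        run = 0
        i = offset
        while i + u <= len(seq):
            mism = sum(a != b for a, b in zip(seq[i : i + u], unit))
            if mism > max_mismatch:
                break
            run += 1
            i += u
        best = max(best, run)
    return best


def detect_telomeres(
    sequence: str,
    unit: str = "CCTAAAAA",
    min_copies: int = 3,
    search_span: int = 1000,
    max_mismatch: int = 0,
) -> dict[str, TelomereHit]:
    """Detect telomeric repeat arrays at both chromosome ends.

    The 5' end is scanned for tandem copies of ``unit`` within the first
    ``search_span`` bases; the 3' end for tandem copies of the reverse
    complement within the last ``search_span`` bases (the repeat sits on
    the opposite strand there).  Exact match by default.
    """
    seq = sequence.upper()
    head = seq[:search_span]
    tail = seq[-search_span:] if len(seq) >= search_span else seq
    five = _max_tandem_run(head, unit.upper(), max_mismatch)
    three = _max_tandem_run(revcomp(tail), unit.upper(), max_mismatch)
    return {
        "five_prime": TelomereHit(five >= min_copies, five),
        "three_prime": TelomereHit(three >= min_copies, three),
    }


@dataclass(frozen=True)
class SharedProteinSummary:
    n_total: int
    n_shared: int
    n_unique: int
    shared_percent: float


def shared_protein_summary(
    total_ids: Iterable[str],
    shared_sets: Mapping[str, Iterable[str]],
) -> SharedProteinSummary:
    """Venn arithmetic: proteins shared with at least one other genome.

    ``shared percent = 100 * |union of shared sets| / |total|``;
    every shared set must be a subset of the total id set.
    """
    total = set(total_ids)
    if not total:
        raise ParameterError("empty protein set")
    union: set[str] = set()
    for name, ids in shared_sets.items():
        ids = set(ids)
        extra = ids - total
        if extra:
            raise ParameterError(f"shared set {name!r} has ids outside the total set: {sorted(extra)[:3]}")
        union |= ids
    return SharedProteinSummary(
        n_total=len(total),
        n_shared=len(union),
        n_unique=len(total) - len(union),
        shared_percent=100.0 * len(union) / len(total),
    )


def read_gff3(path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GFF3 file."""
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = fields["ID"]
                genes[gid] = GeneModel(gid, chrom, strand, int(start), int(end), exons=[])
            elif ftype == "exon":
                exons.setdefault(fields["Parent"], []).append((int(start), int(end)))
    out = []
    for gid, g in genes.items():
        out.append(GeneModel(gid, g.chrom, g.strand, g.start, g.end, exons=exons.get(gid, [])))
    return out
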