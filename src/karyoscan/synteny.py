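"""Gap-tolerant microsynteny block detection between two gene orders.

Two orthologous genes form an anchor; consecutive anchors link when (i)
both members sit on a single contig in each genome, (ii) no more than k
genes are interspersed between them in either genome, and (iii) the two
anchors share the same relative orientation.  Links chain transitively
into maximal blocks, reported separately as collinear (same strand in
both genomes, order preserved) or inverted (opposite strands, order
reversed).  Larger gap tolerances can only add links, so block sizes are
monotone non-decreasing in k.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ParameterError

COLLINEAR = "collinear"
INVERTED = "inverted"


@dataclass
class GeneOrder:
    """Ordered genes per contig of one genome: contig -> [(gene_id, strand)]."""

    genome_id: str
    contigs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for contig, genes in self.contigs.items():
            for gene, strand in genes:
                if strand not in "+-":
                    raise ParameterError(f"{self.genome_id}/{contig}: bad strand {strand!r}")
                if gene in seen:
                    raise ParameterError(f"{self.genome_id}: duplicate gene id {gene!r}")
                seen.add(gene)

    def locate(self) -> dict[str, tuple[str, int, str]]:
        """gene id -> (contig, index within contig, strand)."""
        out = {}
        for contig, genes in self.contigs.items():
            for i, (gene, strand) in enumerate(genes):
                out[gene] = (contig, i, strand)
        return out


@dataclass(frozen=True)
class Anchor:
    """One ortholog pair with its coordinates in both genomes."""

    gene_a: str
    gene_b: str
    contig_a: str
    idx_a: int
    contig_b: str
    idx_b: int
    rel: int  # +1 same strand in both genomes, -1 opposite


@dataclass(frozen=True)
class Link:
    """A gap-tolerant adjacency between two anchors (ordered along genome A)."""

    left: Anchor
    right: Anchor
    orientation: str  # collinear | inverted


@dataclass
class SyntenyBlock:
    """A maximal run of linked ortholog pairs under gap tolerance k."""

    contig_a: str
    contig_b: str
    pairs: list[tuple[str, str]]
    orientation: str
    gap_tolerance: int

    @property
    def size(self) -> int:
        return len(self.pairs)


def _check_one_to_one(orthology: Mapping[str, str]) -> None:
    targets: dict[str, str] = {}
    for a, b in orthology.items():
        if b in targets:
            raise ParameterError(
                f"orthology is not one-to-one: {a!r} and {targets[b]!r} both map to {b!r}; "
                "collapse many-to-many rows to best hits upstream"
            )
        targets[b] = a


def anchors(
    order_a: GeneOrder, order_b: GeneOrder, orthology: Mapping[str, str]
) -> list[Anchor]:
    """Ortholog anchors present in both genomes, sorted along genome A."""
    _check_one_to_one(orthology)
    loc_a, loc_b = order_a.locate(), order_b.locate()
    out = []
    for gene_a, gene_b in orthology.items():
        if gene_a not in loc_a or gene_b not in loc_b:
            continue
        ca, ia, sa = loc_a[gene_a]
        cb, ib, sb = loc_b[gene_b]
        out.append(Anchor(gene_a, gene_b, ca, ia, cb, ib, +1 if sa == sb else -1))
    out.sort(key=lambda x: (x.contig_a, x.idx_a))
    return out


def _compatible(left: Anchor, right: Anchor, k: int) -> str | None:
    """Orientation label if two A-ordered anchors link under gap tolerance k."""
    if left.contig_a != right.contig_a or left.contig_b != right.contig_b:
        return None
    if right.idx_a - left.idx_a - 1 > k:
        return None
    if abs(right.idx_b - left.idx_b) - 1 > k:
        return None
    if left.rel != right.rel:
        return None
    if left.rel == +1 and right.idx_b > left.idx_b:
        return COLLINEAR
    if left.rel == -1 and right.idx_b < left.idx_b:
        return INVERTED
    return None


def find_shared_pairs(
    order_a: GeneOrder,
    order_b: GeneOrder,
    orthology: Mapping[str, str],
    k: int = 0,
) -> list[Link]:
    """Links between anchors adjacent along genome A under gap tolerance k.

    Adjacent means no other anchor lies between them on the shared
    contigs; interspersed non-ortholog genes count toward the gap in
    each genome.
    """
    if k < 0:
        raise ParameterError("gap tolerance must be >= 0")
    anc = anchors(order_a, order_b, orthology)
    links = []
    for left, right in zip(anc, anc[1:]):
        orient = _compatible(left, right, k)
        if orient is not None:
            links.append(Link(left, right, orient))
    return links


def chain_blocks(links: Sequence[Link], k: int = 0) -> list[SyntenyBlock]:
    """Chain links transitively into maximal same-orientation blocks."""
    blocks: list[SyntenyBlock] = []
    current: SyntenyBlock | None = None
    last_anchor: Anchor | None = None
    for link in links:
        extend = (
            current is not None
            and last_anchor is link.left
            and current.orientation == link.orientation
        )
        if extend:
            current.pairs.append((link.right.gene_a, link.right.gene_b))
        else:
            current = SyntenyBlock(
                link.left.contig_a,
                link.left.contig_b,
                [(link.left.gene_a, link.left.gene_b), (link.right.gene_a, link.right.gene_b)],
                link.orientation,
                k,
            )
            blocks.append(current)
        last_anchor = link.right
    return blocks


def synteny_blocks(
    order_a: GeneOrder,
    order_b: GeneOrder,
    orthology: Mapping[str, str],
    k: int = 0,
) -> list[SyntenyBlock]:
    """Convenience: find_shared_pairs then chain_blocks."""
    return chain_blocks(find_shared_pairs(order_a, order_b, orthology, k), k)


def largest_block_size(blocks: Sequence[SyntenyBlock]) -> int:
    return max((b.size for b in blocks), default=0)


def block_size_distribution(blocks: Sequence[SyntenyBlock]) -> pd.Series:
    """Counts of blocks by size (pairs per block)."""
    return pd.Series([b.size for b in blocks], dtype=int).value_counts().sort_index()


def colocalization_matrix(
    order_a: GeneOrder, order_b: GeneOrder, orthology: Mapping[str, str]
) -> pd.DataFrame:
    """Contig-by-contig shared-ortholog counts.

    Entry (i, j) = number of ortholog pairs whose A member lies on
    contig i and whose B member lies on contig j; row sums equal the
    per-contig ortholog counts.
    """
    _check_one_to_one(orthology)
    loc_a, loc_b = order_a.locate(), order_b.locate()
    mat = pd.DataFrame(
        0, index=sorted(order_a.contigs), columns=sorted(order_b.contigs), dtype=int
    )
    for gene_a, gene_b in orthology.items():
        if gene_a in loc_a and gene_b in loc_b:
            mat.loc[loc_a[gene_a][0], loc_b[gene_b][0]] += 1
    return mat


def read_orthology_tsv(path) -> dict[str, str]:
    """Two-column TSV (idA, idB) -> one-to-one mapping; duplicates rejected."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str)
    if frame["a"].duplicated().any() or frame["b"].duplicated().any():
        raise ParameterError("orthology table is not one-to-one; pre-filter to best hits")
    return dict(zip(frame["a"], frame["b"]))


def gene_order_from_gff(genome_id: str, genes) -> GeneOrder:
    """Build a GeneOrder from GeneModel records, ordered by start per chromosome."""
    contigs: dict[str, list[tuple[str, str]]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        contigs.setdefault(g.chrom, []).append((g.gene_id, g.strand))
    return GeneOrder(genome_id, contigs)


def write_blocks_tsv(blocks: Sequence[SyntenyBlock], path) -> None:
    rows = [
        (b.contig_a, b.contig_b, b.size, b.orientation, b.gap_tolerance,
         ";".join(f"{a}|{bb}" for a, bb in b.pairs))
        for b in blocks
    ]
    pd.DataFrame(
        rows, columns=["contig_a", "contig_b", "size", "orientation", "k", "pairs"]
    ).to_csv(path, sep="\t", index=False)
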