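"""Synthetic diploid-genome generator with planted heterozygosity and aneuploidy.

Emulates the sequencing structure of a small, compact, mostly-diploid
algal genome: ~20 chromosomes with telomeric repeat arrays at both ends,
dense non-overlapping gene models (about half a gene per kb, half an
intron per gene averaging ~150 bp), heterozygous SNP/indel sites planted
at class-specific densities (lower in coding sequence than in introns
and intergenic DNA), one optional trisomic chromosome, optional
contiguous skewed-allele segments (allele copies at e.g. 1:2 on a
two-copy chromosome), and organelle contigs at elevated cellular copy
number.

Read evidence is simulated at the pileup level: per-site depth is
Poisson with mean = haploid baseline x copy number (negative-binomial
overdispersion available but off by default), and the alternate-allele
count is Binomial(depth, alt copies / total copies).  No read-level
artifacts (FASTQ, mapping, qualities) are modeled.

Every output is a deterministic function of ``GenomeSpec.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .stats import CODING, INTERGENIC, INTRON, GeneModel, RegionClassMap, revcomp
from .synteny import GeneOrder

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _roman(n: int) -> str:
    numerals = [(50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = ""
    for value, sym in numerals:
        while n >= value:
            out += sym
            n -= value
    return out


@dataclass(frozen=True)
class SkewedSegmentSpec:
    """A planted interval whose sites use skewed allele-copy configurations.

    ``configs`` lists (alt copies, total copies) drawn uniformly per site,
    e.g. ((1, 3), (2, 3)) for a 1:2 allelic-ratio segment.
    Coordinates are 1-based inclusive.
    """

    chrom: str
    start: int
    end: int
    configs: tuple[tuple[int, int], ...] = ((1, 3), (2, 3))

    def __post_init__(self):
        if self.end <= self.start or self.start < 1:
            raise ParameterError(f"skewed segment {self.chrom}:{self.start}-{self.end} malformed")
        for alt, total in self.configs:
            if not (0 < alt < total):
                raise ParameterError("segment allele config must be heterozygous (0 < alt < total)")


@dataclass(frozen=True)
class OrganelleSpec:
    name: str
    length: int
    copies: int

    def __post_init__(self):
        if self.length <= 0 or self.copies < 1:
            raise ParameterError(f"organelle {self.name}: bad length/copies")


@dataclass
class GenomeSpec:
    """Parameters of one synthetic genome; ``seed`` fixes all outputs bit-for-bit.

    Defaults mirror the study conditions: 57.5% GC, CCTAAAAA telomeric
    unit, 0.50 gene/kb with 0.5 intron (152 bp) per gene, heterozygous
    sites ~3.6-3.8-fold denser outside coding sequence (about 0.5
    variants/kb genome-wide at ~74% coding fraction), and a 36.5x
    haploid depth baseline (73x for a two-copy chromosome).
    """

    chromosome_lengths: Sequence[int]
    copy_numbers: Sequence[int] | None = None
    gc: float = 0.575
    telomere_unit: str = "CCTAAAAA"
    telomere_copies: int = 10
    gene_density: float = 0.50          # genes per kb
    gene_length_mean: float = 1500.0
    gene_length_sd: float = 300.0
    introns_per_gene: float = 0.5       # Poisson mean
    intron_length_mean: float = 152.0
    intron_length_sd: float = 30.0
    het_density: Mapping[str, float] = field(
        default_factory=lambda: {"coding": 0.30, "intron": 1.14, "intergenic": 1.08}
    )
    indel_fraction: float = 0.22
    skewed_segments: Sequence[SkewedSegmentSpec] = ()
    organelles: Sequence[OrganelleSpec] = ()
    haploid_depth: float = 36.5         # x per copy; diploid mean = 2x this
    error_rate: float = 0.0
    overdispersion: float | None = None  # negative-binomial size; None = Poisson
    seed: int = 0

    def __post_init__(self):
        self.chromosome_lengths = [int(x) for x in self.chromosome_lengths]
        if not self.chromosome_lengths or any(x <= 0 for x in self.chromosome_lengths):
            raise ParameterError("chromosome lengths must be positive")
        if self.copy_numbers is None:
            self.copy_numbers = [2] * len(self.chromosome_lengths)
        self.copy_numbers = [int(c) for c in self.copy_numbers]
        if len(self.copy_numbers) != len(self.chromosome_lengths):
            raise ParameterError("copy_numbers length mismatch")
        if any(c < 1 for c in self.copy_numbers):
            raise ParameterError("copy numbers must be >= 1")
        if not (0.0 <= self.gc <= 1.0):
            raise ParameterError("gc must be in [0, 1]")
        if any(d < 0 for d in self.het_density.values()):
            raise ParameterError("heterozygous densities must be >= 0")
        if self.gene_density < 0 or self.haploid_depth < 0:
            raise ParameterError("densities and depth must be >= 0")
        names = set(self.chrom_names)
        for seg in self.skewed_segments:
            if seg.chrom not in names:
                raise ParameterError(f"skewed segment on unknown chromosome {seg.chrom}")
            length = dict(zip(self.chrom_names, self.chromosome_lengths))[seg.chrom]
            if seg.end > length:
                raise ParameterError(f"skewed segment {seg.chrom}:{seg.start}-{seg.end} exceeds chromosome")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{_roman(i + 1)}" for i in range(len(self.chromosome_lengths))]

    @property
    def chrom_lengths_map(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chromosome_lengths))

    @property
    def copy_map(self) -> dict[str, int]:
        out = dict(zip(self.chrom_names, self.copy_numbers))
        for org in self.organelles:
            out[org.name] = org.copies
        return out

    @classmethod
    def study_like(
        cls,
        scale: float = 1.0,
        trisomic: int | None = 16,
        skewed: bool = True,
        seed: int = 0,
        **overrides,
    ) -> "GenomeSpec":
        """A 20-chromosome genome shaped like the study system.

        Chromosome lengths interpolate 1.88 -> 0.37 Mb (scaled by
        ``scale``); chromosome 17 (index 16) is trisomic by default, and
        chromosome 4 carries a skewed segment sized ~44% of its length.
        """
        lengths = [int(round(x * scale)) for x in np.linspace(1_880_000, 370_000, 20)]
        copies = [2] * 20
        if trisomic is not None:
            copies[trisomic] = 3
        names = [f"chr{_roman(i + 1)}" for i in range(20)]
        segs = []
        if skewed:
            ch4 = lengths[3]
            segs = [SkewedSegmentSpec(names[3], int(ch4 * 0.1) + 1, int(ch4 * 0.54))]
        organelles = (OrganelleSpec("plastome", 64_300, 12), OrganelleSpec("mitogenome", 37_900, 7))
        return cls(
            chromosome_lengths=lengths, copy_numbers=copies, skewed_segments=segs,
            organelles=organelles, seed=seed, **overrides,
        )


@dataclass
class TruthTable:
    """Ground truth of a simulated genome: planted variants, segments, copies."""

    variants: pd.DataFrame  # chrom,pos,ref,alt,vtype,region_class,alt_copies,total_copies
    segments: list[SkewedSegmentSpec]
    copy_numbers: dict[str, int]

    def __post_init__(self):
        if len(self.variants):
            if (self.variants["alt_copies"] >= self.variants["total_copies"]).any():
                raise ParameterError("truth variants must be heterozygous (alt < total copies)")


@dataclass
class Reference:
    """Generated sequences plus gene annotation and region-class partition."""

    sequences: dict[str, str]
    genes: list[GeneModel]
    class_map: RegionClassMap
    organelle_names: list[str]


TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "vtype", "region_class", "alt_copies", "total_copies"]
_CLASS_NAME = {CODING: "coding", INTRON: "intron", INTERGENIC: "intergenic"}


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _place_genes(
    rng: np.random.Generator, chrom: str, length: int, usable: tuple[int, int], spec: GenomeSpec
) -> list[GeneModel]:
    """Place non-overlapping gene models at the requested density."""
    n_genes = int(round(spec.gene_density * length / 1000.0))
    if n_genes == 0:
        return []
    structures = []
    for _ in range(n_genes):
        coding = max(300, int(round(rng.normal(spec.gene_length_mean, spec.gene_length_sd))))
        n_introns = rng.poisson(spec.introns_per_gene)
        intron_lens = [
            max(40, int(round(rng.normal(spec.intron_length_mean, spec.intron_length_sd))))
            for _ in range(n_introns)
        ]
        structures.append((coding, intron_lens))
    total_span = sum(c + sum(il) for c, il in structures)
    lo, hi = usable
    free = (hi - lo) - total_span
    if free < n_genes + 1:
        raise ParameterError(
            f"{chrom}: gene density {spec.gene_density}/kb unachievable in {hi - lo} usable bp"
        )
    gaps = rng.multinomial(free, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    genes = []
    cursor = lo
    for gi, (coding, intron_lens) in enumerate(structures):
        cursor += int(gaps[gi])
        start = cursor + 1  # 1-based
        span = coding + sum(intron_lens)
        n_introns = len(intron_lens)
        if n_introns:
            cuts = np.sort(rng.choice(np.arange(1, coding), size=n_introns, replace=False))
            exon_lens = np.diff(np.concatenate([[0], cuts, [coding]])).tolist()
        else:
            exon_lens = [coding]
        exons = []
        pos = start
        for ei, elen in enumerate(exon_lens):
            exons.append((pos, pos + elen - 1))
            pos += elen
            if ei < n_introns:
                pos += intron_lens[ei]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"{chrom}.g{gi + 1}", chrom, strand, start, start + span - 1, exons))
        cursor += span
    return genes


def _plant_variants(
    rng: np.random.Generator,
    chrom: str,
    seq: np.ndarray,
    classes: np.ndarray,
    copy_number: int,
    spec: GenomeSpec,
) -> list[tuple]:
    """Draw heterozygous sites at class-specific densities along one chromosome."""
    thresh = np.zeros(3)
    for code, name in _CLASS_NAME.items():
        thresh[code] = spec.het_density.get(name, 0.0) / 1000.0
    u = rng.random(len(seq))
    positions0 = np.nonzero(u < thresh[classes])[0]
    segs = [s for s in spec.skewed_segments if s.chrom == chrom]
    rows = []
    for pos0 in positions0:
        if pos0 >= len(seq) - 4:  # leave room for deletion alleles near the end
            continue
        ref_base = chr(seq[pos0])
        in_seg = next((s for s in segs if s.start - 1 <= pos0 <= s.end - 1), None)
        if in_seg is not None:
            alt_c, total_c = in_seg.configs[rng.integers(len(in_seg.configs))]
        else:
            total_c = copy_number
            alt_c = 1 if total_c == 2 else int(rng.integers(1, total_c))
        if rng.random() >= spec.indel_fraction:
            others = [b for b in "ACGT" if b != ref_base]
            alt = others[rng.integers(3)]
            ref, vtype = ref_base, "SNP"
        else:
            ins_len = int(rng.integers(1, 4))
            piece = "".join(chr(_BASES[i]) for i in rng.integers(0, 4, size=ins_len))
            if rng.random() < 0.5:
                ref, alt = ref_base, ref_base + piece
            else:
                deleted = "".join(chr(b) for b in seq[pos0 + 1 : pos0 + 1 + ins_len])
                ref, alt = ref_base + deleted, ref_base
            vtype = "indel"
        rows.append(
            (chrom, int(pos0) + 1, ref, alt, vtype, _CLASS_NAME[int(classes[pos0])], alt_c, total_c)
        )
    return rows


def generate_reference(spec: GenomeSpec) -> tuple[Reference, TruthTable]:
    """Generate chromosome + organelle sequences, annotations and planted truth.

    Telomeric units tile both chromosome ends (reverse complement at the
    3' end); gene models are placed without overlap between the telomere
    blocks; the region-class map partitions every chromosome into
    coding/intron/intergenic; the truth table records every planted
    heterozygous site with its allele-copy configuration.
    """
    rng = np.random.default_rng([spec.seed, 0])
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    class_arrays: dict[str, np.ndarray] = {}
    truth_rows: list[tuple] = []
    telo = (spec.telomere_unit * spec.telomere_copies).upper()
    for chrom, length, copies in zip(spec.chrom_names, spec.chromosome_lengths, spec.copy_numbers):
        seq = _random_sequence(rng, length, spec.gc)
        if length < 2 * len(telo) + 1000:
            raise ParameterError(f"{chrom}: too short for telomere arrays plus a usable interior")
        head = np.frombuffer(telo.encode(), dtype=np.uint8)
        tail = np.frombuffer(revcomp(telo).encode(), dtype=np.uint8)
        seq[: len(head)] = head
        seq[-len(tail):] = tail
        usable = (len(head), length - len(tail))
        chrom_genes = _place_genes(rng, chrom, length, usable, spec)
        genes.extend(chrom_genes)
        classes = np.full(length, INTERGENIC, dtype=np.int8)
        for g in chrom_genes:
            for s, e in g.introns:
                classes[s - 1 : e] = INTRON
            for s, e in g.exons:
                classes[s - 1 : e] = CODING
        class_arrays[chrom] = classes
        truth_rows.extend(_plant_variants(rng, chrom, seq, classes, copies, spec))
        sequences[chrom] = seq.tobytes().decode()
    organelle_names = []
    for org in spec.organelles:
        sequences[org.name] = _random_sequence(rng, org.length, spec.gc).tobytes().decode()
        organelle_names.append(org.name)
    variants = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    reference = Reference(sequences, genes, RegionClassMap(class_arrays), organelle_names)
    truth = TruthTable(variants, list(spec.skewed_segments), spec.copy_map)
    return reference, truth


def _draw_depth(rng: np.random.Generator, mean: float, size: int, overdispersion: float | None):
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if overdispersion is None:
        return rng.poisson(mean, size=size)
    theta = overdispersion
    return rng.negative_binomial(theta, theta / (theta + mean), size=size)


@dataclass
class PileupResult:
    """Simulated read evidence: pileup rows, windowed depth track, chrom means."""

    pileup: pd.DataFrame                 # chrom,pos,ref,depth,counts
    depth_track: pd.DataFrame            # chrom,start,end,mean_depth (half-open)
    chrom_mean_depth: dict[str, float]


def _variant_counts(rng, ref, alt, vtype, depth, p_alt, error_rate) -> tuple[str, dict]:
    alt_n = int(rng.binomial(depth, p_alt)) if depth > 0 else 0
    ref_n = depth - alt_n
    if error_rate > 0 and ref_n > 0:
        err = int(rng.binomial(ref_n, error_rate))
        ref_n -= err
    if vtype == "SNP":
        key = alt
    elif len(alt) > len(ref):
        key = "+" + alt[1:]
    else:
        key = "-" + ref[1:]
    ref_base = ref[0]
    return ref_base, {ref_base: ref_n, key: alt_n}


def simulate_pileup(
    reference: Reference,
    truth: TruthTable,
    spec: GenomeSpec,
    include_invariant: bool = False,
    depth_window: int = 1000,
) -> PileupResult:
    """Simulate per-site allele counts and a windowed depth track.

    Per-site depth ~ Poisson(haploid baseline x copy number); alternate
    count ~ Binomial(depth, alt copies / total copies).  With
    ``include_invariant`` every base emits a reference-only row (costly:
    one row per base); otherwise only planted sites appear in the pileup
    while the depth track still covers the whole genome.  Windowed depth
    uses the Poisson-sum identity (a window's total read-base count is
    Poisson with the summed mean), which is distributionally identical
    to summing per-base draws.
    """
    rng = np.random.default_rng([spec.seed, 1])
    rows: list[tuple] = []
    track_rows: list[tuple] = []
    chrom_mean: dict[str, float] = {}
    variants = truth.variants
    for chrom, seq in reference.sequences.items():
        length = len(seq)
        copies = truth.copy_numbers.get(chrom, 2)
        mean = spec.haploid_depth * copies
        sub = variants[variants["chrom"] == chrom] if len(variants) else variants
        if include_invariant:
            depth_arr = _draw_depth(rng, mean, length, spec.overdispersion)
            var_pos = set(sub["pos"]) if len(sub) else set()
            var_rows = {int(r.pos): r for r in sub.itertuples(index=False)} if len(sub) else {}
            for pos0 in range(length):
                pos = pos0 + 1
                depth = int(depth_arr[pos0])
                if pos in var_pos:
                    r = var_rows[pos]
                    ref_base, counts = _variant_counts(
                        rng, r.ref, r.alt, r.vtype, depth, r.alt_copies / r.total_copies,
                        spec.error_rate,
                    )
                else:
                    ref_base, counts = seq[pos0], {seq[pos0]: depth}
                rows.append((chrom, pos, ref_base,
                             depth, ",".join(f"{a}:{n}" for a, n in counts.items())))
            starts = np.arange(0, length, depth_window)
            for s in starts:
                e = min(s + depth_window, length)
                track_rows.append((chrom, int(s), int(e), float(depth_arr[s:e].mean())))
            chrom_mean[chrom] = float(depth_arr.mean())
        else:
            depths = _draw_depth(rng, mean, len(sub), spec.overdispersion)
            for r, depth in zip(sub.itertuples(index=False), depths):
                ref_base, counts = _variant_counts(
                    rng, r.ref, r.alt, r.vtype, int(depth), r.alt_copies / r.total_copies,
                    spec.error_rate,
                )
                rows.append((chrom, int(r.pos), ref_base, int(depth),
                             ",".join(f"{a}:{n}" for a, n in counts.items())))
            starts = np.arange(0, length, depth_window)
            widths = np.minimum(starts + depth_window, length) - starts
            totals = rng.poisson(mean * widths) if spec.overdispersion is None else np.array(
                [_draw_depth(rng, mean * w, 1, spec.overdispersion)[0] for w in widths]
            )
            means = totals / widths
            for s, w, m in zip(starts, widths, means):
                track_rows.append((chrom, int(s), int(s + w), float(m)))
            chrom_mean[chrom] = float(totals.sum() / widths.sum())
    pileup = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "depth", "counts"])
    track = pd.DataFrame(track_rows, columns=["chrom", "start", "end", "mean_depth"])
    return PileupResult(pileup, track, chrom_mean)


def simulate_site_frequencies(
    n_sites: int,
    configs: Sequence[tuple[int, int]],
    depth_mean: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Distribution-level shortcut: depths and allele counts without a genome.

    Each site draws an allele-copy configuration uniformly from
    ``configs``, a depth ~ Poisson(depth_mean) and an alternate count ~
    Binomial(depth, alt/total).  Returns depth, alt_count, ref_count, f
    (sites with zero depth are dropped).
    """
    configs = list(configs)
    idx = rng.integers(len(configs), size=n_sites)
    p = np.array([c[0] / c[1] for c in configs])[idx]
    depth = rng.poisson(depth_mean, size=n_sites)
    alt = rng.binomial(depth, p)
    keep = depth > 0
    frame = pd.DataFrame({
        "depth": depth[keep], "alt_count": alt[keep],
        "ref_count": depth[keep] - alt[keep],
    })
    frame["f"] = frame["alt_count"] / frame["depth"]
    return frame


def generate_gene_orders(
    n_genes: int,
    ops: Sequence[tuple] = (),
    seed: int = 0,
) -> tuple[GeneOrder, GeneOrder, dict[str, str]]:
    """Two gene orders and a one-to-one orthology map for synteny fixtures.

    Genome A is the identity order g1..gN on one contig, all forward
    strand.  Genome B starts identical and applies ``ops`` in sequence:

    * ``("invert", i, j)``      — reverse order and flip strands of B[i:j)
    * ``("transpose", i, j, d)``— move B[i:j) to post-removal index d
    * ``("insert", i, k)``      — insert k foreign genes (no orthologs) at i

    The orthology maps every shared gene to itself.
    """
    if n_genes < 1:
        raise ParameterError("need at least one gene")
    rng = np.random.default_rng(seed)
    a_genes = [(f"g{i + 1}", "+") for i in range(n_genes)]
    b_genes = list(a_genes)
    n_foreign = 0
    for op in ops:
        kind = op[0]
        if kind == "invert":
            _, i, j = op
            b_genes[i:j] = [(g, "-" if s == "+" else "+") for g, s in reversed(b_genes[i:j])]
        elif kind == "transpose":
            _, i, j, dest = op
            piece = b_genes[i:j]
            rest = b_genes[:i] + b_genes[j:]
            b_genes = rest[:dest] + piece + rest[dest:]
        elif kind == "insert":
            _, i, k = op
            foreign = [(f"x{n_foreign + m + 1}", "+" if rng.random() < 0.5 else "-") for m in range(k)]
            n_foreign += k
            b_genes = b_genes[:i] + foreign + b_genes[i:]
        else:
            raise ParameterError(f"unknown rearrangement op {kind!r}")
    order_a = GeneOrder("A", {"A1": a_genes})
    order_b = GeneOrder("B", {"B1": b_genes})
    orthology = {g: g for g, _ in a_genes}
    return order_a, order_b, orthology


# --- writers -----------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """Write gene and exon features (1-based inclusive, GFF3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tkaryoscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tkaryoscan\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )


def write_truth_table(truth: TruthTable, path) -> None:
    truth.variants.to_csv(path, sep="\t", index=False)


def write_segments_bed(segments: Sequence[SkewedSegmentSpec], path) -> None:
    """Planted skewed segments as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\tplanted_skew\n")


def write_depth_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False)
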