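"""Heterozygous variant calling from per-site allele counts.

A pileup row gives the depth and per-allele read counts at one position;
a site is retained as a heterozygous variant when its alternate-allele
frequency and alternate-supporting read count clear configurable
thresholds (defaults 0.2 and 50, the retention rules of a conservative
short-read caller) and the position lies outside the repeat mask.
Exactly one alternate allele is reported per site: the highest-count
non-reference allele, ties broken lexicographically.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .errors import ParameterError, PileupParseError, UnsortedInputError

PILEUP_COLUMNS = ["chrom", "pos", "ref", "depth", "counts"]


@dataclass(frozen=True)
class VariantSite:
    """One polymorphic locus with strand-pooled allele read counts.

    Alleles are VCF-style: indels carry the anchor base, so an insertion
    is ``ref="A", alt="ATG"`` and a deletion ``ref="ATG", alt="A"``.
    The frequency denominator is ref+alt by default so that third-allele
    noise reads do not deflate f.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vtype: str  # "SNP" | "indel"
    ref_count: int
    alt_count: int
    depth: int

    def __post_init__(self):
        if self.vtype not in ("SNP", "indel"):
            raise ParameterError(f"bad variant type {self.vtype!r}")
        if self.ref_count + self.alt_count > self.depth:
            raise ParameterError(f"{self.chrom}:{self.pos}: ref+alt exceeds depth")
        if self.pos < 1:
            raise ParameterError(f"{self.chrom}:{self.pos}: position must be 1-based")

    @property
    def frequency(self) -> float:
        return allele_frequency(self.ref_count, self.alt_count)


def allele_frequency(ref_count: int, alt_count: int) -> float:
    """Alternate-allele frequency f = alt / (ref + alt)."""
    informative = ref_count + alt_count
    if informative <= 0:
        raise ParameterError("zero informative reads: frequency undefined")
    return alt_count / informative


@dataclass
class CallerConfig:
    """Retention thresholds and repeat mask for variant calling.

    ``mask`` maps chromosome -> intervals, 0-based half-open (BED
    convention); masked positions are excluded before filtering.
    ``denominator``: "biallelic" uses ref+alt; "depth" uses total depth.
    """

    min_var_freq: float = 0.2
    min_reads2: int = 50
    mask: Mapping[str, Sequence[tuple[int, int]]] = field(default_factory=dict)
    denominator: str = "biallelic"

    def __post_init__(self):
        if not (0 < self.min_var_freq < 1):
            raise ParameterError("min_var_freq must be in (0, 1)")
        if self.min_reads2 < 1:
            raise ParameterError("min_reads2 must be >= 1")
        if self.denominator not in ("biallelic", "depth"):
            raise ParameterError("denominator must be 'biallelic' or 'depth'")

    def is_masked(self, chrom: str, pos: int) -> bool:
        """True if 1-based ``pos`` falls in a masked interval."""
        for start, end in self.mask.get(chrom, ()):
            if start <= pos - 1 < end:
                return True
        return False


def parse_counts(text: str, lineno: int = 0) -> dict[str, int]:
    """Parse a counts field like ``"A:120,G:115,+TG:3"`` into a dict."""
    out: dict[str, int] = {}
    if not text or text == ".":
        return out
    for token in text.split(","):
        try:
            allele, n = token.rsplit(":", 1)
            out[allele] = int(n)
        except ValueError as exc:
            raise PileupParseError(lineno, f"bad counts token {token!r}") from exc
        if out[allele] < 0:
            raise PileupParseError(lineno, f"negative count in {token!r}")
    return out


def _check_sorted(frame: pd.DataFrame) -> None:
    seen: set[str] = set()
    prev_chrom, prev_pos = None, None
    for chrom, pos in zip(frame["chrom"], frame["pos"]):
        if chrom != prev_chrom:
            if chrom in seen:
                raise UnsortedInputError(f"chromosome {chrom} appears in multiple blocks")
            seen.add(chrom)
            prev_chrom, prev_pos = chrom, pos
        elif pos <= prev_pos:
            raise UnsortedInputError(f"{chrom}:{pos} not after {chrom}:{prev_pos}")
        else:
            prev_pos = pos


def _site_from_counts(
    chrom: str, pos: int, ref: str, depth: int, counts: Mapping[str, int]
) -> VariantSite | None:
    """Build the candidate site for the top non-reference allele, or None."""
    ref = ref.upper()
    alts = {a: n for a, n in counts.items() if a.upper() != ref and n > 0}
    if not alts:
        return None
    # highest count wins; ties break lexicographically
    alt_key = min(alts, key=lambda a: (-alts[a], a))
    alt_n = alts[alt_key]
    ref_n = int(counts.get(ref, counts.get(ref.lower(), 0)))
    if alt_key.startswith("+"):
        vref, valt, vtype = ref, ref + alt_key[1:].upper(), "indel"
    elif alt_key.startswith("-"):
        vref, valt, vtype = ref + alt_key[1:].upper(), ref, "indel"
    else:
        vref, valt, vtype = ref, alt_key.upper(), "SNP"
        if any(b not in "ACGT" for b in valt):
            raise ParameterError(f"{chrom}:{pos}: non-ACGT alternate allele {valt!r}")
    return VariantSite(chrom, int(pos), vref, valt, vtype, ref_n, alt_n, int(depth))


def call_variants(pileup: pd.DataFrame, config: CallerConfig | None = None) -> list[VariantSite]:
    """Filter a pileup into the retained heterozygous variant set.

    A site is retained iff its alternate-allele frequency >= min_var_freq,
    its alternate read count >= min_reads2, and its position lies outside
    the repeat mask.  Input must be sorted by chromosome then position.
    """
    config = config or CallerConfig()
    _check_sorted(pileup)
    out: list[VariantSite] = []
    for i, row in enumerate(pileup.itertuples(index=False)):
        counts = row.counts if isinstance(row.counts, dict) else parse_counts(str(row.counts), i + 1)
        try:
            depth = int(row.depth)
        except (TypeError, ValueError) as exc:
            raise PileupParseError(i + 1, f"bad depth {row.depth!r}") from exc
        site = _site_from_counts(str(row.chrom), int(row.pos), str(row.ref), depth, counts)
        if site is None:
            continue
        if config.is_masked(site.chrom, site.pos):
            continue
        denom = site.depth if config.denominator == "depth" else site.ref_count + site.alt_count
        if denom <= 0:
            continue
        freq = site.alt_count / denom
        if freq >= config.min_var_freq and site.alt_count >= config.min_reads2:
            out.append(site)
    return out


def sites_to_frame(sites: Iterable[VariantSite]) -> pd.DataFrame:
    """Tabulate sites as one row per locus with counts and frequency."""
    rows = [
        (s.chrom, s.pos, s.vtype, s.ref, s.alt, s.ref_count, s.alt_count, s.depth, s.frequency)
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "vtype", "ref", "alt", "ref_count", "alt_count", "depth", "f"],
    )


def write_sites_tsv(sites: Iterable[VariantSite], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_pileup(path) -> pd.DataFrame:
    """Read a TSV pileup (chrom, pos, ref, depth, counts)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "counts": str})
    missing = set(PILEUP_COLUMNS) - set(frame.columns)
    if missing:
        raise PileupParseError(1, f"missing pileup columns: {sorted(missing)}")
    return frame


def write_pileup(pileup: pd.DataFrame, path) -> None:
    pileup.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


# --- VCF round-tripping ------------------------------------------------------

def write_vcf(sites: Sequence[VariantSite], path, contigs: Mapping[str, int]) -> None:
    """Write sites as VCF 4.2 with AD-style counts in FORMAT.

    RC/AC (ref/alt supporting reads) and DP round-trip the VariantSite
    fields; alleles are already anchor-base encoded.
    """
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("VT", 1, "String", "Variant type (SNP or indel)")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.add_sample("sample")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sites:
            for b in s.ref + s.alt:
                if b not in "ACGT":
                    raise ParameterError(f"{s.chrom}:{s.pos}: non-ACGT allele")
            rec = vcf.new_record(
                contig=s.chrom, start=s.pos - 1, alleles=(s.ref, s.alt), filter="PASS"
            )
            rec.info["VT"] = s.vtype
            rec.samples["sample"]["AD"] = (s.ref_count, s.alt_count)
            rec.samples["sample"]["DP"] = s.depth
            vcf.write(rec)


def read_vcf(path) -> list[VariantSite]:
    """Read a VCF with AD-style per-allele depths into VariantSite records.

    Works for our own output and for external callers emitting FORMAT/AD;
    frequencies are recomputed from the counts, never trusted from INFO.
    """
    out: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            alt = rec.alts[0]
            vtype = rec.info.get("VT") if "VT" in rec.info else (
                "SNP" if len(rec.ref) == 1 and len(alt) == 1 else "indel"
            )
            sample = rec.samples[0] if rec.samples else None
            if sample is not None and sample.get("AD") is not None:
                ad = sample["AD"]
                ref_n, alt_n = int(ad[0]), int(ad[1])
                depth = int(sample.get("DP") or (ref_n + alt_n))
            else:
                raise ParameterError(f"{rec.chrom}:{rec.pos}: no AD counts to recompute frequency")
            out.append(
                VariantSite(rec.chrom, rec.pos, rec.ref, alt, str(vtype), ref_n, alt_n, depth)
            )
    return out
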