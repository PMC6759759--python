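"""Variant filtering, background removal, receptor classification, SV calls.

The pipeline starts downstream of alignment and variant calling: inputs are
per-mutant called-variant tables (minimal VCF) and per-position read-depth
tracks.  Filtering follows the study's rules — coverage strictly above 20
reads, alternative-allele fraction strictly above 80%, discard of variants
present in every sequenced mutant (reference/ancestor mismatches), and
flagging of variants universal within one ancestral clone's descendants
(pre-existing background SNPs, e.g. the PA3676 SNP of PAO1_FT3).  Large
deletions (>100 bp) and duplications are called from binned coverage depth
normalized by its genome-wide median.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

DEFAULT_MIN_DEPTH = 20
DEFAULT_MIN_ALT_FRACTION = 0.8
DEFAULT_DEL_RATIO = 0.25
DEFAULT_DUP_RATIO = 1.75
DEFAULT_MIN_DELETION_BP = 100
DEFAULT_MIN_DUPLICATION_BP = 300
DEFAULT_MERGE_GAP_BINS = 2


class Category(str, enum.Enum):
    LPS = "LPS"
    TYPE_IV_PILUS = "TYPE_IV_PILUS"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one mutant (VCF-style 1-based position)."""

    lineage: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    gene: str | None = None
    category: Category | None = None
    background: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError("alt_count must be in [0, depth]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of a variant across samples."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass
class GeneCategoryTable:
    """Gene -> receptor-category lookup (LPS / type IV pilus / other)."""

    mapping: dict[str, Category] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = {g: Category(c) for g, c in self.mapping.items()}

    @classmethod
    def from_tsv(cls, path) -> "GeneCategoryTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        if df["gene"].duplicated().any():
            dups = sorted(df.loc[df["gene"].duplicated(), "gene"])
            raise ValueError(f"duplicate genes in category table: {dups}")
        return cls({row.gene: Category(row.category) for row in df.itertuples()})

    def classify(self, gene: str | None) -> Category:
        if gene is None:
            return Category.UNKNOWN
        return self.mapping.get(gene, Category.UNKNOWN)


def packaged_gene_categories() -> GeneCategoryTable:
    """The receptor-category table for the study's mutated PAO1 genes."""
    return GeneCategoryTable.from_tsv(
        Path(__file__).parent / "data" / "gene_categories.tsv"
    )


def quality_filter(
    records: Iterable[VariantRecord],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_alt_fraction: float = DEFAULT_MIN_ALT_FRACTION,
) -> list[VariantRecord]:
    """Keep variants with depth > min_depth AND alt fraction > min_alt_fraction.

    Both inequalities are strict: depth 20 or alt fraction exactly 0.8 are
    removed.
    """
    return [
        r
        for r in records
        if r.depth > min_depth and r.alt_fraction > min_alt_fraction
    ]


def _by_lineage(records: Iterable[VariantRecord]) -> dict[str, list[VariantRecord]]:
    out: dict[str, list[VariantRecord]] = {}
    for r in records:
        out.setdefault(r.lineage, []).append(r)
    return out


def remove_shared_variants(
    records: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], set[tuple[str, int, str, str]]]:
    """Drop variants present in every lineage (reference-mismatch artifacts).

    Returns the retained records and the set of discarded variant keys.
    Requires >= 2 lineages — universality is meaningless for a single one.
    """
    grouped = _by_lineage(records)
    if len(grouped) < 2:
        raise ValueError("shared-variant removal needs >= 2 lineages")
    keysets = [set(r.key for r in recs) for recs in grouped.values()]
    universal = set.intersection(*keysets)
    retained = [r for recs in grouped.values() for r in recs if r.key not in universal]
    return retained, universal


def flag_ancestral_background(
    records: Iterable[VariantRecord],
    pedigree: Mapping[str, str],
) -> list[VariantRecord]:
    """Flag variants universal within one ancestor's lineages and absent elsewhere.

    Such variants pre-date selection (they arose before the fluctuation
    test); they stay in the output but carry ``background=True`` and are
    excluded from mutation counts.
    """
    records = list(records)
    missing = {r.lineage for r in records} - set(pedigree)
    if missing:
        raise ValueError(f"pedigree does not cover lineages: {sorted(missing)}")
    lineages_of: dict[str, set[str]] = {}
    for lin, anc in pedigree.items():
        lineages_of.setdefault(anc, set()).add(lin)
    carriers: dict[tuple, set[str]] = {}
    for r in records:
        carriers.setdefault(r.key, set()).add(r.lineage)
    background_keys = set()
    for key, lins in carriers.items():
        ancestors = {pedigree[lin] for lin in lins}
        if len(ancestors) == 1 and lins == lineages_of[next(iter(ancestors))]:
            background_keys.add(key)
    return [
        replace(r, background=True) if r.key in background_keys else r
        for r in records
    ]


def classify_and_count(
    records: Iterable[VariantRecord],
    table: GeneCategoryTable,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Annotate receptor categories and count mutations per lineage.

    Background-flagged records are annotated but not counted.  Returns the
    annotated records and a per-lineage count table with one column per
    category plus a total.
    """
    annotated = [replace(r, category=table.classify(r.gene)) for r in records]
    lineages = sorted({r.lineage for r in annotated})
    counts = pd.DataFrame(
        0, index=pd.Index(lineages, name="lineage"),
        columns=[c.value for c in Category],
    )
    for r in annotated:
        if not r.background:
            counts.loc[r.lineage, r.category.value] += 1
    counts["total"] = counts.sum(axis=1)
    return annotated, counts.reset_index()


@dataclass(frozen=True)
class SVCall:
    """A coverage-inferred structural variant (0-based half-open interval)."""

    lineage: str
    type: str  # "DELETION" or "DUPLICATION"
    start: int
    end: int
    fraction_of_genome: float  # percent

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def call_svs(
    depth_track: pd.DataFrame,
    genome_length_bp: int,
    lineage: str = "",
    del_ratio: float = DEFAULT_DEL_RATIO,
    dup_ratio: float = DEFAULT_DUP_RATIO,
    min_deletion_bp: int = DEFAULT_MIN_DELETION_BP,
    min_duplication_bp: int = DEFAULT_MIN_DUPLICATION_BP,
    merge_gap_bins: int = DEFAULT_MERGE_GAP_BINS,
) -> list[SVCall]:
    """Call large deletions/duplications from a binned coverage-depth track.

    The track (columns chrom, start, end, depth; 0-based half-open bins) is
    normalized by its genome-wide median depth.  Calling is seed-and-extend
    with hysteresis: runs of bins below ``del_ratio`` (deletion) or above
    ``dup_ratio`` (duplication) seed an event, which is then extended over
    neighbouring bins past the halfway ratio to the unaffected copy number
    (0.5x for deletions, 1.5x for duplications).  Same-type runs separated
    by at most ``merge_gap_bins`` bins are merged, so single-bin Poisson
    excursions inside a real event do not fragment it; calls shorter than
    ``min_deletion_bp`` / ``min_duplication_bp`` are dropped, which
    suppresses lone noise bins.  ``fraction_of_genome`` is percent.
    """
    track = depth_track.sort_values(["chrom", "start"]).reset_index(drop=True)
    depth = track["depth"].to_numpy(float)
    median = float(np.median(depth))
    if median <= 0:
        raise ValueError("genome-wide median depth is zero; track unusable")
    norm = depth / median
    starts = track["start"].to_numpy(int)
    ends = track["end"].to_numpy(int)
    chroms = track["chrom"].to_numpy()
    # bins are contiguous within a chromosome run; break extension at gaps
    contiguous = np.ones(len(track), dtype=bool)
    contiguous[1:] = (chroms[1:] == chroms[:-1]) & (starts[1:] == ends[:-1])

    calls: list[SVCall] = []
    for sign, seed_ok, extend_ok in (
        (-1, norm < del_ratio, norm < (1.0 + del_ratio) / 2.0),
        (1, norm > dup_ratio, norm > (1.0 + dup_ratio) / 2.0),
    ):
        intervals: list[list[int]] = []
        i = 0
        n = len(track)
        while i < n:
            if not seed_ok[i]:
                i += 1
                continue
            lo = i
            while lo > 0 and contiguous[lo] and extend_ok[lo - 1]:
                lo -= 1
            hi = i
            while hi + 1 < n and contiguous[hi + 1] and extend_ok[hi + 1]:
                hi += 1
            if (
                intervals
                and lo - intervals[-1][1] <= merge_gap_bins + 1
                and chroms[intervals[-1][0]] == chroms[lo]
                and contiguous[intervals[-1][1] + 1 : hi + 1].all()
            ):
                intervals[-1][1] = max(intervals[-1][1], hi)
            else:
                intervals.append([lo, hi])
            i = hi + 1
        min_bp = min_deletion_bp if sign == -1 else min_duplication_bp
        typ = "DELETION" if sign == -1 else "DUPLICATION"
        for lo, hi in intervals:
            start, end = int(starts[lo]), int(ends[hi])
            if end - start >= min_bp:
                calls.append(
                    SVCall(lineage, typ, start, end,
                           100.0 * (end - start) / genome_length_bp)
                )
    calls.sort(key=lambda c: (c.start, c.type))
    return calls


def sv_frame(calls: Sequence[SVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lineage": c.lineage,
                "type": c.type,
                "start": c.start,
                "end": c.end,
                "length_bp": c.length_bp,
                "fraction_of_genome": c.fraction_of_genome,
            }
            for c in calls
        ],
        columns=["lineage", "type", "start", "end", "length_bp", "fraction_of_genome"],
    )


# ---------------------------------------------------------------------------
# I/O: minimal VCF (via pysam) and bedgraph-like depth TSV


def read_vcf(path, lineage: str) -> list[VariantRecord]:
    """Read a minimal VCF into VariantRecords.

    Depth is taken from INFO/DP and the alternative-allele count from
    INFO/AO (falling back to FORMAT AD of the first sample when present);
    genotype columns are not required.  INFO/GENE, when present, carries
    the annotated gene name.
    """
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            depth = int(info["DP"]) if "DP" in info else 0
            if "AO" in info:
                ao = info["AO"]
                alt_count = int(ao[0] if isinstance(ao, tuple) else ao)
            elif rec.samples and "AD" in rec.samples[0]:
                alt_count = int(rec.samples[0]["AD"][1])
            else:
                alt_count = depth
            gene = info.get("GENE")
            records.append(
                VariantRecord(
                    lineage=lineage,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    depth=depth,
                    alt_count=min(alt_count, depth),
                    gene=str(gene) if gene is not None else None,
                )
            )
    return records


def read_vcf_dir(vcf_dir) -> list[VariantRecord]:
    """Read every ``<lineage>.vcf`` in a directory; filenames carry lineage ids.

    Lineage labels containing path separators are stored percent-style with
    ``%2F`` for ``/`` (undone here).
    """
    vcf_dir = Path(vcf_dir)
    records = []
    for path in sorted(vcf_dir.glob("*.vcf")):
        lineage = path.stem.replace("%2F", "/").replace("%7C", "|")
        records.extend(read_vcf(path, lineage))
    return records


def lineage_filename(lineage: str) -> str:
    return lineage.replace("/", "%2F").replace("|", "%7C")


def write_vcf(records: Sequence[VariantRecord], path, contig: str, contig_length: int) -> None:
    """Write a minimal single-sample-free VCF (sites + INFO DP/AO/GENE)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={contig_length}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternative allele count">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Annotated gene">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
        info = f"DP={r.depth};AO={r.alt_count}"
        if r.gene:
            info += f";GENE={r.gene}"
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_depth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "depth"], header=0,
    )


def write_depth_tsv(track: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        track.to_csv(fh, sep="\t", index=False)
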