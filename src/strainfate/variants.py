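"""Naive pileup variant filtering and partitioned pairwise SNP distances.

The caller consumes samtools-mpileup text (6 columns: chrom, 1-based
position, reference base, depth, read bases, base qualities; an optional 7th
column carries per-read mapping qualities as produced by ``mpileup -s``).
Per site, reads failing the mapping-quality or base-quality floor are
discarded first; the majority non-reference allele among the remaining
"quality reads" must then be supported by a minimum fraction of reads and a
minimum absolute number of reads, on both strands, with a forward/reverse
strand-bias ratio strictly inside a configured interval.

Pairwise genetic distance between two call sets against the same reference is
the number of positions at which the genomes differ (reference-vs-alt or
alt-vs-alt'), divided by the comparable bases of the genome partition
considered (nuclear, mitochondrial or mating region) and scaled per kilobase.
Indels are filtered like SNPs but excluded from distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "PileupSite",
    "ReadCall",
    "VariantCall",
    "FilterThresholds",
    "PileupFormatError",
    "parse_pileup",
    "filter_site",
    "call_variants",
    "write_vcf",
    "PartitionedDistance",
    "Partitioner",
    "read_partition_bed",
    "pairwise_distance",
    "distance_matrix",
    "write_distance_csv",
]

_VALID_ALLELE_CHARS = set(".,ACGTNacgtn*")


class PileupFormatError(ValueError):
    """Malformed mpileup input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class ReadCall:
    """One read's evidence at one site.

    ``allele`` is the reference base for matches, an upper-case base for
    substitutions, ``*`` for a deleted base, or ``REF+SEQ``/``REF-SEQ`` for
    an insertion/deletion anchored at this position.  ``strand`` is ``+`` or
    ``-`` (``+`` for ``*`` placeholders, which do not encode strand).
    """

    allele: str
    strand: str
    base_quality: int
    mapping_quality: int | None = None


@dataclass(frozen=True)
class PileupSite:
    contig: str
    position: int
    ref_base: str
    depth: int
    calls: tuple[ReadCall, ...]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.depth != len(self.calls):
            raise ValueError(
                f"{self.contig}:{self.position}: depth {self.depth} != "
                f"{len(self.calls)} parsed calls"
            )


@dataclass(frozen=True)
class FilterThresholds:
    """The naive filter's knobs, defaulting to the published rule set."""

    min_mapping_quality: int = 20
    min_base_quality: int = 30
    min_fraction: float = 0.80
    min_reads: int = 5
    bias_low: float = 0.2
    bias_high: float = 5.0


DEFAULT_THRESHOLDS = FilterThresholds()


@dataclass(frozen=True)
class VariantCall:
    contig: str
    position: int
    ref: str
    alt: str
    supporting_reads: int
    support_fraction: float
    strand_bias: float  # forward/reverse among supporting reads; inf if no reverse
    verdict: str  # "pass" or "fail"
    fail_reason: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.support_fraction <= 1.0:
            raise ValueError("support_fraction must be in [0, 1]")
        if (self.verdict == "fail") != (self.fail_reason is not None):
            raise ValueError("fail verdicts carry exactly one reason")

    @property
    def is_snp(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.alt in "ACGT"
        )


def _parse_base_string(
    bases: str, quals: str, ref: str, mapquals: str | None, line_number: int
) -> list[ReadCall]:
    calls: list[ReadCall] = []
    i = 0
    qi = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupFormatError("dangling '^' start mark", line_number)
            i += 2  # skip mark + mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c not in _VALID_ALLELE_CHARS:
            raise PileupFormatError(f"unexpected character {c!r} in base string", line_number)
        if c in ".,":
            allele = ref.upper()
            strand = "+" if c == "." else "-"
        elif c == "*":
            allele = "*"
            strand = "+"
        else:
            allele = c.upper()
            strand = "+" if c.isupper() else "-"
        i += 1
        # indel attached to the preceding call: +NNseq / -NNseq
        if i < n and bases[i] in "+-":
            sign = bases[i]
            i += 1
            num_start = i
            while i < n and bases[i].isdigit():
                i += 1
            if i == num_start:
                raise PileupFormatError("indel mark without length", line_number)
            length = int(bases[num_start:i])
            seq = bases[i : i + length]
            if len(seq) < length:
                raise PileupFormatError("truncated indel sequence", line_number)
            i += length
            allele = f"{allele}{sign}{seq.upper()}"
        if qi >= len(quals):
            raise PileupFormatError("more base calls than quality characters", line_number)
        bq = ord(quals[qi]) - 33
        mq = None
        if mapquals is not None:
            if qi >= len(mapquals):
                raise PileupFormatError("more base calls than mapping qualities", line_number)
            mq = ord(mapquals[qi]) - 33
        qi += 1
        calls.append(ReadCall(allele, strand, bq, mq))
    if qi != len(quals):
        raise PileupFormatError(
            f"{len(quals)} quality characters for {qi} base calls", line_number
        )
    return calls


def parse_pileup(stream: Iterable[str] | TextIO) -> Iterator[PileupSite]:
    """Parse 6/7-column samtools-mpileup text into :class:`PileupSite` records.

    Strand is decoded from base case ('.'/uppercase forward, ','/lowercase
    reverse); ``^X`` read-start marks (and their mapping-quality character)
    and ``$`` read-end marks are stripped; ``+n``/``-n`` indel strings are
    attached to the anchoring call.
    """
    for line_number, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise PileupFormatError(
                f"expected >= 6 tab-separated fields, got {len(fields)}", line_number
            )
        contig, pos_s, ref, depth_s, bases, quals = fields[:6]
        mapquals = fields[6] if len(fields) >= 7 else None
        try:
            pos = int(pos_s)
            depth = int(depth_s)
        except ValueError as exc:
            raise PileupFormatError(f"non-integer position/depth: {exc}", line_number) from exc
        calls = _parse_base_string(bases, quals, ref, mapquals, line_number)
        if depth != len(calls):
            raise PileupFormatError(
                f"declared depth {depth} but parsed {len(calls)} calls", line_number
            )
        yield PileupSite(contig, pos, ref.upper(), depth, tuple(calls))


def filter_site(
    site: PileupSite,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> VariantCall | None:
    """Apply the naive variant filter to one site.

    Reads below the mapping-quality or base-quality floors are removed first;
    the majority non-reference allele among the survivors is then tested, in
    order: minimum supporting reads, minimum support fraction, support on
    both strands, and strand-bias ratio strictly inside
    ``(bias_low, bias_high)``.  The first failing rule names the verdict.
    Returns ``None`` when no non-reference allele remains after quality
    filtering.
    """
    quality = [
        c
        for c in site.calls
        if c.base_quality >= thresholds.min_base_quality
        and (c.mapping_quality is None or c.mapping_quality >= thresholds.min_mapping_quality)
    ]
    if not quality:
        return None
    non_ref = [c for c in quality if c.allele != site.ref_base]
    if not non_ref:
        return None
    counts: dict[str, int] = {}
    for c in non_ref:
        counts[c.allele] = counts.get(c.allele, 0) + 1
    # majority allele; ties broken lexicographically for determinism
    alt = max(sorted(counts), key=counts.get)
    support = [c for c in non_ref if c.allele == alt]
    fwd = sum(1 for c in support if c.strand == "+")
    rev = len(support) - fwd
    fraction = len(support) / len(quality)
    bias = math.inf if rev == 0 else fwd / rev

    ref_out, alt_out = site.ref_base, alt
    if "+" in alt or "-" in alt:
        anchor, sign, seq = alt[0], alt[1], alt[2:]
        if sign == "+":
            ref_out, alt_out = site.ref_base, anchor + seq
        else:
            ref_out, alt_out = site.ref_base + seq, anchor

    def result(reason: str | None) -> VariantCall:
        return VariantCall(
            site.contig,
            site.position,
            ref_out,
            alt_out,
            len(support),
            fraction,
            bias,
            "pass" if reason is None else "fail",
            reason,
        )

    if len(support) < thresholds.min_reads:
        return result("min_reads")
    if fraction < thresholds.min_fraction:
        return result("min_fraction")
    if fwd == 0 or rev == 0:
        return result("strand")
    if not thresholds.bias_low < bias < thresholds.bias_high:
        return result("strand_bias")
    return result(None)


def call_variants(
    sites: Iterable[PileupSite],
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    include_fails: bool = False,
) -> list[VariantCall]:
    """Run :func:`filter_site` over a position-sorted site stream.

    Input must be sorted by contig (order of first appearance) and by
    position within each contig; unsorted input is an error, not silently
    reordered.
    """
    calls: list[VariantCall] = []
    last: dict[str, int] = {}
    seen_order: list[str] = []
    for site in sites:
        if site.contig not in last:
            last[site.contig] = 0
            seen_order.append(site.contig)
        elif site.contig != seen_order[-1]:
            raise ValueError(f"contig {site.contig} appears in non-contiguous blocks")
        if site.position <= last[site.contig]:
            raise ValueError(
                f"unsorted input at {site.contig}:{site.position} "
                f"(previous position {last[site.contig]})"
            )
        last[site.contig] = site.position
        call = filter_site(site, thresholds)
        if call is not None and (call.verdict == "pass" or include_fails):
            calls.append(call)
    return calls


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    reference: str = "unknown",
    include_fails: bool = False,
) -> None:
    """Write calls as minimal VCF 4.2 with depth/support/strand INFO fields."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={reference}",
        '##INFO=<ID=SR,Number=1,Type=Integer,Description="Reads supporting the alternate allele">',
        '##INFO=<ID=SF,Number=1,Type=Float,Description="Fraction of quality reads supporting the alternate allele">',
        '##INFO=<ID=SB,Number=1,Type=Float,Description="Strand bias, forward/reverse among supporting reads">',
        "##FILTER=<ID=min_reads,Description=\"Fewer supporting reads than required\">",
        "##FILTER=<ID=min_fraction,Description=\"Support fraction below threshold\">",
        "##FILTER=<ID=strand,Description=\"Alternate allele absent from one strand\">",
        "##FILTER=<ID=strand_bias,Description=\"Forward/reverse ratio outside accepted interval\">",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        if c.verdict != "pass" and not include_fails:
            continue
        filt = "PASS" if c.verdict == "pass" else c.fail_reason
        bias = "inf" if math.isinf(c.strand_bias) else f"{c.strand_bias:.4g}"
        lines.append(
            f"{c.contig}\t{c.position}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t"
            f"SR={c.supporting_reads};SF={c.support_fraction:.4g};SB={bias}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# partitioned pairwise distances


@dataclass(frozen=True)
class PartitionedDistance:
    partition: str
    snp_differences: int
    compared_bases: int
    distance: float  # SNPs per kilobase

    def __post_init__(self) -> None:
        if self.compared_bases <= 0:
            raise ValueError("compared_bases must be > 0")
        expected = 1000.0 * self.snp_differences / self.compared_bases
        if not math.isclose(self.distance, expected, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("distance must equal 1000 * snp_differences / compared_bases")


class Partitioner:
    """Maps a (contig, position) to a genome partition.

    Built from a contig-level map (e.g. chromosomes -> "nuclear",
    mitochondrion -> "mitochondrial") plus optional BED intervals that
    override the contig default (the mating region sits inside a nuclear
    chromosome).
    """

    def __init__(
        self,
        contig_map: Mapping[str, str],
        intervals: Sequence[tuple[str, int, int, str]] = (),
    ):
        self.contig_map = dict(contig_map)
        # BED half-open 0-based intervals: (contig, start, end, partition)
        self.intervals = list(intervals)

    def partition_of(self, contig: str, position: int) -> str:
        """Partition of a 1-based position."""
        for c, start, end, name in self.intervals:
            if c == contig and start < position <= end:
                return name
        try:
            return self.contig_map[contig]
        except KeyError:
            raise KeyError(f"contig {contig!r} absent from partition map") from None

    def names(self) -> list[str]:
        seen: list[str] = []
        for name in list(self.contig_map.values()) + [iv[3] for iv in self.intervals]:
            if name not in seen:
                seen.append(name)
        return seen


def read_partition_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED intervals (contig, start, end, name) for partition overrides."""
    intervals = []
    for line_number, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}, line {line_number}: BED needs 4 columns")
        intervals.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return intervals


def _snp_alleles(calls: Iterable[VariantCall]) -> dict[tuple[str, int], str]:
    return {
        (c.contig, c.position): c.alt
        for c in calls
        if c.verdict == "pass" and c.is_snp
    }


def pairwise_distance(
    calls_a: Sequence[VariantCall],
    calls_b: Sequence[VariantCall],
    partitioner: Partitioner,
    comparable_bases: Mapping[str, int],
) -> list[PartitionedDistance]:
    """Per-partition SNP distance between two call sets vs the same reference.

    A position contributes one difference when the two genomes carry
    different alleles there: a SNP present in only one genome
    (reference-vs-alt) or different alternate alleles in both (alt-vs-alt').
    Indels and failing calls are excluded.  ``comparable_bases`` supplies the
    per-partition denominator — the positions adequately covered in both
    genomes, decided by the caller.
    """
    a = _snp_alleles(calls_a)
    b = _snp_alleles(calls_b)
    diffs: dict[str, int] = {name: 0 for name in comparable_bases}
    for key in set(a) | set(b):
        if a.get(key) == b.get(key):
            continue
        part = partitioner.partition_of(*key)
        if part not in diffs:
            raise KeyError(f"no comparable_bases entry for partition {part!r}")
        diffs[part] += 1
    return [
        PartitionedDistance(name, diffs[name], comparable_bases[name],
                            1000.0 * diffs[name] / comparable_bases[name])
        for name in comparable_bases
    ]


def distance_matrix(
    genomes: Mapping[str, Sequence[VariantCall]],
    partitioner: Partitioner,
    comparable_bases: Mapping[str, int],
) -> dict[str, pd.DataFrame]:
    """Symmetric per-partition distance matrices (SNP/kb) for >= 2 genomes."""
    names = list(genomes)
    if len(names) < 2:
        raise ValueError("need at least 2 genomes")
    matrices = {
        part: pd.DataFrame(0.0, index=names, columns=names)
        for part in comparable_bases
    }
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for d in pairwise_distance(genomes[a], genomes[b], partitioner, comparable_bases):
                matrices[d.partition].loc[a, b] = d.distance
                matrices[d.partition].loc[b, a] = d.distance
    return matrices


def write_distance_csv(matrices: Mapping[str, pd.DataFrame], prefix: str | Path) -> list[Path]:
    """Write one strain-by-strain CSV per partition; returns the paths."""
    paths = []
    for part, df in matrices.items():
        path = Path(f"{prefix}{part}.csv")
        df.to_csv(path, index_label="strain")
        paths.append(path)
    return paths
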