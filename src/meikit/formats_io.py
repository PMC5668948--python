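"""Readers and writers for the external formats the toolkit touches.

Coordinate conventions
----------------------
Everything internal is 0-based, half-open.  The only place 1-based
coordinates appear is the VCF writer/reader pair.  For an insertion call,
``position`` is the 0-based index of the reference base *after which* the
element is inserted; the VCF ``POS`` column is therefore ``position + 1``
(the anchor base, 1-based), which matches the symbolic-allele norm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import pysam

from .errors import ConfigurationError, IndexingError, ParseError

# CIGAR operations that consume query sequence / reference bases
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_CIGAR_CODE = "MIDNSHP=X"


@dataclass(slots=True)
class ReadAlignment:
    """One aligned (or placed-unmapped) read, the modeled subset of SAM."""

    name: str
    chrom: str
    pos: int  # 0-based leftmost reference coordinate
    strand: str  # '+' or '-'
    mapq: int
    cigar: List[Tuple[str, int]]
    sequence: str
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    is_proper_pair: bool = False
    is_unmapped: bool = False
    mate_unmapped: bool = False
    is_read1: bool = True
    is_duplicate: bool = False
    is_secondary: bool = False
    sample_id: str = ""

    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_OPS)

    @property
    def reference_end(self) -> int:
        """End of the aligned span on the reference (half-open)."""
        return self.pos + sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def left_clip(self) -> int:
        if self.cigar and self.cigar[0][0] in "SH":
            return self.cigar[0][1]
        return 0

    @property
    def right_clip(self) -> int:
        if self.cigar and self.cigar[-1][0] in "SH":
            return self.cigar[-1][1]
        return 0

    def validate(self) -> None:
        if self.pos < 0:
            raise ParseError(f"negative position for read {self.name}")
        if not 0 <= self.mapq <= 60:
            raise ParseError(f"mapq {self.mapq} out of [0,60] for read {self.name}")
        if not self.is_unmapped and self.sequence and self.query_consumed() != len(self.sequence):
            raise ParseError(
                f"CIGAR query length {self.query_consumed()} != sequence length "
                f"{len(self.sequence)} for read {self.name}"
            )


@dataclass(frozen=True, slots=True)
class GenomeInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ParseError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


# ---------------------------------------------------------------------------
# alignment I/O (SAM text or BAM, via pysam)
# ---------------------------------------------------------------------------

def _from_pysam(rec: pysam.AlignedSegment, ordinal: int) -> ReadAlignment:
    cigar = []
    if rec.cigartuples:
        for code, n in rec.cigartuples:
            cigar.append((_CIGAR_CODE[code], n))
    ra = ReadAlignment(
        name=rec.query_name or "",
        chrom=rec.reference_name or "*",
        pos=rec.reference_start if rec.reference_start is not None and rec.reference_start >= 0 else 0,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
        cigar=cigar,
        sequence=rec.query_sequence or "",
        mate_chrom=rec.next_reference_name,
        mate_pos=rec.next_reference_start if rec.next_reference_start is not None and rec.next_reference_start >= 0 else None,
        is_proper_pair=rec.is_proper_pair,
        is_unmapped=rec.is_unmapped,
        mate_unmapped=rec.mate_is_unmapped,
        is_read1=rec.is_read1,
        is_duplicate=rec.is_duplicate,
        is_secondary=rec.is_secondary or rec.is_supplementary,
    )
    try:
        ra.validate()
    except ParseError as exc:
        raise ParseError(f"record {ordinal}: {exc}") from exc
    return ra


def read_alignments(
    path: str, region: Optional[GenomeInterval] = None
) -> Iterator[ReadAlignment]:
    """Stream reads from a SAM/BAM file in position order.

    ``region`` restricts output to reads overlapping the interval.  BAM
    files need an index for region queries; SAM text is scanned and
    filtered (no index exists for text input).
    """
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        if region is not None and path.endswith(".bam"):
            if not fh.has_index():
                raise IndexingError(f"no index found for {path}; cannot query a region")
            it = fh.fetch(region.chrom, region.start, region.end)
            for i, rec in enumerate(it):
                yield _from_pysam(rec, i)
            return
        it = fh.fetch(until_eof=True)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except (OSError, ValueError) as exc:  # htslib-level parse failures
                raise ParseError(f"record {i}: {exc}") from exc
            ra = _from_pysam(rec, i)
            i += 1
            if region is not None:
                if ra.chrom != region.chrom:
                    continue
                if ra.reference_end <= region.start or ra.pos >= region.end:
                    continue
            yield ra


def write_alignments(
    records: Sequence[ReadAlignment],
    path: str,
    references: Dict[str, int],
    sort: bool = True,
    index: bool = True,
) -> None:
    """Write reads as SAM (``.sam``) or BAM (``.bam``, sorted + indexed)."""
    names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if sort else "unsorted"},
        "SQ": [{"SN": n, "LN": references[n]} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    recs = list(records)
    if sort:
        recs.sort(key=lambda r: (tid.get(r.chrom, len(tid)), r.pos))
    is_bam = path.endswith(".bam")
    with pysam.AlignmentFile(path, "wb" if is_bam else "wh", header=header) as out:
        for r in recs:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.query_sequence = r.sequence
            a.reference_id = tid[r.chrom]
            a.reference_start = r.pos
            a.mapping_quality = r.mapq
            a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar) or None
            a.is_paired = True
            a.is_read1 = r.is_read1
            a.is_read2 = not r.is_read1
            a.is_reverse = r.strand == "-"
            a.is_unmapped = r.is_unmapped
            a.mate_is_unmapped = r.mate_unmapped
            a.is_proper_pair = r.is_proper_pair
            a.is_duplicate = r.is_duplicate
            if r.mate_chrom is not None and r.mate_pos is not None:
                a.next_reference_id = tid[r.mate_chrom]
                a.next_reference_start = r.mate_pos
                a.mate_is_reverse = r.strand == "+"  # inward-facing convention
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.sequence))
            out.write(a)
    if is_bam and index:
        pysam.index(path)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str) -> List[GenomeInterval]:
    """Read a 3+ column BED file into 0-based half-open intervals."""
    out: List[GenomeInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: BED line has <3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ParseError(f"{path}:{ln}: start {start} >= end {end}")
            label = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            out.append(GenomeInterval(chrom, start, end, label, strand))
    return out


def write_intervals(intervals: Sequence[GenomeInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> Dict[str, str]:
    """Load a whole FASTA file into memory as {name: sequence}."""
    seqs: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF 4.2
# ---------------------------------------------------------------------------

_VCF_CLASS_ALT = {"ALU": "INS:ME:ALU", "LINE1": "INS:ME:LINE1", "SVA": "INS:ME:SVA"}

_INFO_HEADER = [
    ('MEINFO', '4', 'String', 'Mobile element info: class,start,stop,polarity'),
    ('TSD', '1', 'String', 'Target site duplication sequence, or "null"'),
    ('TSDEL', '1', 'Integer', 'Target-site deletion length (0 if none)'),
    ('SVLEN', '1', 'Integer', 'Estimated length of the inserted element'),
    ('ASSESS', '1', 'Integer', 'Breakpoint evidence quality tranche (0-5)'),
    ('DIFF', '.', 'String', 'Subfamily assignment and interior mutation list'),
    ('INV5', '1', 'String', 'Detected 5-prime inversion junction, or "null"'),
    ('TDN', '1', 'String', 'Detected 3-prime transduction source, or "null"'),
    ('GENEIMPACT', '1', 'String', 'Most severe overlapped gene feature'),
]


@dataclass(slots=True)
class VCFRecord:
    """One parsed VCF data row (positions 1-based, as printed)."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    qual: str
    filters: List[str]
    info: Dict[str, str]
    format_keys: List[str]
    sample_fields: Dict[str, Dict[str, str]] = field(default_factory=dict)


def _vcf_header(samples: Sequence[str], contigs: Optional[Dict[str, int]] = None) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines.append("##source=meikit")
    for c, ln in (contigs or {}).items():
        lines.append(f"##contig=<ID={c},length={ln}>")
    for alt in ("INS:ME:ALU", "INS:ME:LINE1", "INS:ME:SVA", "DEL:ME:ALU", "DEL:ME:LINE1", "DEL:ME:SVA"):
        kind = "deletion" if alt.startswith("DEL") else "insertion"
        lines.append(f'##ALT=<ID={alt},Description="Mobile element {kind} ({alt.split(":")[-1]})">')
    for key, num, typ, desc in _INFO_HEADER:
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">')
    for flt, desc in (
        ("lc", "Single-sided (low complexity) evidence"),
        ("noSR", "No split-read support across samples"),
        ("hNC", "High fraction of no-call genotypes"),
        ("depth", "Local depth outside accepted bounds"),
        ("mask", "Within a masked/gap region"),
        ("refME", "Near a same-class reference mobile element"),
    ):
        lines.append(f'##FILTER=<ID={flt},Description="{desc}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=GL,Number=3,Type=Float,Description="Log10 genotype likelihoods (max 0)">')
    lines.append('##FORMAT=<ID=AD,Number=2,Type=Integer,Description="Ref,alt supporting read counts">')
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + list(samples)
    lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def write_vcf(
    calls: Sequence,
    genotypes: Dict[str, Dict],
    samples: Sequence[str],
    path: str,
    reference: Optional[Dict[str, str]] = None,
    contigs: Optional[Dict[str, int]] = None,
) -> None:
    """Write MEI calls plus per-sample genotypes as a VCF 4.2 file.

    ``genotypes`` maps call id -> {sample -> SampleGenotype}; calls must be
    sorted by (chrom, pos).  Symbolic ALT records carry the annotation
    payload in INFO (MEINFO/TSD/SVLEN/ASSESS/DIFF/INV5/TDN/GENEIMPACT).
    """
    prev = None
    for c in calls:
        key = (c.chrom, c.position)
        if prev is not None and key < prev:
            raise ConfigurationError("calls must be sorted by (chrom, pos)")
        prev = key
    with open(path, "w") as fh:
        fh.write(_vcf_header(samples, contigs))
        for c in calls:
            gts = genotypes.get(c.id, {})
            missing = set(gts) - set(samples)
            if missing:
                raise ConfigurationError(f"genotypes for unknown samples: {sorted(missing)}")
            pos1 = c.position + 1
            ref_base = "N"
            if reference is not None and c.chrom in reference:
                ref_base = reference[c.chrom][c.position]
            if c.kind == "DEL":
                alt = f"<DEL:ME:{c.me_class}>"
            else:
                alt = f"<{_VCF_CLASS_ALT.get(c.me_class, 'INS:ME:' + c.me_class)}>"
            filters = sorted(c.filters) if c.filters else []
            flt = ";".join(filters) if filters else "PASS"
            info = [
                f"MEINFO={c.me_class},{c.consensus_start},{c.consensus_stop},{c.orientation}",
                f"TSD={c.tsd if c.tsd else 'null'}",
                f"TSDEL={c.tsd_deletion}",
                f"SVLEN={c.svlen}",
                f"ASSESS={c.tranche}",
            ]
            feats = c.features or {}
            diff = feats.get("diff")
            info.append(f"DIFF={diff if diff else 'null'}")
            info.append(f"INV5={feats.get('inv5') or 'null'}")
            info.append(f"TDN={feats.get('tdn') or 'null'}")
            info.append(f"GENEIMPACT={feats.get('gene_impact') or 'intergenic'}")
            cols = [
                c.chrom, str(pos1), c.id, ref_base, alt, ".", flt, ";".join(info), "GT:GL:AD",
            ]
            for s in samples:
                g = gts.get(s)
                if g is None:
                    cols.append("./.:.:.")
                else:
                    gl = ",".join(f"{x:.2f}" for x in g.gl)
                    cols.append(f"{g.gt}:{gl}:{g.ad[0]},{g.ad[1]}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path: str) -> Tuple[List[VCFRecord], List[str]]:
    """Parse a VCF produced by :func:`write_vcf` back into records."""
    records: List[VCFRecord] = []
    samples: List[str] = []
    declared_info = set()
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise ParseError(f"{path}: missing ##fileformat header line")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##INFO=<ID="):
                declared_info.add(line.split("ID=")[1].split(",")[0])
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ParseError(f"{path}: data row with <8 columns")
            info: Dict[str, str] = {}
            for kv in parts[7].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    info[k] = v
                elif kv:
                    info[kv] = ""
            for k in info:
                if declared_info and k not in declared_info:
                    raise ParseError(f"{path}: INFO key {k} not declared in header")
            fmt = parts[8].split(":") if len(parts) > 8 else []
            sample_fields = {}
            for s, col in zip(samples, parts[9:]):
                sample_fields[s] = dict(zip(fmt, col.split(":")))
            records.append(
                VCFRecord(
                    chrom=parts[0], pos=int(parts[1]), id=parts[2], ref=parts[3],
                    alt=parts[4], qual=parts[5],
                    filters=parts[6].split(";") if parts[6] != "." else [],
                    info=info, format_keys=fmt, sample_fields=sample_fields,
                )
            )
    return records, samples


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")
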