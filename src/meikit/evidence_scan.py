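"""Discordant-pair and split-read evidence extraction.

A read pair is a discordant-pair (DRP) candidate when its mates map to
different chromosomes or at least ``min_separation`` (default 1 Mbp) apart;
pairs with exactly one unmapped mate are optionally admitted as well, since
reads wholly inside a novel insertion may fail to map.  The non-anchor
mate's sequence is realigned against the mobile-element consensus library;
only pairs whose mate aligns become DRP evidence.

Consensus realignment is an in-house local aligner (match +2, mismatch -2,
gap open -3, gap extend -1): an exact k-mer seed-and-extend fast path for
near-identical sequence, with a full Smith-Waterman fallback.  An alignment
is accepted when its aligned length is >= 30 and identity >= 0.88.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.Align import PairwiseAligner

from .errors import ConfigurationError, ParseError
from .formats_io import ReadAlignment, read_fasta, revcomp

DECOY_PREFIX = "MEDECOY_"

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -2, -3, -1
MIN_ALIGNED_LEN = 30
MIN_IDENTITY = 0.88
SEED_K = 20


# ---------------------------------------------------------------------------
# consensus library
# ---------------------------------------------------------------------------

@dataclass
class MEConsensus:
    """One mobile-element consensus plus its subfamily diagnostic profiles.

    ``subfamilies`` maps subfamily name to a set of (position, ref, alt)
    diagnostic mutations on the consensus; the class root (no diagnostics)
    is always present under the class name itself.
    """

    name: str
    sequence: str
    subfamilies: Dict[str, Set[Tuple[int, str, str]]] = field(default_factory=dict)
    cpg_positions: Set[int] = field(default_factory=set)

    def __post_init__(self):
        if not self.sequence:
            raise ConfigurationError(f"empty consensus sequence for {self.name}")
        if not self.cpg_positions:
            self.cpg_positions = {
                i + d
                for i in range(len(self.sequence) - 1)
                if self.sequence[i : i + 2] == "CG"
                for d in (0, 1)
            }
        self.subfamilies.setdefault(self.name, set())
        for sub, muts in self.subfamilies.items():
            for pos, ref, _alt in muts:
                if pos >= len(self.sequence):
                    raise ConfigurationError(
                        f"{self.name}/{sub}: diagnostic position {pos} outside consensus"
                    )
                if self.sequence[pos] != ref:
                    raise ConfigurationError(
                        f"{self.name}/{sub}: diagnostic ref {ref} != consensus base at {pos}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)


def load_me_library(
    fasta_path: Optional[str] = None, subfamily_tsv: Optional[str] = None
) -> List[MEConsensus]:
    """Load the consensus library; defaults to the bundled synthetic one."""
    if fasta_path is None:
        data = resources.files("meikit.data")
        fasta_path = str(data / "me_consensus.fa")
        if subfamily_tsv is None:
            subfamily_tsv = str(data / "subfamilies.tsv")
    seqs = read_fasta(fasta_path)
    if not seqs:
        raise ConfigurationError(f"no sequences in ME library {fasta_path}")
    profiles: Dict[str, Dict[str, Set[Tuple[int, str, str]]]] = {n: {} for n in seqs}
    if subfamily_tsv:
        with open(subfamily_tsv) as fh:
            rdr = csv.DictReader(fh, delimiter="\t")
            for row in rdr:
                cls = row["class"]
                if cls not in profiles:
                    raise ParseError(f"subfamily table references unknown class {cls}")
                profiles[cls].setdefault(row["subfamily"], set()).add(
                    (int(row["position"]), row["ref"], row["alt"])
                )
    return [MEConsensus(n, s, profiles.get(n, {})) for n, s in seqs.items()]


# ---------------------------------------------------------------------------
# consensus alignment
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class MEAlignment:
    """Local alignment of a query against one consensus."""

    consensus: str
    start: int  # on consensus, 0-based half-open
    end: int
    strand: str
    identity: float
    score: int
    # ungapped blocks (cons_start, query_start, length); query coords refer
    # to the oriented query (reverse-complemented when strand == '-')
    blocks: List[Tuple[int, int, int]]
    oriented_query: str

    @property
    def query_start(self) -> int:
        return min(q for _, q, _ in self.blocks)

    @property
    def query_end(self) -> int:
        return max(q + n for _, q, n in self.blocks)


class ConsensusAligner:
    """Best local alignment of a sequence over both strands of a library."""

    def __init__(
        self,
        library: Sequence[MEConsensus],
        min_aligned_len: int = MIN_ALIGNED_LEN,
        min_identity: float = MIN_IDENTITY,
        min_seq_len: int = 20,
    ):
        if not library:
            raise ConfigurationError("empty consensus library")
        self.library = list(library)
        self.min_aligned_len = min_aligned_len
        self.min_identity = min_identity
        self.min_seq_len = min_seq_len
        self._sw = PairwiseAligner(
            mode="local",
            match_score=MATCH,
            mismatch_score=MISMATCH,
            open_gap_score=GAP_OPEN,
            extend_gap_score=GAP_EXTEND,
        )
        # exact k-mer index per (library index, strand-oriented sequence)
        self._index: List[Tuple[int, str, str, Dict[str, List[int]]]] = []
        for li, cons in enumerate(self.library):
            for strand in "+-":
                seq = cons.sequence if strand == "+" else revcomp(cons.sequence)
                idx: Dict[str, List[int]] = {}
                for i in range(0, len(seq) - SEED_K + 1):
                    idx.setdefault(seq[i : i + SEED_K], []).append(i)
                self._index.append((li, strand, seq, idx))

    def align(self, seq: str) -> Optional[MEAlignment]:
        if len(seq) < self.min_seq_len:
            return None
        seq = seq.upper()
        # short queries (e.g. minimum-length clips) may align full-length
        min_len = min(self.min_aligned_len, len(seq))
        best = self._seed_align(seq, min_len)
        if best is None:
            best = self._sw_align(seq, min_len)
        return best

    # -- fast path: exact-seed, single-diagonal ungapped extension ----------
    def _seed_align(self, seq: str, min_len: int) -> Optional[MEAlignment]:
        best: Optional[MEAlignment] = None
        for li, strand, oriented_cons, idx in self._index:
            cons = self.library[li]
            # the index holds both orientations of the consensus, so the
            # query is always compared as-is; a hit against the '-' entry
            # means the query derives from the consensus minus strand
            q = seq
            diagonals = set()
            for off in range(0, max(1, len(q) - SEED_K + 1), SEED_K):
                for hit in idx.get(q[off : off + SEED_K], ()):
                    diagonals.add(hit - off)
            for diag in sorted(diagonals):
                cand = self._extend_diagonal(q, oriented_cons, diag, cons, strand, li, min_len)
                if cand and self._better(cand, best, li):
                    best = cand
        return best

    def _extend_diagonal(
        self, q: str, oriented_cons: str, diag: int, cons: MEConsensus, strand: str, li: int,
        min_len: int,
    ) -> Optional[MEAlignment]:
        q0 = max(0, -diag)
        q1 = min(len(q), len(oriented_cons) - diag)
        if q1 - q0 < min_len:
            return None
        match = np.frombuffer(q[q0:q1].encode(), dtype=np.uint8) == np.frombuffer(
            oriented_cons[diag + q0 : diag + q1].encode(), dtype=np.uint8
        )
        # maximal-scoring contiguous run (Kadane on +2/-2 scores)
        scores = np.where(match, MATCH, MISMATCH)
        best_s = cur = 0
        best_i = best_j = cur_i = 0
        for j, s in enumerate(scores):
            if cur <= 0:
                cur, cur_i = 0, j
            cur += s
            if cur > best_s:
                best_s, best_i, best_j = cur, cur_i, j + 1
        if best_s <= 0:
            return None
        run = match[best_i:best_j]
        length = best_j - best_i
        ident = float(run.sum()) / length
        if length < min_len or ident < self.min_identity:
            return None
        oq_start = q0 + best_i
        c_start = diag + oq_start
        if strand == "-":
            return MEAlignment(
                consensus=cons.name,
                start=len(oriented_cons) - (c_start + length),
                end=len(oriented_cons) - c_start,
                strand="-",
                identity=ident,
                score=int(best_s),
                blocks=[(len(oriented_cons) - (c_start + length), len(q) - (oq_start + length), length)],
                oriented_query=revcomp(q),
            )
        return MEAlignment(
            consensus=cons.name, start=c_start, end=c_start + length, strand="+",
            identity=ident, score=int(best_s),
            blocks=[(c_start, oq_start, length)], oriented_query=q,
        )

    # -- slow path: full Smith-Waterman over the whole library --------------
    def _sw_align(self, seq: str, min_len: int) -> Optional[MEAlignment]:
        best: Optional[MEAlignment] = None
        for li, cons in enumerate(self.library):
            for strand in "+-":
                q = seq if strand == "+" else revcomp(seq)
                try:
                    score = self._sw.score(cons.sequence, q)
                except Exception:
                    continue
                if score <= 0:
                    continue
                if best is not None and score < best.score:
                    continue
                aln = self._sw.align(cons.sequence, q)[0]
                tb, qb = aln.aligned
                blocks = []
                matches = 0
                cols = 0
                for (ts, te), (qs, _qe) in zip(tb, qb):
                    n = te - ts
                    blocks.append((int(ts), int(qs), int(n)))
                    matches += sum(
                        1 for k in range(n) if cons.sequence[ts + k] == q[qs + k]
                    )
                    cols += n
                if not blocks:
                    continue
                start = blocks[0][0]
                end = blocks[-1][0] + blocks[-1][2]
                span = max(cols, end - start)
                ident = matches / span if span else 0.0
                if span < min_len or ident < self.min_identity:
                    continue
                cand = MEAlignment(
                    consensus=cons.name, start=start, end=end, strand=strand,
                    identity=ident, score=int(score), blocks=blocks, oriented_query=q,
                )
                if self._better(cand, best, li):
                    best = cand
        return best

    def _better(self, cand: MEAlignment, best: Optional[MEAlignment], li: int) -> bool:
        if best is None:
            return True
        # deterministic tie-break: score, then library order, strand, start
        kb = (-best.score, self._li(best.consensus), 0 if best.strand == "+" else 1, best.start)
        kc = (-cand.score, li, 0 if cand.strand == "+" else 1, cand.start)
        return kc < kb

    def _li(self, name: str) -> int:
        return next(i for i, c in enumerate(self.library) if c.name == name)


# ---------------------------------------------------------------------------
# pair classification
# ---------------------------------------------------------------------------

class PairClass(Enum):
    CONCORDANT = "CONCORDANT"
    DRP_CANDIDATE = "DRP_CANDIDATE"
    ONE_END_UNMAPPED = "ONE_END_UNMAPPED"
    UNINFORMATIVE = "UNINFORMATIVE"


def classify_pair(
    a: ReadAlignment, b: ReadAlignment, min_separation: int = 1_000_000
) -> PairClass:
    """Classify a mate pair; symmetric in its arguments."""
    if a.is_unmapped and b.is_unmapped:
        return PairClass.UNINFORMATIVE
    if a.is_unmapped or b.is_unmapped:
        return PairClass.ONE_END_UNMAPPED
    if a.chrom != b.chrom:
        return PairClass.DRP_CANDIDATE
    if abs(a.pos - b.pos) >= min_separation:
        return PairClass.DRP_CANDIDATE
    if a.is_proper_pair and b.is_proper_pair:
        return PairClass.CONCORDANT
    return PairClass.UNINFORMATIVE


# ---------------------------------------------------------------------------
# evidence records
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class DRPRecord:
    """Anchor read on the reference + its mate's consensus alignment."""

    sample_id: str
    chrom: str
    pos: int
    end: int  # anchor reference_end
    strand: str
    mapq: int
    me_alignment: MEAlignment
    frag: str = ""  # fragment (read pair) name, for per-pair dedup


@dataclass(slots=True)
class OrphanMate:
    """Anchored pair whose mate did not align to any consensus.

    Kept because such mates can carry 3' transduction tags or poly(A)."""

    sample_id: str
    chrom: str
    pos: int
    strand: str
    mate_sequence: str


@dataclass(slots=True)
class SplitRead:
    sample_id: str
    chrom: str
    clip_pos: int  # reference coordinate of the clip boundary
    side: str  # 'L' = clip at read start (left-of-read), 'R' = at read end
    clip_seq: str
    me_alignment: Optional[MEAlignment]
    mapq: int = 60
    frag: str = ""


@dataclass
class CoverageSummary:
    """Binned depth per chromosome plus fragment-length statistics."""

    bin_size: int = 100
    depth: Dict[str, np.ndarray] = field(default_factory=dict)
    frag_mean: float = 500.0
    frag_sd: float = 50.0
    n_pairs: int = 0

    def median_depth(self, chrom: str) -> float:
        arr = self.depth.get(chrom)
        if arr is None or len(arr) == 0:
            raise ConfigurationError(f"no coverage recorded for {chrom}")
        return float(np.median(arr))

    def local_depth(self, chrom: str, start: int, end: int) -> float:
        arr = self.depth.get(chrom)
        if arr is None:
            raise ConfigurationError(f"no coverage recorded for {chrom}")
        b0 = max(0, start // self.bin_size)
        b1 = min(len(arr), max(b0 + 1, -(-end // self.bin_size)))
        return float(np.mean(arr[b0:b1])) if b1 > b0 else 0.0


@dataclass
class ScanParams:
    min_anchor_mapq: int = 20
    min_clip_len: int = 20
    min_separation: int = 1_000_000
    use_unmapped_mates: bool = True
    decoy_prefix: str = DECOY_PREFIX


@dataclass
class ScanResult:
    drps: List[DRPRecord]
    srs: List[SplitRead]
    coverage: CoverageSummary
    orphans: List[OrphanMate] = field(default_factory=list)

    def __iter__(self):
        return iter((self.drps, self.srs, self.coverage))


def _pair_iter(
    reads: Iterable[ReadAlignment],
) -> Iterator[Tuple[ReadAlignment, Optional[ReadAlignment]]]:
    """Group a read stream into mate pairs by query name."""
    buf: Dict[str, ReadAlignment] = {}
    for r in reads:
        if r.is_secondary:
            continue
        mate = buf.pop(r.name, None)
        if mate is None:
            buf[r.name] = r
        else:
            yield mate, r
    for r in buf.values():
        yield r, None


def extract_evidence(
    reads: Iterable[ReadAlignment],
    aligner: ConsensusAligner,
    params: Optional[ScanParams] = None,
    sample_id: str = "S1",
) -> ScanResult:
    """Scan a sorted read stream for DRP and split-read MEI evidence."""
    params = params or ScanParams()
    drps: List[DRPRecord] = []
    srs: List[SplitRead] = []
    orphans: List[OrphanMate] = []
    spans: Dict[str, List[Tuple[int, int]]] = {}
    tlens: List[int] = []

    def is_decoy(chrom: str) -> bool:
        return chrom.startswith(params.decoy_prefix)

    def handle_single(r: ReadAlignment) -> None:
        if r.is_unmapped or r.is_duplicate or is_decoy(r.chrom):
            return
        spans.setdefault(r.chrom, []).append((r.pos, r.reference_end))
        if r.mapq < params.min_anchor_mapq:
            return
        if r.left_clip >= params.min_clip_len and r.cigar[0][0] == "S":
            clip = r.sequence[: r.left_clip]
            srs.append(
                SplitRead(sample_id, r.chrom, r.pos, "L", clip, aligner.align(clip), r.mapq, r.name)
            )
        if r.right_clip >= params.min_clip_len and r.cigar[-1][0] == "S":
            clip = r.sequence[len(r.sequence) - r.right_clip :]
            srs.append(
                SplitRead(sample_id, r.chrom, r.reference_end, "R", clip, aligner.align(clip), r.mapq, r.name)
            )

    for a, b in _pair_iter(reads):
        handle_single(a)
        if b is None:
            continue
        handle_single(b)
        cls = classify_pair(a, b, params.min_separation)
        if cls is PairClass.CONCORDANT and not a.is_unmapped and not b.is_unmapped:
            tlens.append(abs(max(a.reference_end, b.reference_end) - min(a.pos, b.pos)))
        admit = cls is PairClass.DRP_CANDIDATE or (
            cls is PairClass.ONE_END_UNMAPPED and params.use_unmapped_mates
        )
        if not admit:
            continue
        for anchor, mate in ((a, b), (b, a)):
            if anchor.is_unmapped or anchor.is_duplicate:
                continue
            if is_decoy(anchor.chrom) or anchor.mapq < params.min_anchor_mapq:
                continue
            aln = aligner.align(mate.sequence) if mate.sequence else None
            if aln is not None:
                drps.append(
                    DRPRecord(
                        sample_id, anchor.chrom, anchor.pos, anchor.reference_end,
                        anchor.strand, anchor.mapq, aln, anchor.name,
                    )
                )
            else:
                orphans.append(
                    OrphanMate(sample_id, anchor.chrom, anchor.pos, anchor.strand, mate.sequence)
                )

    cov = CoverageSummary()
    for chrom, sp in spans.items():
        arr_start = np.fromiter((s for s, _ in sp), dtype=np.int64)
        arr_end = np.fromiter((e for _, e in sp), dtype=np.int64)
        L = int(arr_end.max())
        acc = np.zeros(L + 1, dtype=np.float64)
        # per-base depth via a difference array, then bin means
        np.add.at(acc, arr_start, 1.0)
        np.add.at(acc, arr_end, -1.0)
        per_base = np.cumsum(acc[:-1])
        nbins = -(-L // cov.bin_size)
        padded = np.zeros(nbins * cov.bin_size)
        padded[:L] = per_base
        cov.depth[chrom] = padded.reshape(nbins, cov.bin_size).mean(axis=1)
    if len(tlens) >= 100:
        t = np.asarray(tlens, dtype=np.float64)
        cov.frag_mean = float(np.mean(t))
        cov.frag_sd = float(np.std(t)) or cov.frag_sd
    cov.n_pairs = len(tlens)

    drps.sort(key=lambda d: (d.chrom, d.pos))
    srs.sort(key=lambda s: (s.chrom, s.clip_pos))
    return ScanResult(drps, srs, cov, orphans)


# ---------------------------------------------------------------------------
# evidence TSV serialization (for the multi-sample split mode)
# ---------------------------------------------------------------------------

def write_evidence(result: ScanResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#meikit-evidence\tv1\n")
        for d in result.drps:
            m = d.me_alignment
            blocks = ";".join(f"{c},{q},{n}" for c, q, n in m.blocks)
            fh.write(
                f"DRP\t{d.sample_id}\t{d.chrom}\t{d.pos}\t{d.end}\t{d.strand}\t{d.mapq}\t"
                f"{m.consensus}\t{m.start}\t{m.end}\t{m.strand}\t{m.identity:.4f}\t{m.score}\t"
                f"{blocks}\t{m.oriented_query}\t{d.frag}\n"
            )
        for s in result.srs:
            if s.me_alignment is None:
                aln = "."
            else:
                m = s.me_alignment
                blocks = ";".join(f"{c},{q},{n}" for c, q, n in m.blocks)
                aln = f"{m.consensus}|{m.start}|{m.end}|{m.strand}|{m.identity:.4f}|{m.score}|{blocks}|{m.oriented_query}"
            fh.write(f"SR\t{s.sample_id}\t{s.chrom}\t{s.clip_pos}\t{s.side}\t{s.clip_seq}\t{s.mapq}\t{aln}\t{s.frag}\n")
        for o in result.orphans:
            fh.write(f"ORPHAN\t{o.sample_id}\t{o.chrom}\t{o.pos}\t{o.strand}\t{o.mate_sequence}\n")
        for chrom, arr in result.coverage.depth.items():
            vals = ",".join(f"{v:.2f}" for v in arr)
            fh.write(f"COV\t{chrom}\t{result.coverage.bin_size}\t{vals}\n")
        fh.write(
            f"FRAG\t{result.coverage.frag_mean:.2f}\t{result.coverage.frag_sd:.2f}\t{result.coverage.n_pairs}\n"
        )


def read_evidence(path: str) -> ScanResult:
    drps: List[DRPRecord] = []
    srs: List[SplitRead] = []
    orphans: List[OrphanMate] = []
    cov = CoverageSummary()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            tag = parts[0]
            if tag == "DRP":
                blocks = [tuple(int(x) for x in b.split(",")) for b in parts[13].split(";")]
                m = MEAlignment(parts[7], int(parts[8]), int(parts[9]), parts[10],
                                float(parts[11]), int(parts[12]), blocks, parts[14])
                drps.append(DRPRecord(parts[1], parts[2], int(parts[3]), int(parts[4]),
                                      parts[5], int(parts[6]), m,
                                      parts[15] if len(parts) > 15 else ""))
            elif tag == "SR":
                aln = None
                if parts[7] != ".":
                    f = parts[7].split("|")
                    blocks = [tuple(int(x) for x in b.split(",")) for b in f[6].split(";")]
                    aln = MEAlignment(f[0], int(f[1]), int(f[2]), f[3], float(f[4]), int(f[5]), blocks, f[7])
                srs.append(SplitRead(parts[1], parts[2], int(parts[3]), parts[4], parts[5], aln,
                                     int(parts[6]), parts[8] if len(parts) > 8 else ""))
            elif tag == "ORPHAN":
                orphans.append(OrphanMate(parts[1], parts[2], int(parts[3]), parts[4], parts[5]))
            elif tag == "COV":
                cov.bin_size = int(parts[2])
                cov.depth[parts[1]] = np.array([float(x) for x in parts[3].split(",")])
            elif tag == "FRAG":
                cov.frag_mean, cov.frag_sd, cov.n_pairs = float(parts[1]), float(parts[2]), int(parts[3])
    return ScanResult(drps, srs, cov, orphans)
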