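"""Consensus-space annotation of finalized sites.

From the consensus alignments accumulated at a site this module builds a
pileup, calls interior mutations, assigns the element to a subfamily by
diagnostic-mutation scoring, detects 5' inversions (opposite-strand 5' vs
3' alignment groups, the twin-priming signature) and 3' transductions
(non-poly(A) sequence carried past the element 3' end that maps uniquely
elsewhere in the reference), and annotates gene impact.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import ParseError
from .evidence_scan import MEAlignment, MEConsensus
from .formats_io import GenomeInterval, revcomp
from .site_discovery import CandidateSite, MEICall

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ConsensusPileup:
    consensus: str
    depth: np.ndarray  # int array, length L
    base_counts: np.ndarray  # 4 x L
    strand_counts: np.ndarray  # 2 x L (plus, minus)

    @property
    def covered_span(self) -> Optional[Tuple[int, int]]:
        nz = np.nonzero(self.depth)[0]
        if len(nz) == 0:
            return None
        return int(nz[0]), int(nz[-1]) + 1


@dataclass
class MutationProfile:
    mutations: List[Tuple[int, str, str]]  # (position, ref, alt), increasing
    cpg_flags: List[bool]
    assessable: Set[int]  # consensus positions with depth >= caller minimum

    def as_set(self) -> Set[Tuple[int, str, str]]:
        return set(self.mutations)


@dataclass
class InversionCall:
    inverted: bool
    junction: Optional[int]
    assessable: bool


@dataclass
class TransductionCall:
    transduced_sequence: str
    locus: Optional[GenomeInterval]
    source_id: str
    second_polya: bool


def _site_alignments(site: CandidateSite, me_class: str) -> List[MEAlignment]:
    alns = [d.me_alignment for d in site.all_drps if d.me_alignment.consensus == me_class]
    alns += [
        s.me_alignment
        for s in site.split_reads
        if s.me_alignment is not None and s.me_alignment.consensus == me_class
    ]
    return alns


def build_pileup(site: CandidateSite, consensus: MEConsensus) -> ConsensusPileup:
    """Stack every accepted consensus alignment at the site into a pileup."""
    L = len(consensus)
    depth = np.zeros(L, dtype=np.int32)
    bases = np.zeros((4, L), dtype=np.int32)
    strands = np.zeros((2, L), dtype=np.int32)
    for aln in _site_alignments(site, consensus.name):
        srow = 0 if aln.strand == "+" else 1
        for cstart, qstart, n in aln.blocks:
            for k in range(n):
                cpos = cstart + k
                if cpos >= L:
                    break
                b = aln.oriented_query[qstart + k]
                depth[cpos] += 1
                strands[srow, cpos] += 1
                bi = _BASE_IDX.get(b)
                if bi is not None:
                    bases[bi, cpos] += 1
    return ConsensusPileup(consensus.name, depth, bases, strands)


def element_span(
    site: CandidateSite, consensus: MEConsensus
) -> Tuple[int, int]:
    alns = _site_alignments(site, consensus.name)
    return min(a.start for a in alns), max(a.end for a in alns)


def estimate_polya(site: CandidateSite, consensus: MEConsensus) -> int:
    """Median leading-A run length of mate overhangs past the consensus end."""
    runs = []
    L = len(consensus)
    for d in site.all_drps:
        a = d.me_alignment
        if a.consensus != consensus.name or a.end < L - 5:
            continue
        tail = a.oriented_query[a.query_end :]
        n = 0
        for ch in tail:
            if ch != "A":
                break
            n += 1
        if n:
            runs.append(n)
    for o in site.orphans:
        for seq in (o.mate_sequence, revcomp(o.mate_sequence)):
            n = 0
            for ch in seq:
                if ch != "A":
                    break
                n += 1
            if n >= 8:
                runs.append(n)
                break
    if not runs:
        return 0
    return int(np.median(runs))


def call_interior_mutations(
    pileup: ConsensusPileup,
    consensus: MEConsensus,
    min_depth: int = 3,
    min_frac: float = 0.7,
) -> MutationProfile:
    """Report consensus positions where a non-consensus base dominates."""
    muts: List[Tuple[int, str, str]] = []
    cpg: List[bool] = []
    assessable = {int(p) for p in np.nonzero(pileup.depth >= min_depth)[0]}
    for pos in sorted(assessable):
        ref = consensus.sequence[pos]
        d = int(pileup.depth[pos])
        counts = pileup.base_counts[:, pos]
        bi = int(np.argmax(counts))
        alt = "ACGT"[bi]
        if alt != ref and counts[bi] / d >= min_frac:
            muts.append((pos, ref, alt))
            cpg.append(pos in consensus.cpg_positions)
    return MutationProfile(muts, cpg, assessable)


def assign_subfamily(
    profile: MutationProfile, consensus: MEConsensus
) -> Tuple[str, float]:
    """Score = diagnostics present - 0.5 * diagnostics assessable-but-absent."""
    present_set = profile.as_set()
    best: Optional[Tuple[float, int, str]] = None
    for sub, diags in consensus.subfamilies.items():
        assessable = {m for m in diags if m[0] in profile.assessable}
        present = len(assessable & present_set)
        score = present - 0.5 * (len(assessable) - present)
        key = (-score, len(diags), sub)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[2], -best[0]


def discover_novel_subfamilies(
    calls: Sequence[MEICall],
    library: Sequence[MEConsensus],
    min_copies: int = 5,
) -> List[Tuple[frozenset, List[str]]]:
    """Group calls by shared novel non-CpG mutation sets (>= min_copies loci)."""
    by_class = {c.name: c for c in library}
    groups: Dict[Tuple[str, frozenset], Dict[Tuple[str, int], str]] = {}
    for call in calls:
        cons = by_class.get(call.me_class)
        if cons is None:
            continue
        muts = call.features.get("mutations")
        if not muts:
            continue
        known = set().union(*cons.subfamilies.values()) if cons.subfamilies else set()
        novel = frozenset(
            m for m in muts if m[0] not in cons.cpg_positions and m not in known
        )
        if not novel:
            continue
        groups.setdefault((call.me_class, novel), {})[(call.chrom, call.position)] = call.id
    out = []
    for (_cls, key), members in sorted(groups.items(), key=lambda kv: sorted(kv[0][1])):
        if len(members) >= min_copies:
            out.append((key, sorted(members.values())))
    return out


def detect_inversion(
    site: CandidateSite, consensus: MEConsensus, min_side: int = 3
) -> InversionCall:
    """Twin-priming detection: 5' and 3' alignment groups on opposite strands."""
    alns = _site_alignments(site, consensus.name)
    plus = [a for a in alns if a.strand == "+"]
    minus = [a for a in alns if a.strand == "-"]
    if len(plus) >= min_side and len(minus) >= min_side:
        mean_p = float(np.mean([(a.start + a.end) / 2 for a in plus]))
        mean_m = float(np.mean([(a.start + a.end) / 2 for a in minus]))
        if abs(mean_p - mean_m) < 50:  # interleaved strands, not a 5'/3' split
            return InversionCall(False, None, False)
        five, three = (minus, plus) if mean_m < mean_p else (plus, minus)
        # the 5' (inverted) group's rightmost end sits exactly at the twin-
        # priming junction; average with the 3' group's start only when the
        # two groups adjoin (mate coverage rarely reaches a deep junction
        # from the 3' side of a long element)
        j5 = max(a.end for a in five)
        j3 = min(a.start for a in three)
        junction = (j5 + j3) // 2 if j3 <= j5 + 200 else j5
        return InversionCall(True, int(junction), True)
    # single-strand evidence: assessable only if the covered span reaches the
    # 5' half of the consensus (otherwise there is no 5' portion to judge)
    centers = sorted((a.start + a.end) / 2 for a in alns)
    assessable = (
        len(alns) >= 2 * min_side
        and centers[min_side - 1] < centers[-min_side]
        and min(a.start for a in alns) < len(consensus) // 2
    )
    return InversionCall(False, None, assessable)


def _leading_a(seq: str) -> int:
    n = 0
    for ch in seq:
        if ch != "A":
            break
        n += 1
    return n


def _trailing_a(seq: str) -> int:
    return _leading_a(seq[::-1])


def _a_fraction(seq: str) -> float:
    return seq.count("A") / len(seq) if seq else 1.0


def _find_unique(reference: Dict[str, str], tag: str) -> Optional[GenomeInterval]:
    """Exact unique placement of a tag (either strand) in the reference."""
    hits: List[Tuple[str, int, str]] = []
    for query, strand in ((tag, "+"), (revcomp(tag), "-")):
        for chrom, seq in reference.items():
            start = 0
            while True:
                i = seq.find(query, start)
                if i < 0:
                    break
                hits.append((chrom, i, strand))
                if len(hits) > 1:
                    return None
                start = i + 1
    if len(hits) != 1:
        return None
    chrom, i, strand = hits[0]
    return GenomeInterval(chrom, i, i + len(tag), "tag", strand)


def detect_transduction(
    site: CandidateSite,
    consensus: MEConsensus,
    reference: Dict[str, str],
    fl_sources: Sequence[GenomeInterval] = (),
    min_tag_len: int = 30,
    max_a_fraction: float = 0.8,
    polya_min: int = 8,
    source_window: int = 500,
) -> Optional[TransductionCall]:
    """Look for a non-poly(A) 3' tail that maps uniquely in the reference."""
    L = len(consensus)
    candidates: List[Tuple[str, bool]] = []  # (tag, ends_in_polya)
    for d in site.all_drps:
        a = d.me_alignment
        if a.consensus != consensus.name or a.end < L - 10:
            continue
        tail = a.oriented_query[a.query_end :]
        run = _leading_a(tail)
        if run >= 1:
            tail = tail[run:]
        second = _trailing_a(tail) >= polya_min
        if second:
            tail = tail[: len(tail) - _trailing_a(tail)]
        if len(tail) >= min_tag_len and _a_fraction(tail) < max_a_fraction:
            candidates.append((tail, second))
    for o in site.orphans:
        seq = o.mate_sequence
        # strip flanking poly(A)/poly(T) runs in either orientation
        for s in (seq, revcomp(seq)):
            t = s[_leading_a(s) :]
            second = _trailing_a(t) >= polya_min
            core = t[: len(t) - _trailing_a(t)] if _trailing_a(t) else t
            if len(core) >= min_tag_len and _a_fraction(core) < max_a_fraction:
                candidates.append((core, second))
                break
    if not candidates:
        return None
    # map each candidate tag; keep the modal unique locus
    loci: List[Tuple[GenomeInterval, str, bool]] = []
    for tag, second in candidates:
        iv = _find_unique(reference, tag)
        if iv is not None:
            loci.append((iv, tag, second))
    if not loci:
        return None
    keyed = Counter((iv.chrom, iv.start // 200) for iv, _, _ in loci)
    best_key = keyed.most_common(1)[0][0]
    chosen = [x for x in loci if (x[0].chrom, x[0].start // 200) == best_key]
    iv, tag, second = max(chosen, key=lambda x: len(x[1]))
    second = second or any(s for _, _, s in chosen)
    source_id = "unplaced"
    for src in fl_sources:
        if src.chrom != iv.chrom:
            continue
        if src.strand == "+" and 0 <= iv.start - src.end <= source_window:
            source_id = src.label or f"{src.chrom}:{src.start}"
            break
        if src.strand == "-" and 0 <= src.start - iv.end <= source_window:
            source_id = src.label or f"{src.chrom}:{src.start}"
            break
    return TransductionCall(tag, iv, source_id, second)


# ---------------------------------------------------------------------------
# gene impact
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: List[Tuple[int, int]]


def load_gene_models(path: str) -> List[GeneModel]:
    """Minimal BED12 reader (blocks = exons, thick = CDS)."""
    genes: List[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ParseError(f"{path}:{ln}: BED12 needs 12 columns")
            start, end = int(p[1]), int(p[2])
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offs = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            genes.append(
                GeneModel(p[3], p[0], p[5], start, end, int(p[6]), int(p[7]), exons)
            )
    return genes


_SEVERITY = {"exon": 0, "5UTR": 1, "3UTR": 1, "promoter": 2, "terminator": 2, "intron": 3, "intergenic": 4}


def annotate_gene_impact(
    call: MEICall, genes: Sequence[GeneModel], promoter_size: int = 1000
) -> str:
    """Most severe gene feature overlapped by the insertion point."""
    pos = call.position
    labels: List[str] = []
    for g in genes:
        if g.chrom != call.chrom:
            continue
        tss, tes = (g.tx_start, g.tx_end) if g.strand == "+" else (g.tx_end, g.tx_start)
        if g.strand == "+":
            if g.tx_start - promoter_size <= pos < g.tx_start:
                labels.append("promoter")
            if g.tx_end <= pos < g.tx_end + promoter_size:
                labels.append("terminator")
        else:
            if g.tx_end <= pos < g.tx_end + promoter_size:
                labels.append("promoter")
            if g.tx_start - promoter_size <= pos < g.tx_start:
                labels.append("terminator")
        if g.tx_start <= pos < g.tx_end:
            in_exon = None
            for es, ee in g.exons:
                if es <= pos < ee:
                    in_exon = (es, ee)
                    break
            if in_exon is None:
                labels.append("intron")
            elif g.cds_start <= pos < g.cds_end:
                labels.append("exon")
            else:
                before_cds = pos < g.cds_start
                if (g.strand == "+") == before_cds:
                    labels.append("5UTR")
                else:
                    labels.append("3UTR")
    if not labels:
        return "intergenic"
    return min(labels, key=lambda l: _SEVERITY[l])


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def annotate_call(
    call: MEICall,
    library: Sequence[MEConsensus],
    reference: Dict[str, str],
    fl_sources: Sequence[GenomeInterval] = (),
    genes: Sequence[GeneModel] = (),
) -> None:
    """Fill a call's feature map (subfamily, DIFF, INV5, TDN, gene impact)."""
    cons = next((c for c in library if c.name == call.me_class), None)
    if cons is None or call.site is None:
        return
    site = call.site
    pileup = build_pileup(site, cons)
    profile = call_interior_mutations(pileup, cons)
    call.features["mutations"] = profile.mutations
    span = element_span(site, cons)
    call.consensus_start, call.consensus_stop = span
    polya = estimate_polya(site, cons)
    call.svlen = (span[1] - span[0]) + polya
    call.features["truncated"] = "yes" if span[0] > 50 else "no"
    if len(cons.subfamilies) > 1:  # beyond the class root: Alu/L1 style
        sub, score = assign_subfamily(profile, cons)
    else:
        sub, score = cons.name, 0.0
    mut_str = ",".join(f"{r.lower()}{p}{a.lower()}" for p, r, a in profile.mutations)
    call.features["subfamily"] = sub
    call.features["diff"] = f"{sub}:{mut_str if mut_str else 'none'}"
    inv = detect_inversion(site, cons)
    call.features["inv5"] = f"{inv.junction}" if inv.inverted else ""
    call.features["inv5_assessable"] = "yes" if inv.assessable else "no"
    td = detect_transduction(site, cons, reference, fl_sources)
    if td is not None and td.locus is not None:
        call.features["tdn"] = td.source_id
        call.features["tdn_locus"] = f"{td.locus.chrom}:{td.locus.start}-{td.locus.end}"
    else:
        call.features["tdn"] = ""
    call.features["gene_impact"] = annotate_gene_impact(call, genes)
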