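"""Per-sample genotype likelihoods for insertions and reference-ME deletions.

Diploid binomial-mixture model: with ``g`` alternate copies the chance a
sampled informative read supports the alternate allele is
``p(g) = (g/2)(1-e) + (1-g/2)e`` with read-level error rate ``e``.  With
``a`` alternate- and ``b`` reference-supporting reads the likelihood is
``L(g) = p(g)^a (1-p(g))^b``; genotypes are the flat-prior argmax, GLs are
log10-scaled and normalized to a 0 maximum.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .errors import ConfigurationError
from .formats_io import GenomeInterval, ReadAlignment
from .site_discovery import MEICall

DEFAULT_ERROR_RATE = 0.01
MIN_INFORMATIVE = 2


@dataclass(slots=True)
class EvidenceCounts:
    alt: int
    ref: int
    error_rate: float = DEFAULT_ERROR_RATE

    def __post_init__(self):
        if self.alt < 0 or self.ref < 0:
            raise ConfigurationError("negative evidence counts")
        if not 0.0 < self.error_rate < 0.5:
            raise ConfigurationError("error rate must be in (0, 0.5)")


@dataclass(slots=True)
class SampleGenotype:
    gt: str  # 0/0, 0/1, 1/1 or ./.
    gl: Tuple[float, float, float]
    gq: int
    ad: Tuple[int, int]  # (ref, alt)


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def genotype_likelihoods(
    counts: EvidenceCounts, min_informative: int = MIN_INFORMATIVE
) -> SampleGenotype:
    a, b, e = counts.alt, counts.ref, counts.error_rate
    if a + b < min_informative:
        return SampleGenotype("./.", (0.0, 0.0, 0.0), 0, (b, a))
    logl = []
    for g in (0, 1, 2):
        p = (g / 2.0) * (1.0 - e) + (1.0 - g / 2.0) * e
        logl.append(a * math.log10(p) + b * math.log10(1.0 - p))
    order = sorted(range(3), key=lambda g: -logl[g])
    best = order[0]
    m = logl[best]
    gl = tuple(round(x - m, 6) for x in logl)
    gq = int(round(10.0 * (logl[best] - logl[order[1]])))
    return SampleGenotype(_GT[best], gl, gq, (b, a))


# ---------------------------------------------------------------------------
# read-window index (per sample)
# ---------------------------------------------------------------------------

class ReadIndex:
    """Position-sorted per-chromosome view of a sample's reads."""

    def __init__(self, reads: Iterable[ReadAlignment], sample_id: str = "S1"):
        self.sample_id = sample_id
        self._by_chrom: Dict[str, List[ReadAlignment]] = {}
        for r in reads:
            if r.is_unmapped or r.is_secondary:
                continue
            self._by_chrom.setdefault(r.chrom, []).append(r)
        self._starts: Dict[str, List[int]] = {}
        for chrom, lst in self._by_chrom.items():
            lst.sort(key=lambda r: r.pos)
            self._starts[chrom] = [r.pos for r in lst]

    def fetch(self, chrom: str, start: int, end: int) -> List[ReadAlignment]:
        lst = self._by_chrom.get(chrom)
        if not lst:
            return []
        starts = self._starts[chrom]
        # reads are bounded in length; scan back a little for overlaps
        lo = bisect.bisect_left(starts, start - 1000)
        hi = bisect.bisect_right(starts, end)
        return [r for r in lst[lo:hi] if r.reference_end > start and r.pos < end]


@dataclass
class GenotypeParams:
    error_rate: float = DEFAULT_ERROR_RATE
    min_informative: int = MIN_INFORMATIVE
    sr_bp_slop: int = 5
    span_flank: int = 20
    max_clip: int = 5
    frag_mean: float = 500.0
    frag_sd: float = 50.0
    insert_nsd: float = 4.0
    min_mapq: int = 20
    nocall_max_fraction: float = 0.25


def count_evidence(
    call: MEICall, index: ReadIndex, params: Optional[GenotypeParams] = None
) -> EvidenceCounts:
    """Tally alternate (DRP+SR) and reference (clean spanning) support."""
    params = params or GenotypeParams()
    bp = call.position + 1  # breakpoint boundary coordinate
    bps = {bp}
    if call.breakpoint is not None:
        if call.breakpoint.bp_left is not None:
            bps.add(call.breakpoint.bp_left)
        if call.breakpoint.bp_right is not None:
            bps.add(call.breakpoint.bp_right)
    a = 0
    if call.site is not None:
        a += sum(1 for d in call.site.all_drps if d.sample_id == index.sample_id)
        a += sum(
            1
            for s in call.site.split_reads
            if s.sample_id == index.sample_id
            and min(abs(s.clip_pos - x) for x in bps) <= params.sr_bp_slop
        )
    b = 0
    w0, w1 = bp - params.span_flank, bp + params.span_flank
    lo_ins = params.frag_mean - params.insert_nsd * params.frag_sd
    hi_ins = params.frag_mean + params.insert_nsd * params.frag_sd
    pad = int(hi_ins) + 100
    by_name: Dict[str, List[ReadAlignment]] = {}
    for r in index.fetch(call.chrom, w0 - pad, w1 + pad):
        by_name.setdefault(r.name, []).append(r)
    for reads in by_name.values():
        clean = [
            r for r in reads
            if r.is_proper_pair and max(r.left_clip, r.right_clip) < params.max_clip
        ]
        if len(clean) != len(reads):
            continue  # a clipped mate disqualifies the whole fragment
        if len(clean) == 2:
            span0 = min(r.pos for r in clean)
            span1 = max(r.reference_end for r in clean)
            if span0 <= w0 and span1 >= w1 and lo_ins <= span1 - span0 <= hi_ins:
                b += 1
        elif len(clean) == 1:
            r = clean[0]
            if r.pos <= w0 and r.reference_end >= w1:
                b += 1
    return EvidenceCounts(a, b, params.error_rate)


def genotype_call(
    call: MEICall, indexes: Sequence[ReadIndex], params: Optional[GenotypeParams] = None
) -> Dict[str, SampleGenotype]:
    params = params or GenotypeParams()
    out: Dict[str, SampleGenotype] = {}
    for idx in indexes:
        counts = count_evidence(call, idx, params)
        out[idx.sample_id] = genotype_likelihoods(counts, params.min_informative)
    return out


def apply_site_filters(
    call: MEICall,
    genotypes: Dict[str, SampleGenotype],
    params: Optional[GenotypeParams] = None,
) -> Set[str]:
    """Post-genotyping filters: one-sided evidence, no-call load, SR absence."""
    params = params or GenotypeParams()
    flags: Set[str] = set()
    if call.site is not None:
        if not (call.site.left_drps and call.site.right_drps):
            flags.add("lc")
        if len(call.site.split_reads) == 0:
            flags.add("noSR")
    if genotypes:
        frac = sum(1 for g in genotypes.values() if g.gt == "./.") / len(genotypes)
        if frac > params.nocall_max_fraction:
            flags.add("hNC")
    call.filters |= flags
    return flags


# ---------------------------------------------------------------------------
# reference-ME deletion genotyping
# ---------------------------------------------------------------------------

def genotype_deletion(
    interval: GenomeInterval,
    index: ReadIndex,
    params: Optional[GenotypeParams] = None,
    read_len: int = 100,
) -> SampleGenotype:
    """Genotype absence of an annotated reference ME copy in one sample.

    Deletion support: pairs that jump the interval with a donor-scale
    insert, plus reads clipped at either interval edge; reference support:
    reads mapping wholly inside the interval.
    """
    params = params or GenotypeParams()
    if len(interval) < 2 * read_len:
        return SampleGenotype("./.", (0.0, 0.0, 0.0), 0, (0, 0))
    pad = int(params.frag_mean + params.insert_nsd * params.frag_sd)
    reads = index.fetch(interval.chrom, interval.start - pad, interval.end + pad)
    alt = 0
    ref = 0
    lo = params.frag_mean - 3.0 * params.frag_sd
    hi = params.frag_mean + 3.0 * params.frag_sd
    for r in reads:
        if r.mapq < params.min_mapq:
            continue
        if r.pos >= interval.start and r.reference_end <= interval.end:
            ref += 1
            continue
        # clipped exactly at an interval edge (flank-joining split read)
        if (r.right_clip >= params.max_clip and r.reference_end == interval.start) or (
            r.left_clip >= params.max_clip and r.pos == interval.end
        ):
            alt += 1
            continue
        # jumping pair, counted once from its left read
        if (
            r.mate_chrom == r.chrom
            and r.mate_pos is not None
            and r.pos < r.mate_pos
            and r.reference_end <= interval.start
            and r.mate_pos >= interval.end
        ):
            span = (r.mate_pos + read_len) - r.pos
            if lo <= span - len(interval) <= hi:
                alt += 1
    return genotype_likelihoods(
        EvidenceCounts(alt, ref, params.error_rate), params.min_informative
    )
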