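"""Candidate-site construction from pooled DRP/SR evidence.

DRP anchors are single-linkage clustered along each chromosome (gap <=
``window``); clusters with at least four DRPs summed over samples become
candidate sites.  Anchors on the plus strand point rightward into the site
(left side); minus-strand anchors form the right side.  Split reads then
refine the breakpoint pair: the modal right-of-read clip position gives the
left breakpoint (bpL), the modal left-of-read clip position the right
breakpoint (bpR).  bpL > bpR implies a target-site duplication of
reference[bpR, bpL); bpL < bpR a target-site deletion; equality a blunt
joint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .errors import ConfigurationError, MeikitError
from .evidence_scan import (
    CoverageSummary,
    DRPRecord,
    OrphanMate,
    ScanResult,
    SplitRead,
)
from .formats_io import GenomeInterval

MIN_CLUSTER_DRPS = 4


@dataclass
class DiscoveryParams:
    cluster_window: int = 500
    min_cluster_drps: int = MIN_CLUSTER_DRPS
    sr_attach_pad: int = 500  # ~ one fragment length
    refme_proximity: int = 50
    depth_hi: float = 2.5
    depth_lo: float = 0.25
    gap_pad: int = 500
    depth_window: int = 250


@dataclass
class CandidateSite:
    chrom: str
    window: GenomeInterval
    left_drps: List[DRPRecord] = field(default_factory=list)
    right_drps: List[DRPRecord] = field(default_factory=list)
    split_reads: List[SplitRead] = field(default_factory=list)
    orphans: List[OrphanMate] = field(default_factory=list)

    @property
    def total_drps(self) -> int:
        return len(self.left_drps) + len(self.right_drps)

    @property
    def all_drps(self) -> List[DRPRecord]:
        return self.left_drps + self.right_drps

    def me_class(self) -> str:
        """Majority consensus class over the mate alignments."""
        votes = Counter(d.me_alignment.consensus for d in self.all_drps)
        return votes.most_common(1)[0][0]


@dataclass
class RefinedBreakpoint:
    position: int  # 0-based base after which the insertion occurs
    tsd: str  # "" when absent
    tsd_deletion: int  # >0 for target-site deletion
    blunt: bool
    orientation: str
    bp_left: Optional[int]
    bp_right: Optional[int]
    n_sr_left: int
    n_sr_right: int
    tsd_consistent: bool
    lc: bool = False


@dataclass
class MEICall:
    """Finalized insertion (or reference-deletion) call."""

    id: str
    chrom: str
    position: int  # 0-based base after which insertion occurs
    orientation: str
    me_class: str
    consensus_start: int
    consensus_stop: int
    svlen: int
    tsd: str
    tsd_deletion: int
    tranche: int
    filters: Set[str] = field(default_factory=set)
    features: Dict[str, str] = field(default_factory=dict)
    kind: str = "INS"  # INS or DEL
    site: Optional[CandidateSite] = None
    breakpoint: Optional[RefinedBreakpoint] = None


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_drps(
    drps: Sequence[DRPRecord],
    window: int = 500,
    min_support: int = MIN_CLUSTER_DRPS,
) -> List[CandidateSite]:
    """Single-linkage clustering of DRP anchors, one pass per chromosome."""
    by_chrom: Dict[str, List[DRPRecord]] = {}
    for d in drps:
        by_chrom.setdefault(d.chrom, []).append(d)
    sites: List[CandidateSite] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda d: d.pos)
        cluster: List[DRPRecord] = []
        for d in recs:
            if cluster and d.pos - cluster[-1].pos > window:
                sites.extend(_close_cluster(chrom, cluster, min_support))
                cluster = []
            cluster.append(d)
        sites.extend(_close_cluster(chrom, cluster, min_support))
    return sites


def _close_cluster(
    chrom: str, cluster: List[DRPRecord], min_support: int
) -> List[CandidateSite]:
    if len(cluster) < min_support:
        return []
    start = min(d.pos for d in cluster)
    end = max(d.end for d in cluster)
    site = CandidateSite(chrom, GenomeInterval(chrom, start, max(end, start + 1)))
    for d in cluster:
        (site.left_drps if d.strand == "+" else site.right_drps).append(d)
    return [site]


def attach_split_reads(
    sites: Sequence[CandidateSite],
    srs: Sequence[SplitRead],
    orphans: Sequence[OrphanMate] = (),
    pad: int = 500,
) -> None:
    """Assign split reads (and orphan mates) to the nearest overlapping site."""
    for site in sites:
        lo, hi = site.window.start - pad, site.window.end + pad
        for s in srs:
            if s.chrom == site.chrom and lo <= s.clip_pos <= hi:
                site.split_reads.append(s)
        for o in orphans:
            if o.chrom == site.chrom and lo <= o.pos <= hi:
                site.orphans.append(o)


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def filter_candidate(
    site: CandidateSite,
    ref_mes: Sequence[GenomeInterval],
    gaps: Sequence[GenomeInterval],
    coverage: CoverageSummary,
    params: Optional[DiscoveryParams] = None,
) -> Set[str]:
    """Annotation filters; an empty set means the site is retained clean."""
    if coverage is None:
        raise ConfigurationError("filter_candidate requires a coverage summary")
    params = params or DiscoveryParams()
    flags: Set[str] = set()
    cls = site.me_class()
    w = site.window
    for me in ref_mes:
        if me.label and me.label.split(":")[0] != cls:
            continue
        if me.overlaps(w.chrom, w.start - params.refme_proximity, w.end + params.refme_proximity):
            flags.add("refME")
            break
    for gap in gaps:
        if gap.overlaps(w.chrom, w.start - params.gap_pad, w.end + params.gap_pad):
            flags.add("mask")
            break
    mid = (w.start + w.end) // 2
    local = coverage.local_depth(w.chrom, mid - params.depth_window, mid + params.depth_window)
    med = coverage.median_depth(w.chrom)
    if med > 0 and (local > params.depth_hi * med or local < params.depth_lo * med):
        flags.add("depth")
    return flags


# ---------------------------------------------------------------------------
# breakpoint refinement
# ---------------------------------------------------------------------------

def _modal(positions: Iterable[int]) -> Optional[int]:
    counts = Counter(positions)
    if not counts:
        return None
    # highest count; ties resolved toward the smaller coordinate
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def refine_breakpoint(
    site: CandidateSite, reference: Dict[str, str]
) -> RefinedBreakpoint:
    """Derive breakpoint pair, TSD/deletion and orientation for one site."""
    if site.total_drps == 0:
        raise MeikitError("refine_breakpoint called on a site with no DRPs")
    bpL = _modal(s.clip_pos for s in site.split_reads if s.side == "R")
    bpR = _modal(s.clip_pos for s in site.split_reads if s.side == "L")
    tsd = ""
    tsd_del = 0
    blunt = False
    consistent = False
    if bpL is not None and bpR is not None:
        position = min(bpL, bpR) - 1
        if bpL > bpR:
            tsd = reference[site.chrom][bpR:bpL]
            consistent = True
        elif bpL < bpR:
            tsd_del = bpR - bpL
        else:
            blunt = True
    elif bpL is not None:
        position = bpL - 1
    elif bpR is not None:
        position = bpR - 1
    else:
        left_end = max((d.end for d in site.left_drps), default=None)
        right_start = min((d.pos for d in site.right_drps), default=None)
        if left_end is not None and right_start is not None:
            position = (left_end + right_start) // 2
        elif left_end is not None:
            position = left_end
        else:
            position = right_start
    lc = False
    votes = Counter(d.me_alignment.strand for d in site.left_drps)
    if not votes:
        votes = Counter(d.me_alignment.strand for d in site.right_drps)
    plus, minus = votes.get("+", 0), votes.get("-", 0)
    if plus > minus:
        orientation = "+"
    elif minus > plus:
        orientation = "-"
    else:
        orientation = "+"
        lc = True
    return RefinedBreakpoint(
        position=position, tsd=tsd, tsd_deletion=tsd_del, blunt=blunt,
        orientation=orientation, bp_left=bpL, bp_right=bpR,
        n_sr_left=sum(1 for s in site.split_reads if s.side == "R"),
        n_sr_right=sum(1 for s in site.split_reads if s.side == "L"),
        tsd_consistent=consistent, lc=lc,
    )


def assess_tranche(site: CandidateSite, bp: RefinedBreakpoint) -> int:
    """Map the evidence configuration to the 0-5 breakpoint quality scale."""
    has_left_drp = bool(site.left_drps)
    has_right_drp = bool(site.right_drps)
    if bp.n_sr_left > 0 and bp.n_sr_right > 0:
        return 5 if bp.tsd_consistent else 4
    if (bp.n_sr_left > 0 or bp.n_sr_right > 0) and has_left_drp and has_right_drp:
        return 3
    if has_left_drp and has_right_drp:
        return 2
    if has_left_drp or has_right_drp:
        return 1
    return 0


# ---------------------------------------------------------------------------
# multi-sample pooling
# ---------------------------------------------------------------------------

def merge_samples(results: Sequence[ScanResult]) -> ScanResult:
    """Pool per-sample evidence for joint (split-mode) discovery."""
    if not results:
        raise ConfigurationError("merge_samples needs at least one evidence set")
    seen: Set[str] = set()
    for r in results:
        ids = {d.sample_id for d in r.drps} | {s.sample_id for s in r.srs}
        if not ids:
            continue
        dup = seen & ids
        if dup:
            raise ConfigurationError(f"duplicate sample id(s) in merge: {sorted(dup)}")
        seen |= ids
    drps = sorted((d for r in results for d in r.drps), key=lambda d: (d.chrom, d.pos))
    srs = sorted((s for r in results for s in r.srs), key=lambda s: (s.chrom, s.clip_pos))
    orphans = [o for r in results for o in r.orphans]
    # pooled coverage = element-wise sum of per-sample binned depth
    cov = CoverageSummary(bin_size=results[0].coverage.bin_size)
    for r in results:
        for chrom, arr in r.coverage.depth.items():
            cur = cov.depth.get(chrom)
            if cur is None:
                cov.depth[chrom] = arr.copy()
            else:
                n = max(len(cur), len(arr))
                merged = cur.copy() if len(cur) == n else _padded(cur, n)
                merged[: len(arr)] += arr[: len(merged)] if len(arr) <= n else arr[:n]
                cov.depth[chrom] = merged
    cov.frag_mean = sum(r.coverage.frag_mean for r in results) / len(results)
    cov.frag_sd = sum(r.coverage.frag_sd for r in results) / len(results)
    cov.n_pairs = sum(r.coverage.n_pairs for r in results)
    return ScanResult(drps, srs, cov, orphans)


def _padded(arr, n):
    import numpy as np

    out = np.zeros(n, dtype=arr.dtype)
    out[: len(arr)] = arr
    return out


# ---------------------------------------------------------------------------
# discovery driver
# ---------------------------------------------------------------------------

def discover_sites(
    evidence: ScanResult,
    reference: Dict[str, str],
    ref_mes: Sequence[GenomeInterval] = (),
    gaps: Sequence[GenomeInterval] = (),
    params: Optional[DiscoveryParams] = None,
) -> List[MEICall]:
    """Cluster, filter and refine pooled evidence into raw MEI calls.

    Feature annotation and genotyping are applied downstream; the calls
    carry their candidate sites so later stages can reuse the evidence.
    """
    params = params or DiscoveryParams()
    sites = cluster_drps(evidence.drps, params.cluster_window, params.min_cluster_drps)
    attach_split_reads(sites, evidence.srs, evidence.orphans, params.sr_attach_pad)
    calls: List[MEICall] = []
    for site in sites:
        flags = filter_candidate(site, ref_mes, gaps, evidence.coverage, params)
        bp = refine_breakpoint(site, reference)
        tranche = assess_tranche(site, bp)
        if bp.lc or not (site.left_drps and site.right_drps):
            flags.add("lc")
        alns = [d.me_alignment for d in site.all_drps]
        alns += [s.me_alignment for s in site.split_reads if s.me_alignment is not None]
        cls = site.me_class()
        cls_alns = [a for a in alns if a.consensus == cls]
        span_start = min(a.start for a in cls_alns)
        span_stop = max(a.end for a in cls_alns)
        call = MEICall(
            id="", chrom=site.chrom, position=bp.position, orientation=bp.orientation,
            me_class=cls, consensus_start=span_start, consensus_stop=span_stop,
            svlen=span_stop - span_start, tsd=bp.tsd, tsd_deletion=bp.tsd_deletion,
            tranche=tranche, filters=flags, site=site, breakpoint=bp,
        )
        calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.position))
    for i, c in enumerate(calls, 1):
        c.id = f"MEI_{i:05d}"
    return calls
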