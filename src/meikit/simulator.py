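"""Ground-truth simulation and evaluation harness.

Generates a synthetic reference (optionally with embedded reference ME
copies, full-length L1 source elements and N-gap masks), plants featureful
ME insertions or reference-ME deletions into a diploid donor, simulates
error-free inward-facing read pairs, and projects them into truth-aware
alignments so the whole pipeline runs with no external aligner.  Reads
wholly inside a novel insertion are placed on a per-class decoy contig, so
straddling pairs satisfy the different-chromosome DRP definition.

Default insertion distribution is the NA12878-like set (922 Alu, 146 L1,
46 SVA per full-size genome) with 95% heterozygous / 5% homozygous
non-reference zygosity; reads default to 100-bp pairs at 500 +/- 50 bp
fragments with zero base error.  The deletion-mode default plants 400 Alu
and 50 L1 reference-copy deletions per genome.
"""

from __future__ import annotations

import random
from bisect import bisect_right
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import ConfigurationError, MeikitError
from .evidence_scan import DECOY_PREFIX, MEConsensus
from .formats_io import GenomeInterval, ReadAlignment, revcomp

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

FULL_GENOME_SIZE = 3_100_000_000


@dataclass
class SimulationConfig:
    """All generator knobs with their benchmark defaults."""

    # reference synthesis
    ref_length: int = 1_000_000
    chrom: str = "chr1"
    n_ref_alu: int = 30
    n_ref_l1: int = 3
    n_ref_fl_l1: int = 2
    n_ref_sva: int = 5
    n_gaps: int = 1
    gap_length: int = 5_000
    # insertion distribution (full-genome scale; see scaled_class_counts)
    class_counts: Dict[str, int] = field(
        default_factory=lambda: {"ALU": 922, "LINE1": 146, "SVA": 46}
    )
    het_fraction: float = 0.95
    min_spacing: int = 1_000
    # element features
    tsd_min: int = 4
    tsd_max: int = 20
    tsd_negative_fraction: float = 0.05
    tsd_negative_min: int = 1
    tsd_negative_max: int = 10
    polya_min: int = 10
    polya_max: int = 40
    l1_full_length_prob: float = 0.30
    l1_inversion_prob: float = 0.182  # observed germline rate used as default
    transduction_prob: float = 0.0
    transduction_tag_len: int = 100
    extra_mutation_max: int = 4
    minus_strand_fraction: float = 0.0
    # read simulation
    coverage: float = 60.0
    read_len: int = 100
    frag_mean: int = 500
    frag_sd: int = 50
    base_error: float = 0.0
    # deletion mode
    n_alu_deletions: int = 400
    n_l1_deletions: int = 50

    def scaled_class_counts(self, ref_length: Optional[int] = None) -> Dict[str, int]:
        """Class counts scaled proportionally to a reduced reference size."""
        L = ref_length if ref_length is not None else self.ref_length
        return {
            cls: max(0, round(n * L / FULL_GENOME_SIZE))
            for cls, n in self.class_counts.items()
        }

    def effective_config(self) -> Dict:
        d = asdict(self)
        d["het_percent"] = 100.0 * self.het_fraction
        d["hom_percent"] = 100.0 * (1.0 - self.het_fraction)
        return d

    def dump(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.effective_config(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        fields = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in fields})


# ---------------------------------------------------------------------------
# reference synthesis
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGenome:
    reference: Dict[str, str]
    ref_mes: List[GenomeInterval]
    gaps: List[GenomeInterval]
    accessible: List[GenomeInterval]
    fl_sources: List[GenomeInterval]


def _random_bases(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutated_copy(rng: random.Random, seq: str, n_mut: int) -> str:
    s = list(seq)
    for _ in range(n_mut):
        i = rng.randrange(len(s))
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s)


def generate_reference(
    config: SimulationConfig,
    library: Sequence[MEConsensus],
    rng: random.Random,
) -> SimulatedGenome:
    """Random reference with embedded reference-ME copies and N gaps."""
    by_class = {c.name: c for c in library}
    L = config.ref_length
    chrom = config.chrom
    plan: List[Tuple[str, str, bool]] = []  # (class, sequence, is_fl_source)
    for cls, n in (
        ("ALU", config.n_ref_alu),
        ("LINE1", config.n_ref_l1),
        ("SVA", config.n_ref_sva),
    ):
        cons = by_class.get(cls)
        if cons is None:
            continue
        for _ in range(n):
            plan.append((cls, _mutated_copy(rng, cons.sequence, 5), False))
    if "LINE1" in by_class:
        for _ in range(config.n_ref_fl_l1):
            plan.append(("LINE1", by_class["LINE1"].sequence, True))
    total_me = sum(len(s) for _, s, _ in plan)
    total_gap = config.n_gaps * config.gap_length
    if total_me + total_gap + 2000 * (len(plan) + config.n_gaps) > L:
        raise ConfigurationError(
            "reference too short for the requested reference-ME/gap layout"
        )
    seq = list(_random_bases(rng, L))
    # place features left to right with random spacing
    slots = len(plan) + config.n_gaps
    free = L - total_me - total_gap
    gap_positions = set(rng.sample(range(slots), config.n_gaps)) if config.n_gaps else set()
    order = list(range(len(plan)))
    rng.shuffle(order)
    cuts = sorted(rng.sample(range(1, free), slots)) if slots else []
    ref_mes: List[GenomeInterval] = []
    gaps: List[GenomeInterval] = []
    fl_sources: List[GenomeInterval] = []
    pi = 0
    src_n = 0
    # walk slots left to right, advancing by random spacing + feature length
    spacings = np.diff([0] + cuts) if slots else []
    pos = 0
    for si in range(slots):
        pos += int(spacings[si])
        if si in gap_positions:
            start, end = pos, pos + config.gap_length
            seq[start:end] = "N" * config.gap_length
            gaps.append(GenomeInterval(chrom, start, end, "gap"))
            pos = end
        else:
            cls, s, is_fl = plan[order[pi]]
            pi += 1
            start, end = pos, pos + len(s)
            seq[start:end] = s
            label = f"{cls}:FL" if is_fl else cls
            iv = GenomeInterval(chrom, start, end, label, "+")
            ref_mes.append(iv)
            if is_fl:
                src_n += 1
                fl_sources.append(GenomeInterval(chrom, start, end, f"src{src_n}", "+"))
            pos = end
    reference = {chrom: "".join(seq)}
    accessible = _accessible_intervals(chrom, L, ref_mes, gaps)
    return SimulatedGenome(reference, sorted(ref_mes, key=lambda iv: iv.start), gaps, accessible, fl_sources)


def _accessible_intervals(
    chrom: str,
    length: int,
    ref_mes: Sequence[GenomeInterval],
    gaps: Sequence[GenomeInterval],
    me_pad: int = 150,
    gap_pad: int = 700,
    edge: int = 2_000,
) -> List[GenomeInterval]:
    blocked: List[Tuple[int, int]] = [(0, edge), (length - edge, length)]
    for iv in ref_mes:
        blocked.append((iv.start - me_pad, iv.end + me_pad))
    for iv in gaps:
        blocked.append((iv.start - gap_pad, iv.end + gap_pad))
    blocked.sort()
    merged: List[Tuple[int, int]] = []
    for s, e in blocked:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    out: List[GenomeInterval] = []
    prev = 0
    for s, e in merged:
        if s > prev:
            out.append(GenomeInterval(chrom, prev, s, "accessible"))
        prev = max(prev, e)
    if prev < length:
        out.append(GenomeInterval(chrom, prev, length, "accessible"))
    return out


# ---------------------------------------------------------------------------
# insertion specs and element synthesis
# ---------------------------------------------------------------------------

@dataclass
class InsertionSpec:
    me_class: str
    subfamily: str
    extra_mutations: List[Tuple[int, str, str]]
    truncation_start: int
    inversion_junction: Optional[int]
    tsd_len: int  # negative = target-site deletion
    polya_len: int
    transduction: Optional[Tuple[str, str]]  # (source id, tag sequence)
    zygosity: str  # 'het' or 'hom'
    haplotype: int  # carrier haplotype for het specs
    chrom: str = "chr1"
    position: int = 0  # 0-based base AFTER which the element is inserted
    orientation: str = "+"


@dataclass
class TruthRecord:
    spec: InsertionSpec
    donor_coords: Dict[int, Tuple[int, int]]  # hap -> (donor start, donor end)

    @property
    def position(self) -> int:
        return self.spec.position

    @property
    def me_class(self) -> str:
        return self.spec.me_class


@dataclass
class DeletionTruth:
    interval: GenomeInterval
    me_class: str
    zygosity: str
    haplotype: int


def synthesize_element(spec: InsertionSpec, library: Sequence[MEConsensus]) -> str:
    """Realize one donor element sequence from its spec (deterministic)."""
    cons = next((c for c in library if c.name == spec.me_class), None)
    if cons is None:
        raise ConfigurationError(f"unknown ME class {spec.me_class}")
    if spec.truncation_start >= len(cons.sequence):
        raise ConfigurationError("truncation start beyond consensus length")
    if spec.inversion_junction is not None and spec.inversion_junction <= spec.truncation_start:
        raise ConfigurationError("inversion junction must lie 3' of the truncation start")
    seq = list(cons.sequence)
    diags = cons.subfamilies.get(spec.subfamily, set())
    for pos, _ref, alt in sorted(diags) + sorted(spec.extra_mutations):
        seq[pos] = alt
    s = "".join(seq[spec.truncation_start :])
    if spec.inversion_junction is not None:
        cut = spec.inversion_junction - spec.truncation_start
        s = revcomp(s[:cut]) + s[cut:]
    s += "A" * spec.polya_len
    if spec.transduction is not None:
        _src, tag = spec.transduction
        s += tag + "A" * spec.polya_len
    return s


def plan_insertions(
    genome: SimulatedGenome,
    config: SimulationConfig,
    library: Sequence[MEConsensus],
    rng: random.Random,
    class_counts: Optional[Dict[str, int]] = None,
) -> List[InsertionSpec]:
    """Draw featureful insertion specs at spaced accessible positions."""
    counts = class_counts if class_counts is not None else dict(config.class_counts)
    n_total = sum(counts.values())
    positions = _draw_positions(genome.accessible, n_total, config.min_spacing, rng)
    rng.shuffle(positions)
    by_class = {c.name: c for c in library}
    specs: List[InsertionSpec] = []
    idx = 0
    for cls, n in counts.items():
        cons = by_class.get(cls)
        if cons is None:
            raise ConfigurationError(f"class {cls} missing from library")
        subfams = sorted(cons.subfamilies)
        for _ in range(n):
            chrom, pos = positions[idx]
            idx += 1
            trunc = 0
            junction = None
            transduction = None
            if cls == "LINE1":
                if rng.random() >= config.l1_full_length_prob:
                    trunc = rng.randrange(0, len(cons.sequence) - 1000)
                if rng.random() < config.l1_inversion_prob:
                    lo = trunc + 300
                    hi = len(cons.sequence) - 500
                    if hi > lo:
                        junction = rng.randrange(lo, hi)
                if (
                    trunc == 0
                    and junction is None
                    and genome.fl_sources
                    and rng.random() < config.transduction_prob
                ):
                    transduction = _draw_transduction(genome, config, rng)
            if rng.random() < config.tsd_negative_fraction:
                tsd = -rng.randint(config.tsd_negative_min, config.tsd_negative_max)
            else:
                tsd = rng.randint(config.tsd_min, config.tsd_max)
            n_extra = rng.randint(0, config.extra_mutation_max)
            taken = {p for p, _, _ in set().union(*cons.subfamilies.values())} if cons.subfamilies else set()
            extra: List[Tuple[int, str, str]] = []
            for _ in range(n_extra):
                p = rng.randrange(trunc, len(cons.sequence))
                if p in taken:
                    continue
                taken.add(p)
                ref = cons.sequence[p]
                extra.append((p, ref, rng.choice([b for b in "ACGT" if b != ref])))
            zyg = "het" if rng.random() < config.het_fraction else "hom"
            orient = "-" if rng.random() < config.minus_strand_fraction else "+"
            specs.append(
                InsertionSpec(
                    me_class=cls,
                    subfamily=rng.choice(subfams),
                    extra_mutations=sorted(extra),
                    truncation_start=trunc,
                    inversion_junction=junction,
                    tsd_len=tsd,
                    polya_len=rng.randint(config.polya_min, config.polya_max),
                    transduction=transduction,
                    zygosity=zyg,
                    haplotype=rng.randrange(2) if zyg == "het" else 0,
                    chrom=chrom,
                    position=pos,
                    orientation=orient,
                )
            )
    specs.sort(key=lambda s: (s.chrom, s.position))
    return specs


def _draw_transduction(
    genome: SimulatedGenome, config: SimulationConfig, rng: random.Random
) -> Optional[Tuple[str, str]]:
    for _ in range(10):
        src = rng.choice(genome.fl_sources)
        off = rng.randint(20, 60)
        tag = genome.reference[src.chrom][src.end + off : src.end + off + config.transduction_tag_len]
        if len(tag) < config.transduction_tag_len or "N" in tag:
            continue
        if genome.reference[src.chrom].count(tag) == 1:
            return (src.label, tag)
    return None


def _draw_positions(
    accessible: Sequence[GenomeInterval],
    n: int,
    min_spacing: int,
    rng: random.Random,
) -> List[Tuple[str, int]]:
    total = sum(len(iv) for iv in accessible)
    if total < n * min_spacing * 2:
        raise ConfigurationError(
            f"insufficient accessible space ({total} bp) for {n} insertions"
        )
    offsets = np.cumsum([0] + [len(iv) for iv in accessible])
    chosen: List[Tuple[str, int]] = []
    taken: Dict[str, List[int]] = {}
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ConfigurationError("could not place insertions with required spacing")
        x = rng.randrange(total)
        k = int(np.searchsorted(offsets, x, side="right")) - 1
        iv = accessible[k]
        pos = iv.start + (x - int(offsets[k]))
        if pos - iv.start < 200 or iv.end - pos < 200:
            continue
        lst = taken.setdefault(iv.chrom, [])
        i = bisect_right(lst, pos)
        if (i > 0 and pos - lst[i - 1] < min_spacing) or (
            i < len(lst) and lst[i] - pos < min_spacing
        ):
            continue
        lst.insert(i, pos)
        chosen.append((iv.chrom, pos))
    return chosen


# ---------------------------------------------------------------------------
# donor construction
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class Segment:
    hap_start: int
    hap_end: int
    kind: str  # 'ref' or 'ins'
    ref_start: int = -1  # for 'ref'
    me_class: str = ""  # for 'ins'


@dataclass
class Haplotype:
    chrom: str
    sequence: str
    segments: List[Segment]
    seg_starts: List[int]


@dataclass
class Donor:
    haplotypes: List[Dict[str, Haplotype]]  # index 0/1 -> chrom -> Haplotype
    truth: List[TruthRecord]
    deletion_truth: List[DeletionTruth] = field(default_factory=list)
    reference: Dict[str, str] = field(default_factory=dict)


def _build_haplotype(
    chrom: str,
    ref_seq: str,
    events: List[Tuple[int, int, str, object]],  # (boundary, tsd_len, kind, payload)
) -> Haplotype:
    """Assemble one haplotype from ordered insertion/deletion events."""
    segments: List[Segment] = []
    parts: List[str] = []
    hap_pos = 0
    ref_cursor = 0

    def emit_ref(a: int, b: int):
        nonlocal hap_pos
        if b > a:
            segments.append(Segment(hap_pos, hap_pos + (b - a), "ref", ref_start=a))
            parts.append(ref_seq[a:b])
            hap_pos += b - a

    for boundary, tsd, kind, payload in events:
        if kind == "ins":
            elem, me_class, rec, hap_idx = payload
            if tsd >= 0:
                emit_ref(ref_cursor, boundary + tsd)
                resume = boundary
            else:
                emit_ref(ref_cursor, boundary)
                resume = boundary + (-tsd)
            start = hap_pos
            segments.append(Segment(hap_pos, hap_pos + len(elem), "ins", me_class=me_class))
            parts.append(elem)
            hap_pos += len(elem)
            if rec is not None:
                rec.donor_coords[hap_idx] = (start, hap_pos)
            ref_cursor = resume
        else:  # 'del': payload = deletion end
            emit_ref(ref_cursor, boundary)
            ref_cursor = payload
    emit_ref(ref_cursor, len(ref_seq))
    return Haplotype(chrom, "".join(parts), segments, [s.hap_start for s in segments])


def build_donor(
    genome: SimulatedGenome,
    specs: Sequence[InsertionSpec],
    library: Sequence[MEConsensus],
) -> Donor:
    truth = [TruthRecord(spec, {}) for spec in specs]
    haps: List[Dict[str, Haplotype]] = [{}, {}]
    for hap_idx in (0, 1):
        for chrom, ref_seq in genome.reference.items():
            events = []
            for spec, rec in zip(specs, truth):
                if spec.chrom != chrom:
                    continue
                if spec.zygosity == "het" and spec.haplotype != hap_idx:
                    continue
                elem = synthesize_element(spec, library)
                if spec.orientation == "-":
                    elem = revcomp(elem)
                events.append(
                    (spec.position + 1, spec.tsd_len, "ins", (elem, spec.me_class, rec, hap_idx))
                )
            events.sort(key=lambda e: e[0])
            haps[hap_idx][chrom] = _build_haplotype(chrom, ref_seq, events)
    return Donor(haps, truth, reference=genome.reference)


def plan_deletions(
    genome: SimulatedGenome,
    config: SimulationConfig,
    rng: random.Random,
) -> List[DeletionTruth]:
    """Select reference-ME copies to delete (het/hom weighted)."""
    out: List[DeletionTruth] = []
    for cls, n in (("ALU", config.n_alu_deletions), ("LINE1", config.n_l1_deletions)):
        pool = [iv for iv in genome.ref_mes if iv.label.split(":")[0] == cls]
        if len(pool) < n:
            raise ConfigurationError(
                f"reference has only {len(pool)} {cls} copies; {n} deletions requested"
            )
        for iv in rng.sample(pool, n):
            zyg = "het" if rng.random() < config.het_fraction else "hom"
            out.append(DeletionTruth(iv, cls, zyg, rng.randrange(2) if zyg == "het" else 0))
    out.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return out


def build_deletion_donor(
    genome: SimulatedGenome, deletions: Sequence[DeletionTruth]
) -> Donor:
    haps: List[Dict[str, Haplotype]] = [{}, {}]
    for hap_idx in (0, 1):
        for chrom, ref_seq in genome.reference.items():
            events = []
            for d in deletions:
                if d.interval.chrom != chrom:
                    continue
                if d.zygosity == "het" and d.haplotype != hap_idx:
                    continue
                events.append((d.interval.start, 0, "del", d.interval.end))
            events.sort(key=lambda e: e[0])
            haps[hap_idx][chrom] = _build_haplotype(chrom, ref_seq, events)
    return Donor(haps, [], list(deletions), reference=genome.reference)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class FragmentSet:
    hap: int
    chrom: str
    starts: np.ndarray
    lengths: np.ndarray


def simulate_reads(
    donor: Donor,
    coverage: float,
    read_len: int = 100,
    frag_mean: int = 500,
    frag_sd: int = 50,
    seed: int = 1,
) -> List[FragmentSet]:
    """Uniform fragment sampling; coverage is genome-equivalent depth.

    Total sequenced bases = coverage x (sum of haplotype lengths) / ploidy,
    so a single haplotype at 30x yields 30x over that haplotype and a
    diploid donor at 30x yields ~15x per haplotype.
    """
    if coverage <= 0:
        raise ConfigurationError("coverage must be positive")
    if frag_mean < 2 * read_len:
        raise ConfigurationError("fragment mean must be at least twice the read length")
    rng = np.random.default_rng(seed)
    n_haps = len(donor.haplotypes)
    out: List[FragmentSet] = []
    for hap_idx, chroms in enumerate(donor.haplotypes):
        for chrom, hap in chroms.items():
            L = len(hap.sequence)
            n_frags = int(round(coverage * L / (n_haps * 2 * read_len)))
            lens = np.clip(
                np.round(rng.normal(frag_mean, frag_sd, n_frags)).astype(np.int64),
                2 * read_len + 10,
                None,
            )
            lens = np.minimum(lens, L - 1)
            starts = rng.integers(0, np.maximum(1, L - lens), n_frags)
            out.append(FragmentSet(hap_idx, chrom, starts, lens))
    return out


def downsample_fragments(
    fragments: Sequence[FragmentSet], fraction: float, seed: int = 1
) -> List[FragmentSet]:
    rng = np.random.default_rng(seed)
    out = []
    for fs in fragments:
        keep = rng.random(len(fs.starts)) < fraction
        out.append(FragmentSet(fs.hap, fs.chrom, fs.starts[keep], fs.lengths[keep]))
    return out


# ---------------------------------------------------------------------------
# truth-aware alignment projection
# ---------------------------------------------------------------------------

MIN_ANCHOR_BASES = 20  # below this, a boundary read is treated as ME-interior


def _decoy_lengths(library: Sequence[MEConsensus], pad: int = 600) -> Dict[str, int]:
    return {DECOY_PREFIX + c.name: len(c.sequence) + pad for c in library}


def project_alignments(
    donor: Donor,
    fragments: Sequence[FragmentSet],
    library: Sequence[MEConsensus],
    read_len: int = 100,
    base_error: float = 0.0,
    seed: int = 1,
    sample_id: str = "S1",
    frag_mean: int = 500,
    frag_sd: int = 50,
) -> Tuple[List[ReadAlignment], Dict[str, int]]:
    """Map simulated reads to reference coordinates using the truth map.

    Reads wholly inside unmodified sequence map full-length at the lifted
    coordinate; reads crossing an insertion boundary map to the flank with
    the element-derived bases soft-clipped; reads wholly inside an inserted
    element map to that class's decoy contig.
    """
    if not fragments:
        raise ConfigurationError("no fragments to project")
    decoys = _decoy_lengths(library)
    references: Dict[str, int] = {
        chrom: len(seq) for chrom, seq in donor.reference.items()
    }
    references.update(decoys)
    err_rng = random.Random(seed) if base_error > 0 else None
    records: List[ReadAlignment] = []

    for fs in fragments:
        hap = donor.haplotypes[fs.hap][fs.chrom]
        seq = hap.sequence
        seg_starts = hap.seg_starts
        segments = hap.segments
        for i in range(len(fs.starts)):
            start = int(fs.starts[i])
            flen = int(fs.lengths[i])
            name = f"{sample_id}.{fs.hap}.{fs.chrom}.{start}.{flen}.{i}"
            r1 = _project_read(
                fs.chrom, seq, segments, seg_starts, start, start + read_len, "+", decoys, read_len
            )
            r2 = _project_read(
                fs.chrom, seq, segments, seg_starts, start + flen - read_len, start + flen, "-", decoys, read_len
            )
            for (chrom_a, pos_a, cig_a, sq_a, strand_a), (chrom_b, pos_b, _cb, sb, _stb), is1 in (
                (r1, r2, True),
                (r2, r1, False),
            ):
                if err_rng is not None:
                    sq_a = _apply_errors(sq_a, base_error, err_rng)
                end_a = pos_a + sum(n for op, n in cig_a if op in "MDN")
                end_b = pos_b + sum(n for op, n in _cb if op in "MDN")
                span = max(end_a, end_b) - min(pos_a, pos_b)
                proper = (
                    chrom_a == chrom_b
                    and not chrom_a.startswith(DECOY_PREFIX)
                    and 0 < span <= frag_mean + 6 * frag_sd
                )
                records.append(
                    ReadAlignment(
                        name=name,
                        chrom=chrom_a,
                        pos=pos_a,
                        strand=strand_a,
                        mapq=60,
                        cigar=cig_a,
                        sequence=sq_a,
                        mate_chrom=chrom_b,
                        mate_pos=pos_b,
                        is_proper_pair=proper,
                        is_read1=is1,
                        sample_id=sample_id,
                    )
                )
    order = {c: i for i, c in enumerate(references)}
    records.sort(key=lambda r: (order.get(r.chrom, 99), r.pos))
    return records, references


def _project_read(
    chrom: str,
    hap_seq: str,
    segments: List[Segment],
    seg_starts: List[int],
    s: int,
    e: int,
    strand: str,
    decoys: Dict[str, int],
    read_len: int,
) -> Tuple[str, int, List[Tuple[str, int]], str, str]:
    sq = hap_seq[s:e]
    i = bisect_right(seg_starts, s) - 1
    runs: List[Tuple[Segment, int, int]] = []
    pos = s
    while pos < e and i < len(segments):
        seg = segments[i]
        run_end = min(e, seg.hap_end)
        runs.append((seg, pos, run_end))
        pos = run_end
        i += 1
    ref_runs = [r for r in runs if r[0].kind == "ref"]
    best_ref = max(ref_runs, key=lambda r: r[2] - r[1], default=None)
    if best_ref is not None and best_ref[2] - best_ref[1] >= MIN_ANCHOR_BASES:
        seg, rs, re_ = best_ref
        cig: List[Tuple[str, int]] = []
        if rs - s:
            cig.append(("S", rs - s))
        cig.append(("M", re_ - rs))
        if e - re_:
            cig.append(("S", e - re_))
        return (chrom, seg.ref_start + (rs - seg.hap_start), cig, sq, strand)
    ins_runs = [r for r in runs if r[0].kind == "ins"]
    seg, rs, re_ = max(ins_runs, key=lambda r: r[2] - r[1])
    decoy = DECOY_PREFIX + seg.me_class
    offset = max(0, s - seg.hap_start)
    pos = min(offset, max(0, decoys[decoy] - read_len))
    return (decoy, pos, [("M", e - s)], sq, strand)


def _apply_errors(seq: str, rate: float, rng: random.Random) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_calls(
    calls: Sequence,
    truth: Sequence[TruthRecord],
    window: int = 500,
    classes: Sequence[str] = ("ALU", "LINE1", "SVA"),
) -> Dict[str, Dict[str, float]]:
    """Greedy distance-ordered 1-to-1 matching within +/- window, per class."""
    out: Dict[str, Dict[str, float]] = {}
    agg = {"TP": 0, "FP": 0, "FN": 0}
    for cls in classes:
        cls_calls = [c for c in calls if c.me_class == cls]
        cls_truth = [t for t in truth if t.me_class == cls]
        pairs = []
        for ci, c in enumerate(cls_calls):
            for ti, t in enumerate(cls_truth):
                if t.spec.chrom == c.chrom and abs(c.position - t.position) <= window:
                    pairs.append((abs(c.position - t.position), ci, ti))
        pairs.sort()
        used_c, used_t = set(), set()
        tp = 0
        for _d, ci, ti in pairs:
            if ci in used_c or ti in used_t:
                continue
            used_c.add(ci)
            used_t.add(ti)
            tp += 1
        fp = len(cls_calls) - tp
        fn = len(cls_truth) - tp
        out[cls] = _metrics(tp, fp, fn)
        agg["TP"] += tp
        agg["FP"] += fp
        agg["FN"] += fn
    out["ALL"] = _metrics(agg["TP"], agg["FP"], agg["FN"])
    return out


def _metrics(tp: int, fp: int, fn: int) -> Dict[str, float]:
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "FNR": fn / (tp + fn) if tp + fn else 0.0,
        "FDR": fp / (tp + fp) if tp + fp else 0.0,
    }


# ---------------------------------------------------------------------------
# truth tables
# ---------------------------------------------------------------------------

def write_truth(truth: Sequence[TruthRecord], path: str) -> None:
    cols = [
        "id", "chrom", "position", "class", "subfamily", "orientation", "zygosity",
        "haplotype", "tsd_len", "polya_len", "truncation_start", "inversion_junction",
        "transduction_source", "extra_mutations",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, t in enumerate(truth, 1):
            s = t.spec
            muts = ";".join(f"{p},{r},{a}" for p, r, a in s.extra_mutations) or "."
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        f"TRUTH_{i:05d}", s.chrom, s.position, s.me_class, s.subfamily,
                        s.orientation, s.zygosity, s.haplotype, s.tsd_len, s.polya_len,
                        s.truncation_start,
                        s.inversion_junction if s.inversion_junction is not None else ".",
                        s.transduction[0] if s.transduction else ".", muts,
                    )
                )
                + "\n"
            )


def read_truth(path: str) -> List[TruthRecord]:
    out: List[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            muts = []
            if row["extra_mutations"] != ".":
                for m in row["extra_mutations"].split(";"):
                    p, r, a = m.split(",")
                    muts.append((int(p), r, a))
            spec = InsertionSpec(
                me_class=row["class"], subfamily=row["subfamily"],
                extra_mutations=muts, truncation_start=int(row["truncation_start"]),
                inversion_junction=None if row["inversion_junction"] == "." else int(row["inversion_junction"]),
                tsd_len=int(row["tsd_len"]), polya_len=int(row["polya_len"]),
                transduction=None if row["transduction_source"] == "." else (row["transduction_source"], ""),
                zygosity=row["zygosity"], haplotype=int(row["haplotype"]),
                chrom=row["chrom"], position=int(row["position"]),
                orientation=row["orientation"],
            )
            out.append(TruthRecord(spec, {}))
    return out


def write_deletion_truth(dels: Sequence[DeletionTruth], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tclass\tzygosity\thaplotype\n")
        for d in dels:
            fh.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t"
                f"{d.me_class}\t{d.zygosity}\t{d.haplotype}\n"
            )


def read_deletion_truth(path: str) -> List[DeletionTruth]:
    out: List[DeletionTruth] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            chrom, start, end, cls, zyg, hap = line.rstrip("\n").split("\t")
            out.append(
                DeletionTruth(GenomeInterval(chrom, int(start), int(end), cls), cls, zyg, int(hap))
            )
    return out
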