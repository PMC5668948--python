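"""End-to-end orchestration: scan -> discover -> annotate -> genotype -> VCF.

Two run modes: ``single`` (one sample end to end) and ``split`` (per-sample
scans pooled for joint discovery, then joint genotyping of every sample at
every site).  Split mode on one sample is by construction identical to
single mode.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import ConfigurationError
from .evidence_scan import (
    ConsensusAligner,
    MEConsensus,
    ScanParams,
    ScanResult,
    extract_evidence,
    load_me_library,
)
from .feature_annotation import GeneModel, annotate_call, load_gene_models
from .formats_io import (
    GenomeInterval,
    ReadAlignment,
    read_alignments,
    read_fasta,
    read_intervals,
    write_vcf,
)
from .genotyping import (
    GenotypeParams,
    ReadIndex,
    SampleGenotype,
    apply_site_filters,
    genotype_call,
    genotype_deletion,
)
from .site_discovery import (
    DiscoveryParams,
    MEICall,
    discover_sites,
    merge_samples,
)


@dataclass
class RunConfig:
    mode: str  # 'single' or 'split'
    reference: str
    samples: List[Tuple[str, str]]  # (sample id, alignment path)
    me_library: Optional[str] = None
    subfamilies: Optional[str] = None
    ref_mes: Optional[str] = None
    gaps: Optional[str] = None
    genes: Optional[str] = None
    fl_sources: Optional[str] = None
    out_vcf: str = "out.vcf"
    seed: int = 1
    scan: ScanParams = field(default_factory=ScanParams)
    discovery: DiscoveryParams = field(default_factory=DiscoveryParams)
    genotype: GenotypeParams = field(default_factory=GenotypeParams)

    def validate(self) -> None:
        if self.mode not in ("single", "split"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not self.samples:
            raise ConfigurationError("sample list is empty")
        if self.mode == "single" and len(self.samples) != 1:
            raise ConfigurationError("single mode takes exactly one sample")
        ids = [s for s, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate sample ids")
        for path in [self.reference] + [p for _, p in self.samples]:
            if not os.path.exists(path):
                raise ConfigurationError(f"missing input file: {path}")
        for path in (self.me_library, self.subfamilies, self.ref_mes, self.gaps, self.genes, self.fl_sources):
            if path is not None and not os.path.exists(path):
                raise ConfigurationError(f"missing input file: {path}")


def call_insertions(
    scans: Dict[str, ScanResult],
    indexes: Dict[str, ReadIndex],
    reference: Dict[str, str],
    library: Sequence[MEConsensus],
    ref_mes: Sequence[GenomeInterval] = (),
    gaps: Sequence[GenomeInterval] = (),
    fl_sources: Sequence[GenomeInterval] = (),
    genes: Sequence[GeneModel] = (),
    discovery: Optional[DiscoveryParams] = None,
    genotype: Optional[GenotypeParams] = None,
) -> Tuple[List[MEICall], Dict[str, Dict[str, SampleGenotype]]]:
    """In-memory joint calling over one or more scanned samples."""
    pooled = merge_samples(list(scans.values()))
    gt_params = genotype or GenotypeParams()
    gt_params.frag_mean = pooled.coverage.frag_mean
    gt_params.frag_sd = pooled.coverage.frag_sd
    calls = discover_sites(pooled, reference, ref_mes, gaps, discovery)
    genotypes: Dict[str, Dict[str, SampleGenotype]] = {}
    idx_list = [indexes[s] for s in sorted(indexes)]
    for call in calls:
        annotate_call(call, library, reference, fl_sources, genes)
        gts = genotype_call(call, idx_list, gt_params)
        apply_site_filters(call, gts, gt_params)
        genotypes[call.id] = gts
    return calls, genotypes


def call_deletions(
    ref_mes: Sequence[GenomeInterval],
    indexes: Dict[str, ReadIndex],
    params: Optional[GenotypeParams] = None,
    read_len: int = 100,
) -> Tuple[List[MEICall], Dict[str, Dict[str, SampleGenotype]]]:
    """Genotype every annotated reference-ME copy for deletion."""
    params = params or GenotypeParams()
    calls: List[MEICall] = []
    genotypes: Dict[str, Dict[str, SampleGenotype]] = {}
    for i, iv in enumerate(sorted(ref_mes, key=lambda x: (x.chrom, x.start)), 1):
        cls = iv.label.split(":")[0] if iv.label else "ALU"
        call = MEICall(
            id=f"DEL_{i:05d}", chrom=iv.chrom, position=max(0, iv.start - 1),
            orientation=iv.strand, me_class=cls, consensus_start=0,
            consensus_stop=len(iv), svlen=-len(iv), tsd="", tsd_deletion=0,
            tranche=0, kind="DEL",
        )
        gts = {
            sid: genotype_deletion(iv, idx, params, read_len)
            for sid, idx in indexes.items()
        }
        calls.append(call)
        genotypes[call.id] = gts
    return calls, genotypes


def run_pipeline(config: RunConfig) -> Tuple[List[MEICall], Dict[str, Dict[str, SampleGenotype]], List[str]]:
    """File-based end-to-end run; returns (calls, genotypes, sample ids)."""
    config.validate()
    reference = read_fasta(config.reference)
    library = load_me_library(config.me_library, config.subfamilies)
    aligner = ConsensusAligner(library)
    ref_mes = read_intervals(config.ref_mes) if config.ref_mes else []
    gaps = read_intervals(config.gaps) if config.gaps else []
    fl_sources = read_intervals(config.fl_sources) if config.fl_sources else []
    genes = load_gene_models(config.genes) if config.genes else []
    scans: Dict[str, ScanResult] = {}
    indexes: Dict[str, ReadIndex] = {}
    for sid, path in config.samples:
        reads = list(read_alignments(path))
        for r in reads:
            r.sample_id = sid
        scans[sid] = extract_evidence(reads, aligner, config.scan, sample_id=sid)
        indexes[sid] = ReadIndex(reads, sid)
    calls, genotypes = call_insertions(
        scans, indexes, reference, library, ref_mes, gaps, fl_sources, genes,
        config.discovery, config.genotype,
    )
    samples = [sid for sid, _ in config.samples]
    contigs = {c: len(s) for c, s in reference.items()}
    write_vcf(calls, genotypes, samples, config.out_vcf, reference, contigs)
    return calls, genotypes, samples


# ---------------------------------------------------------------------------
# calls TSV (intermediate serialization between CLI stages)
# ---------------------------------------------------------------------------

def write_calls(calls: Sequence[MEICall], path: str) -> None:
    cols = [
        "id", "chrom", "position", "orientation", "class", "cons_start", "cons_stop",
        "svlen", "tsd", "tsd_deletion", "tranche", "filters", "features",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            feats = {k: v for k, v in c.features.items() if k != "mutations"}
            if "mutations" in c.features:
                feats["mutations"] = [list(m) for m in c.features["mutations"]]
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        c.id, c.chrom, c.position, c.orientation, c.me_class,
                        c.consensus_start, c.consensus_stop, c.svlen,
                        c.tsd or ".", c.tsd_deletion, c.tranche,
                        ",".join(sorted(c.filters)) or "PASS", json.dumps(feats),
                    )
                )
                + "\n"
            )


def read_calls(path: str) -> List[MEICall]:
    out: List[MEICall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            feats = json.loads(row["features"])
            if "mutations" in feats:
                feats["mutations"] = [tuple(m) for m in feats["mutations"]]
            out.append(
                MEICall(
                    id=row["id"], chrom=row["chrom"], position=int(row["position"]),
                    orientation=row["orientation"], me_class=row["class"],
                    consensus_start=int(row["cons_start"]), consensus_stop=int(row["cons_stop"]),
                    svlen=int(row["svlen"]), tsd="" if row["tsd"] == "." else row["tsd"],
                    tsd_deletion=int(row["tsd_deletion"]), tranche=int(row["tranche"]),
                    filters=set() if row["filters"] == "PASS" else set(row["filters"].split(",")),
                    features=feats,
                )
            )
    return out
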