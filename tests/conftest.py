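import random
from types import SimpleNamespace

import pytest

from meikit import simulator as sim
from meikit.evidence_scan import (
    ConsensusAligner,
    ScanParams,
    extract_evidence,
    load_me_library,
)
from meikit.genotyping import ReadIndex
from meikit.pipeline import call_insertions


@pytest.fixture(scope="session")
def library():
    return load_me_library()


@pytest.fixture(scope="session")
def aligner(library):
    return ConsensusAligner(library)


def run_simulation(
    library,
    aligner,
    *,
    ref_length=400_000,
    class_counts=None,
    coverage=30.0,
    seed=7,
    config_kwargs=None,
    sample_id="S1",
):
    """One-sample end-to-end simulation + scan + discovery, for fixtures."""
    kwargs = dict(
        ref_length=ref_length,
        coverage=coverage,
        n_ref_alu=5,
        n_ref_l1=1,
        n_ref_fl_l1=1,
        n_ref_sva=2,
        n_gaps=1,
        gap_length=2_000,
    )
    kwargs.update(config_kwargs or {})
    cfg = sim.SimulationConfig(**kwargs)
    rng = random.Random(seed)
    genome = sim.generate_reference(cfg, library, rng)
    counts = class_counts or {"ALU": 8, "LINE1": 3, "SVA": 2}
    specs = sim.plan_insertions(genome, cfg, library, rng, counts)
    donor = sim.build_donor(genome, specs, library)
    frags = sim.simulate_reads(
        donor, coverage, cfg.read_len, cfg.frag_mean, cfg.frag_sd, seed=seed + 1
    )
    records, refs = sim.project_alignments(
        donor, frags, library, cfg.read_len, seed=seed + 1, sample_id=sample_id,
        frag_mean=cfg.frag_mean, frag_sd=cfg.frag_sd,
    )
    scan = extract_evidence(records, aligner, ScanParams(), sample_id)
    index = ReadIndex(records, sample_id)
    calls, genotypes = call_insertions(
        {sample_id: scan}, {sample_id: index}, genome.reference, library,
        genome.ref_mes, genome.gaps, genome.fl_sources,
    )
    return SimpleNamespace(
        config=cfg, genome=genome, specs=specs, donor=donor, fragments=frags,
        records=records, references=refs, scan=scan, index=index, calls=calls,
        genotypes=genotypes, truth=donor.truth, sample_id=sample_id,
    )


@pytest.fixture(scope="session")
def sim_small(library, aligner):
    """400-kb genome, 13 mixed insertions at 30x; the workhorse fixture."""
    return run_simulation(library, aligner)


@pytest.fixture(scope="session")
def sim_features(library, aligner):
    """L1-rich simulation with frequent inversions and transductions."""
    return run_simulation(
        library,
        aligner,
        ref_length=1_200_000,
        class_counts={"LINE1": 12, "ALU": 6},
        seed=19,
        config_kwargs=dict(
            n_ref_fl_l1=3,
            l1_full_length_prob=0.65,
            l1_inversion_prob=0.4,
            transduction_prob=0.9,
            n_gaps=0,
        ),
    )


@pytest.fixture(scope="session")
def sim_deletion(library):
    """Reference-ME deletion simulation: 8 Alu + 1 L1 deletions at 30x."""
    cfg = sim.SimulationConfig(
        ref_length=400_000, n_ref_alu=24, n_ref_l1=2, n_ref_fl_l1=0,
        n_ref_sva=0, n_gaps=0, n_alu_deletions=8, n_l1_deletions=1,
        het_fraction=0.5,
    )
    rng = random.Random(31)
    genome = sim.generate_reference(cfg, library, rng)
    deletions = sim.plan_deletions(genome, cfg, rng)
    donor = sim.build_deletion_donor(genome, deletions)
    frags = sim.simulate_reads(donor, 30.0, seed=32)
    records, refs = sim.project_alignments(donor, frags, library, seed=32, sample_id="S1")
    return SimpleNamespace(
        config=cfg, genome=genome, deletions=deletions, donor=donor,
        records=records, references=refs, index=ReadIndex(records, "S1"),
    )


@pytest.fixture(scope="session")
def sim_zygosity(library, aligner):
    """Balanced het/hom Alu sites for zygosity-sensitive statistics."""
    return run_simulation(
        library,
        aligner,
        ref_length=2_500_000,
        class_counts={"ALU": 24},
        seed=23,
        config_kwargs=dict(het_fraction=0.5, n_gaps=0, min_spacing=3_000),
    )
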