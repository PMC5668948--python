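import random

import numpy as np
import pytest

from meikit import simulator as sim
from meikit.errors import ConfigurationError
from meikit.evidence_scan import DECOY_PREFIX, classify_pair, PairClass
from meikit.formats_io import revcomp
from meikit.site_discovery import MEICall


def _spec(**kw):
    defaults = dict(
        me_class="ALU", subfamily="ALU", extra_mutations=[], truncation_start=0,
        inversion_junction=None, tsd_len=12, polya_len=20, transduction=None,
        zygosity="hom", haplotype=0, chrom="chr1", position=9_999, orientation="+",
    )
    defaults.update(kw)
    return sim.InsertionSpec(**defaults)


class TestSynthesizeElement:
    def test_plain_full_length(self, library):
        s = _spec(polya_len=20)
        elem = sim.synthesize_element(s, library)
        assert elem == library[0].sequence + "A" * 20

    def test_truncation_arithmetic(self, library):
        s = _spec(me_class="LINE1", subfamily="LINE1", truncation_start=4_000, polya_len=25)
        elem = sim.synthesize_element(s, library)
        assert len(elem) == (6_019 - 4_000) + 25

    def test_inversion_matches_string_oracle(self, library):
        s = _spec(me_class="LINE1", subfamily="LINE1", truncation_start=1_000,
                  inversion_junction=2_500, polya_len=0)
        elem = sim.synthesize_element(s, library)
        cons = library[1].sequence
        # independent re-derivation: revcomp the 5' segment, keep the 3' one
        oracle = revcomp(cons[1_000:2_500]) + cons[2_500:]
        assert elem == oracle

    def test_junction_before_truncation_rejected(self, library):
        s = _spec(me_class="LINE1", subfamily="LINE1", truncation_start=3_000,
                  inversion_junction=2_500)
        with pytest.raises(ConfigurationError):
            sim.synthesize_element(s, library)

    def test_subfamily_diagnostics_applied(self, library):
        alu = library[0]
        s = _spec(subfamily="AluYa5", polya_len=0)
        elem = sim.synthesize_element(s, library)
        for pos, _ref, alt in alu.subfamilies["AluYa5"]:
            assert elem[pos] == alt

    def test_transduction_appended_with_second_polya(self, library):
        s = _spec(polya_len=10, transduction=("src1", "GATTACA" * 10))
        elem = sim.synthesize_element(s, library)
        assert elem.endswith("GATTACA" * 10 + "A" * 10)


class TestPlanting:
    def _genome(self, library, seed=3, length=200_000):
        cfg = sim.SimulationConfig(ref_length=length, n_ref_alu=2, n_ref_l1=0,
                                   n_ref_fl_l1=1, n_ref_sva=0, n_gaps=0)
        return cfg, sim.generate_reference(cfg, library, random.Random(seed))

    def test_tsd_duplicated_around_element(self, library):
        cfg, genome = self._genome(library)
        ref = genome.reference["chr1"]
        spec = _spec(position=100_000, tsd_len=12)
        donor = sim.build_donor(genome, [spec], library)
        hap = donor.haplotypes[0]["chr1"]
        elem = sim.synthesize_element(spec, library)
        tsd = ref[100_001:100_013]
        start, end = donor.truth[0].donor_coords[0]
        assert hap.sequence[start:end] == elem
        assert hap.sequence[start - 12 : start] == tsd
        assert hap.sequence[end : end + 12] == tsd

    def test_negative_tsd_deletes_flank(self, library):
        cfg, genome = self._genome(library)
        ref = genome.reference["chr1"]
        spec = _spec(position=100_000, tsd_len=-8)
        donor = sim.build_donor(genome, [spec], library)
        hap = donor.haplotypes[0]["chr1"]
        start, end = donor.truth[0].donor_coords[0]
        assert hap.sequence[end : end + 30] == ref[100_009 : 100_039]

    def test_het_spec_on_one_haplotype_only(self, library):
        cfg, genome = self._genome(library)
        spec = _spec(position=100_000, zygosity="het", haplotype=1)
        donor = sim.build_donor(genome, [spec], library)
        assert donor.haplotypes[0]["chr1"].sequence == genome.reference["chr1"]
        assert len(donor.haplotypes[1]["chr1"].sequence) > len(genome.reference["chr1"])

    def test_seeded_planting_is_deterministic(self, library):
        outs = []
        for _ in range(2):
            cfg, genome = self._genome(library, seed=11)
            rng = random.Random(99)
            specs = sim.plan_insertions(genome, cfg, library, rng, {"ALU": 4})
            donor = sim.build_donor(genome, specs, library)
            outs.append(
                (genome.reference["chr1"],
                 donor.haplotypes[0]["chr1"].sequence,
                 donor.haplotypes[1]["chr1"].sequence)
            )
        assert outs[0] == outs[1]

    def test_positions_respect_spacing_and_accessibility(self, library):
        cfg, genome = self._genome(library)
        rng = random.Random(5)
        specs = sim.plan_insertions(genome, cfg, library, rng, {"ALU": 20})
        pos = sorted(s.position for s in specs)
        assert min(b - a for a, b in zip(pos, pos[1:])) >= cfg.min_spacing
        for p in pos:
            assert any(iv.start <= p < iv.end for iv in genome.accessible)

    def test_default_distribution_is_na12878_like(self):
        cfg = sim.SimulationConfig()
        assert cfg.class_counts == {"ALU": 922, "LINE1": 146, "SVA": 46}
        assert cfg.effective_config()["het_percent"] == 95.0

    def test_scaled_counts_proportional(self):
        cfg = sim.SimulationConfig()
        scaled = cfg.scaled_class_counts(sim.FULL_GENOME_SIZE // 2)
        assert scaled == {"ALU": 461, "LINE1": 73, "SVA": 23}

    def test_insufficient_space_raises(self, library):
        cfg, genome = self._genome(library, length=60_000)
        with pytest.raises(ConfigurationError):
            sim.plan_insertions(genome, cfg, library, random.Random(1), {"ALU": 500})


class TestReadSimulation:
    def test_single_haplotype_coverage(self, library):
        cfg = sim.SimulationConfig(ref_length=1_000_000, n_ref_alu=0, n_ref_l1=0,
                                   n_ref_fl_l1=0, n_ref_sva=0, n_gaps=0)
        genome = sim.generate_reference(cfg, library, random.Random(1))
        donor = sim.build_donor(genome, [], library)
        donor.haplotypes = donor.haplotypes[:1]
        frags = sim.simulate_reads(donor, 30.0, seed=4)
        total_bases = sum(200 * len(f.starts) for f in frags)
        assert 29.0 <= total_bases / 1_000_000 <= 31.0

    def test_zero_error_reads_are_exact_substrings(self, sim_small):
        hap_seqs = {
            (h, c): sim_small.donor.haplotypes[h][c].sequence
            for h in (0, 1)
            for c in sim_small.donor.haplotypes[h]
        }
        rng = random.Random(0)
        for r in rng.sample(sim_small.records, 500):
            hap = int(r.name.split(".")[1])
            chrom = r.name.split(".")[2]
            assert r.sequence in hap_seqs[(hap, chrom)]

    def test_downsample_ratio(self, library):
        cfg = sim.SimulationConfig(ref_length=500_000, n_ref_alu=0, n_ref_l1=0,
                                   n_ref_fl_l1=0, n_ref_sva=0, n_gaps=0)
        genome = sim.generate_reference(cfg, library, random.Random(1))
        donor = sim.build_donor(genome, [], library)
        frags = sim.simulate_reads(donor, 60.0, seed=5)
        down = sim.downsample_fragments(frags, 7.5 / 60.0, seed=6)
        n0 = sum(len(f.starts) for f in frags)
        n1 = sum(len(f.starts) for f in down)
        assert abs(n1 / n0 - 0.125) <= 0.01

    def test_fragment_shorter_than_two_reads_rejected(self, sim_small):
        with pytest.raises(ConfigurationError):
            sim.simulate_reads(sim_small.donor, 30.0, read_len=100, frag_mean=150)

    def test_zero_coverage_rejected(self, sim_small):
        with pytest.raises(ConfigurationError):
            sim.simulate_reads(sim_small.donor, 0.0)


def independent_liftover(ref_len, elements, s, e):
    """Independent projection oracle built directly from element intervals.

    ``elements``: list of (donor_start, donor_end, ref_resume) meaning donor
    positions [donor_start, donor_end) are inserted sequence and reference
    coordinates resume at ``ref_resume`` after the element.
    """
    # donor -> (kind, ref coordinate) per base, brute force
    parts = []
    cursor_ref = 0
    cursor_donor = 0
    for d0, d1, resume in elements:
        n_ref = d0 - cursor_donor
        parts.append(("ref", cursor_ref, n_ref))
        parts.append(("ins", -1, d1 - d0))
        cursor_ref = resume
        cursor_donor = d1
    parts.append(("ref", cursor_ref, 10**9))
    mapping = []
    for kind, ref0, n in parts:
        for k in range(min(n, 10**7)):
            mapping.append((kind, ref0 + k if kind == "ref" else -1))
            if len(mapping) > e + 10:
                break
        if len(mapping) > e + 10:
            break
    window = mapping[s:e]
    ref_positions = [(i, rp) for i, (kind, rp) in enumerate(window) if kind == "ref"]
    if not ref_positions:
        return None  # decoy-mapped
    # contiguous ref runs; the longest wins, remainder soft-clipped
    runs = []
    run = [ref_positions[0]]
    for prev, cur in zip(ref_positions, ref_positions[1:]):
        if cur[0] == prev[0] + 1 and cur[1] == prev[1] + 1:
            run.append(cur)
        else:
            runs.append(run)
            run = [cur]
    runs.append(run)
    best = max(runs, key=len)
    if len(best) < 20:
        return None
    left = best[0][0]
    mid = len(best)
    right = (e - s) - left - mid
    cigar = []
    if left:
        cigar.append(("S", left))
    cigar.append(("M", mid))
    if right:
        cigar.append(("S", right))
    return best[0][1], cigar


@pytest.fixture(scope="module")
def planted(library):
    cfg = sim.SimulationConfig(ref_length=120_000, n_ref_alu=0, n_ref_l1=0,
                               n_ref_fl_l1=0, n_ref_sva=0, n_gaps=0)
    genome = sim.generate_reference(cfg, library, random.Random(21))
    spec = _spec(position=59_999, tsd_len=12)  # boundary b = 60_000
    donor = sim.build_donor(genome, [spec], library)
    elem_len = len(sim.synthesize_element(spec, library))
    return genome, donor, spec, elem_len


class TestProjection:
    def _project(self, donor, library, start, flen=500):
        fs = sim.FragmentSet(0, "chr1", np.array([start]), np.array([flen]))
        records, refs = sim.project_alignments(donor, [fs], library)
        return records, refs

    def test_read_in_unmodified_sequence(self, planted, library):
        _genome, donor, _spec_, _ = planted
        records, _ = self._project(donor, library, 10_000)
        r1 = next(r for r in records if r.strand == "+")
        assert r1.pos == 10_000 and r1.cigar == [("M", 100)] and r1.mapq == 60

    def test_read_crossing_left_breakpoint(self, planted, library):
        _genome, donor, spec_, _ = planted
        # left junction in donor space: ref[..60_012) then element;
        # a + read starting 60 bp before it carries 60 ref + 40 element bases
        start = 60_012 - 60
        records, _ = self._project(donor, library, start)
        r1 = next(r for r in records if r.strand == "+")
        assert r1.cigar == [("M", 60), ("S", 40)]
        assert r1.pos == start and r1.chrom == "chr1"

    def test_read_inside_element_goes_to_decoy(self, planted, library):
        _genome, donor, _spec_, elem_len = planted
        start = 60_012 + 50  # 50 bp into the element (element len >> 150)
        records, _ = self._project(donor, library, start, flen=210)
        r1 = next(r for r in records if r.strand == "+")
        assert r1.chrom == DECOY_PREFIX + "ALU"
        assert r1.cigar == [("M", 100)] and r1.pos == 50

    def test_straddling_pair_is_drp_candidate(self, planted, library):
        _genome, donor, _spec_, elem_len = planted
        start = 60_012 - 250  # anchor well left, mate inside the element
        records, _ = self._project(donor, library, start, flen=500)
        a, b = records
        assert {a.chrom, b.chrom} == {"chr1", DECOY_PREFIX + "ALU"}
        assert classify_pair(a, b) is PairClass.DRP_CANDIDATE

    def test_cigars_match_independent_liftover(self, planted, library):
        _genome, donor, spec_, elem_len = planted
        b = 60_000
        tsd = 12
        # donor layout: ref[0, b+tsd) + element + ref[b, ...)
        elements = [(b + tsd, b + tsd + elem_len, b)]
        hap = donor.haplotypes[0]["chr1"]
        rng = random.Random(13)
        checked = decoyed = 0
        for _ in range(300):
            s = rng.randrange(59_000, 61_200)
            records, _ = self._project(donor, library, s, flen=400)
            r1 = next(r for r in records if r.strand == "+")
            oracle = independent_liftover(120_000, elements, s, s + 100)
            if oracle is None:
                assert r1.chrom.startswith(DECOY_PREFIX)
                decoyed += 1
            else:
                pos, cigar = oracle
                assert r1.chrom == "chr1"
                assert (r1.pos, r1.cigar) == (pos, cigar), f"start {s}"
                checked += 1
        assert checked > 50 and decoyed > 20

    def test_mates_are_mutually_consistent(self, sim_small):
        by_name = {}
        for r in sim_small.records[:20_000]:
            by_name.setdefault(r.name, []).append(r)
        n = 0
        for rr in by_name.values():
            if len(rr) != 2:
                continue
            a, b = rr
            assert a.mate_chrom == b.chrom and a.mate_pos == b.pos
            assert b.mate_chrom == a.chrom and b.mate_pos == a.pos
            assert a.is_proper_pair == b.is_proper_pair
            n += 1
        assert n > 1_000


def _call(pos, me_class="ALU", chrom="chr1"):
    return MEICall(
        id=f"C{pos}", chrom=chrom, position=pos, orientation="+", me_class=me_class,
        consensus_start=0, consensus_stop=300, svlen=320, tsd="", tsd_deletion=0,
        tranche=5,
    )


def _truth(pos, me_class="ALU"):
    spec = _spec(position=pos, me_class=me_class, subfamily=me_class)
    return sim.TruthRecord(spec, {})


class TestEvaluateCalls:
    def test_exact_positions(self):
        truth = [_truth(1_000), _truth(5_000)]
        calls = [_call(1_000), _call(5_000)]
        m = sim.evaluate_calls(calls, truth)
        assert m["ALU"]["FNR"] == 0.0 and m["ALU"]["FDR"] == 0.0

    def test_499bp_offset_is_tp(self):
        m = sim.evaluate_calls([_call(1_499)], [_truth(1_000)])
        assert m["ALU"] == {"TP": 1, "FP": 0, "FN": 0, "FNR": 0.0, "FDR": 0.0}

    def test_501bp_offset_is_fp_and_fn(self):
        m = sim.evaluate_calls([_call(1_501)], [_truth(1_000)])
        assert m["ALU"]["FP"] == 1 and m["ALU"]["FN"] == 1

    def test_class_mismatch_not_matched(self):
        m = sim.evaluate_calls([_call(1_000, "LINE1")], [_truth(1_000, "ALU")])
        assert m["ALU"]["FN"] == 1 and m["LINE1"]["FP"] == 1

    def test_one_to_one_greedy_matching(self):
        truth = [_truth(1_000)]
        calls = [_call(990), _call(1_010)]
        m = sim.evaluate_calls(calls, truth)
        assert m["ALU"]["TP"] == 1 and m["ALU"]["FP"] == 1


class TestTruthTables:
    def test_insertion_truth_round_trip(self, tmp_path, sim_small):
        p = str(tmp_path / "truth.tsv")
        sim.write_truth(sim_small.truth, p)
        back = sim.read_truth(p)
        assert len(back) == len(sim_small.truth)
        for a, b in zip(sim_small.truth, back):
            assert (a.spec.chrom, a.position, a.me_class, a.spec.tsd_len,
                    a.spec.zygosity, a.spec.subfamily, a.spec.extra_mutations) == (
                b.spec.chrom, b.position, b.me_class, b.spec.tsd_len,
                b.spec.zygosity, b.spec.subfamily, b.spec.extra_mutations)

    def test_deletion_truth_round_trip(self, tmp_path, sim_deletion):
        p = str(tmp_path / "dels.tsv")
        sim.write_deletion_truth(sim_deletion.deletions, p)
        back = sim.read_deletion_truth(p)
        assert [(d.interval.start, d.zygosity) for d in back] == [
            (d.interval.start, d.zygosity) for d in sim_deletion.deletions
        ]

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = sim.SimulationConfig(coverage=15.0, het_fraction=0.9)
        p = str(tmp_path / "cfg.yaml")
        cfg.dump(p)
        back = sim.SimulationConfig.load(p)
        assert back.coverage == 15.0 and back.het_fraction == 0.9
        import yaml

        data = yaml.safe_load(open(p))
        assert data["het_percent"] == 90.0
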