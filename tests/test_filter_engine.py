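"""The four selection criteria: reason mapping, invariance, pipeline truth."""

import itertools

import numpy as np
import pytest

from crossprobe.aligner import GenomeHit
from crossprobe.filter_engine import (
    FilterConfig,
    Reason,
    evaluate_probe,
    run_selection,
)
from crossprobe.genome import Genome
from crossprobe.probe_recon import TargetSeq


@pytest.fixture()
def toy():
    """A 51-nt type II window planted once at chr1:100 in a 1 kb genome."""
    rng = np.random.default_rng(42)
    win = rng.choice(list("ACGT"), size=51)
    win[49], win[50] = "C", "G"
    win = "".join(win)
    bg = "".join(rng.choice(list("ACGT"), size=1000))
    seq = bg[:100] + win + bg[151:]
    genome = Genome({"chr1": seq})
    tgt = TargetSeq(probe_id="q", sequence=win, target_offset=49,
                    infinium_type="II")
    return tgt, genome


def _hit(start=100, mm=(), indel=False, chrom="chr1", strand="+", L=51):
    return GenomeHit(probe_id="q", chrom=chrom, start=start, end=start + L,
                     strand=strand, mismatch_offsets=tuple(mm),
                     has_indel=indel, n_matches=L - len(mm))


class TestEvaluateProbe:
    def test_perfect_unique_hit_passes(self, toy):
        tgt, genome = toy
        d = evaluate_probe(tgt, [_hit()], genome)
        assert d.status == "pass" and d.reasons == frozenset()
        assert d.accepted_hit is not None
        assert d.target_cpg_coord == ("chr1", 100 + 49, "+")

    def test_no_hits(self, toy):
        tgt, genome = toy
        d = evaluate_probe(tgt, [], genome)
        assert d.reasons == {Reason.NO_HIT}

    def test_mismatch_near_target(self, toy):
        tgt, genome = toy
        d = evaluate_probe(tgt, [_hit(mm=(46,))], genome)  # offset t-3
        assert d.reasons == {Reason.NEAR_TARGET_MISMATCH}
        assert d.accepted_hit is None

    @pytest.mark.parametrize("off,near", [
        (43, False), (44, True), (48, True), (50, True),
    ])
    def test_near_window_boundaries(self, toy, off, near):
        """Near window = CpG dinucleotide (49,50) plus 5 nt each side: [44, 56],
        clipped to the 51-nt window."""
        tgt, genome = toy
        d = evaluate_probe(tgt, [_hit(mm=(off,))], genome)
        assert (Reason.NEAR_TARGET_MISMATCH in d.reasons) == near

    def test_two_mismatches_far_allowed(self, toy):
        tgt, genome = toy
        d = evaluate_probe(tgt, [_hit(mm=(5, 20))], genome)
        assert d.status == "pass"

    def test_three_mismatches_far_too_many(self, toy):
        tgt, genome = toy
        d = evaluate_probe(tgt, [_hit(mm=(5, 20, 30))], genome)
        assert d.reasons == {Reason.TOO_MANY_MISMATCHES}

    def test_tied_best_is_multi_hit(self, toy):
        tgt, genome = toy
        d = evaluate_probe(tgt, [_hit(100), _hit(500)], genome)
        assert d.reasons == {Reason.MULTI_HIT}

    def test_extra_hit_within_ceiling_is_suboptimal(self, toy):
        tgt, genome = toy
        d = evaluate_probe(tgt, [_hit(100), _hit(500, mm=(1, 2, 3))], genome)
        assert d.reasons == {Reason.SUBOPTIMAL_HIT}

    def test_extra_hit_beyond_ceiling_ignored(self, toy):
        tgt, genome = toy
        cfg = FilterConfig(suboptimal_mm_ceiling=2)
        d = evaluate_probe(tgt, [_hit(100), _hit(500, mm=(1, 2, 3))], genome, cfg)
        assert d.status == "pass"

    def test_indel_hit_flags_criterion_a(self, toy):
        tgt, genome = toy
        d = evaluate_probe(tgt, [_hit(100), _hit(500, indel=True, L=49)], genome)
        assert d.reasons == {Reason.INDEL}

    def test_ambiguous_reference_span(self, toy):
        tgt, genome = toy
        seq = genome.sequence("chr1")
        genome_n = Genome({"chr1": seq[:105] + "N" + seq[106:]})
        d = evaluate_probe(tgt, [_hit(mm=(5,))], genome_n)
        assert Reason.AMBIGUOUS_BASE in d.reasons

    def test_target_not_cpg(self, toy):
        tgt, genome = toy
        seq = genome.sequence("chr1")
        pos = 100 + 49
        broken = Genome({"chr1": seq[:pos] + "T" + seq[pos + 1:]})
        d = evaluate_probe(tgt, [_hit(mm=(49,))], broken)
        assert Reason.TARGET_NOT_CPG in d.reasons
        cfg = FilterConfig(require_target_cpg=False)
        d2 = evaluate_probe(tgt, [_hit(mm=(49,))], broken, cfg)
        assert Reason.TARGET_NOT_CPG not in d2.reasons

    def test_minus_strand_cpg_coordinate(self, toy):
        tgt, genome = toy
        # plant revcomp window so a minus-strand hit is geometrically real
        from crossprobe.genome import revcomp

        seq = genome.sequence("chr1")
        g2 = Genome({"chr1": seq[:300] + revcomp(tgt.sequence) + seq[351:]})
        d = evaluate_probe(tgt, [_hit(300, strand="-")], g2)
        assert d.status == "pass"
        # probe C at offset 49 maps to plus-strand CG start end - 49 - 2
        assert d.target_cpg_coord == ("chr1", 351 - 49 - 2, "-")

    def test_reasons_stable_under_hit_permutation(self, toy):
        tgt, genome = toy
        hits = [_hit(100), _hit(500, mm=(1,)), _hit(700, indel=True, L=50)]
        verdicts = {
            evaluate_probe(tgt, list(p), genome).reasons
            for p in itertools.permutations(hits)
        }
        assert len(verdicts) == 1

    def test_out_of_genome_hit_is_integrity_error(self, toy):
        tgt, genome = toy
        with pytest.raises(ValueError, match="outside"):
            evaluate_probe(tgt, [_hit(990)], genome)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(max_mm_rest=-1)
        with pytest.raises(ValueError):
            FilterConfig(max_mm_rest=3, suboptimal_mm_ceiling=2)


class TestRunSelection:
    def test_fixture_truth_recovered(self, std_fixture_dir, std_fixture):
        decisions, summary = run_selection(
            std_fixture_dir["manifest"], std_fixture_dir["genome"],
            psl_path=std_fixture_dir.get("psl"),
        )
        truth = std_fixture.truth_by_id()
        for d in decisions:
            t = truth[d.probe_id]
            assert d.status == t.expected_status, d.probe_id
            assert d.reasons == t.expected_reasons, d.probe_id
            if d.status == "pass":
                assert d.target_cpg_coord[:2] == (t.chrom, t.cpg_start)

    def test_empty_manifest(self, tmp_path, std_fixture_dir):
        from crossprobe.manifest_io import write_manifest

        p = tmp_path / "empty.csv"
        write_manifest([], p)
        decisions, summary = run_selection(p, std_fixture_dir["genome"])
        assert decisions == [] and summary.n_pass == 0

    def test_partition_identity(self, std_fixture_dir):
        _, summary = run_selection(
            std_fixture_dir["manifest"], std_fixture_dir["genome"],
            psl_path=std_fixture_dir.get("psl"),
        )
        assert summary.n_pass_type_I + summary.n_pass_type_II == summary.n_pass
        assert summary.n_pass + summary.n_fail == summary.n_probes

    def test_tightening_config_shrinks_pass_set(self, std_fixture_dir):
        loose, _ = run_selection(
            std_fixture_dir["manifest"], std_fixture_dir["genome"],
            cfg=FilterConfig(), psl_path=std_fixture_dir.get("psl"),
        )
        passing_loose = {d.probe_id for d in loose if d.status == "pass"}
        for cfg in (FilterConfig(max_mm_rest=0),
                    FilterConfig(near_target_halfwidth=10)):
            tight, _ = run_selection(
                std_fixture_dir["manifest"], std_fixture_dir["genome"],
                cfg=cfg, psl_path=std_fixture_dir.get("psl"),
            )
            passing_tight = {d.probe_id for d in tight if d.status == "pass"}
            assert passing_tight <= passing_loose
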