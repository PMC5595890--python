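"""Pileup construction, filter thresholds, HGVS annotation, reporting."""
import numpy as np
import pytest

import smmipseq as sq
from smmipseq.models import SmMIP, TranscriptModel, UniqueObservation
from smmipseq.panel import BACKBONE
from smmipseq.simulate import random_transcript
from smmipseq.variants import (
    Pileup, TranscriptPileup, VariantCall, annotate_variant, build_pileup,
    call_variants, normalize_deletion, write_variant_report, write_vcf,
)

from oracles import expected_annotation


def _transcript_with_codon(codon, codon_number=132, seed=0):
    """Random stop-free transcript whose CDS codon ``codon_number`` is forced
    to ``codon`` (the rest untouched)."""
    rng = np.random.default_rng(seed)
    t = random_transcript(rng, "FIX", length=1500)
    off = t.cds_start + (codon_number - 1) * 3
    seq = t.sequence[:off] + codon + t.sequence[off + 3:]
    return TranscriptModel(t.transcript_id, t.gene_symbol, seq, t.exon_ends,
                           t.cds_start, t.cds_end), off


def _mip_for(transcript, gap_start, smmip_id="FIX_1"):
    seq = transcript.sequence
    ge = gap_start + 112
    return SmMIP(smmip_id, transcript.transcript_id,
                 sq.revcomp(seq[gap_start - 16:gap_start]),
                 sq.revcomp(seq[ge:ge + 18]),
                 gap_start, ge, BACKBONE)


def _obs(smmip, gap, umi="ACGTACGT", rev_tail=77):
    n = len(gap)
    cov2 = tuple(i >= n - rev_tail for i in range(n))
    return UniqueObservation(smmip_id=smmip.smmip_id, umi=umi, consensus_gap=gap,
                             n_read_pairs=1, covered_by_mate1=(True,) * n,
                             covered_by_mate2=cov2)


class TestPileup:
    def test_single_observation_depths(self, small_transcriptome):
        tid = sorted(small_transcriptome)[0]
        t = small_transcriptome[tid]
        mip = _mip_for(t, 200)
        panel = sq.Panel(smmips=[mip])
        gap = t.sequence[200:312]
        pile = build_pileup([_obs(mip, gap)], panel, {tid: t})
        tp = pile.transcripts[tid]
        assert (tp.depth_fwd[200:312] == 1).all()
        assert (tp.depth_rev[200 + 35:312] == 1).all()
        assert (tp.depth_rev[200:235] == 0).all()
        assert not tp.base_obs

    def test_overlapping_smmips_pool_observations(self, small_transcriptome):
        tid = sorted(small_transcriptome)[0]
        t = small_transcriptome[tid]
        a, b = _mip_for(t, 200, "FIX_1"), _mip_for(t, 300, "FIX_2")
        panel = sq.Panel(smmips=[a, b])
        obs = [_obs(a, t.sequence[200:312]), _obs(b, t.sequence[300:412])]
        tp = build_pileup(obs, panel, {tid: t}).transcripts[tid]
        assert (tp.depth_fwd[300:312] == 2).all()
        assert (tp.depth_fwd[200:300] == 1).all()

    def test_empty_input_gives_empty_pileup(self, small_transcriptome, small_panel):
        pile = build_pileup([], small_panel, small_transcriptome)
        assert pile.transcripts == {}

    def test_unknown_smmip_rejected(self, small_transcriptome, small_panel):
        mip = small_panel.smmips[0]
        bad = _obs(mip, "A" * 112)
        object.__setattr__  # no-op; UniqueObservation is mutable
        bad.smmip_id = "GHOST_9"
        with pytest.raises(KeyError, match="unknown smMIP"):
            build_pileup([bad], small_panel, small_transcriptome)

    def test_deletion_consensus_registers_deletion(self, small_transcriptome):
        tid = sorted(small_transcriptome)[0]
        t = small_transcriptome[tid]
        mip = _mip_for(t, 200)
        panel = sq.Panel(smmips=[mip])
        gap = t.sequence[200:312]
        dgap = gap[:60] + gap[62:]  # 2-nt deletion at gap offset 60
        tp = build_pileup([_obs(mip, dgap)], panel, {tid: t}).transcripts[tid]
        assert sum(v[0] + v[1] for v in tp.del_obs.values()) > 0
        (pos, ref), _ = next(iter(tp.del_obs.items()))
        npos, nref = normalize_deletion(t.sequence, pos, ref)
        epos, eref = normalize_deletion(t.sequence, 260, gap[60:62])
        assert (npos, nref) == (epos, eref)


def _pileup_single_site(t, pos, alt, fwd, rev, depth_fwd, depth_rev):
    n = len(t.sequence)
    tp = TranscriptPileup(
        transcript_id=t.transcript_id,
        depth_fwd=np.zeros(n, dtype=np.int64),
        depth_rev=np.zeros(n, dtype=np.int64),
        base_obs={(pos, alt): [fwd, rev]},
        del_obs={},
    )
    tp.depth_fwd[pos] = depth_fwd
    tp.depth_rev[pos] = depth_rev
    return Pileup(transcripts={t.transcript_id: tp})


@pytest.fixture(scope="module")
def t():
    return random_transcript(np.random.default_rng(5), "THR", length=900)


class TestCallThresholds:
    def _alt(self, t, pos):
        return "ACGT"[("ACGT".index(t.sequence[pos]) + 1) % 4]

    def test_nine_percent_with_split_support_passes(self, t):
        # 22 supporting observations, 11 forward / 11 reverse, at 9% VAF
        pos = t.cds_start + 60
        pile = _pileup_single_site(t, pos, self._alt(t, pos), 11, 11, 122, 122)
        (call,) = call_variants(pile, {t.transcript_id: t})
        assert call.filter == "PASS"
        assert (call.support_total, call.support_fwd, call.support_rev) == (22, 11, 11)
        assert call.vaf == pytest.approx(22 / 244)
        assert call.coverage_string() == "9% (22) [11 / 11]"

    def test_full_vaf_but_four_reads_fails_support(self, t):
        pos = t.cds_start + 60
        pile = _pileup_single_site(t, pos, self._alt(t, pos), 2, 2, 2, 2)
        (call,) = call_variants(pile, {t.transcript_id: t})
        assert call.vaf == 1.0
        assert call.filter == "low_support"

    def test_just_below_vaf_floor_fails(self, t):
        pos = t.cds_start + 60
        pile = _pileup_single_site(t, pos, self._alt(t, pos), 25, 25, 511, 510)
        (call,) = call_variants(pile, {t.transcript_id: t})
        assert call.vaf == pytest.approx(0.04897, abs=1e-4)
        assert call.filter == "low_vaf"

    def test_single_orientation_support_fails(self, t):
        pos = t.cds_start + 60
        pile = _pileup_single_site(t, pos, self._alt(t, pos), 6, 0, 30, 30)
        (call,) = call_variants(pile, {t.transcript_id: t})
        assert call.filter == "orientation"

    def test_strict_orientation_mode_requires_five_each(self, t):
        pos = t.cds_start + 60
        pile = _pileup_single_site(t, pos, self._alt(t, pos), 8, 2, 40, 40)
        (call,) = call_variants(pile, {t.transcript_id: t}, strict_orientation=True)
        assert call.filter == "orientation"
        (call,) = call_variants(pile, {t.transcript_id: t})
        assert call.filter == "PASS"

    def test_sub_audit_threshold_dropped(self, t):
        pos = t.cds_start + 60
        pile = _pileup_single_site(t, pos, self._alt(t, pos), 1, 1, 200, 200)
        assert call_variants(pile, {t.transcript_id: t}) == []


def _call(t, pos, ref, alt):
    return VariantCall(transcript_id=t.transcript_id, position=pos, ref=ref,
                       alt=alt, vaf=0.5, support_total=20, support_fwd=10,
                       support_rev=10, depth_fwd=20, depth_rev=20)


class TestAnnotation:
    def test_gln_to_stop_at_codon_132(self):
        """CAA -> TAA at codon 132 is a nonsense change, p.Gln132*."""
        t, off = _transcript_with_codon("CAA")
        call = annotate_variant(_call(t, off, "C", "T"), t)
        assert call.classification == "nonsense"
        assert call.hgvs_c == "c.394C>T"
        assert call.hgvs_p == "p.Gln132*"

    def test_arg132his_missense(self):
        """CGT -> CAT at codon 132 (G>A at the second base): p.Arg132His."""
        t, off = _transcript_with_codon("CGT")
        call = annotate_variant(_call(t, off + 1, "G", "A"), t)
        assert call.classification == "missense"
        assert call.hgvs_c == "c.395G>A"
        assert call.hgvs_p == "p.Arg132His"

    def test_synonymous_arginine(self):
        t, off = _transcript_with_codon("CGT")
        call = annotate_variant(_call(t, off + 2, "T", "C"), t)  # CGT -> CGC
        assert call.classification == "synonymous"
        assert call.hgvs_p == "p.(=)"

    def test_vhl_dinucleotide_deletion_frameshift(self):
        """c.246_247delCG on the synthetic VHL-like CDS: frameshift starting
        at Val83, novel Arg, new stop 48 codons in: p.Val83Argfs*48."""
        t = sq.load_vhl_cds_synthetic()
        call = annotate_variant(_call(t, 245, "CG", ""), t)
        assert call.classification == "frameshift"
        assert call.hgvs_c == "c.246_247delCG"
        assert call.hgvs_p == "p.Val83Argfs*48"

    def test_noncoding_position_left_unclassified(self):
        t = random_transcript(np.random.default_rng(6), "UTR", length=900)
        pos = 10  # inside the 5' UTR
        ref = t.sequence[pos]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        call = annotate_variant(_call(t, pos, ref, alt), t)
        assert call.classification is None
        assert call.hgvs_c.startswith("n.11")

    def test_agrees_with_translate_and_diff_oracle(self):
        """1,000 random SNVs and deletions over random coding sequences:
        annotation equals the brute-force translate-and-diff oracle."""
        rng = np.random.default_rng(99)
        transcripts = [random_transcript(rng, f"ORA{i}", length=1200)
                       for i in range(10)]
        checked = 0
        while checked < 1000:
            t = transcripts[int(rng.integers(len(transcripts)))]
            cs, ce = t.cds_start, t.cds_end
            if rng.random() < 0.5:
                pos = int(rng.integers(cs, ce - 3))
                ref = t.sequence[pos]
                alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            else:
                L = int(rng.integers(1, 21))
                pos = int(rng.integers(cs, ce - 3 - L))
                ref, alt = t.sequence[pos:pos + L], ""
            call = annotate_variant(_call(t, pos, ref, alt), t)
            exp_c, exp_p, exp_cls = expected_annotation(t, pos, ref, alt)
            assert (call.hgvs_c, call.hgvs_p, call.classification) == \
                (exp_c, exp_p, exp_cls), (t.transcript_id, pos, ref, alt)
            checked += 1


class TestReporting:
    def test_empty_call_list_writes_header_only(self, tmp_path):
        p = tmp_path / "report.tsv"
        write_variant_report([], p)
        assert p.read_text().splitlines() == [
            "\t".join(["transcript_id", "nuc_change", "coverage", "aa_change",
                       "hgvs_c", "hgvs_p", "classification", "filter"])]

    def test_pass_call_row_present(self, tmp_path):
        t = random_transcript(np.random.default_rng(7), "REP", length=900)
        pos = t.cds_start + 33
        call = annotate_variant(_call(t, pos, t.sequence[pos],
                                      "ACGT"[("ACGT".index(t.sequence[pos]) + 1) % 4]), t)
        p = tmp_path / "report.tsv"
        write_variant_report([call], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 2
        assert "50% (20) [10 / 10]" in lines[1]

    def test_vcf_deletion_uses_anchor_base(self, tmp_path):
        t = sq.load_vhl_cds_synthetic()
        call = annotate_variant(_call(t, 245, "CG", ""), t)
        p = tmp_path / "out.vcf"
        write_vcf([call], {t.transcript_id: t}, p)
        data = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert len(data) == 1
        chrom, pos, _, ref, alt = data[0].split("\t")[:5]
        assert chrom == t.transcript_id
        assert int(pos) == call.position  # anchor base precedes the deletion
        assert ref[1:] == call.ref and ref[0] == alt


class TestSimulatedRecovery:
    def test_spiked_heterozygous_snv_recovered(self, variant_run):
        """A 50% spiked SNV at >= 200 unique molecules is PASS with VAF
        within 3 binomial standard errors of one half."""
        snv = variant_run["snv"]
        hits = [c for c in variant_run["calls"]
                if c.position == snv.position and c.alt == snv.alt]
        assert len(hits) == 1
        call = hits[0]
        assert call.filter == "PASS"
        n_molecules = (call.depth_fwd + call.depth_rev) / 2
        assert n_molecules >= 200
        se = (0.25 / n_molecules) ** 0.5
        assert abs(call.vaf - 0.5) <= 3 * se

    def test_no_false_pass_from_sequencing_errors(self, quant_run):
        """Error-only data (rate 0.001) yields no PASS calls: the 5% VAF
        floor dominates at the simulated coverage."""
        res = quant_run["result"]
        pile = build_pileup(res.observations["Q1"], quant_run["panel"],
                            quant_run["transcripts"])
        calls = call_variants(pile, quant_run["transcripts"])
        assert [c for c in calls if c.filter == "PASS"] == []
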