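"""Shared fixtures: synthetic transcriptomes, panels and simulated runs.

Heavy simulated datasets are session-scoped so unit, property and
acceptance tests reuse one simulation instead of regenerating it.
"""
import numpy as np
import pytest

import smmipseq as sq
from smmipseq.simulate import loguniform_abundance, random_transcriptome

BARCODE_A = "ACGTTGCA"
BARCODE_B = "TGCAGTAC"  # Hamming distance 6 from BARCODE_A

# default study conditions for the quantification run: 50 transcripts,
# 5 probes each, capture-efficiency sigma 1.5, 20,000 molecules
QUANT_SEEDS = dict(transcriptome=11, efficiency=12, abundance=13, plan=14)


@pytest.fixture(scope="session")
def small_transcriptome():
    return random_transcriptome(5, seed=1, length=1200)


@pytest.fixture(scope="session")
def small_panel(small_transcriptome):
    return sq.design_panel(small_transcriptome)


@pytest.fixture(scope="session")
def quant_run():
    """Default-condition simulation and its processing output."""
    ts = random_transcriptome(50, seed=QUANT_SEEDS["transcriptome"], length=1500)
    panel = sq.design_panel(ts)
    eff = sq.EfficiencyModel.draw(panel, sigma=1.5, seed=QUANT_SEEDS["efficiency"])
    abundance = loguniform_abundance(ts, seed=QUANT_SEEDS["abundance"])
    plan = sq.SamplePlan("Q1", BARCODE_A, abundance, 20000,
                         seed=QUANT_SEEDS["plan"])
    pairs, truth = sq.simulate_pairs(panel, ts, plan, eff,
                                     error_rate=0.001, dup_mean=1.0)
    result = sq.process_pairs(pairs, panel, {"Q1": BARCODE_A})
    return dict(transcripts=ts, panel=panel, eff=eff, abundance=abundance,
                plan=plan, truth=truth, result=result, n_pairs=len(pairs))


@pytest.fixture(scope="session")
def variant_run(small_transcriptome):
    """One transcript, uniform capture efficiency, a heterozygous SNV spiked
    at 50% allele fraction in the dual-mate-covered part of one gap."""
    ts = small_transcriptome
    tid = sorted(ts)[0]
    panel = sq.Panel(smmips=[m for m in sq.design_panel(ts).smmips
                             if m.transcript_id == tid])
    eff = sq.EfficiencyModel(efficiency={m.smmip_id: 1.0 for m in panel.smmips})
    mip = panel.smmips[2]
    pos = mip.gap_start + 70  # covered by both mates for any arm length
    ref = ts[tid].sequence[pos]
    alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
    snv = sq.SpikedVariant(tid, pos, ref, alt, 0.5)
    plan = sq.SamplePlan("V1", BARCODE_A, {tid: 1.0}, 2000,
                         variants=[snv], seed=21)
    pairs, truth = sq.simulate_pairs(panel, ts, plan, eff,
                                     error_rate=0.001, dup_mean=1.0)
    result = sq.process_pairs(pairs, panel, {"V1": BARCODE_A})
    pileup = sq.build_pileup(result.observations["V1"], panel, ts)
    calls = sq.call_variants(pileup, ts)
    return dict(transcripts=ts, panel=panel, snv=snv, truth=truth,
                result=result, pileup=pileup, calls=calls)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
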