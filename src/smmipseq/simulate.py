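"""Paired-end read simulation for smMIP capture experiments.

The simulator is the package's ground-truth generator: it emulates the
molecular steps of the assay that matter to downstream analysis —
per-probe capture-efficiency dispersion, 8-nt UMIs, PCR duplication,
substitution sequencing errors, in-read sample barcodes, and spiked
SNVs/small deletions at set allele fractions — and writes 2 x 151 bp
paired-end FASTQ plus truth tables.

Amplicon dialect (shared contract with :mod:`smmipseq.process`)::

    ext_target + gap_fill + lig_target + UMI(8) + backbone(40) + barcode(8)

Read 1 is the first 151 nt of the amplicon; read 2 is the reverse
complement of the last 151 nt, so it begins with the (reverse-complemented)
barcode, backbone and UMI, then the ligation arm target and the 3' portion
of the gap fill.  With minimal arms the insert is 16+112+18+8+40+8 = 202 nt;
mate 1 always covers the whole gap, mate 2 covers its last 95-lig_len bases.
PCR primer tails are not emitted.  Base qualities are constant Phred 30
(Sanger encoding).  A template deletion of d nt shortens the gap fill to
112-d (the arms pin both flanks of the captured region).
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import Panel, SmMIP, TranscriptModel

READ_LENGTH = 151
PHRED33_Q30 = "?"  # chr(33 + 30)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SpikedVariant:
    """A variant planted in the template at a set allele fraction.

    ``ref`` must match the transcript at ``position`` (0-based).  SNV:
    single-base ref and alt.  Deletion: ``ref`` is the deleted sequence
    (1-20 nt), ``alt`` is the empty string.
    """

    transcript_id: str
    position: int
    ref: str
    alt: str
    allele_fraction: float

    def __post_init__(self):
        if not 0.0 < self.allele_fraction <= 1.0:
            raise ValueError("allele_fraction must be in (0, 1]")
        if self.alt == "" and not 1 <= len(self.ref) <= 20:
            raise ValueError("deletions must remove 1-20 nt")
        if self.alt != "" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("substitutions must be single-base")

    @property
    def is_deletion(self) -> bool:
        return self.alt == ""


@dataclass
class SamplePlan:
    """What one sample contains: relative transcript abundances, spiked
    variants, molecule budget, barcode and seed."""

    sample_id: str
    barcode: str
    abundance: dict[str, float]
    n_molecules: int
    variants: list[SpikedVariant] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if len(self.barcode) != 8 or set(self.barcode) - set("ACGT"):
            raise ValueError("barcode must be an 8-nt A/C/G/T string")
        if not any(v > 0 for v in self.abundance.values()):
            raise ValueError("abundances must not be all zero")
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be non-negative")


@dataclass
class EfficiencyModel:
    """Per-smMIP capture efficiencies.

    Probes designed against the same transcript capture with widely varying
    efficiency; the model draws a fixed multiplicative efficiency per probe
    from a log-normal with log-scale sigma (default 1.5), reproducible under
    a fixed seed.
    """

    efficiency: dict[str, float]
    sigma: float = 1.5

    def __post_init__(self):
        if any(e <= 0 for e in self.efficiency.values()):
            raise ValueError("efficiencies must be positive")

    @classmethod
    def draw(cls, panel: Panel, sigma: float = 1.5, seed: int = 0) -> "EfficiencyModel":
        rng = np.random.default_rng(seed)
        eff = {m.smmip_id: float(np.exp(rng.normal(0.0, sigma))) for m in panel.smmips}
        return cls(efficiency=eff, sigma=sigma)


def build_amplicon(smmip: SmMIP, gap_sequence: str, umi: str, barcode: str) -> str:
    """Assemble the sequenced insert for one captured molecule.

    ``gap_sequence`` is 112 nt for a reference or SNV template, 112-d for a
    template carrying a d-nt deletion (d <= 20).
    """
    d = SmMIP.GAP_LENGTH - len(gap_sequence)
    if not 0 <= d <= 20:
        raise ValueError(
            f"gap sequence must be {SmMIP.GAP_LENGTH} nt (or up to 20 nt shorter "
            f"for a deletion template), got {len(gap_sequence)}"
        )
    if len(umi) != smmip.umi_length:
        raise ValueError(f"UMI must be {smmip.umi_length} nt")
    return smmip.ext_target + gap_sequence + smmip.lig_target + umi + smmip.backbone + barcode


def _check_variants(plan: SamplePlan, transcripts: dict[str, TranscriptModel]) -> None:
    for v in plan.variants:
        t = transcripts.get(v.transcript_id)
        if t is None:
            raise ValueError(f"variant on unknown transcript {v.transcript_id}")
        found = t.sequence[v.position:v.position + len(v.ref)]
        if found != v.ref:
            raise ValueError(
                f"variant ref mismatch on {v.transcript_id} at {v.position}: "
                f"plan says {v.ref!r}, transcript has {found!r}"
            )


def _mutant_gap(smmip: SmMIP, transcript: TranscriptModel,
                variants: list[SpikedVariant]) -> str:
    """Gap fill for a molecule carrying ``variants`` (all inside the gap)."""
    gap = transcript.sequence[smmip.gap_start:smmip.gap_end]
    for v in sorted(variants, key=lambda v: -v.position):
        off = v.position - smmip.gap_start
        if v.is_deletion:
            gap = gap[:off] + gap[off + len(v.ref):]
        else:
            gap = gap[:off] + v.alt + gap[off + 1:]
    return gap


def _add_errors(read: np.ndarray, rng: np.random.Generator, error_rate: float) -> None:
    """In-place substitution errors on a uint8 base-code array."""
    if error_rate <= 0:
        return
    k = rng.binomial(read.size, error_rate)
    if k == 0:
        return
    pos = rng.choice(read.size, size=k, replace=False)
    shift = rng.integers(1, 4, size=k)
    read[pos] = (read[pos] + shift) % 4


@dataclass
class SimTruth:
    """Ground truth of one simulated sample."""

    sample_id: str
    molecules: dict[str, int]          # smmip_id -> true molecule count
    unique_umis: dict[str, int]        # smmip_id -> distinct (smMIP, UMI) count
    variant_molecules: dict[SpikedVariant, tuple[int, int]]  # (mutant, total)
    n_read_pairs: int = 0


def simulate_pairs(
    panel: Panel,
    transcripts: dict[str, TranscriptModel],
    plan: SamplePlan,
    eff: EfficiencyModel,
    error_rate: float = 0.001,
    dup_mean: float = 1.0,
) -> tuple[list[tuple[str, str, str, str, str]], SimTruth]:
    """Simulate one sample; returns (read pairs, truth).

    Read pairs are ``(name, read1, qual1, read2, qual2)`` strings
    (qualities are constant Phred 30).  Molecule counts per smMIP follow a multinomial over
    abundance x capture efficiency; each molecule receives a uniform-random
    8-mer UMI and 1 + Poisson(dup_mean) PCR copies; every emitted base is
    substituted independently at ``error_rate``.  Fully deterministic for a
    fixed ``plan.seed``.
    """
    _check_variants(plan, transcripts)
    # two independent streams: molecule identities (counts, alleles, UMIs)
    # and the PCR/sequencing layer (duplication, errors) -- so unique
    # molecule content is invariant under dup_mean/error_rate changes
    mol_seed, pcr_seed = np.random.SeedSequence(plan.seed).spawn(2)
    rng = np.random.default_rng(mol_seed)
    rng_pcr = np.random.default_rng(pcr_seed)

    smmips = [m for m in panel.smmips if m.transcript_id in plan.abundance]
    weights = np.array(
        [plan.abundance.get(m.transcript_id, 0.0) * eff.efficiency[m.smmip_id]
         for m in smmips], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("no smMIP has positive abundance x efficiency")
    counts = rng.multinomial(plan.n_molecules, weights / weights.sum())

    variants_in_gap: dict[str, list[SpikedVariant]] = {}
    for m in smmips:
        vs = [v for v in plan.variants
              if v.transcript_id == m.transcript_id
              and m.gap_start <= v.position and v.position + len(v.ref) <= m.gap_end]
        if vs:
            variants_in_gap[m.smmip_id] = vs

    qual = PHRED33_Q30 * READ_LENGTH
    pairs: list[tuple[str, str, str, str, str]] = []
    molecules: dict[str, int] = {}
    umis_seen: dict[str, set[str]] = {}
    vcount: dict[SpikedVariant, list[int]] = {v: [0, 0] for v in plan.variants}
    serial = 0

    for m, n_mol in zip(smmips, counts):
        if n_mol == 0:
            continue
        molecules[m.smmip_id] = int(n_mol)
        umis_seen[m.smmip_id] = set()
        transcript = transcripts[m.transcript_id]
        ref_gap = transcript.sequence[m.gap_start:m.gap_end]
        gap_variants = variants_in_gap.get(m.smmip_id, [])
        for _ in range(int(n_mol)):
            carried = [v for v in gap_variants if rng.random() < v.allele_fraction]
            for v in gap_variants:
                vcount[v][1] += 1
                if v in carried:
                    vcount[v][0] += 1
            gap = _mutant_gap(m, transcript, carried) if carried else ref_gap
            umi = "".join("ACGT"[b] for b in rng.integers(0, 4, size=8))
            umis_seen[m.smmip_id].add(umi)
            amplicon = build_amplicon(m, gap, umi, plan.barcode)
            amp = np.frombuffer(amplicon.encode(), dtype=np.uint8)
            # base codes 0..3 for fast error injection
            code = np.empty(amp.size, dtype=np.uint8)
            for i, b in enumerate(b"ACGT"):
                code[amp == b] = i
            r1_t = code[:READ_LENGTH]
            # complement of the reversed suffix = reverse complement (A<->T is
            # code 0<->3, C<->G is 1<->2)
            r2_t = (3 - code[-READ_LENGTH:][::-1]).astype(np.uint8)
            n_copies = 1 + rng_pcr.poisson(dup_mean)
            for _copy in range(int(n_copies)):
                r1 = r1_t.copy()
                r2 = r2_t.copy()
                _add_errors(r1, rng_pcr, error_rate)
                _add_errors(r2, rng_pcr, error_rate)
                pairs.append((
                    f"{plan.sample_id}:{serial}",
                    _BASES[r1].tobytes().decode(), qual,
                    _BASES[r2].tobytes().decode(), qual,
                ))
                serial += 1

    truth = SimTruth(
        sample_id=plan.sample_id,
        molecules=molecules,
        unique_umis={k: len(v) for k, v in umis_seen.items()},
        variant_molecules={v: (c[0], c[1]) for v, c in vcount.items()},
        n_read_pairs=len(pairs),
    )
    return pairs, truth


def write_fastq_pair(pairs, r1_path, r2_path) -> None:
    """Write read pairs to (gzip if the name ends in .gz) FASTQ files."""
    def _open(p):
        p = str(p)
        if p.endswith(".gz"):
            # mtime=0 keeps output byte-identical for a fixed seed
            import io
            return io.TextIOWrapper(gzip.GzipFile(p, "wb", mtime=0))
        return open(p, "w")

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for name, r1, q1, r2, q2 in pairs:
            f1.write(f"@{name}/1\n{r1}\n+\n{q1}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{q2}\n")


def write_truth(plan: SamplePlan, truth: SimTruth, panel: Panel, outdir) -> None:
    """Write truth tables: per-smMIP molecule counts and per-variant fractions.

    ``smmip_truth.tsv`` lists both the true molecule count and the distinct
    (smMIP, UMI) count; UMI collisions make the two differ occasionally, and
    deduplication can only recover the latter.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{plan.sample_id}.smmip_truth.tsv", "w") as fh:
        fh.write("smmip_id\ttranscript_id\tn_molecules\tn_unique\n")
        for m in panel.smmips:
            n = truth.molecules.get(m.smmip_id, 0)
            u = truth.unique_umis.get(m.smmip_id, 0)
            fh.write(f"{m.smmip_id}\t{m.transcript_id}\t{n}\t{u}\n")
    with open(outdir / f"{plan.sample_id}.variant_truth.tsv", "w") as fh:
        fh.write("transcript_id\tposition\tref\talt\tallele_fraction\t"
                 "n_mutant\tn_total\trealized_fraction\n")
        for v, (nm, nt) in truth.variant_molecules.items():
            frac = nm / nt if nt else float("nan")
            fh.write(f"{v.transcript_id}\t{v.position}\t{v.ref}\t{v.alt}\t"
                     f"{v.allele_fraction}\t{nm}\t{nt}\t{frac:.6f}\n")


def simulate_sample(
    panel: Panel,
    transcripts: dict[str, TranscriptModel],
    plan: SamplePlan,
    eff: EfficiencyModel,
    outdir,
    error_rate: float = 0.001,
    dup_mean: float = 1.0,
) -> SimTruth:
    """Simulate one sample and write FASTQ pair + truth tables to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs, truth = simulate_pairs(panel, transcripts, plan, eff, error_rate, dup_mean)
    write_fastq_pair(pairs,
                     outdir / f"{plan.sample_id}.R1.fastq.gz",
                     outdir / f"{plan.sample_id}.R2.fastq.gz")
    write_truth(plan, truth, panel, outdir)
    return truth


# ---------------------------------------------------------------------------
# Synthetic transcript models (fixture generators)
# ---------------------------------------------------------------------------

def random_transcript(
    rng: np.random.Generator,
    gene_symbol: str,
    length: int = 1500,
    n_exons: int = 4,
    transcript_id: str | None = None,
    utr5: int = 60,
    utr3: int = 60,
) -> TranscriptModel:
    """A random transcript model with a stop-free CDS.

    The CDS occupies ``[utr5, length - utr3)`` rounded down to a codon
    multiple; internal codons are drawn from the 61 sense codons so the open
    reading frame is valid, which keeps consequence annotation well defined.
    """
    sense = [a + b + c
             for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in ("TAA", "TAG", "TGA")]
    cds_len = ((length - utr5 - utr3) // 3) * 3
    if cds_len < 9:
        raise ValueError("transcript too short for a CDS")
    n_codons = cds_len // 3
    body = "".join(sense[i] for i in rng.integers(0, len(sense), size=n_codons - 2))
    cds = "ATG" + body + "TGA"
    pick = lambda n: "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))
    seq = pick(utr5) + cds + pick(length - utr5 - cds_len)
    cuts = sorted(rng.choice(np.arange(1, len(seq)), size=n_exons - 1, replace=False)) \
        if n_exons > 1 else []
    return TranscriptModel(
        transcript_id=transcript_id or f"SYN_{gene_symbol}",
        gene_symbol=gene_symbol,
        sequence=seq,
        exon_ends=tuple(int(c) for c in cuts) + (len(seq),),
        cds_start=utr5,
        cds_end=utr5 + cds_len,
    )


def random_transcriptome(
    n_transcripts: int = 50,
    seed: int = 0,
    length: int = 1500,
    n_exons: int = 4,
) -> dict[str, TranscriptModel]:
    """A reproducible set of synthetic transcript models."""
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_transcripts):
        t = random_transcript(rng, gene_symbol=f"G{i:03d}", length=length, n_exons=n_exons)
        out[t.transcript_id] = t
    return out


def loguniform_abundance(
    transcripts, seed: int = 0, lo: float = 1.0, hi: float = 1e4
) -> dict[str, float]:
    """Relative abundances drawn log-uniformly over [lo, hi] — roughly the
    four-decade dynamic range of expressed transcripts."""
    rng = np.random.default_rng(seed)
    ids = sorted(transcripts)
    u = rng.uniform(np.log10(lo), np.log10(hi), size=len(ids))
    return {tid: float(10.0 ** x) for tid, x in zip(ids, u)}
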