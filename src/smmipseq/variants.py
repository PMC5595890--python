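"""Variant calling and coding-consequence annotation in transcript space.

Unique-molecule consensus gap fills are piled up per transcript position,
split by mate orientation (forward = mate-1 observations, reverse = mate-2
observations; one unique molecule contributes at most one of each per
position).  Non-reference alleles pass the filter when

* VAF >= 5% of the orientation-split observations at the position,
* total supporting observations >= 5, and
* both orientations contribute at least one supporting observation
  (a strict >= 5 per orientation reading is available via a flag).

Supported alleles are single-nucleotide substitutions and contiguous
deletions of 1-20 nt within one gap fill; insertions are not called.
Consequences are annotated in HGVS-like c./p. notation against the
transcript's CDS, with deletions right-shifted to their 3'-most equivalent
position before reporting.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from Bio.Seq import Seq

from .models import Panel, TranscriptModel, UniqueObservation, data_path

MAX_DELETION = 20

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "*",
}


@dataclass
class VariantCall:
    """One transcript-space variant.

    ``position`` is the 0-based transcript coordinate of the first affected
    base (1-based numbering appears only in the HGVS strings).  ``alt`` is a
    single base for substitutions and the empty string for deletions, in
    which case ``ref`` is the deleted sequence.
    """

    transcript_id: str
    position: int
    ref: str
    alt: str
    vaf: float
    support_total: int
    support_fwd: int
    support_rev: int
    depth_fwd: int
    depth_rev: int
    hgvs_c: str = ""
    hgvs_p: str = ""
    classification: str | None = None
    filter: str = "PASS"

    def __post_init__(self):
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError("vaf must be in (0, 1]")
        if self.support_total != self.support_fwd + self.support_rev:
            raise ValueError("support_total must equal support_fwd + support_rev")

    @property
    def is_deletion(self) -> bool:
        return self.alt == ""

    def coverage_string(self) -> str:
        """Table-style support summary, e.g. ``9% (22) [11 / 11]``."""
        return (f"{round(self.vaf * 100)}% ({self.support_total}) "
                f"[{self.support_fwd} / {self.support_rev}]")


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

@dataclass
class TranscriptPileup:
    """Orientation-split observation counts along one transcript."""

    transcript_id: str
    depth_fwd: np.ndarray                      # per-position mate-1 observations
    depth_rev: np.ndarray                      # per-position mate-2 observations
    # (position, alt_base) -> [fwd, rev] supporting observations
    base_obs: dict[tuple[int, str], list[int]]
    # (position, deleted_ref) -> [fwd, rev]
    del_obs: dict[tuple[int, str], list[int]]


@dataclass
class Pileup:
    transcripts: dict[str, TranscriptPileup]

    def total_observations(self) -> int:
        return int(sum(p.depth_fwd.sum() + p.depth_rev.sum()
                       for p in self.transcripts.values()))


def _place_deletion(consensus: str, ref_window: str, d: int) -> tuple[int, int]:
    """Best contiguous placement of a d-nt deletion.

    Returns (start offset within the gap, mismatch count of the best
    overlay).  Evaluates every start and keeps the leftmost minimum; the
    caller 3'-normalizes, so left/right ambiguity is immaterial.
    """
    best_s, best_mm = 0, None
    n = len(consensus)
    for s in range(0, n + 1):
        mm = 0
        for i in range(n):
            c = consensus[i]
            if c == "N":
                continue
            r = ref_window[i] if i < s else ref_window[i + d]
            if c != r:
                mm += 1
                if best_mm is not None and mm >= best_mm:
                    break
        else:
            if best_mm is None or mm < best_mm:
                best_s, best_mm = s, mm
    return best_s, best_mm if best_mm is not None else 0


def build_pileup(observations: list[UniqueObservation], panel: Panel,
                 transcripts: dict[str, TranscriptModel]) -> Pileup:
    """Accumulate unique-molecule observations into per-position counts.

    Positions covered by overlapping probes pool observations from all of
    them.  A consensus shorter than the 112-nt gap is interpreted as one
    contiguous template deletion and placed by exact best fit.
    """
    by_id = panel.by_id()
    piles: dict[str, TranscriptPileup] = {}

    def pile_for(tid: str) -> TranscriptPileup:
        if tid not in piles:
            n = len(transcripts[tid])
            piles[tid] = TranscriptPileup(
                transcript_id=tid,
                depth_fwd=np.zeros(n, dtype=np.int64),
                depth_rev=np.zeros(n, dtype=np.int64),
                base_obs=defaultdict(lambda: [0, 0]),
                del_obs=defaultdict(lambda: [0, 0]),
            )
        return piles[tid]

    for obs in observations:
        smmip = by_id.get(obs.smmip_id)
        if smmip is None:
            raise KeyError(f"observation references unknown smMIP {obs.smmip_id}")
        t = transcripts[smmip.transcript_id]
        pile = pile_for(smmip.transcript_id)
        gs, ge = smmip.gap_start, smmip.gap_end
        ref_gap = t.sequence[gs:ge]
        cons = obs.consensus_gap
        d = (ge - gs) - len(cons)
        cov1 = np.fromiter(obs.covered_by_mate1, dtype=np.int64, count=len(cons))
        cov2 = np.fromiter(obs.covered_by_mate2, dtype=np.int64, count=len(cons))

        if d == 0:
            pile.depth_fwd[gs:ge] += cov1
            pile.depth_rev[gs:ge] += cov2
            if cons != ref_gap:
                for i, (c, r) in enumerate(zip(cons, ref_gap)):
                    if c != r and c != "N":
                        rec = pile.base_obs[(gs + i, c)]
                        rec[0] += int(cov1[i])
                        rec[1] += int(cov2[i])
            continue

        if not 0 < d <= MAX_DELETION:
            raise ValueError(
                f"{obs.smmip_id}: consensus length {len(cons)} incompatible "
                f"with gap length {ge - gs}")
        s, _ = _place_deletion(cons, ref_gap, d)
        # observed positions flank the deletion
        pile.depth_fwd[gs:gs + s] += cov1[:s]
        pile.depth_rev[gs:gs + s] += cov2[:s]
        pile.depth_fwd[gs + s + d:ge] += cov1[s:]
        pile.depth_rev[gs + s + d:ge] += cov2[s:]
        # the molecule spans the deleted bases; its flank orientation counts
        flank = max(0, s - 1)
        f1, f2 = int(cov1[flank]), int(cov2[flank])
        pile.depth_fwd[gs + s:gs + s + d] += f1
        pile.depth_rev[gs + s:gs + s + d] += f2
        rec = pile.del_obs[(gs + s, ref_gap[s:s + d])]
        rec[0] += f1
        rec[1] += f2
        for i, c in enumerate(cons):
            if c == "N":
                continue
            r_idx = i if i < s else i + d
            if c != ref_gap[r_idx]:
                rec = pile.base_obs[(gs + r_idx, c)]
                rec[0] += int(cov1[i])
                rec[1] += int(cov2[i])

    return Pileup(transcripts=piles)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def normalize_deletion(sequence: str, position: int, deleted: str) -> tuple[int, str]:
    """Right-shift a deletion to its 3'-most equivalent placement (HGVS)."""
    L = len(deleted)
    while position + L < len(sequence) and sequence[position] == sequence[position + L]:
        position += 1
    return position, sequence[position:position + L]


def call_variants(pileup: Pileup, transcripts: dict[str, TranscriptModel],
                  min_vaf: float = 0.05, min_support: int = 5,
                  strict_orientation: bool = False) -> list[VariantCall]:
    """Emit filtered variant calls from a pileup.

    PASS requires VAF >= ``min_vaf``, total support >= ``min_support`` and
    both orientations represented (``strict_orientation`` demands
    ``min_support`` in each orientation instead).  Sub-threshold alleles
    with VAF >= min_vaf/2 are emitted with a failure reason for audit;
    anything weaker is dropped.
    """
    calls: list[VariantCall] = []
    for tid in sorted(pileup.transcripts):
        pile = pileup.transcripts[tid]
        t = transcripts[tid]
        entries = []
        for (pos, alt), (fwd, rev) in pile.base_obs.items():
            entries.append((pos, t.sequence[pos], alt, fwd, rev))
        merged_dels: dict[tuple[int, str], list[int]] = defaultdict(lambda: [0, 0])
        for (pos, deleted), (fwd, rev) in pile.del_obs.items():
            npos, ndel = normalize_deletion(t.sequence, pos, deleted)
            merged_dels[(npos, ndel)][0] += fwd
            merged_dels[(npos, ndel)][1] += rev
        for (pos, deleted), (fwd, rev) in merged_dels.items():
            entries.append((pos, deleted, "", fwd, rev))

        for pos, ref, alt, fwd, rev in sorted(entries):
            depth_f = int(pile.depth_fwd[pos])
            depth_r = int(pile.depth_rev[pos])
            depth = depth_f + depth_r
            total = fwd + rev
            if depth == 0 or total == 0:
                continue
            vaf = total / depth
            if vaf < min_vaf / 2:
                continue
            reasons = []
            if vaf < min_vaf:
                reasons.append("low_vaf")
            if total < min_support:
                reasons.append("low_support")
            if strict_orientation:
                if fwd < min_support or rev < min_support:
                    reasons.append("orientation")
            elif fwd < 1 or rev < 1:
                reasons.append("orientation")
            call = VariantCall(
                transcript_id=tid, position=pos, ref=ref, alt=alt,
                vaf=vaf, support_total=total, support_fwd=fwd, support_rev=rev,
                depth_fwd=depth_f, depth_rev=depth_r,
                filter="PASS" if not reasons else ";".join(reasons),
            )
            calls.append(annotate_variant(call, transcripts[tid]))
    return calls


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _aa3(seq: str) -> str:
    return "".join(AA3[a] for a in seq)


def _translate(seq: str) -> str:
    trimmed = seq[:len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


def annotate_variant(call: VariantCall, transcript: TranscriptModel) -> VariantCall:
    """Attach HGVS c./p. strings and a consequence class to a call.

    Substitutions are annotated by codon replacement under the standard
    genetic code; frameshifting deletions are annotated by translating the
    shifted sequence (continuing past the native stop into the 3' region if
    needed) to the first novel stop; ``fs*?`` marks a frame that never finds
    one.  Variants outside the CDS get transcript-level ``n.`` notation and
    no classification.
    """
    seq, cs, ce = transcript.sequence, transcript.cds_start, transcript.cds_end
    pos, ref, alt = call.position, call.ref, call.alt

    if call.is_deletion:
        pos, ref = normalize_deletion(seq, pos, ref)
    in_cds = cs <= pos and pos + len(ref) <= ce

    if not in_cds:
        if call.is_deletion:
            h = (f"n.{pos + 1}del{ref}" if len(ref) == 1
                 else f"n.{pos + 1}_{pos + len(ref)}del{ref}")
        else:
            h = f"n.{pos + 1}{ref}>{alt}"
        return dc_replace(call, position=pos, ref=ref, hgvs_c=h, hgvs_p="",
                          classification=None)

    c1 = pos - cs + 1  # 1-based coding position of the first affected base

    if not call.is_deletion:
        hgvs_c = f"c.{c1}{ref}>{alt}"
        ci = (pos - cs) // 3
        codon_start = cs + ci * 3
        codon = seq[codon_start:codon_start + 3]
        off = pos - codon_start
        mcodon = codon[:off] + alt + codon[off + 1:]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mcodon).translate())
        n = ci + 1
        if aa_ref == aa_alt:
            cls, hgvs_p = "synonymous", "p.(=)"
        elif aa_alt == "*":
            cls, hgvs_p = "nonsense", f"p.{AA3[aa_ref]}{n}*"
        elif aa_ref == "*":
            cls, hgvs_p = "stop_lost", f"p.*{n}{AA3[aa_alt]}ext*?"
        else:
            cls, hgvs_p = "missense", f"p.{AA3[aa_ref]}{n}{AA3[aa_alt]}"
        return dc_replace(call, hgvs_c=hgvs_c, hgvs_p=hgvs_p, classification=cls)

    # deletion inside the CDS
    L = len(ref)
    c2 = c1 + L - 1
    hgvs_c = f"c.{c1}del{ref}" if L == 1 else f"c.{c1}_{c2}del{ref}"
    ref_prot = _translate(seq[cs:ce])
    mut = seq[:pos] + seq[pos + L:]

    if L % 3 != 0:
        mut_prot = _translate(mut[cs:])
        i = _first_difference(ref_prot, mut_prot)
        if i is None:
            return dc_replace(call, position=pos, ref=ref, hgvs_c=hgvs_c,
                              hgvs_p="p.(=)", classification="frameshift")
        n = i + 1
        aa_ref = ref_prot[i] if i < len(ref_prot) else "*"
        aa_new = mut_prot[i] if i < len(mut_prot) else None
        if aa_new is None:
            hgvs_p = f"p.{AA3[aa_ref]}{n}fs*?"
        elif aa_new == "*":
            hgvs_p = f"p.{AA3[aa_ref]}{n}*"
        else:
            stop = mut_prot.find("*", i)
            fs = f"*{stop - i + 1}" if stop != -1 else "*?"
            hgvs_p = f"p.{AA3[aa_ref]}{n}{AA3[aa_new]}fs{fs}"
        return dc_replace(call, position=pos, ref=ref, hgvs_c=hgvs_c,
                          hgvs_p=hgvs_p, classification="frameshift")

    # in-frame deletion: express as residue-level del / delins
    mut_prot = _translate(mut[cs:ce - L])
    p = 0
    while p < len(mut_prot) and p < len(ref_prot) and ref_prot[p] == mut_prot[p]:
        p += 1
    s = 0
    while (s < len(mut_prot) - p and s < len(ref_prot) - p
           and ref_prot[len(ref_prot) - 1 - s] == mut_prot[len(mut_prot) - 1 - s]):
        s += 1
    lost = ref_prot[p:len(ref_prot) - s]
    gained = mut_prot[p:len(mut_prot) - s]
    if not lost:
        hgvs_p = "p.(=)"
    else:
        first, last = p + 1, len(ref_prot) - s
        span = (f"{AA3[lost[0]]}{first}" if first == last
                else f"{AA3[lost[0]]}{first}_{AA3[lost[-1]]}{last}")
        hgvs_p = f"p.{span}del" if not gained else f"p.{span}delins{_aa3(gained)}"
    return dc_replace(call, position=pos, ref=ref, hgvs_c=hgvs_c,
                      hgvs_p=hgvs_p, classification="inframe_deletion")


def _first_difference(a: str, b: str) -> int | None:
    for i in range(min(len(a), len(b))):
        if a[i] != b[i]:
            return i
    return min(len(a), len(b)) if len(a) != len(b) else None


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["transcript_id", "nuc_change", "coverage", "aa_change",
                  "hgvs_c", "hgvs_p", "classification", "filter"]


def write_variant_report(calls: list[VariantCall], path) -> None:
    """Tabular variant report, one row per call."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for c in calls:
            nuc = f"del{c.ref}" if c.is_deletion else f"{c.ref}>{c.alt}"
            fh.write("\t".join([
                c.transcript_id, nuc, c.coverage_string(),
                c.hgvs_p or ".", c.hgvs_c, c.hgvs_p or ".",
                c.classification or ".", c.filter,
            ]) + "\n")


def write_vcf(calls: list[VariantCall], transcripts: dict[str, TranscriptModel],
              path) -> None:
    """Minimal VCF with transcript-space coordinates (not genomic).

    Deletions use the standard VCF anchored representation (POS is the base
    before the deletion).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##reference=transcript-space; CHROM is a transcript_id, "
                 "POS is a 1-based transcript coordinate, not genomic\n")
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">\n')
        fh.write('##INFO=<ID=SF,Number=1,Type=Integer,Description="Forward unique-read support">\n')
        fh.write('##INFO=<ID=SR,Number=1,Type=Integer,Description="Reverse unique-read support">\n')
        for tid in sorted({c.transcript_id for c in calls}):
            fh.write(f"##contig=<ID={tid},length={len(transcripts[tid])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.transcript_id, c.position)):
            if c.is_deletion:
                seq = transcripts[c.transcript_id].sequence
                anchor_pos = c.position - 1
                anchor = seq[anchor_pos] if anchor_pos >= 0 else "N"
                pos, ref, alt = anchor_pos + 1, anchor + c.ref, anchor
            else:
                pos, ref, alt = c.position + 1, c.ref, c.alt
            info = f"VAF={c.vaf:.4f};SF={c.support_fwd};SR={c.support_rev}"
            fh.write(f"{c.transcript_id}\t{pos}\t.\t{ref}\t{alt}\t.\t{c.filter}\t{info}\n")


def load_vhl_cds_synthetic() -> TranscriptModel:
    """The repository's synthetic VHL-like coding sequence.

    A constructed stand-in (not the RefSeq sequence) whose CDS reproduces
    the canonical worked example of this assay's variant annotation: the
    dinucleotide deletion c.246_247delCG is 3'-unambiguous and frameshifts
    at Val83 into a novel Arg with a new stop 48 codons downstream.
    """
    from Bio import SeqIO
    rec = next(SeqIO.parse(str(data_path("vhl_cds_synthetic.fa")), "fasta"))
    seq = str(rec.seq).upper()
    return TranscriptModel(
        transcript_id="VHL_SYNTHETIC",
        gene_symbol="VHL",
        sequence=seq,
        exon_ends=(len(seq),),
        cds_start=0,
        cds_end=len(seq),
    )
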