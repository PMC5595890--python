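"""smMIP panel design against transcript models.

A probe consists of an extension arm (>= 16 nt) and a ligation arm
(>= 18 nt) that hybridize to the antisense strand of the cDNA, leaving a
112-nt gap which is enzymatically filled and ligated.  Arms are joined by a
constant 40-nt backbone carrying an 8-nt UMI next to the ligation arm.
Candidates are enumerated along the transcript at a configurable stride,
scored with a transparent GC/homopolymer score, and selected either for even
spacing across the coding region (default, 5-10 probes per transcript) or to
tile the full CDS.  Placing the two arms on adjacent exons is preferred where
possible, so probes cannot capture contaminating genomic DNA (an intervening
intron breaks arm adjacency).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, asdict, replace

import pandas as pd

from .models import Panel, SmMIP, TranscriptModel, revcomp, data_path

#: Constant linker joining the two arms; carries the PCR primer sites.
#: A fixed repository convention (any 40-mer without extreme composition
#: works; the physical probe's backbone is a reagent, not data).
BACKBONE = "ATCAGGTGACGTCGAGTCCTAAGGCACTGCAGTTCGACAT"
assert len(BACKBONE) == 40

UMI_LENGTH = 8


@dataclass(frozen=True)
class DesignParams:
    """Tunable knobs of panel design.

    gap_length is fixed by the assay chemistry; arm minima follow the probe
    architecture.  Arm maxima, GC window and stride are design choices with
    documented defaults.
    """

    gap_length: int = 112
    ext_min: int = 16
    ext_max: int = 30
    lig_min: int = 18
    lig_max: int = 30
    gc_min: float = 0.2
    gc_max: float = 0.8
    stride: int = 10
    n_per_transcript: int = 5
    max_per_transcript: int = 10
    #: distance credit (nt) given to junction-spanning candidates during
    #: selection; a soft preference, not a hard filter
    junction_bonus: float = 10.0
    backbone: str = BACKBONE

    def __post_init__(self):
        if self.n_per_transcript < 1:
            raise ValueError("n_per_transcript must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.ext_min < 16 or self.lig_min < 18:
            raise ValueError("arm minima below assay architecture (16/18 nt)")


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def score_candidate(candidate: SmMIP, params: DesignParams = DesignParams()) -> float:
    """Transparent arm-quality score in [0, 1].

    Multiplicative penalties per arm: GC outside [gc_min, gc_max] is
    penalized linearly in its distance from the window; homopolymer runs of
    6 nt or more are penalized linearly in the excess run length.  Arms
    containing N score 0.  Deterministic; rounded to 6 decimals so the score
    survives TSV round-trips exactly.
    """
    score = 1.0
    for arm in (candidate.ext_arm, candidate.lig_arm):
        if "N" in arm:
            return 0.0
        gc = _gc_fraction(arm)
        excess = max(0.0, params.gc_min - gc, gc - params.gc_max)
        score *= max(0.0, 1.0 - 2.0 * excess)
        run = _max_homopolymer(arm)
        if run >= 6:
            score *= max(0.0, 1.0 - 0.25 * (run - 5))
    return round(score, 6)


def _pick_arm_length(seq: str, start: int, end_options, extract, params: DesignParams):
    """Shortest arm length whose target GC falls inside the window; falls
    back to the minimum length (the score then carries the penalty)."""
    for length in end_options:
        target = extract(length)
        if target is None:
            break
        if params.gc_min <= _gc_fraction(target) <= params.gc_max:
            return length, target
    length = end_options[0]
    return length, extract(length)


def enumerate_candidates(
    transcript: TranscriptModel, params: DesignParams = DesignParams()
) -> list[SmMIP]:
    """All admissible smMIP candidates on one transcript at the configured stride.

    Returns an empty list (not an exception) when no gap window fits.  Arm
    lengths are chosen per window as the shortest length whose target GC lies
    in the configured window.  Candidate ids are provisional
    (``GENE@gap_start``); :func:`select_panel` assigns final ordinals.
    """
    seq = transcript.sequence
    n = len(seq)
    gap = params.gap_length
    out: list[SmMIP] = []
    if n < params.ext_min + gap + params.lig_min:
        return out
    first = params.ext_min
    last = n - gap - params.lig_min  # inclusive
    for gs in range(first, last + 1, params.stride):
        ge = gs + gap
        ext_len, ext_target = _pick_arm_length(
            seq, gs,
            list(range(params.ext_min, min(params.ext_max, gs) + 1)),
            lambda L: seq[gs - L:gs] if L <= gs else None,
            params,
        )
        lig_len, lig_target = _pick_arm_length(
            seq, ge,
            list(range(params.lig_min, min(params.lig_max, n - ge) + 1)),
            lambda L: seq[ge:ge + L] if ge + L <= n else None,
            params,
        )
        spans = transcript.exon_index(gs - ext_len) != transcript.exon_index(ge + lig_len - 1)
        cand = SmMIP(
            smmip_id=f"{transcript.gene_symbol}@{gs}",
            transcript_id=transcript.transcript_id,
            ext_arm=revcomp(ext_target),
            lig_arm=revcomp(lig_target),
            gap_start=gs,
            gap_end=ge,
            backbone=params.backbone,
            umi_length=UMI_LENGTH,
            spans_junction=spans,
        )
        out.append(replace(cand, score=score_candidate(cand, params)))
    return out


def _midpoint(m: SmMIP) -> float:
    return (m.gap_start + m.gap_end) / 2.0


def _select_even(
    candidates: list[SmMIP],
    transcript: TranscriptModel,
    params: DesignParams,
) -> list[SmMIP]:
    """Greedy pick of n candidates whose gap midpoints best match an ideal
    even grid over the CDS.  Junction-spanning candidates receive a distance
    credit; ties break by score, then gap_start, then id."""
    n = min(params.n_per_transcript, len(candidates))
    span = transcript.cds_end - transcript.cds_start
    ideal = [transcript.cds_start + (k + 0.5) * span / n for k in range(n)]
    remaining = sorted(candidates, key=lambda m: (m.gap_start, m.smmip_id))
    chosen: list[SmMIP] = []
    for target in ideal:
        best = min(
            remaining,
            key=lambda m: (
                abs(_midpoint(m) - target) - (params.junction_bonus if m.spans_junction else 0.0),
                -m.score,
                m.gap_start,
                m.smmip_id,
            ),
        )
        chosen.append(best)
        remaining.remove(best)

    # soft junction preference: guarantee one junction-spanning probe when
    # any candidate allows it
    if len(transcript.exon_ends) > 1 and not any(m.spans_junction for m in chosen):
        junction = [m for m in candidates if m.spans_junction]
        if junction:
            best_j = min(
                junction,
                key=lambda m: (
                    min(abs(_midpoint(m) - t) for t in ideal),
                    -m.score,
                    m.gap_start,
                    m.smmip_id,
                ),
            )
            slot = min(range(len(ideal)), key=lambda k: abs(ideal[k] - _midpoint(best_j)))
            chosen[slot] = best_j

    return sorted(chosen, key=lambda m: m.gap_start)


def _select_full_coverage(
    candidates: list[SmMIP], transcript: TranscriptModel
) -> tuple[list[SmMIP], bool]:
    """Greedy interval cover of the CDS by gap intervals.

    Returns (selection, fully_covered).
    """
    cds_start, cds_end = transcript.cds_start, transcript.cds_end
    cands = sorted(candidates, key=lambda m: (m.gap_start, -m.score, m.smmip_id))
    chosen: list[SmMIP] = []
    pos = cds_start
    covered = True
    i = 0
    while pos < cds_end:
        best = None
        while i < len(cands) and cands[i].gap_start <= pos:
            if best is None or cands[i].gap_end > best.gap_end:
                best = cands[i]
            i += 1
        if best is None or best.gap_end <= pos:
            # hole: jump to the next candidate that starts beyond pos
            nxt = next((c for c in cands if c.gap_start > pos), None)
            covered = False
            if nxt is None:
                break
            pos = nxt.gap_start
            i = cands.index(nxt)
            continue
        chosen.append(best)
        pos = best.gap_end
    return sorted(set(chosen), key=lambda m: m.gap_start), covered


def select_panel(
    candidates_by_transcript: dict[str, list[SmMIP]],
    transcripts: dict[str, TranscriptModel],
    params: DesignParams = DesignParams(),
    full_coverage: set[str] | None = None,
) -> Panel:
    """Assemble a panel from per-transcript candidate lists.

    Default mode picks ``params.n_per_transcript`` probes per transcript
    maximizing even spacing of gap midpoints across the CDS.  Transcripts in
    ``full_coverage`` are instead tiled so the union of gaps covers the whole
    CDS where candidates allow.  Transcripts ending up with fewer than 5
    probes, or with uncovered CDS in full-coverage mode, are listed in
    ``Panel.under_covered``.  Deterministic for identical inputs.
    """
    full_coverage = full_coverage or set()
    smmips: list[SmMIP] = []
    under: list[str] = []
    for tid in sorted(candidates_by_transcript):
        cands = candidates_by_transcript[tid]
        transcript = transcripts[tid]
        if not cands:
            under.append(tid)
            continue
        if tid in full_coverage:
            chosen, covered = _select_full_coverage(cands, transcript)
            if not covered or len(chosen) < 5:
                under.append(tid)
        else:
            chosen = _select_even(cands, transcript, params)
            if len(chosen) < 5:
                under.append(tid)
        for k, m in enumerate(chosen, start=1):
            smmips.append(replace(m, smmip_id=f"{transcript.gene_symbol}_{k}"))
    return Panel(
        smmips=smmips,
        design_params={k: v for k, v in asdict(params).items()},
        under_covered=under,
    )


def design_panel(
    transcripts: dict[str, TranscriptModel],
    params: DesignParams = DesignParams(),
    full_coverage: set[str] | None = None,
) -> Panel:
    """Enumerate + select in one call."""
    cands = {tid: enumerate_candidates(t, params) for tid, t in transcripts.items()}
    return select_panel(cands, transcripts, params, full_coverage)


# ---------------------------------------------------------------------------
# Panel serialization (TSV) and BED export
# ---------------------------------------------------------------------------

PANEL_COLUMNS = [
    "smmip_id", "transcript_id", "ext_arm", "lig_arm",
    "gap_start", "gap_end", "backbone", "umi_length", "spans_junction", "score",
]


def write_panel(panel: Panel, path) -> None:
    """Serialize a panel as a TSV with the documented header."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PANEL_COLUMNS)
        for m in panel.smmips:
            w.writerow([
                m.smmip_id, m.transcript_id, m.ext_arm, m.lig_arm,
                m.gap_start, m.gap_end, m.backbone, m.umi_length,
                int(m.spans_junction), f"{m.score:.6f}",
            ])


def read_panel(path) -> Panel:
    """Parse a panel TSV; malformed rows raise with their line number."""
    smmips: list[SmMIP] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PANEL_COLUMNS:
            raise ValueError(f"{path}:1: unexpected panel header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(PANEL_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(PANEL_COLUMNS)} fields, got {len(fields)}"
                )
            try:
                smmips.append(SmMIP(
                    smmip_id=fields[0],
                    transcript_id=fields[1],
                    ext_arm=fields[2],
                    lig_arm=fields[3],
                    gap_start=int(fields[4]),
                    gap_end=int(fields[5]),
                    backbone=fields[6],
                    umi_length=int(fields[7]),
                    spans_junction=bool(int(fields[8])),
                    score=float(fields[9]),
                ))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed panel row: {exc}") from exc
    return Panel(smmips=smmips)


def write_gap_bed(panel: Panel, path) -> None:
    """Export gap intervals as BED (transcript-space coordinates)."""
    with open(path, "w") as fh:
        for m in panel.smmips:
            fh.write(f"{m.transcript_id}\t{m.gap_start}\t{m.gap_end}\t{m.smmip_id}\t"
                     f"{int(round(m.score * 1000))}\t+\n")


def load_panel_targets() -> pd.DataFrame:
    """The repository's metabolic target list (gene symbol, transcript id,
    full-coverage flag): 104 transcripts encoding metabolic enzymes, of which
    18 are designated for full-CDS tiling."""
    return pd.read_csv(data_path("metabolic_panel_targets.tsv"), sep="\t",
                       dtype={"gene_symbol": str, "transcript_id": str, "full_coverage": int})
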