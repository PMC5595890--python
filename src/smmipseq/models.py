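"""Core domain objects shared across the pipeline.

Coordinates are 0-based, half-open transcript coordinates throughout the
library; 1-based numbering appears only in HGVS output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from bisect import bisect_right
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced mRNA with its exon structure and coding region.

    Parameters
    ----------
    transcript_id : str
        Identifier (RefSeq-style, e.g. ``NM_198156.2``).
    gene_symbol : str
        HGNC-style gene symbol.
    sequence : str
        Spliced mRNA sequence, sense strand, alphabet A/C/G/T.
    exon_ends : tuple of int
        Strictly increasing transcript offsets of exon 3' boundaries; the
        last entry equals ``len(sequence)``.  A single-exon transcript has
        one entry.
    cds_start, cds_end : int
        Coding region as a 0-based half-open interval; the CDS length must
        be a multiple of 3.
    """

    transcript_id: str
    gene_symbol: str
    sequence: str
    exon_ends: tuple[int, ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "exon_ends", tuple(int(e) for e in self.exon_ends))
        if set(seq) - set("ACGT"):
            raise ValueError(
                f"{self.transcript_id}: sequence alphabet must be A/C/G/T"
            )
        ends = self.exon_ends
        if not ends or list(ends) != sorted(set(ends)):
            raise ValueError(f"{self.transcript_id}: exon_ends must be strictly increasing")
        if ends[-1] != len(seq):
            raise ValueError(
                f"{self.transcript_id}: last exon end ({ends[-1]}) must equal "
                f"sequence length ({len(seq)})"
            )
        if not (0 <= self.cds_start < self.cds_end <= len(seq)):
            raise ValueError(f"{self.transcript_id}: CDS interval out of bounds")
        if (self.cds_end - self.cds_start) % 3:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start:self.cds_end]

    def exon_index(self, pos: int) -> int:
        """0-based index of the exon containing transcript position ``pos``."""
        if not 0 <= pos < len(self.sequence):
            raise IndexError(f"position {pos} outside transcript")
        return bisect_right(self.exon_ends, pos)

    def protein(self) -> str:
        """Translation of the CDS (standard code), including terminal ``*``."""
        return str(Seq(self.cds).translate())


@dataclass(frozen=True)
class SmMIP:
    """One single-molecule molecular inversion probe.

    The two arms hybridize to the antisense strand of the cDNA, flanking a
    112-nt gap that is filled and ligated.  ``ext_arm``/``lig_arm`` store the
    probe (antisense) sequences; ``ext_target``/``lig_target`` give the sense
    transcript regions they pair with, so

    ``ext_target + transcript[gap_start:gap_end] + lig_target``

    is the contiguous transcript substring the probe was designed on.
    """

    smmip_id: str
    transcript_id: str
    ext_arm: str
    lig_arm: str
    gap_start: int
    gap_end: int
    backbone: str
    umi_length: int = 8
    spans_junction: bool = False
    score: float = 1.0

    GAP_LENGTH = 112
    EXT_MIN = 16
    LIG_MIN = 18
    BACKBONE_LENGTH = 40

    def __post_init__(self):
        if self.gap_end - self.gap_start != self.GAP_LENGTH:
            raise ValueError(
                f"{self.smmip_id}: gap length must be {self.GAP_LENGTH}, "
                f"got {self.gap_end - self.gap_start}"
            )
        if len(self.ext_arm) < self.EXT_MIN:
            raise ValueError(f"{self.smmip_id}: extension arm shorter than {self.EXT_MIN} nt")
        if len(self.lig_arm) < self.LIG_MIN:
            raise ValueError(f"{self.smmip_id}: ligation arm shorter than {self.LIG_MIN} nt")
        if len(self.backbone) != self.BACKBONE_LENGTH:
            raise ValueError(f"{self.smmip_id}: backbone must be {self.BACKBONE_LENGTH} nt")
        if self.umi_length != 8:
            raise ValueError(f"{self.smmip_id}: UMI length must be 8")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"{self.smmip_id}: score outside [0, 1]")

    @property
    def ext_target(self) -> str:
        """Sense-strand transcript region paired by the extension arm."""
        return revcomp(self.ext_arm)

    @property
    def lig_target(self) -> str:
        """Sense-strand transcript region paired by the ligation arm."""
        return revcomp(self.lig_arm)

    @property
    def ext_len(self) -> int:
        return len(self.ext_arm)

    @property
    def lig_len(self) -> int:
        return len(self.lig_arm)

    def target_span(self) -> tuple[int, int]:
        """Transcript interval covered by arms plus gap (half-open)."""
        return self.gap_start - self.ext_len, self.gap_end + self.lig_len


@dataclass
class Panel:
    """A designed set of smMIPs plus the parameters used to design it."""

    smmips: list[SmMIP]
    design_params: dict = field(default_factory=dict)
    under_covered: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [m.smmip_id for m in self.smmips]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate smmip_ids in panel: {dup}")

    def __len__(self) -> int:
        return len(self.smmips)

    def __iter__(self):
        return iter(self.smmips)

    def by_id(self) -> dict[str, SmMIP]:
        return {m.smmip_id: m for m in self.smmips}

    def by_transcript(self) -> dict[str, list[SmMIP]]:
        out: dict[str, list[SmMIP]] = {}
        for m in self.smmips:
            out.setdefault(m.transcript_id, []).append(m)
        return out


@dataclass
class UniqueObservation:
    """One deduplicated captured molecule.

    ``consensus_gap`` is the per-position majority consensus over every mate
    observation in the (smMIP, UMI) family.  Its length is 112 minus the
    length of any template deletion (the capture arms pin both flanks, so a
    deletion shortens the gap fill).  ``covered_by_mate1/2`` are per-position
    masks in consensus coordinates: mate 1 reads the gap from the extension
    arm and always covers it fully; mate 2 enters through barcode, backbone,
    UMI and ligation arm and covers only the 3' portion.
    """

    smmip_id: str
    umi: str
    consensus_gap: str
    n_read_pairs: int
    covered_by_mate1: tuple[bool, ...]
    covered_by_mate2: tuple[bool, ...]

    def __post_init__(self):
        if len(self.umi) != 8:
            raise ValueError("UMI must be 8 nt")
        if self.n_read_pairs < 1:
            raise ValueError("n_read_pairs must be >= 1")
        if not (len(self.consensus_gap) == len(self.covered_by_mate1) == len(self.covered_by_mate2)):
            raise ValueError("coverage masks must match consensus length")


# ---------------------------------------------------------------------------
# Transcript model I/O: FASTA + sidecar TSV
# ---------------------------------------------------------------------------

_META_COLUMNS = ["transcript_id", "gene_symbol", "exon_ends", "cds_start", "cds_end"]


def write_transcripts(transcripts: Iterable[TranscriptModel], fasta_path, meta_path) -> None:
    """Write transcript models as FASTA plus a sidecar TSV."""
    transcripts = list(transcripts)
    with open(fasta_path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id} {t.gene_symbol}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i:i + 70] + "\n")
    with open(meta_path, "w") as fh:
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for t in transcripts:
            ends = ",".join(str(e) for e in t.exon_ends)
            fh.write(f"{t.transcript_id}\t{t.gene_symbol}\t{ends}\t{t.cds_start}\t{t.cds_end}\n")


def read_transcripts(fasta_path, meta_path) -> dict[str, TranscriptModel]:
    """Load transcript models from FASTA + sidecar TSV.

    Returns a dict keyed by transcript_id, in file order.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out: dict[str, TranscriptModel] = {}
    with open(meta_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _META_COLUMNS:
            raise ValueError(f"{meta_path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(f"{meta_path}:{lineno}: expected 5 fields, got {len(fields)}")
            tid, gene, ends_s, cs, ce = fields
            if tid not in seqs:
                raise ValueError(f"{meta_path}:{lineno}: transcript {tid} missing from FASTA")
            out[tid] = TranscriptModel(
                transcript_id=tid,
                gene_symbol=gene,
                sequence=seqs[tid],
                exon_ends=tuple(int(x) for x in ends_s.split(",")),
                cds_start=int(cs),
                cds_end=int(ce),
            )
    return out


def data_path(name: str) -> Path:
    """Path to a file shipped in ``smmipseq/data``."""
    return Path(__file__).parent / "data" / name
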