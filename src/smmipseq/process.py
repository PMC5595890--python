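"""From paired FASTQ to per-smMIP unique molecules.

Three stages, mirroring the assay's read structure: barcode demultiplexing
(the 8-nt sample barcode is the last segment of the insert, so it is the
first 8 nt of read 2, reverse-complemented), probe assignment by positional
arm matching with a Hamming tolerance, and PCR-duplicate collapse on the
(smMIP, UMI) pair with a per-position majority consensus over both mates.

Positions in read 2 under the amplicon dialect (see :mod:`smmipseq.simulate`):
``[0:8)`` barcode, ``[8:48)`` backbone, ``[48:56)`` UMI, ``[56:56+lig)``
ligation-arm target, remainder gap fill — all reverse-complemented.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .models import Panel, SmMIP, UniqueObservation, revcomp

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"
READ_LENGTH = 151
_R2_UMI = slice(48, 56)
_R2_LIG_OFFSET = 56
MAX_DELETION = 20


def read_fastq_pairs(r1_path, r2_path):
    """Iterate (name, seq1, qual1, seq2, qual2) from a FASTQ pair (gzip ok)."""
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for rec1, rec2 in zip(f1, f2):
            yield rec1.name, rec1.sequence.upper(), rec1.quality, \
                rec2.sequence.upper(), rec2.quality


def _hamming(a: str, b: str, cutoff: int) -> int:
    """Hamming distance with early exit; returns cutoff+1 once exceeded."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > cutoff:
                return d
    return d


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def validate_barcodes(barcode_map: dict[str, str], max_mismatch: int = 1) -> None:
    """Barcodes must be pairwise separable at the configured tolerance."""
    items = sorted(barcode_map.items())
    for sid, bc in items:
        if len(bc) != 8 or set(bc) - set("ACGT"):
            raise ValueError(f"sample {sid}: barcode must be an 8-nt A/C/G/T string")
    for i, (sa, a) in enumerate(items):
        for sb, b in items[i + 1:]:
            if _hamming(a, b, 2 * max_mismatch) <= 2 * max_mismatch:
                raise ValueError(
                    f"barcodes for {sa} and {sb} are within Hamming distance "
                    f"{2 * max_mismatch}; demultiplexing would be ambiguous"
                )


def assign_barcode(read2: str, barcode_map: dict[str, str], max_mismatch: int = 1) -> str:
    """Sample id for a read pair, or UNASSIGNED."""
    observed = revcomp(read2[:8])
    for sid, bc in barcode_map.items():
        if _hamming(observed, bc, max_mismatch) <= max_mismatch:
            return sid
    return UNASSIGNED


def demultiplex(pairs, barcode_map: dict[str, str], max_mismatch: int = 1):
    """Split read pairs by sample barcode.

    ``pairs`` yields (name, seq1, qual1, seq2, qual2).  Returns a dict
    mapping sample_id (plus UNASSIGNED) to lists of pairs; counts are
    conserved.
    """
    validate_barcodes(barcode_map, max_mismatch)
    out: dict[str, list] = {sid: [] for sid in barcode_map}
    out[UNASSIGNED] = []
    for pair in pairs:
        out[assign_barcode(pair[3], barcode_map, max_mismatch)].append(pair)
    return out


# ---------------------------------------------------------------------------
# smMIP assignment
# ---------------------------------------------------------------------------

class PanelIndex:
    """Panel indexed for positional arm matching.

    For each probe we precompute the sense extension-arm target (expected at
    the start of read 1) and the reverse-complemented ligation-arm target
    (expected at read-2 offset 56).  An exact-match dictionary on the 16-nt
    read-1 prefix serves as a fast path; reads with errors in that prefix
    fall back to a full scan with early-exit Hamming distances.
    """

    def __init__(self, panel: Panel):
        self.smmips = list(panel.smmips)
        self.entries = [
            (m, m.ext_target, revcomp(m.lig_target)) for m in self.smmips
        ]
        self.by_prefix: dict[str, list[tuple[SmMIP, str, str]]] = defaultdict(list)
        for entry in self.entries:
            self.by_prefix[entry[1][:16]].append(entry)


def _arm_distance(read1: str, read2: str, entry, cutoff: int):
    m, ext_t, lig_rc = entry
    d_ext = _hamming(read1[:len(ext_t)], ext_t, cutoff)
    if d_ext > cutoff:
        return None
    d_lig = _hamming(read2[_R2_LIG_OFFSET:_R2_LIG_OFFSET + len(lig_rc)], lig_rc, cutoff)
    if d_lig > cutoff:
        return None
    return d_ext + d_lig


def match_smmip(read1: str, read2: str, index: PanelIndex,
                max_arm_mismatch: int = 1) -> str:
    """Assign a read pair to a probe, or UNASSIGNED.

    Both arm images must match at their expected positions within
    ``max_arm_mismatch`` each; if two probes tie at the best total distance
    the pair is UNASSIGNED.
    """
    best_id, best_d, tie = UNASSIGNED, None, False
    bucket = index.by_prefix.get(read1[:16])
    if bucket:
        for entry in bucket:
            d = _arm_distance(read1, read2, entry, max_arm_mismatch)
            if d is None:
                continue
            if best_d is None or d < best_d:
                best_id, best_d, tie = entry[0].smmip_id, d, False
            elif d == best_d:
                tie = True
        if best_d == 0:
            return UNASSIGNED if tie else best_id
    # slow path: errors in the read-1 prefix, or no exact-prefix hit
    best_id, best_d, tie = UNASSIGNED, None, False
    for entry in index.entries:
        d = _arm_distance(read1, read2, entry, max_arm_mismatch)
        if d is None:
            continue
        if best_d is None or d < best_d:
            best_id, best_d, tie = entry[0].smmip_id, d, False
        elif d == best_d:
            tie = True
    return UNASSIGNED if tie or best_d is None else best_id


# ---------------------------------------------------------------------------
# Per-pair gap observation extraction
# ---------------------------------------------------------------------------

@dataclass
class ReadPairRecord:
    """One assigned read pair with its gap observations.

    ``gap_obs_1``/``gap_obs_2`` are in gap-fill coordinates (length
    112 - deletion); uncovered positions are ``N``.  Mate 1 always covers
    the whole gap fill; mate 2 covers its 3' tail.
    """

    name: str
    sample_id: str
    smmip_id: str
    umi: str
    gap_obs_1: str
    gap_obs_2: str
    gap_qual_1: tuple[int, ...]
    gap_qual_2: tuple[int, ...]


def infer_deletion_length(read1: str, read2: str, smmip: SmMIP,
                          max_deletion: int = MAX_DELETION) -> int:
    """Template deletion length from mate-overlap agreement.

    The insert length is 178 + ext + lig - d; sliding read 2 against read 1
    at each candidate d and counting overlap mismatches identifies d (exact
    for error-free reads; substitution errors leave the minimum at the true
    offset).  Ties resolve to the smallest d.
    """
    rc2 = revcomp(read2)
    best_d, best_mm = 0, None
    for d in range(0, max_deletion + 1):
        insert_len = smmip.ext_len + (SmMIP.GAP_LENGTH - d) + smmip.lig_len + 56
        s = insert_len - READ_LENGTH  # mate-2 start in mate-1 coordinates
        if s < 0 or s >= READ_LENGTH:
            continue
        mm = sum(1 for a, b in zip(read1[s:], rc2) if a != b)
        if best_mm is None or mm < best_mm:
            best_d, best_mm = d, mm
            if d == 0 and mm <= max(2, (READ_LENGTH - s) // 20):
                return 0  # fast path: overwhelmingly the common case
    return best_d


def extract_record(name: str, sample_id: str, read1: str, qual1: str,
                   read2: str, qual2: str, smmip: SmMIP) -> ReadPairRecord:
    """Slice UMI and per-mate gap observations out of an assigned pair."""
    d = infer_deletion_length(read1, read2, smmip)
    gf_len = SmMIP.GAP_LENGTH - d
    umi = revcomp(read2[_R2_UMI])
    ext = smmip.ext_len
    obs1 = read1[ext:ext + gf_len]
    q1 = tuple(ord(c) - 33 for c in qual1[ext:ext + gf_len])
    m2 = min(gf_len, READ_LENGTH - _R2_LIG_OFFSET - smmip.lig_len)
    start2 = _R2_LIG_OFFSET + smmip.lig_len
    obs2 = "N" * (gf_len - m2) + revcomp(read2[start2:start2 + m2])
    q2 = (0,) * (gf_len - m2) + tuple(
        ord(c) - 33 for c in reversed(qual2[start2:start2 + m2]))
    return ReadPairRecord(
        name=name, sample_id=sample_id, smmip_id=smmip.smmip_id, umi=umi,
        gap_obs_1=obs1, gap_obs_2=obs2, gap_qual_1=q1, gap_qual_2=q2,
    )


# ---------------------------------------------------------------------------
# UMI collapse
# ---------------------------------------------------------------------------

def _consensus(records: list[ReadPairRecord]) -> UniqueObservation:
    # a (smMIP, UMI) family descends from one molecule; all its members share
    # the gap-fill length except for misinferred deletion lengths, which are
    # excluded from voting by majority length
    lengths = [len(r.gap_obs_1) for r in records]
    gf_len = max(set(lengths), key=lambda L: (lengths.count(L), -L))
    voting = [r for r in records if len(r.gap_obs_1) == gf_len]

    obs1 = [r.gap_obs_1 for r in voting]
    obs2 = [r.gap_obs_2 for r in voting]
    if len(set(obs1)) == 1 and all(
        o2[i] in ("N", obs1[0][i]) for o2 in set(obs2) for i in range(gf_len)
    ):
        consensus = obs1[0]
    else:
        chars = []
        for i in range(gf_len):
            votes: dict[str, list[float]] = {}
            for r in voting:
                b1 = r.gap_obs_1[i]
                if b1 != "N":
                    votes.setdefault(b1, [0, 0.0])
                    votes[b1][0] += 1
                    votes[b1][1] += r.gap_qual_1[i]
                b2 = r.gap_obs_2[i]
                if b2 != "N":
                    votes.setdefault(b2, [0, 0.0])
                    votes[b2][0] += 1
                    votes[b2][1] += r.gap_qual_2[i]
            if not votes:
                chars.append("N")
                continue
            # majority vote; ties by summed base quality, then alphabetically
            chars.append(min(votes, key=lambda b: (-votes[b][0], -votes[b][1], b)))
        consensus = "".join(chars)

    cov1 = tuple(any(r.gap_obs_1[i] != "N" for r in voting) for i in range(gf_len))
    cov2 = tuple(any(r.gap_obs_2[i] != "N" for r in voting) for i in range(gf_len))
    return UniqueObservation(
        smmip_id=records[0].smmip_id,
        umi=records[0].umi,
        consensus_gap=consensus,
        n_read_pairs=len(records),
        covered_by_mate1=cov1,
        covered_by_mate2=cov2,
    )


def collapse_umis(records: list[ReadPairRecord]) -> list[UniqueObservation]:
    """Collapse PCR duplicates: one consensus molecule per (smMIP, UMI).

    UMI grouping is exact-match on the 8-mer.  Idempotent: collapsing
    already-unique families changes nothing.
    """
    groups: dict[tuple[str, str], list[ReadPairRecord]] = defaultdict(list)
    for r in records:
        groups[(r.smmip_id, r.umi)].append(r)
    return [_consensus(groups[k]) for k in sorted(groups)]


# ---------------------------------------------------------------------------
# Counting and the end-to-end pipeline
# ---------------------------------------------------------------------------

def count_table(observations_by_sample: dict[str, list[UniqueObservation]],
                panel: Panel) -> pd.DataFrame:
    """Unique-molecule counts: rows = smMIPs (panel order), columns = samples.

    smMIPs with no observations appear as zero rows; an observation naming a
    probe absent from the panel raises.
    """
    known = {m.smmip_id for m in panel.smmips}
    samples = sorted(observations_by_sample)
    table = pd.DataFrame(0, index=[m.smmip_id for m in panel.smmips],
                         columns=samples, dtype=int)
    for sid in samples:
        for obs in observations_by_sample[sid]:
            if obs.smmip_id not in known:
                raise KeyError(f"observation references unknown smMIP {obs.smmip_id}")
            table.loc[obs.smmip_id, sid] += 1
    table.index.name = "smmip_id"
    return table


@dataclass
class ProcessResult:
    counts: pd.DataFrame
    observations: dict[str, list[UniqueObservation]]
    stats: dict[str, int] = field(default_factory=dict)


def process_pairs(pairs, panel: Panel, barcode_map: dict[str, str],
                  max_mismatch: int = 1, max_arm_mismatch: int = 1) -> ProcessResult:
    """Demultiplex, assign, and collapse an in-memory stream of read pairs."""
    validate_barcodes(barcode_map, max_mismatch)
    index = PanelIndex(panel)
    by_id = panel.by_id()
    by_sample: dict[str, list[ReadPairRecord]] = {sid: [] for sid in barcode_map}
    n_total = n_nobc = n_nomip = 0
    for name, s1, q1, s2, q2 in pairs:
        n_total += 1
        sid = assign_barcode(s2, barcode_map, max_mismatch)
        if sid == UNASSIGNED:
            n_nobc += 1
            continue
        mid = match_smmip(s1, s2, index, max_arm_mismatch)
        if mid == UNASSIGNED:
            n_nomip += 1
            continue
        by_sample[sid].append(
            extract_record(name, sid, s1, q1, s2, q2, by_id[mid]))
    observations = {sid: collapse_umis(recs) for sid, recs in by_sample.items()}
    stats = {
        "total_pairs": n_total,
        "unassigned_barcode": n_nobc,
        "unassigned_smmip": n_nomip,
        "assigned_pairs": n_total - n_nobc - n_nomip,
        "unique_molecules": sum(len(o) for o in observations.values()),
    }
    logger.info("processed %(total_pairs)d pairs: %(assigned_pairs)d assigned, "
                "%(unassigned_barcode)d no barcode, %(unassigned_smmip)d no smMIP, "
                "%(unique_molecules)d unique molecules", stats)
    return ProcessResult(counts=count_table(observations, panel),
                         observations=observations, stats=stats)


def process_fastq(r1_path, r2_path, panel: Panel, barcode_map: dict[str, str],
                  max_mismatch: int = 1, max_arm_mismatch: int = 1) -> ProcessResult:
    """End-to-end processing of a FASTQ pair."""
    return process_pairs(read_fastq_pairs(r1_path, r2_path), panel, barcode_map,
                         max_mismatch, max_arm_mismatch)


# ---------------------------------------------------------------------------
# Observation serialization
# ---------------------------------------------------------------------------

OBS_COLUMNS = ["sample_id", "smmip_id", "umi", "consensus_gap",
               "n_read_pairs", "mate2_first_covered"]


def write_observations(observations_by_sample, path) -> None:
    """Per-molecule TSV.  Mate-1 coverage is complete by construction; the
    mate-2 mask is a suffix and stored as its first covered index (-1: none)."""
    with open(path, "w") as fh:
        fh.write("\t".join(OBS_COLUMNS) + "\n")
        for sid in sorted(observations_by_sample):
            for o in observations_by_sample[sid]:
                first2 = next((i for i, c in enumerate(o.covered_by_mate2) if c), -1)
                fh.write(f"{sid}\t{o.smmip_id}\t{o.umi}\t{o.consensus_gap}\t"
                         f"{o.n_read_pairs}\t{first2}\n")


def read_observations(path) -> dict[str, list[UniqueObservation]]:
    out: dict[str, list[UniqueObservation]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != OBS_COLUMNS:
            raise ValueError(f"{path}:1: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(OBS_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(OBS_COLUMNS)} fields")
            gf_len = len(f[3])
            first2 = int(f[5])
            cov2 = tuple(first2 != -1 and i >= first2 for i in range(gf_len))
            out.setdefault(f[0], []).append(UniqueObservation(
                smmip_id=f[1], umi=f[2], consensus_gap=f[3],
                n_read_pairs=int(f[4]),
                covered_by_mate1=(True,) * gf_len,
                covered_by_mate2=cov2,
            ))
    return out
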