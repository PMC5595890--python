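"""Independent brute-force oracle for coding-consequence annotation.

Works purely by mutating the full transcript, translating both sequences
and diffing the proteins — no codon arithmetic shared with the library.
"""
from Bio.Seq import Seq

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "*",
}


def _translate(seq):
    return str(Seq(seq[:len(seq) - len(seq) % 3]).translate())


def _shift_3prime(seq, pos, deleted):
    while pos + len(deleted) < len(seq) and seq[pos] == seq[pos + len(deleted)]:
        pos += 1
    return pos, seq[pos:pos + len(deleted)]


def expected_annotation(transcript, pos, ref, alt):
    """(hgvs_c, hgvs_p, classification) by translate-and-diff.

    ``pos`` is 0-based transcript coordinate; deletion when alt == "".
    Assumes the variant lies fully inside the CDS and, for deletions,
    upstream of the stop codon.
    """
    seq, cs, ce = transcript.sequence, transcript.cds_start, transcript.cds_end
    ref_prot = _translate(seq[cs:ce])

    if alt != "":
        c = pos - cs + 1
        hgvs_c = f"c.{c}{ref}>{alt}"
        mut = seq[:pos] + alt + seq[pos + 1:]
        mut_prot = _translate(mut[cs:ce])
        diffs = [i for i, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b]
        if not diffs:
            return hgvs_c, "p.(=)", "synonymous"
        (i,) = diffs
        n = i + 1
        if mut_prot[i] == "*":
            return hgvs_c, f"p.{AA3[ref_prot[i]]}{n}*", "nonsense"
        if ref_prot[i] == "*":
            return hgvs_c, f"p.*{n}{AA3[mut_prot[i]]}ext*?", "stop_lost"
        return hgvs_c, f"p.{AA3[ref_prot[i]]}{n}{AA3[mut_prot[i]]}", "missense"

    # deletion
    pos, ref = _shift_3prime(seq, pos, ref)
    L = len(ref)
    c1 = pos - cs + 1
    hgvs_c = f"c.{c1}del{ref}" if L == 1 else f"c.{c1}_{c1 + L - 1}del{ref}"
    mut = seq[:pos] + seq[pos + L:]

    if L % 3:
        mut_prot = _translate(mut[cs:])
        i = 0
        while i < min(len(ref_prot), len(mut_prot)) and ref_prot[i] == mut_prot[i]:
            i += 1
        n = i + 1
        aa_ref = ref_prot[i] if i < len(ref_prot) else "*"
        if i >= len(mut_prot):
            return hgvs_c, f"p.{AA3[aa_ref]}{n}fs*?", "frameshift"
        if mut_prot[i] == "*":
            return hgvs_c, f"p.{AA3[aa_ref]}{n}*", "frameshift"
        stop = mut_prot.find("*", i)
        fs = f"*{stop - i + 1}" if stop != -1 else "*?"
        return hgvs_c, f"p.{AA3[aa_ref]}{n}{AA3[mut_prot[i]]}fs{fs}", "frameshift"

    mut_prot = _translate(mut[cs:ce - L])
    p = 0
    while p < len(mut_prot) and ref_prot[p] == mut_prot[p]:
        p += 1
    s = 0
    while (s < len(mut_prot) - p and ref_prot[len(ref_prot) - 1 - s]
           == mut_prot[len(mut_prot) - 1 - s]):
        s += 1
    lost = ref_prot[p:len(ref_prot) - s]
    gained = mut_prot[p:len(mut_prot) - s]
    if not lost:
        return hgvs_c, "p.(=)", "inframe_deletion"
    first, last = p + 1, len(ref_prot) - s
    span = (f"{AA3[lost[0]]}{first}" if first == last
            else f"{AA3[lost[0]]}{first}_{AA3[lost[-1]]}{last}")
    hgvs_p = f"p.{span}del" if not gained else \
        f"p.{span}delins" + "".join(AA3[a] for a in gained)
    return hgvs_c, hgvs_p, "inframe_deletion"
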