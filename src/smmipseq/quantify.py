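"""Expression quantification: FPM, transcript aggregates, TPM, concordance.

FPM (fragments per million) normalizes each probe's unique-molecule count by
the sample's total assigned unique molecules:

    FPM_i = count_i / sum_j(count_j) * 1e6

so per-sample FPM sums to 1e6.  The denominator is deliberately the total
over the panel (no housekeeping-gene normalization).  Transcript-level
values aggregate over the probes targeting a transcript (mean by default;
zero-count probes are included, since non-performing probes are information,
not missing data).  TPM applies the usual length-normalized transform to
whole-transcriptome gene counts; concordance between the two is summarized
by Pearson r on log10(x + pseudocount).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import Panel

logger = logging.getLogger(__name__)

MILLION = 1e6
AGGREGATE_METHODS = ("mean", "median", "best")


def compute_fpm(counts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Fragments-per-million per smMIP.

    ``counts`` holds unique-molecule counts (rows = smMIPs, columns =
    samples; a Series is treated as a single sample).  Samples with a zero
    total yield all-zero FPM with a logged warning.
    """
    if isinstance(counts, pd.Series):
        return compute_fpm(counts.to_frame("sample"))["sample"]
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        logger.warning("samples with zero assigned unique reads: %s", zero)
    safe = totals.replace(0, 1)
    return counts.div(safe, axis=1) * MILLION


def aggregate_transcript(fpm: pd.DataFrame | pd.Series, panel: Panel,
                         method: str = "mean") -> pd.DataFrame | pd.Series:
    """Aggregate per-smMIP FPM to per-transcript values.

    ``mean`` averages over all probes of a transcript including zeros;
    ``median`` is the standard midpoint rule; ``best`` takes the maximum
    (the best-performing probe).
    """
    if method not in AGGREGATE_METHODS:
        raise ValueError(f"unknown aggregation method {method!r}; "
                         f"choose from {AGGREGATE_METHODS}")
    if isinstance(fpm, pd.Series):
        return aggregate_transcript(fpm.to_frame("sample"), panel, method)["sample"]
    mapping = {m.smmip_id: m.transcript_id for m in panel.smmips}
    missing = [i for i in fpm.index if i not in mapping]
    if missing:
        raise KeyError(f"smMIPs not in panel: {missing[:5]}")
    grouped = fpm.groupby(fpm.index.map(mapping))
    out = {"mean": grouped.mean, "median": grouped.median, "best": grouped.max}[method]()
    out.index.name = "transcript_id"
    return out


def compute_tpm(gene_counts, effective_lengths) -> pd.Series:
    """Transcripts-per-million from gene counts and effective lengths.

    TPM_i = (count_i / length_i) / sum_j(count_j / length_j) * 1e6.
    """
    counts = pd.Series(gene_counts, dtype=float)
    lengths = pd.Series(effective_lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("every gene needs an effective length")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        logger.warning("all-zero gene counts; TPM undefined, returning zeros")
        return rate * 0.0
    return rate / total * MILLION


@dataclass
class ConcordanceResult:
    """Pearson concordance between targeted (FPM) and whole-transcriptome
    (TPM) expression values on a shared transcript set."""

    r: float
    p_value: float
    n: int
    pairs: pd.DataFrame            # transcript_id-indexed: fpm, tpm (+ transformed)
    missing_in_fpm: list[str]
    missing_in_tpm: list[str]
    transform: str


def correlate_fpm_tpm(aggregates: pd.Series, tpm: pd.Series,
                      pseudocount: float = 0.01, log: bool = True) -> ConcordanceResult:
    """Correlate per-transcript aggregate FPM with TPM.

    By default both sides are transformed as log10(x + pseudocount); the
    pseudocount (default 0.01) sits below the smallest non-zero FPM values
    seen in practice so zeros remain in the analysis without dominating it.
    Transcripts present on only one side are reported, never silently
    dropped.  Requires at least 3 shared transcripts.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    shared = sorted(set(aggregates.index) & set(tpm.index))
    missing_fpm = sorted(set(tpm.index) - set(aggregates.index))
    missing_tpm = sorted(set(aggregates.index) - set(tpm.index))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared transcripts, have {len(shared)}")
    x = aggregates.loc[shared].astype(float)
    y = tpm.loc[shared].astype(float)
    if log:
        xt, yt = np.log10(x + pseudocount), np.log10(y + pseudocount)
        transform = f"log10(x + {pseudocount})"
    else:
        xt, yt = x, y
        transform = "identity"
    r, p = stats.pearsonr(xt, yt)
    pairs = pd.DataFrame({"fpm": x, "tpm": y, "fpm_t": xt, "tpm_t": yt})
    pairs.index.name = "transcript_id"
    return ConcordanceResult(r=float(r), p_value=float(p), n=len(shared),
                             pairs=pairs, missing_in_fpm=missing_fpm,
                             missing_in_tpm=missing_tpm, transform=transform)


@dataclass
class ExpressionTable:
    """Raw unique counts, FPM, per-sample totals and transcript aggregates."""

    counts: pd.DataFrame
    fpm: pd.DataFrame
    totals: pd.Series
    transcript_mean: pd.DataFrame
    transcript_median: pd.DataFrame
    transcript_best: pd.DataFrame

    @classmethod
    def build(cls, counts: pd.DataFrame, panel: Panel) -> "ExpressionTable":
        fpm = compute_fpm(counts)
        return cls(
            counts=counts,
            fpm=fpm,
            totals=counts.sum(axis=0),
            transcript_mean=aggregate_transcript(fpm, panel, "mean"),
            transcript_median=aggregate_transcript(fpm, panel, "median"),
            transcript_best=aggregate_transcript(fpm, panel, "best"),
        )

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "unique_counts.tsv", sep="\t")
        self.fpm.to_csv(outdir / "fpm.tsv", sep="\t", float_format="%.4f")
        self.transcript_mean.to_csv(outdir / "transcript_mean_fpm.tsv",
                                    sep="\t", float_format="%.4f")


def scatter_plot(result: ConcordanceResult, path) -> None:
    """Export an FPM-vs-TPM scatter on the transformed scale."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(result.pairs["tpm_t"], result.pairs["fpm_t"], s=12, alpha=0.7)
    ax.set_xlabel(f"TPM, {result.transform}")
    ax.set_ylabel(f"aggregate FPM, {result.transform}")
    ax.set_title(f"Pearson r = {result.r:.3f} (n = {result.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
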