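"""In-silico sexing, genotyping and QC of single-embryo RNA-seq samples.

Sex is called from the summed normalized counts of Y-linked genes (Ddx3y,
Eif2s3y in the mouse); genotype either from reads spanning the mutated codon
(distinguishing a wild-type, a missense and a 3-bp-deletion allele, the
latter recognizable only through soft-clipped read tails) or from the count
of reads mapping to an exogenous tag sequence. QC removes shallow embryos
and robust outliers in mitochondrial / rDNA read fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EmbryoRecord",
    "AlleleCall",
    "SexResult",
    "assign_sex",
    "call_allele_at_locus",
    "extract_locus_reads",
    "genotype_from_tag_counts",
    "qc_filter_embryos",
]

TAG_CUTOFF = 72  # reads on the exogenous tag below this => wild type
DEPTH_MIN = 1_000_000


@dataclass
class EmbryoRecord:
    sample_id: str
    total_reads: int
    mt_fraction: float
    rdna_fraction: float
    y_gene_norm_counts: float = 0.0
    tag_read_sum: int = 0
    sex_call: str = "ambiguous"
    genotype_call: str = "no-call"
    qc_pass: bool = True
    qc_reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.qc_pass and not self.qc_reasons:
            raise ValueError("qc_pass=False requires at least one reason code")


@dataclass
class AlleleCall:
    n_wt_reads: int
    n_missense_reads: int
    n_deletion_reads: int
    call: str  # WT | missense | deletion | heterozygous | no-call
    wt_by_absence: bool = False
    het_alleles: tuple[str, ...] = ()


@dataclass
class SexResult:
    calls: pd.Series  # per-embryo {male, female, ambiguous}
    scores: pd.Series
    gap_statistic: float
    single_cluster: bool


def assign_sex(
    norm_counts: pd.DataFrame,
    y_genes: list[str],
    threshold: float = 10.0,
    ambiguity_band: float = 0.0,
) -> SexResult:
    """Call sex from summed normalized counts of Y-linked genes.

    score > ``threshold`` => male, score <= threshold => female (ties go to
    female); scores within ``ambiguity_band`` of the threshold are called
    ambiguous. The gap statistic is the largest sorted-score gap divided by
    the score range — a crude bimodality diagnostic (a value near 1 means
    two tight, well separated clusters; ``single_cluster`` is set when the
    range is negligible or the gap does not dominate).
    """
    missing = [g for g in y_genes if g not in norm_counts.index]
    if missing:
        raise KeyError(f"Y genes missing from matrix: {missing}")
    scores = norm_counts.loc[y_genes].sum(axis=0)
    calls = pd.Series(
        np.where(scores > threshold, "male", "female"), index=scores.index, dtype=object
    )
    if ambiguity_band > 0:
        near = (scores - threshold).abs() <= ambiguity_band
        calls[near] = "ambiguous"

    srt = np.sort(scores.to_numpy(dtype=float))
    rng_ = srt[-1] - srt[0]
    if len(srt) < 2 or rng_ <= 1e-12:
        gap, single = 0.0, True
    else:
        gaps = np.diff(srt)
        gap = float(gaps.max() / rng_)
        single = gap < 0.5
    return SexResult(calls=calls, scores=scores, gap_statistic=gap, single_cluster=single)


# ---------------------------------------------------------------------------
# allele calling at the mutated codon


def _classify_read(seq: str, templates: dict[str, str]) -> str | None:
    matches = [name for name, t in templates.items() if t in seq]
    if len(matches) == 1:
        return matches[0]
    return None  # unclassifiable (no template, or consistent with several)


def call_allele_at_locus(
    reads: list[str],
    templates: dict[str, str],
    min_reads: int = 3,
    het_min_fraction: float = 0.2,
) -> AlleleCall:
    """Classify codon-spanning reads by exact template match and call the allele.

    ``templates`` maps ``{"WT", "missense", "deletion"}`` to sequence
    windows; the deletion template is the wild-type window with the 3-bp
    codon removed, i.e. the junction a soft-clipped deletion read exposes.
    Classification is by substring match against the full read sequence
    (soft-clipped tails included), so no deletion-aware alignment is needed.
    A single allele with >= ``min_reads`` support is called; two alleles
    each with >= min_reads and >= ``het_min_fraction`` of informative reads
    give a heterozygous call; fewer informative reads give no-call. A WT
    call based only on absence of mutant reads carries the ``wt_by_absence``
    qualifier.
    """
    for a in ("WT", "missense", "deletion"):
        if a not in templates:
            raise ValueError(f"missing template {a}")
    names = list(templates)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if templates[a] in templates[b] or templates[b] in templates[a]:
                raise ValueError(f"templates {a} and {b} do not distinguish alleles")

    tally = {"WT": 0, "missense": 0, "deletion": 0}
    for seq in reads:
        hit = _classify_read(seq, templates)
        if hit is not None:
            tally[hit] += 1
    informative = sum(tally.values())

    supported = [a for a in tally if tally[a] >= min_reads]
    if informative < min_reads or not supported:
        call, het = "no-call", ()
    else:
        strong = [
            a for a in supported if informative and tally[a] / informative >= het_min_fraction
        ]
        if len(strong) >= 2:
            call, het = "heterozygous", tuple(sorted(strong))
        else:
            best = max(supported, key=lambda a: tally[a])
            call, het = best, ()
    return AlleleCall(
        n_wt_reads=tally["WT"],
        n_missense_reads=tally["missense"],
        n_deletion_reads=tally["deletion"],
        call=call,
        wt_by_absence=(call == "WT" and tally["missense"] == 0 and tally["deletion"] == 0),
        het_alleles=het,
    )


def extract_locus_reads(sam_path, region: str) -> list[str]:
    """Query sequences (soft clips included) of reads overlapping
    ``chrom:start-end`` (1-based, inclusive) in a SAM file."""
    import pysam

    chrom, span = region.rsplit(":", 1)
    start, end = (int(x) for x in span.split("-"))
    seqs = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for a in fh.fetch(until_eof=True):
            if a.is_unmapped or a.reference_name != chrom:
                continue
            if a.reference_start < end and (a.reference_end or a.reference_start) > start - 1:
                if a.query_sequence:
                    seqs.append(a.query_sequence)
    return seqs


def genotype_from_tag_counts(tag_read_sum: int, cutoff: int = TAG_CUTOFF) -> str:
    """Wild type iff the summed tag-mapping reads are below the cutoff."""
    if tag_read_sum < 0:
        raise ValueError("tag_read_sum must be >= 0")
    return "WT" if tag_read_sum < cutoff else "tagged"


# ---------------------------------------------------------------------------
# QC


def qc_filter_embryos(
    records: pd.DataFrame,
    depth_min: int = DEPTH_MIN,
    mad_k: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard shallow embryos, then mt/rDNA-fraction outliers.

    ``records`` needs columns ``total_reads``, ``mt_fraction``,
    ``rdna_fraction`` (index = embryo ids). An embryo is discarded when
    ``total_reads < depth_min``, or when its mt or rDNA fraction deviates
    from the median by more than ``mad_k`` * MAD on either axis; medians and
    MADs are computed over the depth-passing embryos only. Zero MAD on an
    axis means no outliers on that axis. With fewer than 4 depth-passing
    embryos the outlier step is skipped with a warning. Returns
    ``(kept, discarded)`` where discarded carries a ``reasons`` column.
    """
    import warnings

    for col in ("total_reads", "mt_fraction", "rdna_fraction"):
        if col not in records.columns:
            raise KeyError(f"records missing column {col}")
    reasons: dict[object, list[str]] = {i: [] for i in records.index}
    deep = records.total_reads >= depth_min
    for i in records.index[~deep]:
        reasons[i].append("depth")

    passing = records[deep]
    if len(passing) < 4:
        warnings.warn("fewer than 4 depth-passing embryos; outlier step skipped")
    else:
        for col, tag in (("mt_fraction", "mt-outlier"), ("rdna_fraction", "rdna-outlier")):
            x = passing[col].to_numpy(dtype=float)
            med = float(np.median(x))
            mad = float(np.median(np.abs(x - med)))
            if mad <= 0:
                continue
            bad = np.abs(x - med) > mad_k * mad
            for i in passing.index[bad]:
                reasons[i].append(tag)

    discard_idx = [i for i in records.index if reasons[i]]
    keep_idx = [i for i in records.index if not reasons[i]]
    discarded = records.loc[discard_idx].copy()
    discarded["reasons"] = [",".join(reasons[i]) for i in discard_idx]
    return records.loc[keep_idx].copy(), discarded
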