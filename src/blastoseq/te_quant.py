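"""Repeat-aware retrotransposon quantification.

The quantification strategy targets multi-mapping repeat-derived reads for
which per-locus assignment is meaningless: with one random alignment
reported per multimapper, fragments are filtered down to pairs where both
mates are completely included in a repeat element and neither mate touches a
gene body, counted per repName (all genomic copies of one element type
pooled), and normalized to FPKM at the repName or repFamily level. The
summed FPKM of DNA-transposon families serves as a per-sample genomic-DNA
contamination covariate: DNA transposons are transcriptionally silent, so
their apparent RNA signal tracks DNA carry-over.

FPKM definitions (fragment counts, aligner *input reads* as depth):

    FPKM(repName r, sample s)  = count(r,s) / (input_reads(s)/2) * 1e6 / length_kb(r)
    FPKM(repFamily f, sample s) = sum_r∈f count / (input_reads(s)/2) * 1e6 / sum_r∈f length_kb

The /2 converts read depth to fragment depth. Family FPKM aggregates counts
and lengths before dividing — it is not a mean of member FPKMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "RepeatElement",
    "AlignedFragment",
    "RepeatCountTable",
    "FpkmTable",
    "AnnotationError",
    "ParseError",
    "load_repeat_annotation",
    "load_gene_annotation",
    "read_fragments_from_sam",
    "filter_repeat_fragments",
    "count_by_repname",
    "fpkm_repname",
    "fpkm_repfamily",
    "dna_contamination_covariate",
]

EXCLUDED_CLASSES = ("Simple_repeat", "Low_complexity")


class ParseError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatElement:
    """One annotated repeat copy; coordinates 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    rep_name: str
    rep_family: str
    rep_class: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ParseError(f"element {self.rep_name}: end <= start ({self.start}, {self.end})")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedFragment:
    """A paired-end fragment: two mate intervals on one chromosome."""

    read_id: str
    chrom: str
    mate1: tuple[int, int]
    mate2: tuple[int, int]
    proper_pair: bool = True


@dataclass
class RepeatCountTable:
    counts: pd.DataFrame  # repName x sample, int
    length_kb: pd.Series  # per repName, summed element length in kb
    input_read_count: pd.Series  # per sample, aligner input READS
    name_to_family: dict[str, str] = field(default_factory=dict)
    name_to_class: dict[str, str] = field(default_factory=dict)
    n_ambiguous: pd.Series | None = None  # per sample, pairs spanning two repNames


@dataclass
class FpkmTable:
    level: str  # "repName" | "repFamily"
    fpkm: pd.DataFrame  # feature x sample
    dna_fpkm: pd.Series | None = None
    dna_flags: pd.Series | None = None


# ---------------------------------------------------------------------------
# annotation loading


def _parse_class_family(cf: str) -> tuple[str, str]:
    if "/" in cf:
        cls, fam = cf.split("/", 1)
    else:
        cls = fam = cf
    return cls.rstrip("?"), fam.rstrip("?")


def load_repeat_annotation(path, exclude_simple: bool = True) -> list[RepeatElement]:
    """Load repeats from RepeatMasker ``.out`` dialect or an extended BED.

    ``.out`` rows use 1-based inclusive query coordinates and a joined
    ``class/family`` column; extended BED is
    ``chrom start end name score strand repName repFamily repClass`` with
    0-based half-open coordinates. When ``exclude_simple`` is set (the
    default), Simple_repeat and Low_complexity rows are dropped. A repName
    mapping to more than one family or class raises
    :class:`AnnotationError`.
    """
    path = str(path)
    with open(path) as fh:
        lines = fh.readlines()
    is_out = _looks_like_rm_out(lines)
    elements: list[RepeatElement] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "track", "browser")):
            continue
        try:
            if is_out:
                el = _parse_out_row(stripped)
                if el is None:  # header rows
                    continue
            else:
                el = _parse_bed_row(stripped)
        except ParseError:
            raise
        except Exception as exc:  # malformed row
            raise ParseError(f"{path}:{lineno}: malformed row ({exc})") from exc
        elements.append(el)

    if exclude_simple:
        elements = [e for e in elements if e.rep_class not in EXCLUDED_CLASSES]

    seen: dict[str, tuple[str, str]] = {}
    for e in elements:
        prev = seen.setdefault(e.rep_name, (e.rep_family, e.rep_class))
        if prev != (e.rep_family, e.rep_class):
            raise AnnotationError(
                f"repName {e.rep_name} maps to both {prev} and ({e.rep_family}, {e.rep_class})"
            )
    return elements


def _looks_like_rm_out(lines) -> bool:
    for line in lines:
        s = line.strip()
        if not s:
            continue
        if s.startswith("SW") or s.startswith("score"):
            return True
        first = s.split()[0]
        try:
            int(first)
            return not ("\t" in line)  # BED with tabs starts with a chrom name anyway
        except ValueError:
            return False
    return False


def _parse_out_row(row: str) -> RepeatElement | None:
    fields = row.split()
    if fields[0] in ("SW", "score") or fields[0].startswith("perc"):
        return None
    if len(fields) < 11:
        raise ValueError(f"expected >= 11 whitespace fields, got {len(fields)}")
    chrom = fields[4]
    start = int(fields[5]) - 1  # 1-based inclusive -> 0-based half-open
    end = int(fields[6])
    strand = "-" if fields[8] == "C" else "+"
    name = fields[9]
    cls, fam = _parse_class_family(fields[10])
    return RepeatElement(chrom, start, end, strand, name, fam, cls)


def _parse_bed_row(row: str) -> RepeatElement:
    fields = row.split("\t")
    if len(fields) < 9:
        raise ValueError(f"expected >= 9 tab fields, got {len(fields)}")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    strand = fields[5] if fields[5] in ("+", "-", ".") else "."
    return RepeatElement(chrom, start, end, strand, fields[6], fields[7], fields[8])


def load_gene_annotation(path) -> pd.DataFrame:
    """Gene bodies from GTF (``gene`` features, or the envelope of all rows
    per gene_id) as a DataFrame with 0-based half-open coordinates."""
    rows = []
    with open(str(path)) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"GTF row with {len(f)} fields")
            attrs = f[8]
            gene_id = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene_id = part.split(None, 1)[1].strip('" ')
            rows.append((f[0], int(f[3]) - 1, int(f[4]), f[6], gene_id, f[2]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id", "feature"])
    if (df.feature == "gene").any():
        df = df[df.feature == "gene"]
    else:
        df = (
            df.groupby("gene_id")
            .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"), strand=("strand", "first"))
            .reset_index()
        )
    return df[["chrom", "start", "end", "strand", "gene_id"]].reset_index(drop=True)


def read_fragments_from_sam(path) -> list[AlignedFragment]:
    """Pair primary alignments by read name; keep proper pairs with both
    mates mapped to the same chromosome."""
    import pysam

    first: dict[str, tuple] = {}
    frags = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary or not a.is_paired:
                continue
            iv = (a.reference_name, a.reference_start, a.reference_end)
            if a.query_name in first:
                chrom0, s0, e0 = first.pop(a.query_name)
                if chrom0 != a.reference_name:
                    continue
                m1, m2 = sorted([(s0, e0), (a.reference_start, a.reference_end)])
                frags.append(AlignedFragment(a.query_name, chrom0, m1, m2, a.is_proper_pair))
            else:
                first[a.query_name] = iv
    return frags


# ---------------------------------------------------------------------------
# fragment filter and counting


def _build_trees(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, payload in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, payload)
    return trees


def _repeat_trees(repeats: list[RepeatElement]) -> dict[str, IntervalTree]:
    return _build_trees((e.chrom, e.start, e.end, e) for e in repeats)


def _gene_trees(genes: pd.DataFrame) -> dict[str, IntervalTree]:
    return _build_trees(
        (r.chrom, int(r.start), int(r.end), getattr(r, "gene_id", None))
        for r in genes.itertuples(index=False)
    )


def _containing_elements(tree: IntervalTree | None, start: int, end: int):
    if tree is None:
        return []
    return [iv.data for iv in tree.overlap(start, end) if iv.begin <= start and iv.end >= end]


def filter_repeat_fragments(
    fragments: list[AlignedFragment],
    repeats: list[RepeatElement],
    genes: pd.DataFrame,
) -> list[AlignedFragment]:
    """Keep fragments whose mates are each completely included in a repeat
    element and neither of which overlaps a gene body by >= 1 bp.

    Containment is evaluated per mate against single elements (a mate that
    spans two abutting copies is not contained). Gene overlap is unstranded.
    Order-preserving and idempotent.
    """
    rtrees = _repeat_trees(repeats)
    gtrees = _gene_trees(genes) if genes is not None and len(genes) else {}
    kept = []
    for f in fragments:
        rt = rtrees.get(f.chrom)
        if rt is None:
            continue
        if not _containing_elements(rt, *f.mate1) or not _containing_elements(rt, *f.mate2):
            continue
        gt = gtrees.get(f.chrom)
        if gt is not None and (gt.overlaps(*f.mate1) or gt.overlaps(*f.mate2)):
            continue
        kept.append(f)
    return kept


def summarized_lengths(repeats: list[RepeatElement]) -> pd.Series:
    """Per-repName summed element length in kb (featureCounts-style)."""
    acc: dict[str, int] = {}
    for e in repeats:
        acc[e.rep_name] = acc.get(e.rep_name, 0) + e.length_bp
    return pd.Series(acc, dtype=float).sort_index() / 1000.0


def count_by_repname(
    fragments: list[AlignedFragment],
    repeats: list[RepeatElement],
    input_read_count: int | dict[str, int] | None = None,
    sample: str = "s1",
) -> RepeatCountTable:
    """Fragment counts per repName (unstranded, pair-level counting).

    A fragment counts for repName R iff both mates are completely included
    in elements of repName R; pairs whose mates fall in elements of
    different repNames are discarded as ambiguous (counted separately).
    Fragments failing containment entirely violate the
    :func:`filter_repeat_fragments` contract and raise ``RuntimeError``.
    """
    rtrees = _repeat_trees(repeats)
    lengths = summarized_lengths(repeats)
    tally: dict[str, int] = {}
    n_ambiguous = 0
    for f in fragments:
        names1 = {e.rep_name for e in _containing_elements(rtrees.get(f.chrom), *f.mate1)}
        names2 = {e.rep_name for e in _containing_elements(rtrees.get(f.chrom), *f.mate2)}
        if not names1 or not names2:
            raise RuntimeError(
                f"fragment {f.read_id} has a mate outside any repeat element; "
                "run filter_repeat_fragments first"
            )
        common = names1 & names2
        if len(common) == 1:
            name = next(iter(common))
            tally[name] = tally.get(name, 0) + 1
        else:  # different repNames (or nested elements of several): ambiguous
            n_ambiguous += 1
    counts = pd.Series(tally, dtype=int).reindex(lengths.index, fill_value=0)

    elements = {e.rep_name: e for e in repeats}
    depth = input_read_count if input_read_count is not None else 0
    if isinstance(depth, dict):
        depth = depth.get(sample, 0)
    return RepeatCountTable(
        counts=counts.to_frame(sample),
        length_kb=lengths,
        input_read_count=pd.Series({sample: int(depth)}),
        name_to_family={n: e.rep_family for n, e in elements.items()},
        name_to_class={n: e.rep_class for n, e in elements.items()},
        n_ambiguous=pd.Series({sample: n_ambiguous}),
    )


def merge_count_tables(tables: list[RepeatCountTable]) -> RepeatCountTable:
    base = tables[0]
    counts = pd.concat([t.counts for t in tables], axis=1).fillna(0).astype(int)
    depth = pd.concat([t.input_read_count for t in tables])
    amb = pd.concat([t.n_ambiguous for t in tables if t.n_ambiguous is not None])
    return RepeatCountTable(
        counts=counts,
        length_kb=base.length_kb,
        input_read_count=depth,
        name_to_family=base.name_to_family,
        name_to_class=base.name_to_class,
        n_ambiguous=amb,
    )


# ---------------------------------------------------------------------------
# FPKM


def _check_depth(table: RepeatCountTable) -> None:
    if (table.input_read_count <= 0).any():
        raise ValueError("input_read_count must be > 0 for every sample")


def fpkm_repname(table: RepeatCountTable) -> FpkmTable:
    """FPKM per repName: count / (input_reads/2) * 1e6 / summed length_kb."""
    _check_depth(table)
    if (table.length_kb.reindex(table.counts.index) <= 0).any():
        raise ValueError("summarized lengths must be > 0")
    frag_depth = table.input_read_count / 2.0
    per_million = table.counts.div(frag_depth, axis=1) * 1e6
    fpkm = per_million.div(table.length_kb.reindex(table.counts.index), axis=0)
    return FpkmTable(level="repName", fpkm=fpkm)


def fpkm_repfamily(table: RepeatCountTable, name_to_family: dict[str, str] | None = None) -> FpkmTable:
    """Family FPKM: counts and lengths summed over members before dividing."""
    _check_depth(table)
    fam = pd.Series(name_to_family or table.name_to_family)
    fam = fam.reindex(table.counts.index)
    if fam.isna().any():
        raise AnnotationError(f"missing family for {list(fam.index[fam.isna()])}")
    counts = table.counts.groupby(fam).sum()
    lengths = table.length_kb.reindex(table.counts.index).groupby(fam).sum()
    frag_depth = table.input_read_count / 2.0
    fpkm = (counts.div(frag_depth, axis=1) * 1e6).div(lengths, axis=0)
    return FpkmTable(level="repFamily", fpkm=fpkm)


def dna_contamination_covariate(
    fpkm: FpkmTable,
    name_to_class: dict[str, str],
    mad_k: float = 3.0,
) -> tuple[pd.Series, pd.Series]:
    """Per-sample DNA-transposon FPKM sum plus a robust high-contamination flag.

    Returns ``(dna_fpkm, flagged)``; a sample is flagged when its dna_fpkm
    exceeds median + ``mad_k`` * MAD across samples (MAD = median absolute
    deviation, unscaled). With no DNA-class features the covariate is
    all-zero and a warning is issued.
    """
    import warnings

    cls = pd.Series(name_to_class).reindex(fpkm.fpkm.index)
    dna_mask = (cls == "DNA").to_numpy()
    if not dna_mask.any():
        warnings.warn("no DNA-class features in annotation; covariate is all-zero")
        dna = pd.Series(0.0, index=fpkm.fpkm.columns)
        return dna, pd.Series(False, index=fpkm.fpkm.columns)
    dna = fpkm.fpkm.loc[dna_mask].sum(axis=0)
    med = float(dna.median())
    mad = float((dna - med).abs().median())
    flagged = dna > med + mad_k * mad if mad > 0 else pd.Series(False, index=dna.index)
    fpkm.dna_fpkm = dna
    fpkm.dna_flags = flagged
    return dna, flagged
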