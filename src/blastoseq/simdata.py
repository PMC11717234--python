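"""Seeded generators for every input the pipeline consumes.

The module builds a toy genome with RepeatMasker-style repeat annotation and
a gene annotation (including designated Y-linked, mitochondrial, rDNA-proxy,
tag and mutation-target genes), simulates paired-end fragments with known
provenance (repeat / gene / intergenic / DNA contaminant), negative-binomial
count matrices with planted condition and batch effects, and single-embryo
cohorts with known sex, genotype and allele composition.

Every generator draws from its own RNG stream derived from the master seed,
so adding a generator never perturbs the output of an existing one.
Coordinates are 0-based half-open internally; emitted SAM records follow the
1-based SAM convention (pysam handles the conversion).
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimConfig",
    "GroundTruth",
    "DEFAULT_REPNAME_CATALOG",
    "make_toy_annotation",
    "simulate_fragments",
    "simulate_counts",
    "simulate_embryo_cohort",
    "write_sam",
    "write_repeatmasker_out",
    "write_repeat_bed",
    "write_gene_gtf",
]

# Catalog entries are (repName, repFamily, repClass). The default mirrors the
# element types that matter downstream: young LTR and LINE families, a SINE,
# DNA transposons (the contamination readout) and the simple/low-complexity
# classes that the loader must be able to exclude.
DEFAULT_REPNAME_CATALOG: list[tuple[str, str, str]] = [
    ("IAPLTR2_Mm", "ERVK", "LTR"),
    ("IAPEz-int", "ERVK", "LTR"),
    ("MERVL-int", "ERVL", "LTR"),
    ("MT2_Mm", "ERVL", "LTR"),
    ("L1MdTf_I", "L1", "LINE"),
    ("L1MdTf_II", "L1", "LINE"),
    ("B1_Mus1", "Alu", "SINE"),
    ("Charlie1", "hAT-Charlie", "DNA"),
    ("Tigger1", "TcMar-Tigger", "DNA"),
    ("(TA)n", "Simple_repeat", "Simple_repeat"),
    ("G-rich", "Low_complexity", "Low_complexity"),
]

# Fixed stream labels: one RNG stream per generator operation.
_STREAMS = {
    "annotation": 1,
    "fragments": 2,
    "counts": 3,
    "embryos": 4,
}

_CODON_WINDOW = 20  # bases flanking the mutated codon used for allele templates


def _rng(seed: int, stream: str, sub: str | None = None) -> np.random.Generator:
    key = (_STREAMS[stream],) if sub is None else (_STREAMS[stream], zlib.crc32(sub.encode()))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    ``allele_mix`` maps a sample id to ``(wt, missense, deletion)`` fractions
    of reads over the mutated codon; fractions must sum to 1 per sample.
    ``effect_log2fc`` maps perturbed feature ids to their true log2
    fold-change; unlisted features are null.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 200_000
    n_repeat_elements: int = 40
    repname_catalog: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(DEFAULT_REPNAME_CATALOG)
    )
    n_genes: int = 30
    n_samples_per_group: int = 10
    mean_depth_fragments: int = 20_000
    nb_dispersion: float = 0.05
    effect_log2fc: dict[str, float] = field(default_factory=dict)
    dna_contamination_fraction: float | dict[str, float] = 0.0
    batch_strength: float = 0.0
    allele_mix: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    # structural knobs
    include_simple_repeats: bool = True
    boundary_straddle_fraction: float = 0.1
    gene_overlap_fraction: float = 0.0
    repeat_length_range: tuple[int, int] = (400, 1500)
    gene_length_range: tuple[int, int] = (2000, 6000)
    size_factor_sigma: float = 0.15

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise SimConfigError("nb_dispersion must be > 0")
        fracs = (
            list(self.dna_contamination_fraction.values())
            if isinstance(self.dna_contamination_fraction, dict)
            else [self.dna_contamination_fraction]
        )
        for f in fracs + [self.boundary_straddle_fraction, self.gene_overlap_fraction]:
            if not 0.0 <= f <= 1.0:
                raise SimConfigError(f"fraction {f} outside [0, 1]")
        for sample, mix in self.allele_mix.items():
            if len(mix) != 3 or any(m < 0 for m in mix):
                raise SimConfigError(f"allele_mix for {sample} must be 3 non-negative fractions")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise SimConfigError(f"allele_mix for {sample} must sum to 1")
        if not self.repname_catalog:
            raise SimConfigError("repname_catalog must be non-empty")

    def contamination_for(self, sample: str) -> float:
        if isinstance(self.dna_contamination_fraction, dict):
            return self.dna_contamination_fraction.get(sample, 0.0)
        return self.dna_contamination_fraction

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class GroundTruth:
    """What the generators actually planted, for downstream verification."""

    log2fc: pd.Series | None = None
    batch_values: pd.Series | None = None
    batch_loadings: pd.Series | None = None
    size_factors: pd.Series | None = None
    sex: pd.Series | None = None
    genotype: pd.Series | None = None
    contamination: pd.Series | None = None
    provenance: list[str] | None = None
    flags: pd.DataFrame | None = None


@dataclass
class ToyAnnotation:
    repeats: pd.DataFrame  # chrom,start,end,strand,repName,repFamily,repClass
    genes: pd.DataFrame  # chrom,start,end,strand,gene_id,gene_role
    genome: dict[str, np.ndarray]  # chrom -> byte array of ACGT
    mutation_locus: tuple[str, int]  # (chrom, 0-based codon start)

    def sequence(self, chrom: str, start: int, end: int) -> str:
        return self.genome[chrom][start:end].tobytes().decode()

    def allele_templates(self, window: int = _CODON_WINDOW) -> dict[str, str]:
        """WT / missense / deletion sequence templates over the codon window.

        The missense template substitutes the codon's middle base; the
        deletion template removes the whole 3-bp codon (the post-deletion
        junction a soft-clipped read exposes).
        """
        chrom, codon = self.mutation_locus
        wt = self.sequence(chrom, codon - window, codon + 3 + window)
        mid = window + 1
        sub = {"A": "G", "C": "T", "G": "A", "T": "C"}[wt[mid]]
        missense = wt[:mid] + sub + wt[mid + 1 :]
        deletion = wt[:window] + self.sequence(chrom, codon + 3, codon + 3 + window + 3)[: window + 3]
        return {"WT": wt, "missense": missense, "deletion": deletion}


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length)


def make_toy_annotation(config: SimConfig) -> ToyAnnotation:
    """Place non-overlapping repeat elements and gene bodies on a toy genome.

    Autosomes carry the repeats and regular genes; chrX carries the mutation
    target gene, chrY the two Y-linked sexing genes, chrM two mitochondrial
    genes, and a separate ``transgene`` contig the tag gene. Raises
    :class:`SimConfigError` when the requested elements cannot fit.
    """
    rng = _rng(config.seed, "annotation")
    catalog = [c for c in config.repname_catalog]
    if not config.include_simple_repeats:
        catalog = [c for c in catalog if c[2] not in ("Simple_repeat", "Low_complexity")]
    if config.n_repeat_elements < len(catalog):
        raise SimConfigError("n_repeat_elements smaller than catalog size")

    autosomes = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_sizes = {c: config.chrom_length_bp for c in autosomes}
    chrom_sizes["chrX"] = max(30_000, config.chrom_length_bp // 4)
    chrom_sizes["chrY"] = 20_000
    chrom_sizes["chrM"] = 16_000
    chrom_sizes["transgene"] = 4_000

    # every repName at least once, remainder multinomial
    names = [catalog[i % len(catalog)] for i in range(config.n_repeat_elements)]
    rng.shuffle(names)

    lo, hi = config.repeat_length_range
    glo, ghi = config.gene_length_range
    repeat_rows, gene_rows = [], []
    cursors = {c: 100 for c in autosomes}
    min_gap, max_gap = 50, 300

    n_special = 0
    regular_genes = max(config.n_genes - n_special, 0)
    # interleave: genes first so overlap-requests can nest repeats inside them
    gene_lengths = rng.integers(glo, ghi + 1, size=regular_genes)
    placements: list[tuple[str, object]] = [("gene", int(L)) for L in gene_lengths]
    placements += [("repeat", nm) for nm in names]
    order = rng.permutation(len(placements))

    gi = 0
    last_gene: tuple[str, int, int] | None = None
    for idx in order:
        kind, payload = placements[idx]
        chrom = autosomes[int(rng.integers(0, len(autosomes)))]
        if kind == "gene":
            length = payload
            start = cursors[chrom] + int(rng.integers(min_gap, max_gap))
            end = start + length
            if end > chrom_sizes[chrom] - 100:
                raise SimConfigError(
                    f"chromosome {chrom} too short to place requested elements"
                )
            cursors[chrom] = end
            gi += 1
            gene_rows.append((chrom, start, end, "+", f"gene{gi:04d}", "regular"))
            last_gene = (chrom, start, end)
        else:
            name, fam, cls = payload
            length = int(rng.integers(lo, hi + 1))
            if last_gene is not None and rng.random() < config.gene_overlap_fraction:
                gchrom, gstart, gend = last_gene
                if gend - gstart > length + 20:
                    start = gstart + int(rng.integers(0, gend - gstart - length))
                    repeat_rows.append((gchrom, start, start + length, "+", name, fam, cls))
                    continue
            start = cursors[chrom] + int(rng.integers(min_gap, max_gap))
            end = start + length
            if end > chrom_sizes[chrom] - 100:
                raise SimConfigError(
                    f"chromosome {chrom} too short to place requested elements"
                )
            cursors[chrom] = end
            strand = "+" if rng.random() < 0.5 else "-"
            repeat_rows.append((chrom, start, end, strand, name, fam, cls))

    # special genes on dedicated contigs
    gene_rows.append(("chrX", 5_000, 12_000, "+", "Ogt", "target"))
    gene_rows.append(("chrY", 2_000, 6_000, "+", "Ddx3y", "y_linked"))
    gene_rows.append(("chrY", 8_000, 12_000, "+", "Eif2s3y", "y_linked"))
    gene_rows.append(("chrM", 1_000, 4_000, "+", "mt-Nd1", "mito"))
    gene_rows.append(("chrM", 5_000, 9_000, "+", "mt-Co1", "mito"))
    gene_rows.append(("chr1", chrom_sizes["chr1"] - 8_000, chrom_sizes["chr1"] - 1_000, "+", "Rn45s_proxy", "rdna"))
    gene_rows.append(("transgene", 100, 2_100, "+", "AID_2xMyc_FLAG", "tag"))

    repeats = pd.DataFrame(
        repeat_rows,
        columns=["chrom", "start", "end", "strand", "repName", "repFamily", "repClass"],
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    genes = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "strand", "gene_id", "gene_role"]
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    genome = {c: _random_sequence(rng, n) for c, n in chrom_sizes.items()}
    codon_start = 5_000 + 1_200  # inside the target gene on chrX
    return ToyAnnotation(repeats, genes, genome, ("chrX", codon_start))


# ---------------------------------------------------------------------------
# fragments


def _fragment_in(rng, start, end, frag_lo=160, frag_hi=320, read_len=80):
    span = end - start
    flen = int(rng.integers(frag_lo, min(frag_hi, max(frag_lo + 1, span)) + 1))
    flen = min(flen, span)
    fstart = start + int(rng.integers(0, span - flen + 1))
    m1 = (fstart, min(fstart + read_len, fstart + flen))
    m2 = (max(fstart + flen - read_len, fstart), fstart + flen)
    return m1, m2


def simulate_fragments(
    config: SimConfig,
    annotation: ToyAnnotation,
    truth_expression: pd.Series,
    sample: str = "s1",
    n_fragments: int | None = None,
):
    """Sample paired-end fragments with known provenance for one sample.

    ``truth_expression`` holds non-negative rates keyed by repName or
    gene_id; fragment counts per feature are multinomial with weights
    rate × summarized feature length. A configurable fraction of repeat
    fragments straddle the element boundary (and so must be removed by the
    containment filter); DNA-contaminant fragments are drawn uniformly over
    DNA-class elements. Returns a fragment table and the ground truth.
    """
    if (truth_expression < 0).any():
        raise SimConfigError("rates must be >= 0")
    rng = _rng(config.seed, "fragments", sub=sample)
    depth = n_fragments if n_fragments is not None else config.mean_depth_fragments
    repeats, genes = annotation.repeats, annotation.genes

    rep_len = repeats.assign(length=repeats.end - repeats.start).groupby("repName")["length"].sum()
    gene_len = (genes.set_index("gene_id").pipe(lambda d: d.end - d.start))
    feat_len = pd.concat([rep_len, gene_len])
    rates = truth_expression.reindex(feat_len.index).fillna(0.0)
    weights = (rates * feat_len).to_numpy(dtype=float)

    contam_frac = config.contamination_for(sample)
    n_contam = rng.binomial(depth, contam_frac) if contam_frac > 0 else 0
    n_expr = depth - n_contam
    if weights.sum() <= 0 and n_expr > 0:
        raise SimConfigError("all expression rates are zero")
    alloc = rng.multinomial(n_expr, weights / weights.sum()) if n_expr > 0 else np.zeros(len(weights), int)

    rep_arr = {
        n: (g.index.to_numpy(), g.chrom.to_numpy(), g.start.to_numpy(), g.end.to_numpy())
        for n, g in repeats.groupby("repName")
    }
    gene_arr = genes.set_index("gene_id")
    dna_elements = repeats.index[repeats.repClass == "DNA"].to_numpy()

    rows, provenance = [], []
    fid = 0

    def emit(chrom, m1, m2, label):
        nonlocal fid
        fid += 1
        rows.append((f"{sample}.frag{fid:07d}", chrom, m1[0], m1[1], m2[0], m2[1]))
        provenance.append(label)

    for feat, n in zip(feat_len.index, alloc):
        if n == 0:
            continue
        if feat in rep_arr:
            idxs, chroms, starts, ends = rep_arr[feat]
            elem_w = (ends - starts).astype(float)
            picks = rng.choice(len(idxs), size=n, p=elem_w / elem_w.sum())
            straddle = rng.random(n) < config.boundary_straddle_fraction
            for e, st in zip(picks, straddle):
                m1, m2 = _fragment_in(rng, starts[e], ends[e])
                if st:
                    # straddle: shift fragment so mate2 crosses the 3' edge
                    shift = (ends[e] - m2[0]) + int(rng.integers(5, 40))
                    m1 = (m1[0] + shift, m1[1] + shift)
                    m2 = (m2[0] + shift, m2[1] + shift)
                    emit(chroms[e], m1, m2, f"repeat_straddle:{idxs[e]}")
                else:
                    emit(chroms[e], m1, m2, f"repeat:{idxs[e]}")
        else:
            row = gene_arr.loc[feat]
            gchrom, gstart, gend = row.chrom, int(row.start), int(row.end)
            for _ in range(n):
                m1, m2 = _fragment_in(rng, gstart, gend)
                emit(gchrom, m1, m2, f"gene:{feat}")

    if n_contam and len(dna_elements) == 0:
        raise SimConfigError("contamination requested but no DNA-class elements")
    if n_contam:
        dstart = repeats.start.to_numpy()
        dend = repeats.end.to_numpy()
        dchrom = repeats.chrom.to_numpy()
        for e in rng.choice(dna_elements, size=n_contam):
            m1, m2 = _fragment_in(rng, dstart[e], dend[e])
            emit(dchrom[e], m1, m2, f"dna_contaminant:{e}")

    frags = pd.DataFrame(
        rows, columns=["read_id", "chrom", "m1_start", "m1_end", "m2_start", "m2_end"]
    )
    truth = GroundTruth(provenance=provenance)
    return frags, truth


def simulate_locus_reads(
    config: SimConfig,
    annotation: ToyAnnotation,
    sample: str,
    n_reads: int = 20,
    rng: np.random.Generator | None = None,
) -> list[dict]:
    """Reads spanning the mutated codon for one sample, per its allele mix.

    Each read dict carries the full query sequence plus the alignment
    representation: deletion-allele reads have the post-codon bases as a
    soft-clipped tail (``cigar`` = matched prefix + soft clip), mirroring
    what an end-to-end aligner emits for a 3-bp deletion.
    """
    if sample not in config.allele_mix:
        raise SimConfigError(f"allele_mix not defined for {sample}")
    if rng is None:
        rng = _rng(config.seed, "fragments", sub=sample)
    chrom, codon = annotation.mutation_locus
    templates = annotation.allele_templates()
    window = _CODON_WINDOW
    mix = np.asarray(config.allele_mix[sample], dtype=float)
    alleles = rng.choice(["WT", "missense", "deletion"], size=n_reads, p=mix)
    reads = []
    start = codon - window
    for i, a in enumerate(alleles):
        seq = templates[a]
        if a == "deletion":
            # aligned prefix matches the reference up to the codon; the rest
            # of the read (post-deletion junction) is soft-clipped
            match_len = window
            cigar = [(0, match_len), (4, len(seq) - match_len)]
        else:
            cigar = [(0, len(seq))]
        reads.append(
            {
                "read_id": f"{sample}.locus{i:04d}",
                "chrom": chrom,
                "start": start,
                "sequence": seq,
                "cigar": cigar,
                "true_allele": a,
            }
        )
    return reads


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    config: SimConfig,
    group_labels,
    baseline: pd.Series | None = None,
    feature_ids: list[str] | None = None,
    batch_values=None,
):
    """NB count matrix with planted condition effects and batch structure.

    counts ~ NB(mean = baseline · 2^(log2FC·group) · 2^(loading·batch) · sf,
    dispersion = ``nb_dispersion``); gamma–Poisson sampling keeps the small-
    dispersion limit exact. Group labels are 0/1 (or two level labels);
    features absent from ``config.effect_log2fc`` are null.
    """
    groups = pd.Series(group_labels)
    if groups.nunique() == 2 and not set(groups.unique()) <= {0, 1}:
        levels = sorted(groups.unique())
        groups = groups.map({levels[0]: 0, levels[1]: 1})
    if (groups.value_counts() < 2).any():
        raise SimConfigError("need >= 2 samples per group")
    rng = _rng(config.seed, "counts")
    n_samples = len(groups)
    samples = [f"sample{i + 1:03d}" for i in range(n_samples)]

    if baseline is None:
        nfeat = len(feature_ids) if feature_ids is not None else 1000
        ids = feature_ids or [f"gene{i + 1:05d}" for i in range(nfeat)]
        baseline = pd.Series(np.exp(rng.uniform(np.log(5), np.log(500), size=nfeat)), index=ids)
    else:
        baseline = pd.Series(baseline).astype(float)
    feat = baseline.index

    lfc = pd.Series(0.0, index=feat)
    for k, v in config.effect_log2fc.items():
        if k in lfc.index:
            lfc[k] = v

    sf = np.exp(rng.normal(0.0, config.size_factor_sigma, size=n_samples))
    sf /= np.exp(np.mean(np.log(sf)))

    if batch_values is None:
        batch_values = np.zeros(n_samples)
    batch_values = np.asarray(batch_values, dtype=float)
    loadings = (
        rng.normal(0.0, config.batch_strength, size=len(feat))
        if config.batch_strength > 0
        else np.zeros(len(feat))
    )

    g = groups.to_numpy()
    log_mu = (
        np.log(baseline.to_numpy())[:, None]
        + np.log(2.0) * (lfc.to_numpy()[:, None] * g[None, :])
        + np.log(2.0) * (loadings[:, None] * batch_values[None, :])
        + np.log(sf)[None, :]
    )
    mu = np.exp(log_mu)
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)

    cm = pd.DataFrame(counts, index=feat, columns=samples)
    truth = GroundTruth(
        log2fc=lfc,
        batch_values=pd.Series(batch_values, index=samples),
        batch_loadings=pd.Series(loadings, index=feat),
        size_factors=pd.Series(sf, index=samples),
    )
    meta = pd.DataFrame({"group": g, "batch": batch_values}, index=samples)
    return cm, meta, truth


# ---------------------------------------------------------------------------
# embryo cohort


def simulate_embryo_cohort(
    config: SimConfig,
    annotation: ToyAnnotation | None = None,
    n_embryos: int | None = None,
    sexes: list[str] | None = None,
    y_rate: float = 50.0,
    total_reads: dict[str, int] | None = None,
    mean_total_reads: int = 3_000_000,
    mt_fraction: float = 0.05,
    rdna_fraction: float = 0.02,
    fraction_overrides: dict[str, tuple[float, float]] | None = None,
    tag_rate: float = 500.0,
    n_locus_reads: int = 20,
    n_genes: int = 400,
):
    """Per-embryo gene counts, mutation-locus reads and the truth table.

    Males receive ``y_rate`` expected counts on each Y-linked gene, females
    zero. Per-embryo totals / mt / rDNA fractions follow the defaults unless
    overridden (for planted QC outliers). Genotypes derive from
    ``config.allele_mix``; tagged embryos (genotype containing ``"tagged"``)
    receive Poisson(``tag_rate``) tag-gene reads, others zero.
    """
    rng = _rng(config.seed, "embryos")
    if annotation is None:
        annotation = make_toy_annotation(config)
    embryos = sorted(config.allele_mix) if config.allele_mix else [
        f"embryo{i + 1:03d}" for i in range(n_embryos or 2 * config.n_samples_per_group)
    ]
    n = len(embryos)
    if sexes is None:
        sexes = ["male" if i < n // 2 else "female" for i in range(n)]
    totals = {
        e: (total_reads or {}).get(e, int(rng.normal(mean_total_reads, mean_total_reads * 0.1)))
        for e in embryos
    }
    overrides = fraction_overrides or {}

    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    special = ["Ddx3y", "Eif2s3y", "mt-Nd1", "mt-Co1", "Rn45s_proxy", "AID_2xMyc_FLAG", "Ogt"]
    base_w = np.exp(rng.uniform(np.log(5), np.log(500), size=n_genes))
    base_w /= base_w.sum()

    cols, records = {}, []
    for i, e in enumerate(embryos):
        sex = sexes[i]
        mt_f, rd_f = overrides.get(e, (mt_fraction, rdna_fraction))
        tot = totals[e]
        mix = config.allele_mix.get(e, (1.0, 0.0, 0.0))
        genotype = _genotype_label(mix)
        tag_reads = int(rng.poisson(tag_rate)) if "tagged" in genotype else 0

        y_counts = rng.poisson(y_rate, size=2) if sex == "male" else np.zeros(2, int)
        mt_counts = rng.multinomial(int(tot * mt_f), [0.6, 0.4])
        rd_count = int(tot * rd_f)
        ogt_count = int(rng.poisson(200))
        n_regular = max(tot - mt_counts.sum() - rd_count - int(y_counts.sum()) - tag_reads - ogt_count, 0)
        reg = rng.multinomial(n_regular, base_w)
        col = pd.Series(
            np.concatenate([y_counts, mt_counts, [rd_count, tag_reads, ogt_count], reg]),
            index=special + gene_ids,
        )
        cols[e] = col
        records.append(
            {
                "sample_id": e,
                "sex": sex,
                "genotype": genotype,
                "total_reads": tot,
                "mt_fraction": mt_f,
                "rdna_fraction": rd_f,
                "tag_read_sum": tag_reads,
                "below_depth_threshold": tot < 1_000_000,
            }
        )

    counts = pd.DataFrame(cols)
    truth = pd.DataFrame(records).set_index("sample_id")
    locus_reads = {
        e: simulate_locus_reads(config, annotation, e, n_reads=n_locus_reads, rng=rng)
        for e in embryos
        if e in config.allele_mix
    }
    return counts, locus_reads, truth


def _genotype_label(mix: tuple[float, float, float]) -> str:
    wt, mis, dele = mix
    parts = [n for n, f in (("WT", wt), ("missense", mis), ("deletion", dele)) if f > 0]
    return "het_" + "_".join(parts) if len(parts) > 1 else parts[0]


# ---------------------------------------------------------------------------
# writers


def write_sam(path, fragments: pd.DataFrame, annotation: ToyAnnotation, locus_reads=None) -> None:
    """Write paired-end fragments (and optional locus reads) as headered,
    coordinate-sorted SAM."""
    import pysam

    chrom_order = list(annotation.genome)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(annotation.genome[c])} for c in chrom_order],
    }
    tid = {c: i for i, c in enumerate(chrom_order)}

    records = []
    for row in fragments.itertuples(index=False):
        for mate, (s, e), (os_, oe) in (
            (1, (row.m1_start, row.m1_end), (row.m2_start, row.m2_end)),
            (2, (row.m2_start, row.m2_end), (row.m1_start, row.m1_end)),
        ):
            a = pysam.AlignedSegment()
            a.query_name = row.read_id
            a.reference_id = tid[row.chrom]
            a.reference_start = s
            a.cigartuples = [(0, e - s)]
            a.query_sequence = annotation.sequence(row.chrom, s, e)
            a.flag = 0x1 | 0x2 | (0x40 if mate == 1 else 0x80) | (0x20 if mate == 1 else 0x10)
            a.next_reference_id = tid[row.chrom]
            a.next_reference_start = os_
            a.template_length = (oe - s) if mate == 1 else -(e - os_)
            a.mapping_quality = 255
            records.append(a)
    for reads in (locus_reads or {}).values():
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r["read_id"]
            a.reference_id = tid[r["chrom"]]
            a.reference_start = r["start"]
            a.cigartuples = r["cigar"]
            a.query_sequence = r["sequence"]
            a.flag = 0
            a.mapping_quality = 255
            records.append(a)
    records.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in records:
            fh.write(a)


def write_repeatmasker_out(path, repeats: pd.DataFrame) -> None:
    """RepeatMasker ``.out`` dialect: 3 header lines then whitespace columns;
    query coordinates are 1-based inclusive, class/family joined by '/'."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query           matching"
            "       repeat              position in  repeat\n"
            "score  div. del. ins.  sequence    begin     end    (left)    repeat"
            "       class/family         begin  end (left)   ID\n\n"
        )
        for i, row in enumerate(repeats.itertuples(index=False), start=1):
            cf = (
                row.repClass
                if row.repClass == row.repFamily
                else f"{row.repClass}/{row.repFamily}"
            )
            strand = "C" if row.strand == "-" else "+"
            fh.write(
                f" 1000 10.0  0.0  0.0  {row.chrom} {row.start + 1} {row.end} (0) {strand} "
                f"{row.repName} {cf} 1 {row.end - row.start} (0) {i}\n"
            )


def write_repeat_bed(path, repeats: pd.DataFrame) -> None:
    """6-column BED plus repName/repFamily/repClass columns (0-based half-open)."""
    out = repeats[["chrom", "start", "end", "repName", "strand", "repFamily", "repClass"]].copy()
    out.insert(4, "score", 0)
    out.columns = ["chrom", "start", "end", "name", "score", "strand", "repFamily", "repClass"]
    out.insert(6, "repName", out["name"])
    out.to_csv(path, sep="\t", header=False, index=False)


def write_gene_gtf(path, genes: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}"; gene_role "{row.gene_role}";'
            fh.write(
                f"{row.chrom}\ttoy\tgene\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )
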