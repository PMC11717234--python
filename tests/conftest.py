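import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from blastoseq import simdata, te_quant

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config():
    return simdata.SimConfig(seed=7)


@pytest.fixture(scope="session")
def annotation(sim_config):
    return simdata.make_toy_annotation(sim_config)


@pytest.fixture(scope="session")
def repeat_elements(annotation):
    return [
        te_quant.RepeatElement(
            r.chrom, int(r.start), int(r.end), r.strand, r.repName, r.repFamily, r.repClass
        )
        for r in annotation.repeats.itertuples(index=False)
    ]


def random_annotation(rng, n_repeats=50, n_genes=20, chrom_len=100_000, n_chroms=2):
    """Unconstrained random intervals (overlaps allowed) for oracle checks."""
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    fams = [("R%02d" % i, "F%d" % (i % 5), "LTR") for i in range(10)]
    reps = []
    for _ in range(n_repeats):
        c = chroms[rng.integers(0, n_chroms)]
        s = int(rng.integers(0, chrom_len - 2000))
        e = s + int(rng.integers(200, 2000))
        name, fam, cls = fams[rng.integers(0, len(fams))]
        reps.append(te_quant.RepeatElement(c, s, e, "+", name, fam, cls))
    genes = pd.DataFrame(
        {
            "chrom": [chroms[rng.integers(0, n_chroms)] for _ in range(n_genes)],
            "start": [int(rng.integers(0, chrom_len - 5000)) for _ in range(n_genes)],
        }
    )
    genes["end"] = genes.start + rng.integers(1000, 5000, size=n_genes)
    genes["gene_id"] = [f"g{i}" for i in range(n_genes)]
    return reps, genes


def random_fragments(rng, n, chrom_len=100_000, n_chroms=2):
    frags = []
    for i in range(n):
        c = f"chr{rng.integers(0, n_chroms) + 1}"
        s = int(rng.integers(0, chrom_len - 1000))
        l1 = int(rng.integers(30, 150))
        gap = int(rng.integers(0, 300))
        l2 = int(rng.integers(30, 150))
        frags.append(
            te_quant.AlignedFragment(f"f{i}", c, (s, s + l1), (s + l1 + gap, s + l1 + gap + l2))
        )
    return frags


def brute_force_filter(fragments, repeats, genes):
    """Naive O(F x E x G) reference for the containment/no-gene-overlap rule."""
    kept = []
    for f in fragments:
        ok = True
        for mate in (f.mate1, f.mate2):
            contained = any(
                e.chrom == f.chrom and e.start <= mate[0] and e.end >= mate[1] for e in repeats
            )
            overlaps_gene = any(
                g.chrom == f.chrom and max(g.start, mate[0]) < min(g.end, mate[1])
                for g in genes.itertuples(index=False)
            )
            if not contained or overlaps_gene:
                ok = False
                break
        if ok:
            kept.append(f)
    return kept
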