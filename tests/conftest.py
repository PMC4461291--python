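import numpy as np
import pytest

from cubkit import (
    SyntheticSpec,
    cai_weights,
    composition_table,
    count_codons,
    filter_cds,
    generate_genome,
    indices_table,
    pool_counts,
    standard_code,
)
from cubkit.cds_io import CdsRecord, CodonCounts


@pytest.fixture(scope="session")
def code():
    return standard_code()


def make_gene(codon_multiset, gene_id="g", start=True, stop="TAA"):
    """Build a CdsRecord from an explicit codon list."""
    seq = ("ATG" if start else "") + "".join(codon_multiset) + (stop or "")
    return CdsRecord(id=gene_id, sequence=seq)


def counts_from(codon_count_map, gene_id="g"):
    """CodonCounts directly from a codon -> count map (no sequence)."""
    return CodonCounts(gene_id=gene_id, counts=dict(codon_count_map))


def random_gene_counts(rng, code, max_count=30):
    """Random non-negative counts over the sense codons (some zero)."""
    counts = {}
    for c in code.sense_codons:
        if rng.random() < 0.7:
            counts[c] = int(rng.integers(0, max_count + 1))
    return counts_from({c: n for c, n in counts.items() if n > 0})


@pytest.fixture(scope="session")
def tiered_genome(code):
    """One 2,000-gene synthetic genome with the default expression tier.

    Session-scoped because several analyses (tail selection, optimal-codon
    recovery, correlations) share it.
    """
    spec = SyntheticSpec(n_genes=2000, seed=11)
    records, truth = generate_genome(spec)
    kept, _ = filter_cds(records)
    counts = [count_codons(r) for r in kept]
    pooled = pool_counts(counts, "genome")
    weights = cai_weights(pooled)
    idx = indices_table(counts, weights)
    return {
        "spec": spec,
        "records": kept,
        "truth": truth,
        "counts": counts,
        "pooled": pooled,
        "weights": weights,
        "indices": idx,
    }


@pytest.fixture(scope="session")
def small_composition(tiered_genome):
    return composition_table(tiered_genome["counts"][:300])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
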