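import pytest

from plastrep.synthetic import (
    LargeIRSpec,
    PlantedIR,
    PlantedTR,
    SyntheticSpec,
    generate_genome,
)


@pytest.fixture(scope="session")
def ctobin_like():
    """Chloroplast-scale synthetic genome mirroring the published census of
    the C. tobin plastid: 16 planted inverted repeats (stems ~25 bp, loops
    ~6 bp), one 15-bp duplicated tandem repeat, and a 4656 bp ribosomal IR
    whose copies differ by 6 SNPs in 16S and 5 in 23S, with the tRNA-Ala /
    tRNA-Ile spacer arrangement."""
    spec = SyntheticSpec(
        seed=11,
        genome_length=60000,
        gc=0.363,
        planted_irs=tuple(PlantedIR(stem=25, loop=6) for _ in range(16)),
        planted_trs=(PlantedTR(period=15, copies=2),),
        large_ir=LargeIRSpec(length=4656, snps_16s=6, snps_23s=5, isr_layout="ctobin"),
        n_genes=30,
        group="CASH",
        genome_id="ctobin_cp_like",
    )
    return generate_genome(spec)


@pytest.fixture(scope="session")
def bfs_tables():
    """Exact reversal distances by BFS for all signed permutations n <= 6."""
    from plastrep.gene_order import bfs_distance_table

    return {n: bfs_distance_table(n) for n in range(1, 7)}


@pytest.fixture(scope="session")
def bfs_table_n7():
    """Exact reversal distances for all signed permutations of length 7."""
    from plastrep.gene_order import bfs_distance_table

    return bfs_distance_table(7)
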