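import pytest

from pirnadev import smallrna_io as sio
from pirnadev import synthetic_data as syn


@pytest.fixture(scope="session")
def toy_genome():
    spec = syn.ToyGenomeSpec(
        (
            syn.RegionSpec("cluster", 5000, "dual_strand_cluster"),
            syn.RegionSpec("subtelomere", 2000, "subtelomere"),
            syn.RegionSpec("transgene", 1500, "transgene"),
        ),
        seed=7,
    )
    return syn.make_toy_genome(spec)


@pytest.fixture(scope="session")
def small_cluster():
    """A single 2-kb dual-strand cluster; cheap to align against."""
    spec = syn.ToyGenomeSpec(
        (syn.RegionSpec("cluster", 2000, "dual_strand_cluster"),), seed=13
    )
    return syn.make_toy_genome(spec)


def simulate_and_align(genome, spec, max_mismatch=1):
    """simulate -> trim -> collapse -> align; returns (reads, hits, truth)."""
    records, truth = syn.simulate_library(genome, spec)
    inserts = []
    for rec in records:
        res = sio.trim_adapter(rec.sequence, spec.adapter)
        assert res, res.reason
        inserts.append(res.insert)
    reads = sio.collapse_reads(inserts)
    hits = sio.match_reads(reads, genome, max_mismatch)
    return {r.read_id: r for r in reads}, hits, truth


@pytest.fixture(scope="session")
def aligned_library(toy_genome):
    """A 10^4-read library with ping-pong pairs, multimappers and 1U bias,
    pushed through trim/collapse/align once for the whole session."""
    spec = syn.PiRnaLibrarySpec(
        n_reads=10_000,
        pingpong_fraction=0.4,
        u1_bias=0.8,
        multimap_rate=0.05,
        seed=42,
    )
    reads, hits, truth = simulate_and_align(toy_genome, spec)
    return {"spec": spec, "reads": reads, "hits": hits, "truth": truth}
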