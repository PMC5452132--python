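import numpy as np
import pytest

from chloredit import synthetic_data as synth


@pytest.fixture(scope="session")
def genome_set():
    return synth.generate_genome_set(
        synth.GenomeConfig(
            cp_length=4000,
            n_genes=5,
            cds_length=300,
            n_trnas=2,
            trna_length=60,
            nuclear_length=5000,
            mito_length=3000,
            n_shared_kmers=1,
            seed=1,
        )
    )


@pytest.fixture(scope="session")
def sites(genome_set):
    return synth.generate_site_table(
        genome_set, 4, {"control": 0.8, "salt": 0.5}, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def hamming_scan(read: str, targets: dict[str, str], max_mismatch: int):
    """Independent brute-force oracle: every offset of every target,
    positional mismatch count, best stratum."""
    hits = []
    for tid in sorted(targets):
        tseq = targets[tid]
        for off in range(0, len(tseq) - len(read) + 1):
            mm = sum(1 for a, b in zip(read, tseq[off : off + len(read)]) if a != b)
            if mm <= max_mismatch:
                hits.append((tid, off, mm))
    if not hits:
        return []
    best = min(h[2] for h in hits)
    return sorted(h for h in hits if h[2] == best)
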