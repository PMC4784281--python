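import numpy as np
import pytest
from hypothesis import settings

import dropcirc as dc

settings.register_profile("dropcirc", database=None, deadline=None)
settings.load_profile("dropcirc")


def reads_iter(reads: dc.SimReads):
    """Adapt a SimReads bundle to the process_reads input shape."""
    return list(zip(reads.ids, reads.r1_seq, reads.r1_qual, reads.r2_seq, reads.r2_qual))


@pytest.fixture(scope="session")
def small_genome() -> str:
    return dc.generate_reference(20_000, seed=101)


@pytest.fixture(scope="session")
def nonoise_run():
    """A small no-noise 1:1 run processed end to end (shared across tests)."""
    cfg = dc.SimConfig(
        genome_length=8_000, n_snps=20, n_indels=0, mixture_ratio=(1, 1),
        n_molecules=1500, n_droplets=500, n_read_pairs=1200,
        deamination_rate=0.0, polymerase_error_rate=0.0, seq_error_rate=0.0,
        seed=42,
    )
    ref = dc.generate_reference(cfg.genome_length, cfg.seed)
    minor, variants = dc.derive_strain(ref, cfg.n_snps, cfg.n_indels, cfg.seed + 1)
    reads, truth = dc.simulate_run(cfg, ref, minor, variants)
    mapped, inter, counters = dc.process_reads(reads_iter(reads), ref)
    return {
        "cfg": cfg, "ref": ref, "minor": minor, "variants": variants,
        "reads": reads, "truth": truth, "mapped": mapped,
        "intermediates": inter, "counters": counters,
    }
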