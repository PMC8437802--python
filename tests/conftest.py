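import numpy as np
import pandas as pd
import pytest

from pirnascape.io import AlignedRead, GenomeModel
from pirnascape.simulate import hamster_like, simulate_study


def make_read(read_id="r1", chrom="chr1", start=100, length=28, strand="+",
              n_hits=1, mismatches=0, is_primary=True, clipped5=False,
              sequence=None):
    """AlignedRead helper: coordinates derived from 5'-anchored placement."""
    end = start + length
    return AlignedRead(read_id=read_id, chrom=chrom, start=start, end=end,
                       strand=strand, read_length=length, n_hits=n_hits,
                       mismatches=mismatches, is_primary=is_primary,
                       clipped5=clipped5, sequence=sequence)


@pytest.fixture
def small_genome():
    return GenomeModel(chrom_names=["chr1", "chr2"],
                       chrom_lengths={"chr1": 10_000, "chr2": 5_000})


@pytest.fixture(scope="session")
def hamster_study(tmp_path_factory):
    """One full default-config synthetic study, shared across tests."""
    outdir = tmp_path_factory.mktemp("hamster") / "study"
    simulate_study(hamster_like(seed=7), outdir)
    return outdir


@pytest.fixture(scope="session")
def hamster_truth(hamster_study):
    return {
        "clusters": pd.read_csv(hamster_study / "truth" / "clusters.tsv", sep="\t"),
        "te_groups": pd.read_csv(hamster_study / "truth" / "te_groups.tsv", sep="\t"),
        "totals": pd.read_csv(hamster_study / "truth" / "library_totals.tsv", sep="\t"),
    }
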