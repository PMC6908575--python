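import numpy as np
import pandas as pd
import pytest

from imprintscan import MethylomeTrack, Region


def make_track(sample, sites):
    """sites: iterable of (chrom, pos, count_meth, count_unmeth)."""
    df = pd.DataFrame(sites, columns=["chrom", "pos", "count_meth", "count_unmeth"])
    return MethylomeTrack(sample, df)


def uniform_track(sample, fraction, n=10, chrom="chr1", start=100, spacing=10, coverage=20):
    m = int(round(fraction * coverage))
    return make_track(sample, [(chrom, start + i * spacing, m, coverage - m)
                               for i in range(n)])


@pytest.fixture
def region():
    return Region("chr1", 0, 10_000, name="r1", gene_strand="+")


@pytest.fixture
def tissue_panel():
    """Tracks matching the canonical igDMR profile over one region."""
    return {
        "oocyte": uniform_track("oocyte", 0.9),
        "sperm": uniform_track("sperm", 0.05),
        "blastocyst": uniform_track("blastocyst", 0.45),
        "placenta": uniform_track("placenta", 0.50),
    }


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Deterministic synthetic bundle in the noise-free limit (shared)."""
    from imprintscan import SimulationConfig, simulate_annotation, simulate_methylomes

    cfg = SimulationConfig(seed=1, n_regions=200).noise_free()
    bundle = simulate_annotation(cfg)
    tracks = simulate_methylomes(bundle, cfg)
    return bundle, tracks
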