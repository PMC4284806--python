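import numpy as np
import pytest

from methylseries.core import SampleSeries, SiteMatrix
from methylseries.dmr import ARCHETYPE_LABELS
from methylseries.simulate import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def series() -> SampleSeries:
    """Compact 6-sample series used by unit tests."""
    return SampleSeries(
        labels=("MEF", "D2", "D8", "F1", "IPS", "ESC"),
        baseline_label="MEF",
        esc_like_labels=("IPS", "ESC"),
        fclass_labels=("F1",),
    )


@pytest.fixture(scope="session")
def small_bundle():
    """One moderately sized simulated bundle shared across tests."""
    cfg = SimConfig(
        seed=7,
        n_cpgs=15_000,
        chrom_length=3_000_000,
        n_islands=12,
        dmr_counts={k: 10 for k in ARCHETYPE_LABELS},
        genes_per_class=6,
        n_unclassified_genes=12,
        tf_sites_per_factor=6,
    )
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def small_site_matrix(small_bundle):
    from methylseries.calling import add_levels, estimate_error_rate
    from methylseries.core import stack_methylomes

    mets = [
        add_levels(m, estimate_error_rate(small_bundle.spikeins[m.sample_label]))
        for m in small_bundle.methylomes
    ]
    return stack_methylomes(mets, small_bundle.series)


def make_site_matrix(pos, levels, samples, depth=30, chrom="chr1") -> SiteMatrix:
    """Deterministic SiteMatrix where counts exactly reflect the levels."""
    pos = np.asarray(pos, dtype=np.int64)
    levels = np.asarray(levels, dtype=float)
    n, s = levels.shape
    assert len(pos) == n and len(samples) == s
    total = np.full((n, s), depth, dtype=np.int64)
    meth = np.rint(levels * depth).astype(np.int64)
    return SiteMatrix(
        chrom=np.asarray([chrom] * n, dtype=object),
        pos=pos,
        meth=meth,
        total=total,
        levels=levels.copy(),
        samples=list(samples),
    )
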