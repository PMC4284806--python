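"""Spike-in calibrated methylcytosine calling.

Simulates a methylome in which 70% of CpGs are methylated at level 0.8 and
the rest are unmethylated, with a 0.5% bisulfite nonconversion rate, then
calibrates the binomial call threshold from an unmethylated spike-in and
calls methylcytosines. The printed false-positive fraction is the share of
calls landing on truly unmethylated CpGs — the calibration keeps it under
the 1%-of-calls control.
"""

import numpy as np
import pandas as pd

from methylseries import Methylome, SpikeInControl
from methylseries.calling import (
    calibrate_call_threshold,
    call_methylcytosines,
    estimate_error_rate,
)

rng = np.random.default_rng(0)
n = 50_000
nonconversion = 0.005

methylated = rng.random(n) < 0.7
level = np.where(methylated, 0.8, 0.0)
depth = rng.poisson(30, n)
meth = rng.binomial(depth, level + (1 - level) * nonconversion)
methylome = Methylome(
    "demo",
    pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(n) * 100, "meth_count": meth, "total_count": depth}
    ),
)

spike = SpikeInControl(100_000, int(rng.binomial(100_000, nonconversion)))
p = estimate_error_rate(spike)
table = calibrate_call_threshold(methylome, p)
calls = call_methylcytosines(methylome.with_rates(p), table)

fp = int((calls.called & ~methylated).sum())
print(f"spike-in error rate p = {p:.5f} (conversion rate {1 - p:.5f})")
print(f"tail cutoff M = {table.p_cutoff:.4g}; k_min at depth 30 = {table.k_min(30)}")
print(f"{calls.n_called} of {n} sites called methylated")
print(f"false-positive fraction among calls = {fp / calls.n_called:.4%} (control: <= 1%)")
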