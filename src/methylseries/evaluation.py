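"""Ground-truth evaluation experiments on synthetic methylomes.

Each function generates its own inputs from a seed, runs the pipeline
end to end and measures performance against the generator's manifest:
false-positive control of the methylcytosine caller, null calibration and
planted-region recovery of the DMR caller, focal-vs-broad kernel width
recovery, and expression-class round trips.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import (
    add_levels,
    calibrate_call_threshold,
    call_methylcytosines,
    estimate_error_rate,
)
from .core import FeatureSet, Methylome, SiteMatrix, stack_methylomes
from .dmr import find_dmrs, mark_differential, scan_windows
from .genes import GeneEpigenomeState, assign_expr_class, gene_records
from .simulate import SimConfig, SimBundle, simulate_bundle
from .tfbs import _site_level_matrix, half_width_at_half_depth, neighborhood_profile

__all__ = [
    "null_caller_fp_experiment",
    "called_site_matrix",
    "dmr_null_experiment",
    "dmr_recovery_experiment",
    "tfbs_kernel_experiment",
    "expr_roundtrip_experiment",
]


def null_caller_fp_experiment(
    seed: int,
    n_sites: int = 100_000,
    depth_mean: float = 30.0,
    nonconversion: float = 0.005,
    spike_total: int = 100_000,
) -> dict:
    """Run calibrate + call on a fully unmethylated methylome.

    Every call would be a false positive; the scan must keep the expected
    error-driven fraction of calls below the configured 1%. Returns the
    calibration-predicted false-positive percentage among calls
    (M * n_uncalled / n_called * 100; zero when nothing is called), the
    realized call rate, and call counts.
    """
    rng = np.random.default_rng(seed)
    depth = rng.poisson(depth_mean, n_sites)
    meth = rng.binomial(depth, nonconversion)
    m = Methylome(
        "null",
        pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(n_sites, dtype=np.int64) * 100,
                "meth_count": meth,
                "total_count": depth,
            }
        ),
    )
    from .calling import SpikeInControl

    spike = SpikeInControl(spike_total, int(rng.binomial(spike_total, nonconversion)))
    p = estimate_error_rate(spike)
    table = calibrate_call_threshold(m, p)
    calls = call_methylcytosines(m.with_rates(p), table)
    tested = int((depth > 0).sum())
    n_called = calls.n_called
    predicted_fp_pct = (
        100.0 * table.p_cutoff * (tested - n_called) / n_called if n_called else 0.0
    )
    return {
        "n_sites": n_sites,
        "n_called": n_called,
        "predicted_fp_pct": predicted_fp_pct,
        "realized_call_rate_pct": 100.0 * n_called / tested,
        "error_rate": p,
        "p_cutoff": table.p_cutoff,
    }


def called_site_matrix(bundle: SimBundle) -> SiteMatrix:
    """Spike-in calibrate every sample and stack adjusted levels."""
    mets = []
    for m in bundle.methylomes:
        p = estimate_error_rate(bundle.spikeins[m.sample_label])
        mets.append(add_levels(m, p))
    return stack_methylomes(mets, bundle.series)


def dmr_null_experiment(seed: int, n_cpgs: int = 50_000) -> dict:
    """Window scan on a series with nothing planted: the fraction of tested
    windows passing all filters estimates the empirical false-window rate."""
    bundle = simulate_bundle(SimConfig.null(seed=seed, n_cpgs=n_cpgs))
    sm = called_site_matrix(bundle)
    scan = mark_differential(scan_windows(sm))
    n = len(scan.table)
    flagged = int(scan.table["differential"].sum())
    return {
        "n_windows": n,
        "n_flagged": flagged,
        "flagged_fraction": flagged / n if n else 0.0,
    }


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def dmr_recovery_experiment(seed: int, config: SimConfig | None = None) -> dict:
    """Recall/precision of planted-region recovery and trajectory-cluster
    agreement (ARI) on the standard study conditions."""
    from sklearn.metrics import adjusted_rand_score

    bundle = simulate_bundle(config if config is not None else SimConfig(seed=seed))
    sm = called_site_matrix(bundle)
    _, dmrs = find_dmrs(sm, bundle.series)
    truth = bundle.truth.dmr_regions
    diff_truth = bundle.truth.differential_regions

    recall = float(
        np.mean(
            [
                any(
                    _overlaps(r.start, r.end, d.interval.start, d.interval.end)
                    for d in dmrs
                )
                for r in truth.itertuples(index=False)
            ]
        )
    )
    precision = float(
        np.mean(
            [
                any(
                    _overlaps(d.interval.start, d.interval.end, r.start, r.end)
                    for r in diff_truth.itertuples(index=False)
                )
                for d in dmrs
            ]
        )
    ) if dmrs else 0.0
    pairs = []
    for d in dmrs:
        hits = [
            r.label
            for r in truth.itertuples(index=False)
            if _overlaps(d.interval.start, d.interval.end, r.start, r.end)
        ]
        if hits:
            pairs.append((d.cluster_id, hits[0]))
    ari = (
        float(adjusted_rand_score([p[1] for p in pairs], [p[0] for p in pairs]))
        if len(pairs) >= 2
        else 0.0
    )
    return {
        "n_dmrs": len(dmrs),
        "n_truth": len(truth),
        "recall": recall,
        "precision": precision,
        "ari": ari,
    }


def tfbs_kernel_experiment(
    seed: int, intermediate_label: str = "D8H", esc_label: str = "ESC"
) -> dict:
    """Half-width of the demethylation dip around an early-activated factor's
    sites in an intermediate vs an ESC-like sample."""
    bundle = simulate_bundle(SimConfig(seed=seed))
    sm = called_site_matrix(bundle)
    factor = bundle.layout.tf_truth[bundle.layout.tf_truth["mode"] == "active_early"][
        "factor"
    ].iloc[0]
    prof = neighborhood_profile(bundle.tf_sites[factor], sm, bundle.series)
    j_int = prof.samples.index(intermediate_label)
    j_esc = prof.samples.index(esc_label)
    hw_int = half_width_at_half_depth(prof.delta_matrix[:, j_int], prof.bin_width)
    hw_esc = half_width_at_half_depth(prof.delta_matrix[:, j_esc], prof.bin_width)
    ratio = hw_esc / hw_int if hw_int and hw_esc else float("nan")
    return {
        "factor": factor,
        "half_width_intermediate_bp": hw_int,
        "half_width_esc_bp": hw_esc,
        "ratio": ratio,
    }


def expr_roundtrip_experiment(seed: int, config: SimConfig | None = None) -> dict:
    """Fraction of class-labelled genes recovered by the rule cascade from
    simulated expression plus measured promoter methylation."""
    bundle = simulate_bundle(config if config is not None else SimConfig(seed=seed))
    sm = called_site_matrix(bundle)
    genes = bundle.layout.genes
    records = gene_records(genes[["gene_id", "chrom", "strand", "start", "end"]])
    prom_lv = _site_level_matrix(
        FeatureSet("promoters", [g.promoter for g in records]), sm
    )
    n_ok = 0
    n_tot = 0
    for i, g in enumerate(records):
        truth_cls = genes.iloc[i]["class_label"]
        if truth_cls == "unclassified":
            continue
        state = GeneEpigenomeState(
            gene_id=g.gene_id,
            promoter_meth_by_sample={
                lab: float(prom_lv[i, j]) for j, lab in enumerate(sm.samples)
            },
            fpkm_by_sample={
                lab: float(bundle.expression.loc[g.gene_id, lab])
                for lab in bundle.series.labels
            },
        )
        got = assign_expr_class(state, bundle.series).class_label
        n_tot += 1
        n_ok += got == truth_cls
    return {"n_genes": n_tot, "n_correct": n_ok, "recovery": n_ok / n_tot if n_tot else 0.0}
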