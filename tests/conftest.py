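"""Shared fixtures. The expensive end-to-end computations (reduced
hierarchical fit, recovery replicates, joint-model rho sweep, full EEG
pipeline) are session-scoped so that module tests and the acceptance
checks assert against a single computation."""

import numpy as np
import pandas as pd
import pytest

from jointddm import demcmc, eeg, joint, prep, studies, synthetic
from jointddm.model import HierarchicalDDM
from jointddm.synthetic import GroundTruth


@pytest.fixture(scope="session")
def reduced_fit():
    """Hierarchical fit of a reduced synthetic study: 8 participants per
    group, 60 trials per difficulty, 15 chains, 1000 iterations."""
    result, model, data = studies.reduced_synthetic_fit(seed=1)
    return result, model, data


@pytest.fixture(scope="session")
def small_tables():
    """A small behaviour table + participant truth reused by cheap tests."""
    truth = GroundTruth(seed=11)
    parts = synthetic.generate_participants(4, truth)
    design = prep.build_design("motion_coherence", blocks=1, repetitions=6,
                               catch_per_block=2)
    beh = synthetic.generate_behaviour(parts, design, seed=12)
    table, report = prep.filter_trials(beh)
    return {"truth": truth, "participants": parts, "design": design,
            "behaviour": beh, "table": table, "report": report}


@pytest.fixture(scope="session")
def recovery_suite():
    """20 replicate hierarchical fits with true group-level means and
    offsets drawn from their priors (spreads at the generator defaults);
    returns per-replicate truth and 95% CI bounds for mu and delta."""
    rows = []
    for rep in range(20):
        rng = np.random.default_rng(5000 + rep)
        means = {
            "a": float(_draw_trunc(rng, 0.2, 0.2, lo=0.0)),
            "z": float(_draw_trunc(rng, 0.5, 0.2, lo=0.0, hi=1.0)),
            "ter": float(_draw_trunc(rng, 0.3, 0.3, lo=0.0)),
            "v_diff": float(rng.normal(0.0, 0.1)),
            "v_mean": float(rng.normal(0.3, 0.3)),
        }
        offsets = {k: float(rng.normal(0.0, 0.01)) for k in means}
        truth = GroundTruth(hyper_means=means, group_offsets=offsets,
                            seed=6000 + rep)
        parts = synthetic.generate_participants(6, truth, rng=rng)
        design = prep.build_design("motion_coherence", blocks=2,
                                   repetitions=6, catch_per_block=0)
        beh = synthetic.generate_behaviour(parts, design, rng=rng)
        table, _ = prep.filter_trials(beh)
        model = HierarchicalDDM(table)
        sched = demcmc.SamplerSchedule(iterations=600, burn_in=250,
                                       migration_interval=14,
                                       migration_window=(60, 300))
        result = demcmc.fit(model, sched, n_chains=12, seed=7000 + rep)
        post = result.posterior()
        for i, k in enumerate(("a", "z", "ter", "v_diff", "v_mean")):
            for kind, true_val, idx in (("mu", means[k], i),
                                        ("delta", offsets[k], 10 + i)):
                lo, hi = np.percentile(post[:, idx], [2.5, 97.5])
                rows.append({"rep": rep, "parameter": f"{kind}_{k}",
                             "true": true_val, "lo": lo, "hi": hi,
                             "covered": lo <= true_val <= hi})
    return pd.DataFrame(rows)


def _draw_trunc(rng, loc, sd, lo=-np.inf, hi=np.inf):
    while True:
        x = rng.normal(loc, sd)
        if lo < x < hi:
            return x


@pytest.fixture(scope="session")
def joint_rho_sweep():
    """Joint EEG fits across target correlations {-0.5, 0, 0.5}, six
    replicates each; returns posterior means of the shared rho_mean."""
    rows = []
    design = prep.build_design("motion_coherence", blocks=2, repetitions=10,
                               catch_per_block=0)
    sched = demcmc.SamplerSchedule(iterations=800, burn_in=300,
                                   migration_interval=14,
                                   migration_window=(80, 400))
    for rep in range(6):
        for rho in (-0.5, 0.0, 0.5):
            truth = GroundTruth(seed=3000 + rep, rho_eeg=rho)
            rng = np.random.default_rng(3100 + rep)
            parts = synthetic.generate_participants(12, truth, rng=rng)
            beh = synthetic.generate_behaviour(parts, design, rng=rng)
            table, _ = prep.filter_trials(beh)
            slopes = synthetic.generate_slope_measures(parts, truth, rng=rng)
            model = joint.JointEEGModel(table, slopes)
            res = joint.fit_joint(model, sched, n_chains=12, seed=3200 + rep)
            rows.append({"rep": rep, "rho": rho,
                         "post_mean": float(res.draws("rho_mean").mean()),
                         "max_psrf": float(res.psrf().max())})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def pipeline_recovery():
    """Full EEG pipeline (pooled RCA -> projection -> deconvolution ->
    slopes) on 50 synthetic participants at the default noise level."""
    truth = GroundTruth(seed=42)
    parts = synthetic.generate_participants(25, truth)
    design = prep.build_design("motion_coherence")
    beh = synthetic.generate_behaviour(parts, design, seed=43)
    recs, true_slopes = synthetic.generate_eeg(parts, beh, truth=truth, seed=44)
    table = eeg.compute_slopes(recs, ridge_lambda=None)
    merged = table.merge(true_slopes, on="participant",
                         suffixes=("_rec", "_true"))
    return merged
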