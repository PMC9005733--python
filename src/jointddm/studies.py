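"""Pre-packaged study recipes used by the examples and the acceptance
script: generate a synthetic study at a stated size, fit it, and report
diagnostics. Problem sizes here are desk-scale reductions of the full
protocol (which uses 4000 iterations with 1500 burn-in and 152 trials per
task); see docs/methods.md."""

from __future__ import annotations

import numpy as np

from . import demcmc, prep, synthetic
from .model import HierarchicalDDM

__all__ = ["reduced_synthetic_fit"]


def reduced_synthetic_fit(seed: int = 1, n_per_group: int = 8,
                          trials_per_difficulty: int = 60,
                          n_chains: int = 15, iterations: int = 1000,
                          burn_in: int = 400):
    """Generate behaviour from the hierarchical model (group-level means at
    the analysis-prior locations, spreads at the generator defaults, no
    group difference) and fit it with DE-MCMC with early-window migration.

    Returns ``(result, model, data)``; ``result.psrf()`` gives the
    Gelman-Rubin diagnostic for every sampled parameter.
    """
    truth = synthetic.GroundTruth(seed=int(seed))
    reps = max(trials_per_difficulty // 4, 1)
    design = prep.build_design("motion_coherence", blocks=2, repetitions=reps,
                               catch_per_block=0)
    rng = np.random.default_rng(int(seed))
    participants = synthetic.generate_participants(n_per_group, truth, rng=rng)
    behaviour = synthetic.generate_behaviour(participants, design, rng=rng)
    table, report = prep.filter_trials(behaviour, rt_floor=design.rt_floor,
                                       deadline=design.deadline)
    model = HierarchicalDDM(table, deadline=design.deadline)
    schedule = demcmc.SamplerSchedule(
        iterations=iterations, burn_in=burn_in, migration_interval=14,
        migration_window=(iterations // 10, iterations // 2))
    result = demcmc.fit(model, schedule, n_chains=n_chains, seed=int(seed) + 1)
    data = {"participants": participants, "behaviour": table,
            "report": report, "truth": truth, "design": design}
    return result, model, data
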