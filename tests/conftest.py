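"""Shared fixtures.

The two heavy fixtures run the full EEG pipeline once per session and
are reused across recognition, free-energy and acceptance tests:

* ``snr_battery`` — one 240-trial participant analyzed at each SNR in
  {0, 1, 2, 4, 5} with 50 classifier repeats;
* ``cohort_run`` — a 40-participant synthetic task cohort analyzed at
  20 classifier repeats.
"""

from __future__ import annotations

import numpy as np
import pytest

from brainfe.pipeline import run_participant, run_task_cohort
from brainfe.synthetic import CohortConfig, simulate_behavior, simulate_epochs


@pytest.fixture(scope="session")
def snr_battery():
    """Pipeline results for one participant across SNR levels."""
    results = {}
    for snr in (0.0, 1.0, 2.0, 4.0, 5.0):
        cfg = CohortConfig(n_trials=240, p=0.7, lapse=0.0, snr=snr, n_channels=32, master_seed=11)
        rng = np.random.default_rng(101)
        nu = rng.permutation(np.repeat([1, 2], cfg.n_trials // 2))
        trials = simulate_behavior(nu, p=cfg.p, lapse=0.0, rng_seed=202, nonresponse_rate=0.01)
        epochs = simulate_epochs(trials, cfg, rng_seed=303)
        res = run_participant(epochs.trials, epochs, n_repeats=50, rng_seed=404)
        results[snr] = {"trials": epochs.trials, "result": res}
    return results


@pytest.fixture(scope="session")
def cohort_run():
    """Analyzed 40-participant synthetic cohort (II-task conditions)."""
    cfg = CohortConfig(
        n_participants=40, n_trials=240, p=0.72, p_spread=0.15, snr=2.0, master_seed=17
    )
    return run_task_cohort(cfg, task="II", n_repeats=20)
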