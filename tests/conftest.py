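import numpy as np
import pytest

import wmconn as w

ALPHA = w.Band("alpha", 8.0, 14.0)
THETA = w.Band("theta", 4.0, 7.0)


def make_analytic(z, fs=600.0, t0=0.0, band=ALPHA, labels=None):
    """Wrap a complex (trials, regions, samples) array as AnalyticEpochs."""
    z = np.asarray(z, dtype=complex)
    n = z.shape[-1]
    time = t0 + np.arange(n) / fs
    if labels is None:
        labels = np.array(["correct"] * z.shape[0])
    return w.AnalyticEpochs(
        data=z, time=time, sampling_rate=fs, trial_labels=labels, band=band
    )


def make_epochs(x, fs=600.0, t0=-1.0, labels=None, **kw):
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    time = t0 + np.arange(n) / fs
    if labels is None:
        labels = np.array(["correct"] * x.shape[0])
    return w.SourceEpochs(
        data=x, time=time, sampling_rate=fs, trial_labels=labels, **kw
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-group cohort with a fully coupled alpha edge in the FT group."""
    cfg = w.SimulationConfig(
        n_regions=6,
        n_trials_per_condition=20,
        groups=(w.GroupSpec("FT", 2), w.GroupSpec("VPT", 2)),
        bands=(ALPHA,),
        planted_networks=(
            w.PlantedNetwork("alpha", ((0, 1),), kappa=1.0, group="FT"),
        ),
        master_seed=99,
    )
    return cfg, w.make_cohort(cfg)
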