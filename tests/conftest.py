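import numpy as np
import pytest

import ctpc


@pytest.fixture(scope="session")
def default_traits() -> ctpc.TrueTraits:
    """One individual's generative truth: optimum at 44 C, flatline at 52 C."""
    return ctpc.TrueTraits(
        r_tref=60.0, E=0.8, Eh=4.0,
        Th=ctpc.th_for_topt(0.8, 4.0, 44.0), ULT_true=52.0,
    )


@pytest.fixture(scope="session")
def fast_ramp() -> ctpc.RampProtocol:
    """Cheap assay protocol for unit tests: 1 C/min at 20 Hz."""
    return ctpc.RampProtocol(start_C=30.0, end_C=65.0,
                             rate_C_per_min=1.0, sample_hz=20.0)


@pytest.fixture(scope="session")
def assay_ramp() -> ctpc.RampProtocol:
    """The full assay protocol: 0.25 C/min between 30 and 65 C at 40 Hz."""
    return ctpc.RampProtocol()


def run_trace_pipeline(trace, seed=0, smooth_s=0.15):
    """Smoothed-path single-individual chain used across tests."""
    sm = ctpc.bartlett_smooth(trace, max(smooth_s, 3.0 / trace.sample_hz))
    beats = ctpc.detect_beats(sm)
    series = ctpc.hr_series(beats, sm)
    flat = ctpc.detect_flatline(series)
    fit = ctpc.fit_ss(series, seed=seed, flatline=flat)
    return ctpc.extract_traits(fit, series, flat), series, flat


@pytest.fixture(scope="session")
def noisefree_series(default_traits, fast_ramp):
    """Heart-rate series recovered from a noise-free simulated trace."""
    trace = ctpc.simulate_trace(default_traits, fast_ramp, noise_sd=0.0, seed=7)
    beats = ctpc.detect_beats(trace)
    return ctpc.hr_series(beats, trace)


def synthetic_hr_series(params, temps=None, window_s=60.0, step_s=30.0):
    """Exact Sharpe-Schoolfield rate samples packaged as a HeartRateSeries."""
    if temps is None:
        temps = np.arange(30.0, 52.0, 0.5)
    temps = np.asarray(temps, dtype=float)
    hr = np.asarray(ctpc.ss_rate(params, temps), dtype=float)
    t_start = np.arange(len(temps)) * step_s
    return ctpc.HeartRateSeries(temps, hr, np.round(hr).astype(int),
                                t_start, window_s, step_s)
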