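import numpy as np
import pytest

import selt1

# Non-overlapping extraction windows for the in-cell preset peaks.
IN_CELL_WINDOWS = [
    selt1.PeakWindow("T8", 13.85, 14.05),
    selt1.PeakWindow("T9", 13.60, 13.80),
    selt1.PeakWindow("T4/T22/T18", 13.30, 13.50),
    selt1.PeakWindow("G20/G6", 12.70, 12.90),
    selt1.PeakWindow("G11", 12.05, 12.25),
]


@pytest.fixture
def acq():
    return selt1.AcquisitionConfig()


@pytest.fixture
def short_schedule():
    return selt1.delay_schedule_preset("short9")


@pytest.fixture
def long_schedule():
    return selt1.delay_schedule_preset("long9")


@pytest.fixture
def single_resonance():
    return selt1.ResonanceSpec("T4/T22/T18", 13.40, 25.0, A=3.0, selt1=84.0)


def noiseless_pipeline_selt1(resonances, schedule, recipe, windows,
                             peak_id=None):
    """Simulate noiselessly, process with one recipe, extract, fit.

    Returns dict peak_id -> fitted selT1 (unweighted fit; noiseless data
    carry no meaningful errors)."""
    acq = selt1.AcquisitionConfig()
    fids = selt1.simulate_experiment(resonances, acq, schedule)
    spectra = [selt1.run_recipe(f, recipe) for f in fids]
    table = selt1.locate_peaks(spectra[0], windows)
    series = selt1.extract_series(spectra, table)
    out = {pid: selt1.fit_recovery(s, weighted=False).selt1
           for pid, s in series.items()}
    if peak_id is not None:
        return out[peak_id]
    return out
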