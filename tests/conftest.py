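import numpy as np
import pytest

from cbctdose.geometry import build_ctdi_phantom
from cbctdose.spectrum import generate_spectrum
from cbctdose.transport import ScanProtocol, run_simulation

SEED = 20314


@pytest.fixture(scope="session")
def spectrum125():
    """Default study beam: 125 kVp, 2.5 mm inherent + 3 mm added Al."""
    return generate_spectrum(125, 3.0, 2.5)


def run_ctdi(kind, fan_mode, spectrum, n_histories, seed=SEED, mode="standard",
             n_batches=10):
    ctdi = build_ctdi_phantom(kind)
    ma, ms = (80, 25) if mode == "standard" else (40, 10)
    protocol = ScanProtocol(tube_current_ma=ma, pulse_time_ms=ms,
                            fan_mode=fan_mode, n_histories=n_histories,
                            n_batches=n_batches, seed=seed)
    dosemap = run_simulation(ctdi.phantom, protocol, spectrum,
                             regions=ctdi.scoring_masks)
    return ctdi, protocol, dosemap


@pytest.fixture(scope="session")
def head_run(spectrum125):
    """Head CTDI phantom, full-fan, standard mode, 2e6 histories."""
    return run_ctdi("head", "full", spectrum125, 2_000_000)


@pytest.fixture(scope="session")
def body_run(spectrum125):
    """Body CTDI phantom, half-fan, standard mode, 2e6 histories."""
    return run_ctdi("body", "half", spectrum125, 2_000_000)


def hole_doses(dosemap, estimator="kerma"):
    return {name: dosemap.region_dose(name, estimator)
            for name in ("center", "A", "B", "C", "D")}
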