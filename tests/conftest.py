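"""Shared fixtures: desk-scale cluster simulations and analytic dipoles.

The MD fixtures are session-scoped because they back several unit tests and
the acceptance suite; sizes (2 ps equilibration, 2 ps NVE segments) are the
package's reduced desk-scale protocol.
"""

import numpy as np
import pytest

from protir.cluster_sim import (
    ConfinementSpec,
    HopperSpec,
    SimParams,
    attach_proton_hopper,
    build_cluster,
    run_toy_md,
)
from protir.dipole_defect import ChargeModel, dipole_series
from protir.spectra import SpectralConfig, average_segments, smooth_gaussian, spectrum_from_dipole

SEED = 1


def make_segments(geometry: str, protonated: bool, n_segments: int = 4,
                  segment_time: float = 2.0, equil_time: float = 2.0,
                  n_waters: int | None = None, seed: int = SEED):
    spec = {
        "chain_narrow": ConfinementSpec.narrow_chain,
        "chain_wide": ConfinementSpec.wide_chain,
        "disc": ConfinementSpec.disc,
        "droplet": ConfinementSpec.droplet,
    }[geometry]()
    if n_waters is None:
        n_waters = 26 if geometry == "droplet" else 15
    params = SimParams(
        n_waters=n_waters, protonated=protonated, equil_time=equil_time,
        segment_time=segment_time, n_segments=n_segments, seed=seed,
    )
    return run_toy_md(build_cluster(spec, params), spec, params), params


def emulator_spectrum(segments, policy: str | None, seed: int = SEED,
                      sigma_nu: float = 50.0):
    """Averaged direction-resolved spectrum of molecular (+ defect) dipoles."""
    specs = []
    for k, seg in enumerate(segments):
        series = dipole_series(seg, ChargeModel.nuclear_effective())
        if policy is not None:
            series = series + attach_proton_hopper(
                seg, HopperSpec(policy=policy), seed=seed * 100 + k
            )
        specs.append(spectrum_from_dipole(series, SpectralConfig(sigma_nu=0.0)))
    return smooth_gaussian(average_segments(specs), sigma_nu)


@pytest.fixture(scope="session")
def chain_segments():
    segments, _ = make_segments("chain_narrow", protonated=True)
    return segments


@pytest.fixture(scope="session")
def neutral_chain_segments():
    segments, _ = make_segments("chain_narrow", protonated=False, n_segments=2)
    return segments


@pytest.fixture(scope="session")
def disc_segments():
    segments, _ = make_segments("disc", protonated=True)
    return segments


@pytest.fixture(scope="session")
def droplet_segments():
    segments, _ = make_segments("droplet", protonated=True)
    return segments


@pytest.fixture(scope="session")
def chain_spectrum(chain_segments):
    return emulator_spectrum(chain_segments, "chain")


@pytest.fixture(scope="session")
def disc_spectrum(disc_segments):
    return emulator_spectrum(disc_segments, "disc")


@pytest.fixture(scope="session")
def droplet_spectrum(droplet_segments):
    return emulator_spectrum(droplet_segments, "droplet")


@pytest.fixture(scope="session")
def thermostat_info():
    """10 ps thermostatted run of a 15-water chain; returns its diagnostics."""
    segments, _ = make_segments(
        "chain_narrow", protonated=False, n_segments=1,
        segment_time=0.05, equil_time=10.0,
    )
    return segments[0].info


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
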