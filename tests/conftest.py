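"""Shared fixtures: packaged tables, a small library, and a seeded run."""

from __future__ import annotations

import numpy as np
import pytest

from phytoms import synthetic_data as sd
from phytoms.spectra_io import Spectrum


@pytest.fixture(scope="session")
def tables():
    """(prototype records, metabolite records) from the packaged tables."""
    return sd.table_fixtures()


@pytest.fixture(scope="session")
def small_library(tables):
    """Five chemically distinct prototypes spanning three classes."""
    t1, _ = tables
    lib = [c for c in t1 if c.id in ("P2", "P17", "P26", "P33", "P37")]
    # generator-consistent reference fragments (noise-free template)
    clean = sd.SimulationConfig(seed=0, ms2_noise_fraction=0.0, mz_jitter_ppm_sd=0.0)
    for c in lib:
        spec = sd.simulate_spectrum(c, clean, np.random.default_rng(0))
        c.ms2_fragments = [float(m) for m in spec.mz if 80.0 < m < 1250.0]
    return lib


@pytest.fixture(scope="session")
def seeded_run(small_library):
    """One seeded acquisition with two planted metabolites and two decoys."""
    config = sd.SimulationConfig(seed=7, decoy_count=2)
    planted = [
        ("P17", "+CH2", ("dosed_plasma",)),
        ("P2", "+SO3", ("dosed_plasma",)),
    ]
    return sd.simulate_acquisition(small_library, config, planted)


def toy_spectrum(
    peaks, precursor_mz, polarity="negative", rt=5.0, spectrum_id="toy", charge=None
) -> Spectrum:
    charge = charge if charge is not None else (-1 if polarity == "negative" else 1)
    return Spectrum(
        id=spectrum_id,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        polarity=polarity,
        rt=rt,
        peaks=np.asarray(peaks, dtype=float),
    )
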