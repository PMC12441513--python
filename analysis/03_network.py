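#!/usr/bin/env python
"""Molecular networking over the extract features.

Builds the modified-cosine network (cosine >= 0.70, >= 6 matched
fragments), annotates nodes against an in-silico spectral library of
the eight prototypes, propagates class hypotheses through clusters, and
writes GraphML plus the cluster accounting to results/network/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phytoms import spectra_io, synthetic_data as sd
from phytoms.benchmark import _benchmark_library
from phytoms.feature_finder import Feature
from phytoms.networking import (
    annotate_with_library,
    build_network,
    network_stats,
    propagate_annotations,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "network"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(ROOT / "features" / "features_extract.csv")
    spectra = {s.id: s for s in spectra_io.read_mgf(ROOT / "features" / "features_extract.mgf")}
    feats = [
        Feature(id=r["id"], mz=r["mz"], rt_apex=r["rt_min"], height=r["height"],
                ms2=spectra.get(r["id"]))
        for _, r in df.iterrows()
    ]
    # split by polarity: modified cosine is defined within one ion mode
    for polarity in ("negative", "positive"):
        subset = [f for f in feats if f.ms2 and f.ms2.polarity == polarity]
        g = build_network(subset)
        clean = sd.SimulationConfig(seed=0, ms2_noise_fraction=0.0, mz_jitter_ppm_sd=0.0)
        library = [
            (c, sd.simulate_spectrum(c, clean, np.random.default_rng(0)))
            for c in _benchmark_library()
            if c.selected_adduct.polarity == polarity
        ]
        annotate_with_library(g, subset, library)
        propagate_annotations(g)
        stats = network_stats(g)
        spectra_io.write_graphml(g, OUT / f"network_{polarity}.graphml")
        pd.DataFrame([stats]).to_csv(OUT / f"stats_{polarity}.csv", index=False)
        print(f"{polarity}: {stats}")


if __name__ == "__main__":
    main()
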