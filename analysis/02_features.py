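#!/usr/bin/env python
"""Extract aligned MS2-bearing features from the simulated runs.

Runs the full feature-finder chain (chromatogram tracing, local-minimum
resolving, 13C filtering, MS2 pairing) per matrix, then join-aligns the
dosed samples.  Found features are written to results/features/.
"""

from dataclasses import replace
from pathlib import Path

import pandas as pd

from phytoms import spectra_io
from phytoms.feature_finder import FeatureFinderParams, find_features, join_align

ROOT = Path(__file__).resolve().parent.parent / "results"
RUN = ROOT / "run"
OUT = ROOT / "features"


def load_scans(matrix: str):
    df = pd.read_csv(RUN / f"scans_{matrix}.csv")
    scans = [
        spectra_io.MS1Scan(rt=float(rt), peaks=g[["mz", "intensity"]].to_numpy())
        for rt, g in df.groupby("rt_min")
    ]
    scans.sort(key=lambda s: s.rt)
    return scans


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = FeatureFinderParams()
    per_sample = {}
    for matrix in ("extract", "dosed_plasma", "dosed_cerebrum",
                   "blank_plasma", "blank_cerebrum"):
        ms2 = spectra_io.read_mgf(RUN / f"ms2_{matrix}.mgf")
        feats = find_features(load_scans(matrix), ms2, params, sample_id=matrix)
        per_sample[matrix] = feats
        print(f"{matrix}: {len(feats)} features "
              f"({sum(f.ms2 is not None for f in feats)} with MS2)")
        pd.DataFrame(
            [{"id": f.id, "mz": f.mz, "rt_min": f.rt_apex, "height": f.height}
             for f in feats]
        ).to_csv(OUT / f"features_{matrix}.csv", index=False)
        spectra_io.write_mgf(  # keyed by feature id for re-pairing downstream
            [replace(f.ms2, id=f.id) for f in feats if f.ms2],
            OUT / f"features_{matrix}.mgf",
        )
    rows = join_align(
        {m: per_sample[m] for m in ("extract", "dosed_plasma", "dosed_cerebrum")},
        params,
    )
    pd.DataFrame(
        [{"id": f.id, "mz": f.mz, "rt_min": f.rt_apex, "height": f.height,
          **{f"intensity_{k}": v for k, v in f.sample_intensities.items()}}
         for f in rows]
    ).to_csv(OUT / "aligned_features.csv", index=False)
    print(f"aligned table: {len(rows)} rows -> {OUT / 'aligned_features.csv'}")


if __name__ == "__main__":
    main()
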