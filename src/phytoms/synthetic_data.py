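"""Synthetic LC-MS/MS acquisitions with known ground truth.

Every pipeline stage is exercised against data this module fabricates:
class-consistent MS2 spectra whose fragments follow the same
fragmentation chemistry the rule engine encodes, and full multi-sample
runs (herbal extract, blank and dosed plasma, blank and dosed cerebrum)
with planted prototypes, planted biotransformation products, mass
decoys and additive noise.

Chromatographic peaks are symmetric triangles 0.3 min wide sampled at
0.05-min spacing with apex 1e5 counts — the simplest elution shape that
clears every feature-finder threshold (>= 5 consecutive scans above the
noise floor, apex >= 7000).  Fragment intensities follow a fixed
descending rank profile; only their ordering matters downstream.  Noise
peaks are uniform in m/z with intensities kept below the relevant noise
floor so they are invisible to the finder unless a test asks otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import importlib.resources
import numpy as np
import pandas as pd
import yaml

from .chem import adduct_mz, monoisotopic_mass, parse_formula
from .metabolism import Biotransformation, transformation_by_label
from .spectra_io import CompoundRecord, MS1Scan, Spectrum, read_compound_table, write_mgf

__all__ = [
    "SimulationConfig",
    "GroundTruthEntry",
    "SimulationResult",
    "simulate_spectrum",
    "simulate_acquisition",
    "table_fixtures",
    "MATRICES",
]

MATRICES = (
    "extract",
    "blank_plasma",
    "dosed_plasma",
    "blank_cerebrum",
    "dosed_cerebrum",
)

# neutral-loss building blocks (Da)
GLCA = monoisotopic_mass("C6H8O6")
GLC = monoisotopic_mass("C6H10O5")
H2O = monoisotopic_mass("H2O")
CO = monoisotopic_mass("CO")
CO2 = monoisotopic_mass("CO2")
CH2 = monoisotopic_mass("CH2")
CH3 = monoisotopic_mass("CH3")
CH2O = monoisotopic_mass("CH2O")
CH4O = monoisotopic_mass("CH4O")
OX = monoisotopic_mass("O")
FERULOYL = monoisotopic_mass("C10H8O3")

#: fixed per-rank fragment intensity profile (base peak 1e5)
_RANK_PROFILE = (1.0, 0.8, 0.6, 0.45, 0.33, 0.25, 0.18, 0.13, 0.10, 0.08)


def _template(compound_class: str, polarity: str, precursor: float,
              formula) -> list[float]:
    """Class-consistent fragment m/z list for one compound."""
    has_glca = all(
        formula.counts.get(el, 0) >= n
        for el, n in parse_formula("C6H8O6").counts.items()
    )
    if compound_class == "flavonoids":
        if polarity == "negative":
            if has_glca:
                # aglycone cascade + glucuronate anion + A-ring RDA ion
                agly = precursor - GLCA
                return [agly, agly - H2O, agly - CO, agly - H2O - CO,
                        175.0248, 169.0661]
            return [precursor - H2O, precursor - H2O - CO, 169.0661]
        # positive mode: A-ring RDA ions plus the usual small losses
        if has_glca:
            agly = precursor - GLCA
            return [agly, agly - CH3, 169.0649, 123.0080]
        return [precursor - CH3, precursor - H2O, precursor - H2O - CO,
                169.0649, 123.0080]
    if compound_class == "terpenoids":
        if polarity == "negative":  # iridoid / monoterpene glycoside
            p1 = precursor - CH2O
            p2 = p1 - OX
            return [p1, p2, p2 - GLC, 179.0565, 89.0249]
        # sesquiterpene CH2 ladder off the dehydrated ion
        p0 = precursor - H2O
        return [p0 - k * CH2 for k in range(0, 6)]
    if compound_class == "phenylpropanoids":
        return [
            precursor - CH3,
            precursor - CH2O,
            precursor - 2 * CH2O,
            precursor - 3 * CH2O,
            precursor - CO2,
        ]
    if compound_class == "alkaloids":
        return [precursor - CH4O, 170.0966, 160.0757, 144.0851]
    if compound_class == "anthraquinones":
        p1 = precursor - CH3
        p2 = p1 - CH3
        if polarity == "positive":
            return [p1, p2, p2 - CO, precursor - OX]
        g = precursor - GLC if has_glca else precursor - OX
        return [p1, p2, p2 - CO, g, g - OX]
    if compound_class == "phenylethanoid glycosides":
        p1 = precursor - GLC
        return [p1, p1 - H2O, 179.0351, 135.0452]
    if compound_class == "oligosaccharides":
        return [
            precursor - GLC,
            precursor - CH2O,
            precursor - 2 * CH2O,
            precursor - FERULOYL,
        ]
    if compound_class == "phenolic acids":
        p1 = precursor - CO2
        return [p1, p1 - H2O, p1 - H2O - CO]
    if compound_class == "xanthones":
        p1 = precursor - H2O
        return [precursor - CH3, p1, p1 - CO]
    raise ValueError(
        f"no fragmentation template for class {compound_class!r}; "
        "templates exist for flavonoids, terpenoids, phenylpropanoids, "
        "alkaloids, anthraquinones, phenylethanoid glycosides, "
        "oligosaccharides, phenolic acids, xanthones"
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    scan_spacing: float = 0.05  # minutes
    peak_width: float = 0.3  # minutes, full base width of the triangle
    base_intensity: float = 1e5
    ms1_noise_peaks: int = 15  # per scan
    ms1_noise_intensity: tuple[float, float] = (100.0, 900.0)  # below floor
    ms2_noise_fraction: float = 0.2  # noise peaks per template peak
    ms2_noise_intensity: tuple[float, float] = (120.0, 1000.0)
    rt_jitter_sd: float = 0.0  # minutes
    mz_jitter_ppm_sd: float = 1.0  # within the 5 ppm error envelope
    decoy_count: int = 0
    matrices: tuple[str, ...] = MATRICES


@dataclass
class GroundTruthEntry:
    feature_id: str
    source: str  # compound id, or "decoy"/"noise"
    kind: str  # "prototype" | "metabolite" | "decoy"
    compound_class: str
    chain: str  # "" for prototypes
    mz: float
    rt: float
    matrices: tuple[str, ...]


@dataclass
class SimulationResult:
    config: SimulationConfig
    scans: dict[str, list[MS1Scan]]
    ms2: dict[str, list[Spectrum]]
    ground_truth: list[GroundTruthEntry]
    library: list[CompoundRecord]

    def write(self, outdir: str | Path) -> None:
        """Serialize scans CSV, MGF, ground truth CSV and config YAML."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for matrix, scans in self.scans.items():
            rows = [
                (scan.rt, mz, inten)
                for scan in scans
                for mz, inten in scan.peaks
            ]
            pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"]).to_csv(
                outdir / f"scans_{matrix}.csv", index=False
            )
            write_mgf(self.ms2[matrix], outdir / f"ms2_{matrix}.mgf")
        pd.DataFrame(
            [
                {
                    "feature_id": g.feature_id,
                    "source": g.source,
                    "kind": g.kind,
                    "compound_class": g.compound_class,
                    "chain": g.chain,
                    "mz": g.mz,
                    "rt": g.rt,
                    "matrices": ";".join(g.matrices),
                }
                for g in self.ground_truth
            ]
        ).to_csv(outdir / "ground_truth.csv", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(self.config).items()
                },
                fh,
            )


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def simulate_spectrum(
    compound: CompoundRecord,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    spectrum_id: str | None = None,
    mass_shift: float = 0.0,
    shift_fraction: float = 0.5,
) -> Spectrum:
    """Rule-consistent MS2 spectrum for one compound.

    Fragments come from the class template evaluated at the adduct m/z;
    a non-zero ``mass_shift`` models a biotransformation product whose
    precursor and the first ``shift_fraction`` of fragments move by the
    shift while the rest (the conserved core) stay put.  Poisson-count
    noise peaks are appended per config.
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    adduct = compound.selected_adduct
    precursor = adduct_mz(compound.neutral_mass, adduct)
    frags = _template(
        compound.compound_class, adduct.polarity, precursor, compound.formula
    )
    if mass_shift:
        n_shift = max(1, int(round(shift_fraction * len(frags))))
        frags = [f + mass_shift for f in frags[:n_shift]] + frags[n_shift:]
        precursor += mass_shift
    frags = [f for f in frags if 80.0 < f < 1250.0]
    intensities = [
        config.base_intensity * _RANK_PROFILE[min(i, len(_RANK_PROFILE) - 1)]
        for i in range(len(frags))
    ]
    n_noise = rng.poisson(config.ms2_noise_fraction * len(frags))
    noise_mz = rng.uniform(80.0, 1250.0, n_noise)
    noise_int = rng.uniform(*config.ms2_noise_intensity, n_noise)
    jitter = rng.normal(0.0, config.mz_jitter_ppm_sd * 1e-6, len(frags))
    peaks = np.column_stack(
        (
            np.concatenate([np.asarray(frags) * (1 + jitter), noise_mz]),
            np.concatenate([intensities, noise_int]),
        )
    )
    return Spectrum(
        id=spectrum_id or f"sim_{compound.id}",
        precursor_mz=precursor,
        precursor_charge=adduct.charge,
        polarity=adduct.polarity,
        rt=compound.rt,
        peaks=peaks,
    )


# ---------------------------------------------------------------------------
# acquisitions
# ---------------------------------------------------------------------------


def _plant_peak(
    scan_grid: np.ndarray,
    peaks_per_scan: list[list[tuple[float, float]]],
    mz: float,
    rt: float,
    height: float,
    width: float,
) -> None:
    half = width / 2.0
    for i, t in enumerate(scan_grid):
        dt = abs(t - rt)
        if dt < half:
            inten = height * (1.0 - dt / half)
            if inten > 0:
                peaks_per_scan[i].append((mz, inten))


def simulate_acquisition(
    library: Sequence[CompoundRecord],
    config: SimulationConfig | None = None,
    planted: Sequence[tuple[str, str, tuple[str, ...]]] = (),
    prototype_matrices: dict[str, tuple[str, ...]] | None = None,
) -> SimulationResult:
    """Multi-sample synthetic acquisition with ground truth.

    Library compounds appear in the extract and, per
    ``prototype_matrices`` (default: their ``detected_in`` flags), in
    the dosed biofluids.  ``planted`` lists metabolites as (prototype
    id, chain label like "+CH2+O", matrices); they appear only in dosed
    matrices.  ``config.decoy_count`` adds dosed-plasma features at
    metabolite-like masses with scrambled fragments.  Blanks contain
    only sub-threshold noise.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    by_id = {c.id: c for c in library}
    prototype_matrices = prototype_matrices or {
        c.id: ("extract",)
        + tuple(f"dosed_{m}" for m in sorted(c.detected_in))
        for c in library
    }

    max_rt = max([c.rt for c in library], default=5.0) + 1.0
    grid = np.arange(0.0, max_rt + config.scan_spacing, config.scan_spacing)

    ground_truth: list[GroundTruthEntry] = []
    # (mz, rt, height, spectrum | None, matrices, gt)
    planted_ions: list[tuple[float, float, float, Spectrum | None, tuple[str, ...]]] = []

    for c in library:
        mats = tuple(m for m in prototype_matrices.get(c.id, ()) if m in config.matrices)
        if not mats:
            continue
        jitter_rt = float(rng.normal(0.0, config.rt_jitter_sd)) if config.rt_jitter_sd else 0.0
        mz = c.theoretical_mz * (1 + float(rng.normal(0.0, config.mz_jitter_ppm_sd * 1e-6)))
        rt = c.rt + jitter_rt
        spec = simulate_spectrum(c, config, rng, spectrum_id=f"{c.id}_ms2")
        spec.rt = rt
        planted_ions.append((mz, rt, config.base_intensity, spec, mats))
        ground_truth.append(
            GroundTruthEntry(
                feature_id=c.id, source=c.id, kind="prototype",
                compound_class=c.compound_class, chain="",
                mz=mz, rt=rt, matrices=mats,
            )
        )

    for proto_id, chain_label, mats in planted:
        proto = by_id[proto_id]
        chain = _parse_chain(chain_label)
        shift = sum(bt.mass_delta for bt in chain)
        mz = proto.theoretical_mz + shift
        # conjugates elute earlier, cleavage products later; offset keeps
        # the metabolite resolved from its prototype
        rt = max(0.3, proto.rt + (0.8 if shift < 0 else -0.8))
        mz *= 1 + float(rng.normal(0.0, config.mz_jitter_ppm_sd * 1e-6))
        spec = simulate_spectrum(
            proto, config, rng,
            spectrum_id=f"{proto_id}{chain_label}_ms2", mass_shift=shift,
        )
        spec.rt = rt
        mats = tuple(m for m in mats if m.startswith("dosed"))
        planted_ions.append((mz, rt, 0.6 * config.base_intensity, spec, mats))
        ground_truth.append(
            GroundTruthEntry(
                feature_id=f"{proto_id}{chain_label}", source=proto_id,
                kind="metabolite", compound_class=proto.compound_class,
                chain=chain_label, mz=mz, rt=rt, matrices=mats,
            )
        )

    for d in range(config.decoy_count):
        proto = library[int(rng.integers(len(library)))]
        shift = CH2 if d % 2 == 0 else GLCA
        mz = proto.theoretical_mz + shift + float(rng.uniform(-0.002, 0.002))
        rt = float(rng.uniform(1.0, max_rt - 1.0))
        n_frag = 5
        peaks = np.column_stack(
            (
                np.sort(rng.uniform(80.0, mz - 20.0, n_frag)),
                config.base_intensity * np.asarray(_RANK_PROFILE[:n_frag]),
            )
        )
        adduct = proto.selected_adduct
        spec = Spectrum(
            id=f"decoy{d}_ms2", precursor_mz=mz,
            precursor_charge=adduct.charge, polarity=adduct.polarity,
            rt=rt, peaks=peaks,
        )
        planted_ions.append((mz, rt, 0.5 * config.base_intensity, spec,
                             ("dosed_plasma",)))
        ground_truth.append(
            GroundTruthEntry(
                feature_id=f"decoy{d}", source="decoy", kind="decoy",
                compound_class="", chain="", mz=mz, rt=rt,
                matrices=("dosed_plasma",),
            )
        )

    scans: dict[str, list[MS1Scan]] = {}
    ms2: dict[str, list[Spectrum]] = {}
    for matrix in config.matrices:
        peaks_per_scan: list[list[tuple[float, float]]] = [[] for _ in grid]
        spectra: list[Spectrum] = []
        for mz, rt, height, spec, mats in planted_ions:
            if matrix not in mats:
                continue
            _plant_peak(grid, peaks_per_scan, mz, rt, height, config.peak_width)
            if spec is not None:
                spectra.append(spec)
        for i, t in enumerate(grid):
            n = config.ms1_noise_peaks
            mzs = rng.uniform(100.0, 1250.0, n)
            ints = rng.uniform(*config.ms1_noise_intensity, n)
            peaks_per_scan[i].extend(zip(mzs.tolist(), ints.tolist()))
        scans[matrix] = [
            MS1Scan(rt=float(t), peaks=np.array(p) if p else np.empty((0, 2)))
            for t, p in zip(grid, peaks_per_scan)
        ]
        ms2[matrix] = spectra

    return SimulationResult(
        config=config, scans=scans, ms2=ms2,
        ground_truth=ground_truth, library=list(library),
    )


def _parse_chain(label: str) -> tuple[Biotransformation, ...]:
    import re

    tokens = re.findall(r"[+-][A-Za-z0-9]+", label)
    if not tokens or "".join(tokens) != label:
        raise ValueError(f"cannot parse transformation chain {label!r}")
    return tuple(transformation_by_label(t) for t in tokens)


# ---------------------------------------------------------------------------
# packaged compound tables
# ---------------------------------------------------------------------------

_EXPECTED_ROWS = {"prototypes_plasma.csv": 50, "metabolites_plasma.csv": 60}
_EXPECTED_T2_CLASSES = {
    "flavonoids": 34,
    "phenolic acids": 18,
    "phenylpropanoids": 6,
    "terpenoids": 1,
    "anthraquinones": 1,
}


def _data_path(name: str) -> Path:
    ref = importlib.resources.files("phytoms") / "data" / name
    with importlib.resources.as_file(ref) as p:
        return Path(p)


def table_fixtures() -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """The packaged absorbed-prototype and metabolite tables.

    Returns (50 prototype records, 60 metabolite records); integrity of
    the packaged files is checked against the expected row counts and
    the metabolite class tallies (34 flavonoids, 18 phenolic acids,
    6 phenylpropanoids, 1 terpenoid, 1 anthraquinone).
    """
    t1 = read_compound_table(_data_path("prototypes_plasma.csv"))
    t2 = read_compound_table(_data_path("metabolites_plasma.csv"))
    if len(t1) != _EXPECTED_ROWS["prototypes_plasma.csv"]:
        raise RuntimeError(
            f"packaged prototype table has {len(t1)} rows, expected 50"
        )
    if len(t2) != _EXPECTED_ROWS["metabolites_plasma.csv"]:
        raise RuntimeError(
            f"packaged metabolite table has {len(t2)} rows, expected 60"
        )
    tally: dict[str, int] = {}
    for r in t2:
        tally[r.compound_class] = tally.get(r.compound_class, 0) + 1
    if tally != _EXPECTED_T2_CLASSES:
        raise RuntimeError(
            f"packaged metabolite table class tally {tally} does not match "
            f"{_EXPECTED_T2_CLASSES}"
        )
    return t1, t2


def table2_frame() -> pd.DataFrame:
    """The metabolite table with parent/chain columns, as a DataFrame."""
    return pd.read_csv(_data_path("metabolites_plasma.csv"))
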