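"""Readers and writers for every artifact the pipeline touches.

MGF tandem spectra (the molecular-networking interchange format), a
centroided-mzML reader, compound/rule/feature CSV tables and GraphML
network export.  Parsing of the standard formats is delegated to
pyteomics (MGF, mzML) and networkx (GraphML); this module only maps them
onto the pipeline's own in-memory records.

Retention time is minutes everywhere internally; MGF ``RTINSECONDS`` is
converted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as _mgf

from .chem import Adduct, ElementalFormula, get_adduct, parse_formula

log = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "MS1Scan",
    "CompoundRecord",
    "COMPOUND_CLASSES",
    "read_mgf",
    "write_mgf",
    "read_mzml_centroided",
    "read_compound_table",
    "write_graphml",
    "read_graphml",
]

#: The closed vocabulary of compound classes used throughout the pipeline.
COMPOUND_CLASSES = (
    "flavonoids",
    "terpenoids",
    "phenylpropanoids",
    "alkaloids",
    "anthraquinones",
    "phenylethanoid glycosides",
    "phenolic acids",
    "xanthones",
    "oligosaccharides",
    "phthaleins",
    "naphthopyrones",
    "organic acids",
    "aromatic aldehydes",
    "diarylheptanoids",
)


@dataclass
class Spectrum:
    """A centroided MS2 peak list with precursor metadata.

    ``peaks`` is an (n, 2) float array of (m/z, intensity) sorted
    ascending by m/z; intensities are non-negative, no NaN.
    """

    id: str
    precursor_mz: float
    precursor_charge: int
    polarity: str  # "positive" | "negative"
    rt: float  # minutes
    peaks: np.ndarray

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if peaks.size and np.isnan(peaks).any():
            raise ValueError(f"spectrum {self.id}: NaN peak values")
        if peaks.size and (peaks[:, 1] < 0).any():
            raise ValueError(f"spectrum {self.id}: negative intensity")
        if self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.id}: non-positive precursor m/z")
        order = np.argsort(peaks[:, 0], kind="stable") if peaks.size else []
        self.peaks = peaks[order] if peaks.size else peaks

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0] if self.peaks.size else np.empty(0)

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1] if self.peaks.size else np.empty(0)

    def __len__(self) -> int:
        return self.peaks.shape[0] if self.peaks.size else 0


@dataclass
class MS1Scan:
    """A centroided survey scan: retention time plus an (n, 2) peak array."""

    rt: float  # minutes
    peaks: np.ndarray

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        order = np.argsort(peaks[:, 0], kind="stable") if peaks.size else []
        self.peaks = peaks[order] if peaks.size else peaks


@dataclass
class CompoundRecord:
    """One row of the compound library (name, formula, adduct, class, MS2)."""

    id: str
    name: str
    formula: ElementalFormula
    selected_adduct: Adduct
    compound_class: str
    rt: float  # minutes
    ms2_fragments: list[float] = field(default_factory=list)
    detected_in: set[str] = field(default_factory=set)  # subset of {plasma, cerebrum}

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(
                f"{self.id}: unknown compound class {self.compound_class!r}"
            )
        for f in self.ms2_fragments:
            if not (80.0 < f < 1250.0):
                raise ValueError(
                    f"{self.id}: MS2 fragment {f} outside the 80-1250 scan range"
                )

    @property
    def neutral_mass(self) -> float:
        return self.formula.mass

    @property
    def theoretical_mz(self) -> float:
        from .chem import adduct_mz

        return adduct_mz(self.neutral_mass, self.selected_adduct)


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into Spectrum records.

    TITLE is used as the spectrum id; RT is taken from RTINMINUTES or
    RTINSECONDS (converted); charge defaults to +1 when absent, with a
    logged note.  Blocks without PEPMASS are rejected with a warning.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"scan_{i}"))
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                log.warning("MGF block %s (%s) lacks PEPMASS; skipped", i, title)
                continue
            if "rtinminutes" in params:
                rt = float(params["rtinminutes"])
            elif "rtinseconds" in params:
                rt = float(params["rtinseconds"]) / 60.0
            else:
                rt = 0.0
            charge_list = params.get("charge")
            if charge_list:
                charge = int(charge_list[0])
            else:
                charge = 1
                log.debug("MGF block %s: no CHARGE, defaulting to +1", title)
            polarity = "negative" if charge < 0 else "positive"
            peaks = np.column_stack(
                (entry["m/z array"], entry["intensity array"])
            ) if len(entry["m/z array"]) else np.empty((0, 2))
            spectra.append(
                Spectrum(
                    id=title,
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=charge,
                    polarity=polarity,
                    rt=rt,
                    peaks=peaks,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.id,
                    "pepmass": s.precursor_mz,
                    "rtinseconds": s.rt * 60.0,
                    "charge": s.precursor_charge,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# mzML (read-only, centroid-only)
# ---------------------------------------------------------------------------


_ACC = {
    "ms_level": "MS:1000511",
    "centroid": "MS:1000127",
    "profile": "MS:1000128",
    "scan_start": "MS:1000016",
    "selected_mz": "MS:1000744",
    "charge_state": "MS:1000041",
    "negative": "MS:1000129",
    "positive": "MS:1000130",
    "f64": "MS:1000523",
    "f32": "MS:1000521",
    "zlib": "MS:1000574",
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
}


def _cv(elem, accession: str):
    """First cvParam with the accession under elem (namespace-agnostic)."""
    for p in elem.iter("{*}cvParam"):
        if p.get("accession") == accession:
            return p
    return None


def _decode_binary_array(array_elem) -> np.ndarray:
    import base64
    import zlib as _zlib

    binary = array_elem.findtext("{*}binary") or ""
    raw = base64.b64decode(binary)
    if _cv(array_elem, _ACC["zlib"]) is not None:
        raw = _zlib.decompress(raw)
    dtype = "<f4" if _cv(array_elem, _ACC["f32"]) is not None else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml_centroided(
    path: str | Path,
) -> tuple[list[MS1Scan], list[Spectrum]]:
    """Read a centroided mzML file into (MS1 scans, MS2 spectra).

    A small lxml-based reader covering the centroided dialect this
    pipeline needs (64/32-bit float arrays, optional zlib).  Profile-
    mode spectra raise a ValueError: peak picking is a precondition of
    this pipeline, not something it re-does.  Scans without a retention
    time are rejected with a logged warning.
    """
    ms1: list[MS1Scan] = []
    ms2: list[Spectrum] = []
    tree = etree.parse(str(path))
    for spec in tree.iter("{*}spectrum"):
        spec_id = spec.get("id", "")
        if _cv(spec, _ACC["profile"]) is not None:
            raise ValueError(
                f"{path}: profile-mode spectrum {spec_id!r}; "
                "only centroided mzML is supported"
            )
        level_param = _cv(spec, _ACC["ms_level"])
        level = int(level_param.get("value")) if level_param is not None else 1
        rt = None
        for scan in spec.iter("{*}scan"):
            p = _cv(scan, _ACC["scan_start"])
            if p is not None:
                rt = float(p.get("value"))
                if p.get("unitName", "minute").startswith("second"):
                    rt /= 60.0
            break
        if rt is None:
            log.warning("%s: scan %s has no retention time; skipped", path, spec_id)
            continue
        mz = inten = np.empty(0)
        for array in spec.iter("{*}binaryDataArray"):
            values = _decode_binary_array(array)
            if _cv(array, _ACC["mz_array"]) is not None:
                mz = values
            elif _cv(array, _ACC["intensity_array"]) is not None:
                inten = values
        peaks = np.column_stack((mz, inten)) if mz.size else np.empty((0, 2))
        if level == 1:
            ms1.append(MS1Scan(rt=rt, peaks=peaks))
            continue
        polarity = "negative" if _cv(spec, _ACC["negative"]) is not None else "positive"
        pmz = charge = None
        for ion in spec.iter("{*}selectedIon"):
            p = _cv(ion, _ACC["selected_mz"])
            if p is not None:
                pmz = float(p.get("value"))
            c = _cv(ion, _ACC["charge_state"])
            if c is not None:
                charge = int(c.get("value"))
            break
        if pmz is None:
            log.warning("%s: MS2 scan %s lacks precursor m/z; skipped", path, spec_id)
            continue
        if charge is None:
            charge = -1 if polarity == "negative" else 1
        ms2.append(
            Spectrum(
                id=spec_id or f"scan_{len(ms2)}",
                precursor_mz=pmz,
                precursor_charge=charge,
                polarity=polarity,
                rt=rt,
                peaks=peaks,
            )
        )
    return ms1, ms2


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------


def _parse_fragments(cell) -> list[float]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    return [float(x) for x in str(cell).replace(";", " ").split() if x]


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound library CSV into CompoundRecord objects.

    Required columns: id, name, formula, adduct, compound_class, rt_min,
    ms2_fragments (whitespace/semicolon separated m/z).  Optional plasma /
    cerebrum columns hold +/- detectability flags.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    records: list[CompoundRecord] = []
    for _, row in df.iterrows():
        detected = set()
        for matrix in ("plasma", "cerebrum"):
            if matrix in df.columns and row[matrix].strip() == "+":
                detected.add(matrix)
        records.append(
            CompoundRecord(
                id=row["id"],
                name=row["name"],
                formula=parse_formula(row["formula"]),
                selected_adduct=get_adduct(row["adduct"]),
                compound_class=row["compound_class"],
                rt=float(row["rt_min"]) if row["rt_min"] else 0.0,
                ms2_fragments=_parse_fragments(row["ms2_fragments"]),
                detected_in=detected,
            )
        )
    return records


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Write a network to GraphML, coercing attribute values to plain types."""
    out = graph.copy()
    for _, data in out.nodes(data=True):
        for k, v in list(data.items()):
            if isinstance(v, (np.floating, np.integer)):
                data[k] = v.item()
            elif v is None:
                data[k] = ""
    for _, _, data in out.edges(data=True):
        for k, v in list(data.items()):
            if isinstance(v, (np.floating, np.integer)):
                data[k] = v.item()
    nx.write_graphml(out, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
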