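"""In-vivo identification: prototype presence calls and metabolite inference.

Orally dosed herbal constituents appear in biofluids either unchanged
(prototypes) or as phase-I/II biotransformation products.  This module
makes presence calls by extracted-ion chromatography against dosed and
blank runs, enumerates candidate metabolites by applying transformation
chains (methylation, hydroxylation, sulfation, glucuronidation, ...) to
prototype formulas, matches candidates against dosed-only features with
fragment-shift evidence, and assembles the resulting prototype ->
metabolite pathway graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .annotate import RuleBase, validate_annotation
from .chem import (
    ElementalFormula,
    FormulaError,
    adduct_mz,
    get_adduct,
    parse_formula,
    ppm_error,
)
from .feature_finder import Feature
from .spectra_io import CompoundRecord, MS1Scan

__all__ = [
    "Biotransformation",
    "BIOTRANSFORMATIONS",
    "MetaboliteCandidate",
    "PresenceCall",
    "extract_xic",
    "call_prototypes",
    "predict_metabolites",
    "match_metabolites",
    "assemble_pathways",
]


@dataclass(frozen=True)
class Biotransformation:
    """A named formula delta, e.g. methylation = +CH2, sulfation = +SO3."""

    name: str
    formula_delta: ElementalFormula
    direction: str  # "gain" | "loss"
    moiety: str = ""  # conventional rendering of the group, e.g. "SO3"

    @property
    def mass_delta(self) -> float:
        sign = 1.0 if self.direction == "gain" else -1.0
        return sign * self.formula_delta.mass

    @property
    def label(self) -> str:
        sign = "+" if self.direction == "gain" else "-"
        return f"{sign}{self.moiety or self.formula_delta}"

    def apply(self, formula: ElementalFormula) -> ElementalFormula:
        if self.direction == "gain":
            return formula + self.formula_delta
        return formula - self.formula_delta


def _bt(name: str, delta: str, direction: str, moiety: str = "") -> Biotransformation:
    return Biotransformation(name, parse_formula(delta), direction, moiety)


#: The shipped transformation ledger: the common phase-I/II reactions of
#: orally absorbed herbal constituents.  Labels follow the customary
#: mass-shift naming ("X + SO3", "X - CH2", "X + 2H").
BIOTRANSFORMATIONS: tuple[Biotransformation, ...] = (
    _bt("methylation", "CH2", "gain"),
    _bt("demethylation", "CH2", "loss"),
    _bt("hydroxylation", "O", "gain"),
    _bt("dehydroxylation", "O", "loss"),
    _bt("reduction", "H2", "gain", moiety="2H"),
    _bt("dehydrogenation", "H2", "loss", moiety="2H"),
    _bt("sulfation", "SO3", "gain", moiety="SO3"),
    _bt("glucuronidation", "C6H8O6", "gain"),
    _bt("glucosylation", "C6H10O5", "gain"),
    _bt("glucuronide hydrolysis", "C6H8O6", "loss"),
    _bt("glucoside hydrolysis", "C6H10O5", "loss"),
    _bt("decarboxylation", "CO2", "loss"),
)

_BY_LABEL = {bt.label: bt for bt in BIOTRANSFORMATIONS}


def transformation_by_label(label: str) -> Biotransformation:
    """Look up a ledger entry by its +/- formula label, e.g. "+SO3"."""
    if label not in _BY_LABEL:
        raise KeyError(
            f"unknown biotransformation {label!r}; known: {sorted(_BY_LABEL)}"
        )
    return _BY_LABEL[label]


@dataclass
class MetaboliteCandidate:
    prototype_id: str
    chain: tuple[Biotransformation, ...]
    predicted_formula: ElementalFormula
    predicted_mz: dict[str, float]  # adduct name -> m/z
    matched_feature: Feature | None = None
    matched_adduct: str = ""
    evidence: dict = field(default_factory=dict)

    @property
    def chain_label(self) -> str:
        return "".join(bt.label for bt in self.chain)

    @property
    def mass_shift(self) -> float:
        return sum(bt.mass_delta for bt in self.chain)


@dataclass
class PresenceCall:
    compound_id: str
    matrix: str  # "plasma" | "cerebrum"
    detected: bool
    dosed_height: float
    blank_height: float
    criterion: str


# ---------------------------------------------------------------------------
# XIC
# ---------------------------------------------------------------------------


def extract_xic(
    ms1_scans: Sequence[MS1Scan],
    target_mz: float,
    ppm_tol: float = 5.0,
    rt_window: tuple[float, float] | None = None,
) -> tuple[list[tuple[float, float]], float, float]:
    """Extracted-ion chromatogram for a narrow m/z window.

    Returns (trace of (rt, intensity), apex height, apex rt); an empty
    window yields an all-zero trace with apex 0.
    """
    if target_mz <= 0:
        raise ValueError("target m/z must be positive")
    tol = ppm_tol * 1e-6 * target_mz
    trace: list[tuple[float, float]] = []
    for scan in ms1_scans:
        if rt_window is not None and not (rt_window[0] <= scan.rt <= rt_window[1]):
            continue
        if scan.peaks.size:
            sel = np.abs(scan.peaks[:, 0] - target_mz) <= tol
            inten = float(scan.peaks[sel, 1].sum())
        else:
            inten = 0.0
        trace.append((scan.rt, inten))
    if trace:
        apex_rt, apex = max(trace, key=lambda p: p[1])
    else:
        apex_rt, apex = 0.0, 0.0
    if apex == 0.0:
        apex_rt = 0.0
    return trace, apex, apex_rt


# ---------------------------------------------------------------------------
# prototype calls
# ---------------------------------------------------------------------------


def call_prototypes(
    library: Sequence[CompoundRecord],
    dosed_scans: Sequence[MS1Scan],
    blank_scans: Sequence[MS1Scan],
    matrix: str = "plasma",
    ppm_tol: float = 5.0,
    min_height: float = 7000.0,
    blank_fraction: float = 0.05,
    rt_window_width: float | None = 1.0,
) -> list[PresenceCall]:
    """Presence/absence of each library compound in a dosed vs blank run.

    A compound is detected when its selected-adduct XIC apex in the
    dosed run reaches ``min_height`` while the blank apex stays below
    ``blank_fraction`` of it (present in dosed, absent in blank).  The
    XIC is restricted around the library retention time when a window
    width is given.
    """
    calls = []
    for record in library:
        target = record.theoretical_mz
        window = None
        if rt_window_width is not None and record.rt > 0:
            window = (record.rt - rt_window_width, record.rt + rt_window_width)
        _, dosed_apex, _ = extract_xic(dosed_scans, target, ppm_tol, window)
        _, blank_apex, _ = extract_xic(blank_scans, target, ppm_tol, window)
        detected = dosed_apex >= min_height and blank_apex < blank_fraction * dosed_apex
        calls.append(
            PresenceCall(
                compound_id=record.id,
                matrix=matrix,
                detected=detected,
                dosed_height=dosed_apex,
                blank_height=blank_apex,
                criterion=(
                    f"dosed>={min_height:g} and blank<{blank_fraction:g}*dosed "
                    f"at {target:.4f} +/- {ppm_tol:g} ppm"
                ),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# metabolite prediction
# ---------------------------------------------------------------------------


def predict_metabolites(
    prototype: CompoundRecord,
    ledger: Sequence[Biotransformation] = BIOTRANSFORMATIONS,
    max_depth: int = 2,
    adducts: Sequence[str] = ("[M+H]+", "[M-H]-"),
) -> list[MetaboliteCandidate]:
    """All transformation chains up to ``max_depth`` applied to a prototype.

    Chains are identified by their transformation multiset (order does
    not change the product), deduplicated by resulting formula with the
    shortest chain kept, and pruned when a loss would drive an element
    count negative or when the chain nets to the unchanged prototype.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    seen: dict[str, tuple[Biotransformation, ...]] = {}
    candidates: list[MetaboliteCandidate] = []
    for depth in range(1, max_depth + 1):
        for combo in itertools.combinations_with_replacement(ledger, depth):
            formula = prototype.formula
            try:
                for bt in combo:
                    formula = bt.apply(formula)
            except FormulaError:
                continue
            key = str(formula)
            if key == str(prototype.formula) or key in seen:
                continue
            seen[key] = combo
            candidates.append(
                MetaboliteCandidate(
                    prototype_id=prototype.id,
                    chain=combo,
                    predicted_formula=formula,
                    predicted_mz={
                        name: adduct_mz(formula.mass, name) for name in adducts
                    },
                )
            )
    return candidates


def match_metabolites(
    candidates: Sequence[MetaboliteCandidate],
    dosed_features: Sequence[Feature],
    blank_features: Sequence[Feature] = (),
    prototypes: dict[str, CompoundRecord] | None = None,
    ppm_tol: float = 5.0,
    require_evidence: bool = True,
    min_shared_fragments: int = 1,
    fragment_tol: float = 0.03,
    rulebase: RuleBase | None = None,
) -> list[MetaboliteCandidate]:
    """Match predicted metabolites against dosed-only features.

    A candidate matches a feature when the feature m/z lies within
    ``ppm_tol`` of a predicted adduct m/z of the feature's own polarity
    and no blank feature does.
    With ``require_evidence`` the feature's MS2 must additionally share
    at least ``min_shared_fragments`` fragments with the prototype's
    fragments, either directly or shifted by the chain mass delta, or
    its spectrum must pass the rule-engine class check for the
    prototype's class.
    """
    prototypes = prototypes or {}
    matched: list[MetaboliteCandidate] = []
    for cand in candidates:
        proto = prototypes.get(cand.prototype_id)
        for adduct_name, pred_mz in cand.predicted_mz.items():
            adduct_polarity = get_adduct(adduct_name).polarity
            tol = ppm_tol * 1e-6 * pred_mz
            if any(abs(b.mz - pred_mz) <= tol for b in blank_features):
                continue
            hits = [
                f
                for f in dosed_features
                if abs(f.mz - pred_mz) <= tol
                and (f.ms2 is None or f.ms2.polarity == adduct_polarity)
            ]
            for feature in sorted(hits, key=lambda f: -f.height):
                evidence: dict = {
                    "mass_match_ppm": ppm_error(feature.mz, pred_mz),
                    "shared_fragments": 0,
                    "class_check": "",
                }
                ok = True
                if require_evidence:
                    shared = 0
                    if feature.ms2 is not None and proto is not None:
                        shift = cand.mass_shift
                        for frag in proto.ms2_fragments:
                            for obs in feature.ms2.mz:
                                if (
                                    abs(obs - frag) <= fragment_tol
                                    or abs(obs - (frag + shift)) <= fragment_tol
                                ):
                                    shared += 1
                                    break
                    evidence["shared_fragments"] = shared
                    ok = shared >= min_shared_fragments
                    if not ok and proto is not None and feature.ms2 is not None:
                        accepted, reason = validate_annotation(
                            feature.ms2, proto.compound_class, rulebase
                        )
                        evidence["class_check"] = reason
                        ok = accepted
                if ok:
                    matched.append(
                        MetaboliteCandidate(
                            prototype_id=cand.prototype_id,
                            chain=cand.chain,
                            predicted_formula=cand.predicted_formula,
                            predicted_mz=dict(cand.predicted_mz),
                            matched_feature=feature,
                            matched_adduct=adduct_name,
                            evidence=evidence,
                        )
                    )
                    break  # best (tallest) qualifying feature for this adduct
            else:
                continue
            break  # one adduct match per candidate is enough
    return matched


# ---------------------------------------------------------------------------
# pathway assembly
# ---------------------------------------------------------------------------


def assemble_pathways(
    prototypes: Sequence[CompoundRecord],
    matched_metabolites: Sequence[MetaboliteCandidate],
) -> nx.DiGraph:
    """Directed prototype -> metabolite graph labeled by chains.

    Hydrolysis edges between two detected prototypes (glucuronide ->
    aglycone or glucoside -> aglycone) are added when the formula
    arithmetic links them.  Metabolite masses reachable from more than
    one prototype keep every incoming edge, flagged ambiguous.
    """
    g = nx.DiGraph()
    for p in prototypes:
        g.add_node(p.id, kind="prototype", name=p.name, formula=str(p.formula))
    targets: dict[str, list[str]] = {}
    for m in matched_metabolites:
        node = f"{m.prototype_id}{m.chain_label}"
        g.add_node(
            node,
            kind="metabolite",
            formula=str(m.predicted_formula),
            chain=m.chain_label,
        )
        g.add_edge(m.prototype_id, node, transformation=m.chain_label)
        targets.setdefault(str(m.predicted_formula), []).append(node)
    for nodes in targets.values():
        if len(nodes) > 1:
            for n in nodes:
                g.nodes[n]["ambiguous"] = True
    # prototype-to-prototype hydrolysis (e.g. glucuronide -> aglycone)
    for sugar in ("C6H8O6", "C6H10O5"):
        delta = parse_formula(sugar)
        for a in prototypes:
            for b in prototypes:
                if a.id == b.id:
                    continue
                try:
                    if str(a.formula - delta) == str(b.formula):
                        g.add_edge(a.id, b.id, transformation=f"-{sugar}")
                except FormulaError:
                    continue
    return g
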