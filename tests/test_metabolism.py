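"""XICs, presence calls, metabolite prediction, matching and pathways."""

import itertools

import numpy as np
import pytest

from phytoms import synthetic_data as sd
from phytoms.chem import adduct_mz, monoisotopic_mass, parse_formula
from phytoms.feature_finder import Feature, find_features
from phytoms.metabolism import (
    BIOTRANSFORMATIONS,
    assemble_pathways,
    call_prototypes,
    extract_xic,
    match_metabolites,
    predict_metabolites,
    transformation_by_label,
)
from phytoms.spectra_io import MS1Scan

from .conftest import toy_spectrum


def _scans_with_ion(mz, rt_center, apex, spacing=0.05, width=0.3, t0=0.0, t1=20.0):
    scans = []
    for t in np.arange(t0, t1, spacing):
        peaks = []
        dt = abs(t - rt_center)
        if dt < width / 2:
            peaks.append((mz, apex * (1 - dt / (width / 2))))
        scans.append(MS1Scan(rt=float(t), peaks=np.asarray(peaks).reshape(-1, 2)))
    return scans


# ---------------------------------------------------------------------------
# XIC
# ---------------------------------------------------------------------------


def test_xic_recovers_planted_ion():
    scans = _scans_with_ion(445.0777, 7.3, 1e5)
    trace, apex, apex_rt = extract_xic(scans, 445.0776, ppm_tol=5.0)
    assert apex == pytest.approx(1e5)
    assert apex_rt == pytest.approx(7.3, abs=0.05)


def test_xic_query_outside_tolerance_is_empty():
    scans = _scans_with_ion(445.0776 * (1 + 10e-6), 7.3, 1e5)
    _, apex, _ = extract_xic(scans, 445.0776, ppm_tol=5.0)
    assert apex == 0.0


def test_isomer_pair_resolved_by_rt_window():
    scans_a = _scans_with_ion(209.1172, 7.3, 8e4)
    scans_b = _scans_with_ion(209.1172, 8.3, 6e4)
    merged = [
        MS1Scan(rt=a.rt, peaks=np.vstack([a.peaks, b.peaks]))
        for a, b in zip(scans_a, scans_b)
    ]
    _, apex_a, rt_a = extract_xic(merged, 209.1172, 5.0, rt_window=(6.8, 7.8))
    _, apex_b, rt_b = extract_xic(merged, 209.1172, 5.0, rt_window=(7.8, 8.8))
    assert (apex_a, rt_a) == (pytest.approx(8e4), pytest.approx(7.3, abs=0.05))
    assert (apex_b, rt_b) == (pytest.approx(6e4), pytest.approx(8.3, abs=0.05))


# ---------------------------------------------------------------------------
# presence calls
# ---------------------------------------------------------------------------


def test_planted_prototypes_and_only_those_are_called(tables):
    t1, _ = tables
    library = t1[:10]
    planted = {c.id for c in library[:4]}
    rng = np.random.default_rng(0)
    grid = np.arange(0.0, 22.0, 0.05)
    dosed = [MS1Scan(rt=float(t), peaks=np.empty((0, 2))) for t in grid]
    for c in library:
        if c.id in planted:
            for i, t in enumerate(grid):
                dt = abs(t - c.rt)
                if dt < 0.15:
                    peak = np.array([[c.theoretical_mz, 1e5 * (1 - dt / 0.15)]])
                    dosed[i] = MS1Scan(rt=float(t), peaks=np.vstack([dosed[i].peaks, peak]))
    blank = [MS1Scan(rt=float(t), peaks=np.empty((0, 2))) for t in grid]
    calls = call_prototypes(library, dosed, blank)
    assert {c.compound_id for c in calls if c.detected} == planted


def test_equal_blank_signal_vetoes_detection(tables):
    t1, _ = tables
    c = t1[0]
    dosed = _scans_with_ion(c.theoretical_mz, c.rt, 1e5, t0=0, t1=3)
    calls = call_prototypes([c], dosed, dosed)
    assert not calls[0].detected
    assert calls[0].blank_height == pytest.approx(calls[0].dosed_height)


def test_empty_dosed_run_detects_nothing(tables):
    t1, _ = tables
    empty = [MS1Scan(rt=t, peaks=np.empty((0, 2))) for t in np.arange(0, 21, 0.5)]
    calls = call_prototypes(t1, empty, empty)
    assert not any(c.detected for c in calls)


# ---------------------------------------------------------------------------
# metabolite prediction
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def baicalin(tables):
    t1, _ = tables
    return next(c for c in t1 if c.id == "P17")


def test_methylation_of_glucuronide_prototype(baicalin):
    cands = predict_metabolites(baicalin, max_depth=1)
    meth = next(c for c in cands if c.chain_label == "+CH2")
    assert str(meth.predicted_formula) == "C22H20O11"
    assert meth.predicted_mz["[M-H]-"] == pytest.approx(459.0933, abs=1e-4)


def test_glucuronidation_of_glucuronide_prototype(baicalin):
    cands = predict_metabolites(baicalin, max_depth=1)
    glcu = next(c for c in cands if c.chain_label == "+C6H8O6")
    assert str(glcu.predicted_formula) == "C27H26O17"
    assert glcu.predicted_mz["[M-H]-"] == pytest.approx(621.1097, abs=1e-4)


def test_depth_zero_predicts_nothing(baicalin):
    assert predict_metabolites(baicalin, max_depth=0) == []


def test_chain_mass_equals_formula_arithmetic(baicalin):
    """Summed transformation mass deltas equal the formula-difference
    mass for every chain up to depth 3."""
    for depth in (1, 2, 3):
        for combo in itertools.combinations_with_replacement(
            BIOTRANSFORMATIONS, depth
        ):
            formula = baicalin.formula
            try:
                for bt in combo:
                    formula = bt.apply(formula)
            except Exception:
                continue
            chain_shift = sum(bt.mass_delta for bt in combo)
            formula_shift = formula.mass - baicalin.formula.mass
            assert chain_shift == pytest.approx(formula_shift, abs=1e-5)


def test_ledger_mass_deltas_match_reference_values():
    expected = {
        "+CH2": 14.01565, "+O": 15.99491, "+2H": 2.01565, "+SO3": 79.95682,
        "+C6H8O6": 176.03209, "+C6H10O5": 162.05282, "-CO2": -43.98983,
    }
    for label, delta in expected.items():
        assert transformation_by_label(label).mass_delta == pytest.approx(
            delta, abs=1e-5
        )


def test_chains_deduplicate_by_resulting_formula(baicalin):
    cands = predict_metabolites(baicalin, max_depth=2)
    formulas = [str(c.predicted_formula) for c in cands]
    assert len(formulas) == len(set(formulas))
    # +O-O nets to the prototype and must not appear
    assert str(baicalin.formula) not in formulas


def test_impossible_losses_are_pruned(tables):
    t1, _ = tables
    calamenene = next(c for c in t1 if c.id == "P48")  # C15H22, no oxygen
    labels = {c.chain_label for c in predict_metabolites(calamenene, max_depth=1)}
    assert "-O" not in labels
    assert "-CO2" not in labels
    assert "+O" in labels


# ---------------------------------------------------------------------------
# metabolite matching
# ---------------------------------------------------------------------------


def _feature(mz, rt, ms2=None, fid="F"):
    return Feature(id=fid, mz=mz, rt_apex=rt, height=5e4, ms2=ms2)


def test_methylated_analog_matches_with_shared_fragment_evidence(baicalin):
    baicalin = _with_template_fragments(baicalin)
    cands = predict_metabolites(baicalin, max_depth=1)
    shifted = toy_spectrum(
        [(283.0620, 100.0), (268.0386, 50.0)], precursor_mz=459.0930,
        spectrum_id="m34_analog",
    )
    feature = _feature(459.0930, 8.06, ms2=shifted, fid="M34F")
    matched = match_metabolites(
        cands, [feature], prototypes={baicalin.id: baicalin}, require_evidence=True
    )
    labels = {m.chain_label for m in matched}
    assert "+CH2" in labels
    m34 = next(m for m in matched if m.chain_label == "+CH2")
    assert m34.evidence["shared_fragments"] >= 1


def _with_template_fragments(record):
    clean = sd.SimulationConfig(seed=0, ms2_noise_fraction=0.0, mz_jitter_ppm_sd=0.0)
    spec = sd.simulate_spectrum(record, clean, np.random.default_rng(0))
    record.ms2_fragments = [float(m) for m in spec.mz if 80 < m < 1250]
    return record


def test_decoy_at_right_mass_with_wrong_fragments_is_unmatched(baicalin):
    baicalin = _with_template_fragments(baicalin)
    cands = predict_metabolites(baicalin, max_depth=1)
    decoy_ms2 = toy_spectrum(
        [(611.8, 100.0), (733.2, 50.0), (910.4, 20.0)], precursor_mz=459.0931,
        spectrum_id="decoy",
    )
    feature = _feature(459.0931, 3.0, ms2=decoy_ms2, fid="D1")
    matched = match_metabolites(
        cands, [feature], prototypes={baicalin.id: baicalin}, require_evidence=True
    )
    assert "+CH2" not in {m.chain_label for m in matched}


def test_candidate_mass_present_in_blank_is_unmatched(baicalin):
    baicalin = _with_template_fragments(baicalin)
    cands = predict_metabolites(baicalin, max_depth=1)
    shifted = toy_spectrum([(283.0620, 100.0)], precursor_mz=459.0930)
    feature = _feature(459.0930, 8.06, ms2=shifted)
    blank = [_feature(459.0931, 8.00, fid="B1")]
    matched = match_metabolites(
        cands, [feature], blank_features=blank,
        prototypes={baicalin.id: baicalin}, require_evidence=True,
    )
    assert "+CH2" not in {m.chain_label for m in matched}


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------


def test_glucuronide_to_aglycone_hydrolysis_edge(tables, baicalin):
    t1, _ = tables
    baicalein = next(c for c in t1 if c.id == "P33")
    cands = predict_metabolites(baicalin, max_depth=1)
    selected = [
        c for c in cands if c.chain_label in ("+CH2", "+C6H8O6", "-O")
    ]
    for c in selected:
        c.matched_feature = _feature(c.predicted_mz["[M-H]-"], 8.0)
    g = assemble_pathways([baicalin, baicalein], selected)
    assert g.number_of_nodes() == 5
    assert g.has_edge("P17", "P33")
    assert g.edges["P17", "P33"]["transformation"] == "-C6H8O6"


def test_no_metabolites_gives_isolated_prototypes(tables):
    t1, _ = tables
    g = assemble_pathways(t1[:3], [])
    assert g.number_of_nodes() == 3
    assert g.number_of_edges() == 0


def test_formula_collision_is_flagged_ambiguous(tables):
    t1, _ = tables
    ferulic = next(c for c in t1 if c.id == "P5")  # caffeic + CH2
    caffeic = next(c for c in t1 if c.id == "P2")
    m_fer = predict_metabolites(ferulic, max_depth=1)
    m_caf = predict_metabolites(caffeic, max_depth=2)
    sulfated_fer = next(c for c in m_fer if c.chain_label == "+SO3")
    sulfated_meth_caf = next(
        c for c in m_caf if c.chain_label == "+CH2+SO3"
    )
    assert str(sulfated_fer.predicted_formula) == str(
        sulfated_meth_caf.predicted_formula
    )
    g = assemble_pathways([ferulic, caffeic], [sulfated_fer, sulfated_meth_caf])
    amb = [n for n, d in g.nodes(data=True) if d.get("ambiguous")]
    assert len(amb) == 2
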