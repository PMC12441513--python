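"""Modified cosine, network construction, library matching, propagation."""

import itertools

import numpy as np
import pytest

from phytoms.feature_finder import Feature
from phytoms.networking import (
    NetworkParams,
    annotate_with_library,
    build_network,
    library_match,
    modified_cosine,
    network_stats,
    propagate_annotations,
)

from .conftest import toy_spectrum


def brute_force_modified_cosine(a, b, tol=0.02):
    """Exhaustive max over all one-to-one peak matchings (oracle)."""
    ia, ib = np.sqrt(a.intensity), np.sqrt(b.intensity)
    norm = np.linalg.norm(ia) * np.linalg.norm(ib)
    shift = b.precursor_mz - a.precursor_mz
    eligible = [
        (i, j)
        for i in range(len(a))
        for j in range(len(b))
        if abs(b.mz[j] - a.mz[i]) <= tol or abs(b.mz[j] - a.mz[i] - shift) <= tol
    ]
    best, best_n = 0.0, 0
    n = min(len(a), len(b))
    for k in range(n + 1):
        for ai in itertools.permutations(range(len(a)), k):
            for bj in itertools.permutations(range(len(b)), k):
                if all((i, j) in eligible for i, j in zip(ai, bj)):
                    s = sum(ia[i] * ib[j] for i, j in zip(ai, bj))
                    if s > best:
                        best, best_n = s, k
    return (best / norm if norm else 0.0), best_n


def test_self_similarity_is_one():
    s = toy_spectrum(
        [(100.0, 5.0), (150.0, 2.0), (200.0, 9.0)], precursor_mz=250.0
    )
    cos, n = modified_cosine(s, s)
    assert cos == pytest.approx(1.0, abs=1e-12)
    assert n == 3


def test_disjoint_spectra_score_zero():
    a = toy_spectrum([(100.0, 1.0), (150.0, 1.0)], precursor_mz=250.0)
    b = toy_spectrum([(120.0, 1.0), (130.0, 1.0)], precursor_mz=250.0)
    assert modified_cosine(a, b) == (0.0, 0)


def test_shifted_match_equals_bruteforce_on_toy_pair():
    """One direct and one precursor-shifted match; greedy equals the
    exhaustive optimum."""
    a = toy_spectrum([(100.0, 4.0), (150.0, 9.0), (210.0, 1.0)], precursor_mz=250.0)
    b = toy_spectrum([(100.0, 4.0), (164.0157, 9.0), (220.0, 1.0)], precursor_mz=264.0157)
    cos, n = modified_cosine(a, b)
    ref_cos, ref_n = brute_force_modified_cosine(a, b)
    assert cos == pytest.approx(ref_cos, abs=1e-12)
    assert n == ref_n
    assert n == 2


def test_opposite_polarity_is_an_error():
    a = toy_spectrum([(100.0, 1.0)], precursor_mz=250.0, polarity="negative")
    b = toy_spectrum([(100.0, 1.0)], precursor_mz=250.0, polarity="positive")
    with pytest.raises(ValueError):
        modified_cosine(a, b)


def test_symmetry():
    rng = np.random.default_rng(11)
    for _ in range(30):
        a = toy_spectrum(
            np.column_stack((rng.uniform(80, 500, 5), rng.uniform(1, 100, 5))),
            precursor_mz=rng.uniform(300, 600),
        )
        b = toy_spectrum(
            np.column_stack((rng.uniform(80, 500, 5), rng.uniform(1, 100, 5))),
            precursor_mz=rng.uniform(300, 600),
        )
        ca, na = modified_cosine(a, b)
        cb, nb = modified_cosine(b, a)
        assert ca == pytest.approx(cb, abs=1e-9)
        assert na == nb


def test_greedy_is_near_optimal_on_random_spectra():
    """Greedy matching attains >= 0.95 x the exhaustive optimum on
    randomized 6-peak spectra (200 seeded trials here; the acceptance
    suite runs 1000)."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n_a, n_b = rng.integers(2, 7), rng.integers(2, 7)
        prec_a = float(rng.uniform(300, 500))
        a = toy_spectrum(
            np.column_stack(
                (np.sort(rng.uniform(80, prec_a, n_a)), rng.uniform(1, 100, n_a))
            ),
            precursor_mz=prec_a,
        )
        shift = float(rng.uniform(-30, 30))
        k = min(n_a, n_b // 2)
        mzb = np.sort(
            np.concatenate(
                [
                    a.mz[:k] + np.where(rng.random(k) < 0.5, 0.0, shift),
                    rng.uniform(80, prec_a + shift, n_b - k),
                ]
            )
        )
        b = toy_spectrum(
            np.column_stack((mzb, rng.uniform(1, 100, n_b))),
            precursor_mz=prec_a + shift,
        )
        greedy, _ = modified_cosine(a, b)
        optimal, _ = brute_force_modified_cosine(a, b)
        assert greedy >= 0.95 * optimal - 1e-12


def test_agrees_with_matchms_reference_implementation():
    """Independent cross-check against matchms.ModifiedCosine on random
    spectra (intensities pre-square-rooted to align conventions)."""
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    rng = np.random.default_rng(5)
    sim = ModifiedCosine(tolerance=0.02)
    for _ in range(50):
        n_a, n_b = int(rng.integers(3, 8)), int(rng.integers(3, 8))
        prec_a = float(rng.uniform(300, 500))
        shift = float(rng.uniform(-20, 20))
        mza = np.sort(rng.uniform(80, 280, n_a))
        mzb = np.sort(
            np.concatenate([mza[: n_b // 2] + shift, rng.uniform(80, 280, n_b - n_b // 2)])
        )
        inta = rng.uniform(1, 100, n_a)
        intb = rng.uniform(1, 100, n_b)
        ours_a = toy_spectrum(np.column_stack((mza, inta)), precursor_mz=prec_a)
        ours_b = toy_spectrum(np.column_stack((mzb, intb)), precursor_mz=prec_a + shift)
        ref_a = matchms.Spectrum(
            mz=mza, intensities=np.sqrt(inta), metadata={"precursor_mz": prec_a},
            metadata_harmonization=False,
        )
        ref_b = matchms.Spectrum(
            mz=mzb, intensities=np.sqrt(intb),
            metadata={"precursor_mz": prec_a + shift},
            metadata_harmonization=False,
        )
        score = sim.pair(ref_a, ref_b)
        cos, n = modified_cosine(ours_a, ours_b)
        assert cos == pytest.approx(float(score["score"]), abs=1e-6)
        assert n == int(score["matches"])


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def _family(precursors, shared_frags, polarity="negative"):
    """Features whose spectra share fragments (a structural family)."""
    feats = []
    for k, prec in enumerate(precursors):
        peaks = [(m, 100.0 - i) for i, m in enumerate(shared_frags)]
        peaks.append((prec - 18.0106, 40.0))
        feats.append(
            Feature(
                id=f"fam{shared_frags[0]:.0f}_{k}",
                mz=prec,
                rt_apex=5.0 + k,
                height=1e5,
                ms2=toy_spectrum(
                    peaks, precursor_mz=prec, polarity=polarity,
                    spectrum_id=f"s{prec:.1f}",
                ),
            )
        )
    return feats


FRAGS_A = [110.0, 125.0, 140.5, 155.2, 170.9, 190.3]
FRAGS_B = [310.1, 325.7, 333.3, 351.2, 377.7, 390.0]


def test_single_feature_network():
    (f,) = _family([300.0], FRAGS_A)[:1]
    g = build_network([f])
    stats = network_stats(g)
    assert stats["total_nodes"] == 1
    assert stats["n_edges"] == 0
    assert stats["n_clusters"] == 0
    assert stats["non_clustered_nodes"] == 1


def test_structural_family_forms_one_cluster():
    """Aglycone / glucuronide / methylated analogs sharing six fragments
    cluster together."""
    feats = _family([270.0, 446.03, 284.02], FRAGS_A)
    g = build_network(feats)
    stats = network_stats(g)
    assert stats["total_nodes"] == 3
    assert stats["n_clusters"] == 1
    assert stats["clustered_nodes"] == 3
    for _, _, d in g.edges(data=True):
        assert d["cosine"] >= 0.70
        assert d["n_matched"] >= 6


def test_two_unrelated_families_make_two_clusters():
    feats = _family([270.0, 446.03], FRAGS_A) + _family([500.0, 514.02], FRAGS_B)
    g = build_network(feats)
    assert network_stats(g)["n_clusters"] == 2


def test_node_count_is_threshold_independent():
    feats = _family([270.0, 446.03, 284.02], FRAGS_A)
    for min_cos in (0.1, 0.7, 0.99):
        g = build_network(feats, NetworkParams(min_cosine=min_cos))
        assert g.number_of_nodes() == 3


def test_raising_min_cosine_never_adds_edges():
    rng = np.random.default_rng(9)
    feats = []
    for k in range(8):
        n = int(rng.integers(6, 10))
        peaks = np.column_stack(
            (np.sort(rng.choice(FRAGS_A + FRAGS_B, n, replace=False)),
             rng.uniform(10, 100, n))
        )
        feats.append(
            Feature(id=f"r{k}", mz=float(rng.uniform(250, 600)), rt_apex=1.0 + k,
                    height=1e5,
                    ms2=toy_spectrum(peaks, precursor_mz=float(rng.uniform(250, 600))))
        )
    previous = None
    for min_cos in (0.0, 0.3, 0.5, 0.7, 0.9, 1.0):
        g = build_network(feats, NetworkParams(min_cosine=min_cos, min_matched_peaks=2))
        edges = g.number_of_edges()
        if previous is not None:
            assert edges <= previous
        previous = edges


# ---------------------------------------------------------------------------
# library matching and propagation
# ---------------------------------------------------------------------------


@pytest.fixture()
def baicalin_like_pair(tables):
    import numpy as np

    from phytoms import synthetic_data as sd

    t1, _ = tables
    p17 = next(c for c in t1 if c.id == "P17")
    clean = sd.SimulationConfig(seed=0, ms2_noise_fraction=0.0, mz_jitter_ppm_sd=0.0)
    lib_spec = sd.simulate_spectrum(p17, clean, np.random.default_rng(0))
    # observed spectrum: same chemistry, slight m/z jitter
    obs_cfg = sd.SimulationConfig(seed=3, ms2_noise_fraction=0.2, mz_jitter_ppm_sd=2.0)
    obs_spec = sd.simulate_spectrum(p17, obs_cfg, np.random.default_rng(3))
    feature = Feature(id="F1", mz=obs_spec.precursor_mz, rt_apex=7.3, height=1e5,
                      ms2=obs_spec)
    return p17, lib_spec, feature


def test_library_match_recovers_planted_identity(baicalin_like_pair):
    p17, lib_spec, feature = baicalin_like_pair
    params = NetworkParams(min_matched_peaks=4, library_min_matched_peaks=4)
    hit = library_match(feature, [(p17, lib_spec)], params)
    assert hit is not None
    record, cos, n = hit
    assert record.name == "Baicalin"
    assert cos >= 0.70


def test_empty_library_returns_none(baicalin_like_pair):
    _, _, feature = baicalin_like_pair
    assert library_match(feature, []) is None


def test_decoy_library_returns_none(baicalin_like_pair):
    p17, lib_spec, feature = baicalin_like_pair
    rng = np.random.default_rng(1)
    decoy = toy_spectrum(
        np.column_stack((np.sort(rng.uniform(500, 1200, len(lib_spec))),
                         lib_spec.intensity)),
        precursor_mz=lib_spec.precursor_mz,
        spectrum_id="decoy",
    )
    assert library_match(feature, [(p17, decoy)]) is None


def test_annotation_propagates_class_hypothesis():
    feats = _family([270.0, 446.03], FRAGS_A)
    g = build_network(feats)
    node = feats[0].id
    g.nodes[node].update(
        annotation="baicalein", annotation_source="library",
        compound_class="flavonoids",
    )
    propagate_annotations(g)
    other = feats[1].id
    assert g.nodes[other]["class_hypothesis"] == "flavonoids"
    assert g.nodes[node].get("class_hypothesis") is None


def test_conflicting_cluster_classes_flag_ambiguous():
    feats = _family([270.0, 446.03, 284.02], FRAGS_A)
    g = build_network(feats)
    g.nodes[feats[0].id].update(
        annotation="x", annotation_source="library", compound_class="flavonoids"
    )
    g.nodes[feats[1].id].update(
        annotation="y", annotation_source="library", compound_class="terpenoids"
    )
    propagate_annotations(g)
    unknown = g.nodes[feats[2].id]
    assert unknown["class_hypothesis"] == "ambiguous"
    assert set(unknown["class_candidates"].split(";")) == {"flavonoids", "terpenoids"}


def test_singleton_unknown_is_unchanged():
    feats = _family([270.0], FRAGS_A)
    g = build_network(feats)
    propagate_annotations(g)
    assert "class_hypothesis" not in g.nodes[feats[0].id]
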