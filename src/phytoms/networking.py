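"""Feature-based molecular networking.

Aligned features carrying MS2 spectra become nodes; edges connect pairs
whose modified-cosine similarity and matched-peak count clear the
thresholds (defaults: cosine >= 0.70 with >= 6 matched fragments at
0.02 Da tolerances).  Connected components with at least two nodes are
"clusters"; structurally related compounds co-cluster because they share
fragments directly or shifted by the precursor mass difference.

The modified cosine operates on square-root-transformed intensities and
allows each fragment pair to match either directly or shifted by the
precursor delta; a greedy one-to-one matching (descending pair score)
approximates the optimal assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .feature_finder import Feature
from .spectra_io import CompoundRecord, Spectrum

__all__ = [
    "NetworkParams",
    "modified_cosine",
    "build_network",
    "network_stats",
    "library_match",
    "propagate_annotations",
]


@dataclass(frozen=True)
class NetworkParams:
    precursor_tol: float = 0.02  # Da
    fragment_tol: float = 0.02  # Da
    min_cosine: float = 0.70
    min_matched_peaks: int = 6
    library_min_matched_peaks: int = 6
    top_k: int | None = None  # optional per-node edge cap, off by default
    max_component: int | None = None  # optional component cap, off by default


def modified_cosine(
    a: Spectrum, b: Spectrum, fragment_tol: float = 0.02
) -> tuple[float, int]:
    """Modified-cosine similarity and matched-peak count for two spectra.

    Peaks pair when their m/z agree within tolerance either directly or
    after shifting by the precursor mass difference; among candidate
    pairs a one-to-one matching is chosen greedily by descending
    sqrt-intensity product.  Returns (cosine in [0, 1], n matched).
    """
    if a.polarity != b.polarity:
        raise ValueError(
            f"cannot compare spectra of opposite polarity "
            f"({a.id}: {a.polarity}, {b.id}: {b.polarity})"
        )
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    ia = np.sqrt(a.intensity)
    ib = np.sqrt(b.intensity)
    norm = float(np.linalg.norm(ia) * np.linalg.norm(ib))
    if norm == 0.0:
        return 0.0, 0
    shift = b.precursor_mz - a.precursor_mz

    pairs = []
    for i, mza in enumerate(a.mz):
        for j, mzb in enumerate(b.mz):
            d = mzb - mza
            if abs(d) <= fragment_tol or abs(d - shift) <= fragment_tol:
                pairs.append((float(ia[i] * ib[j]), i, j))
    # greedy descending score; deterministic tie-break on indices
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    total = 0.0
    n_matched = 0
    for score, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += score
        n_matched += 1
    return min(total / norm, 1.0), n_matched


def build_network(
    features: Sequence[Feature], params: NetworkParams | None = None
) -> nx.Graph:
    """All-pairs modified-cosine network over MS2-bearing features.

    Every feature becomes a node regardless of thresholds; an edge is
    kept iff cosine >= min_cosine and matched peaks >= min_matched_peaks.
    Opposite-polarity pairs are never scored.
    """
    params = params or NetworkParams()
    g = nx.Graph()
    feats = list(features)
    for f in feats:
        g.add_node(
            f.id,
            mz=float(f.mz),
            rt=float(f.rt_apex),
            annotation="",
            annotation_source="none",
            compound_class="",
        )
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            a, b = feats[i], feats[j]
            if a.ms2 is None or b.ms2 is None:
                continue
            if a.ms2.polarity != b.ms2.polarity:
                continue
            cos, n = modified_cosine(a.ms2, b.ms2, params.fragment_tol)
            if cos >= params.min_cosine and n >= params.min_matched_peaks:
                g.add_edge(a.id, b.id, cosine=float(cos), n_matched=int(n))
    if params.top_k is not None:
        _prune_top_k(g, params.top_k)
    return g


def _prune_top_k(g: nx.Graph, k: int) -> None:
    """Keep an edge only if it ranks in the top-k of both endpoints."""
    doomed = []
    for u, v, data in g.edges(data=True):
        for node, other in ((u, v), (v, u)):
            ranked = sorted(
                g.edges(node, data=True), key=lambda e: -e[2]["cosine"]
            )
            if (u, v) not in [(e[0], e[1]) for e in ranked[:k]] and (
                v, u
            ) not in [(e[0], e[1]) for e in ranked[:k]]:
                doomed.append((u, v))
                break
    g.remove_edges_from(doomed)


def network_stats(g: nx.Graph) -> dict[str, int]:
    """Node/cluster accounting: a cluster is a component with >= 2 nodes."""
    components = list(nx.connected_components(g))
    clusters = [c for c in components if len(c) >= 2]
    clustered = sum(len(c) for c in clusters)
    annotated = sum(
        1 for _, d in g.nodes(data=True) if d.get("annotation_source") not in ("none", "")
    )
    return {
        "total_nodes": g.number_of_nodes(),
        "clustered_nodes": clustered,
        "non_clustered_nodes": g.number_of_nodes() - clustered,
        "n_clusters": len(clusters),
        "n_edges": g.number_of_edges(),
        "annotated_nodes": annotated,
    }


def library_match(
    feature: Feature,
    library: Sequence[tuple[CompoundRecord, Spectrum]],
    params: NetworkParams | None = None,
) -> tuple[CompoundRecord, float, int] | None:
    """Best spectral-library hit for one feature, or None.

    A hit needs cosine >= min_cosine and matched peaks >=
    library_min_matched_peaks against a same-polarity library spectrum.
    """
    params = params or NetworkParams()
    if feature.ms2 is None:
        return None
    best = None
    for record, spectrum in library:
        if spectrum.polarity != feature.ms2.polarity:
            continue
        cos, n = modified_cosine(feature.ms2, spectrum, params.fragment_tol)
        if cos < params.min_cosine or n < params.library_min_matched_peaks:
            continue
        if best is None or cos > best[1]:
            best = (record, cos, n)
    return best


def annotate_with_library(
    g: nx.Graph,
    features: Sequence[Feature],
    library: Sequence[tuple[CompoundRecord, Spectrum]],
    params: NetworkParams | None = None,
) -> nx.Graph:
    """Attach library annotations to matching network nodes in place."""
    by_id = {f.id: f for f in features}
    for node in g.nodes:
        f = by_id.get(node)
        if f is None:
            continue
        hit = library_match(f, library, params)
        if hit is not None:
            record, cos, n = hit
            g.nodes[node].update(
                annotation=record.name,
                annotation_source="library",
                compound_class=record.compound_class,
                library_cosine=float(cos),
                library_matched_peaks=int(n),
            )
    return g


def propagate_annotations(g: nx.Graph) -> nx.Graph:
    """Give unannotated cluster members a class hypothesis.

    Members of a cluster that contains annotated nodes inherit the
    annotated class as a flagged hypothesis; conflicting classes within
    one cluster yield the hypothesis "ambiguous" with all candidates
    listed.  Library and reference-standard annotations are never
    overwritten; singletons are untouched.
    """
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        classes = sorted(
            {
                g.nodes[n]["compound_class"]
                for n in comp
                if g.nodes[n].get("annotation_source") in ("library", "reference-standard")
                and g.nodes[n].get("compound_class")
            }
        )
        if not classes:
            continue
        hypothesis = classes[0] if len(classes) == 1 else "ambiguous"
        for n in comp:
            if g.nodes[n].get("annotation_source") in ("library", "reference-standard"):
                continue
            g.nodes[n]["class_hypothesis"] = hypothesis
            if len(classes) > 1:
                g.nodes[n]["class_candidates"] = ";".join(classes)
    return g
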