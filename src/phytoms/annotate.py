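"""Diagnostic-ion and neutral-loss rule engine.

Compound classes leave characteristic traces in tandem spectra:
retro-Diels-Alder products of the flavonoid C ring, glycoside losses
(162.0528 Da glucosyl, 176.0321 Da glucuronyl), serial CH2 losses of
sesquiterpenes, the ring-C cleavage ions of monoterpene indole
alkaloids, and so on.  The engine encodes each as a
:class:`FragmentationRule` and scores a spectrum against every class:
diagnostic ions are matched against fragment peaks, neutral losses
against all precursor/fragment mass differences, and serial losses
against the longest equally-spaced peak ladder.

Scoring is deliberately minimal so the qualitative filtering practice
becomes reproducible: each satisfied rule contributes its weight
(diagnostic ions default 2, losses 1); a class is assigned when at
least ``min_rules`` rules fire and the best class beats the runner-up
by at least ``min_margin``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .spectra_io import COMPOUND_CLASSES, Spectrum

__all__ = [
    "FragmentationRule",
    "RuleBase",
    "ClassificationResult",
    "load_rulebase",
    "default_rulebase",
    "detect_neutral_losses",
    "detect_serial_losses",
    "classify_spectrum",
    "validate_annotation",
]

RULE_KINDS = ("diagnostic_ion", "neutral_loss", "serial_loss")


@dataclass(frozen=True)
class FragmentationRule:
    rule_id: str
    compound_class: str
    polarity: str  # "positive" | "negative"
    kind: str  # diagnostic_ion | neutral_loss | serial_loss
    value: float  # m/z (diagnostic) or Da (loss)
    series_count: int = 1  # for serial_loss: required consecutive losses
    tolerance: float = 0.01  # Da
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(f"{self.rule_id}: unknown rule kind {self.kind!r}")
        if self.value <= 0:
            raise ValueError(f"{self.rule_id}: non-positive value")
        if self.kind == "serial_loss" and self.series_count < 2:
            raise ValueError(f"{self.rule_id}: serial_loss needs series_count >= 2")
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(
                f"{self.rule_id}: unknown class {self.compound_class!r}"
            )


@dataclass
class RuleBase:
    rules: list[FragmentationRule] = field(default_factory=list)

    def for_polarity(self, polarity: str) -> list[FragmentationRule]:
        return [r for r in self.rules if r.polarity == polarity]

    @property
    def classes(self) -> list[str]:
        return sorted({r.compound_class for r in self.rules})


@dataclass
class ClassificationResult:
    compound_class: str  # class label or "unclassified"
    score: float
    matched_rules: list[tuple[str, float]]  # (rule_id, observed m/z or loss)
    runner_up_class: str = ""
    runner_up_score: float = 0.0


def load_rulebase(path: str | Path) -> RuleBase:
    df = pd.read_csv(path)
    rules = [
        FragmentationRule(
            rule_id=r["rule_id"],
            compound_class=r["compound_class"],
            polarity=r["polarity"],
            kind=r["kind"],
            value=float(r["value"]),
            series_count=int(r["series_count"]),
            tolerance=float(r["tolerance"]),
            weight=float(r["weight"]),
        )
        for _, r in df.iterrows()
    ]
    return RuleBase(rules)


def default_rulebase() -> RuleBase:
    """The packaged rulebase covering the classes with known chemistry."""
    ref = importlib.resources.files("phytoms") / "data" / "fragmentation_rules.csv"
    with importlib.resources.as_file(ref) as path:
        return load_rulebase(path)


# ---------------------------------------------------------------------------
# primitive detectors
# ---------------------------------------------------------------------------


def detect_neutral_losses(
    spectrum: Spectrum, include_precursor: bool = True
) -> list[tuple[float, float, float]]:
    """All pairwise (from_mz, to_mz, loss) with loss > 1 Da, sorted by loss.

    The precursor participates as a virtual peak, so single-fragment
    spectra still expose the precursor-to-fragment loss.
    """
    mzs = list(spectrum.mz)
    if include_precursor:
        mzs.append(spectrum.precursor_mz)
    losses = []
    for i, hi in enumerate(mzs):
        for j, lo in enumerate(mzs):
            if i == j:
                continue
            loss = hi - lo
            if loss > 1.0:
                losses.append((hi, lo, loss))
    losses.sort(key=lambda t: (t[2], t[0]))
    return losses


def detect_serial_losses(
    spectrum: Spectrum, delta: float, tol: float = 0.01
) -> int:
    """Length (in peaks) of the longest chain spaced by ``delta`` +/- tol.

    The chain may start from the precursor or any fragment; a single
    unchained peak counts as length 1.
    """
    nodes = sorted([*spectrum.mz, spectrum.precursor_mz], reverse=True)
    n = len(nodes)
    best = [1] * n  # longest chain starting at node i, walking down in mass
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if abs((nodes[i] - nodes[j]) - delta) <= tol:
                best[i] = max(best[i], 1 + best[j])
    return max(best, default=1)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _satisfied(rule: FragmentationRule, spectrum: Spectrum,
               losses: list[tuple[float, float, float]]) -> float | None:
    """Observed m/z or loss if the rule fires on this spectrum, else None."""
    if rule.kind == "diagnostic_ion":
        for mz in spectrum.mz:
            if abs(mz - rule.value) <= rule.tolerance:
                return float(mz)
        return None
    if rule.kind == "neutral_loss":
        for _, _, loss in losses:
            if abs(loss - rule.value) <= rule.tolerance:
                return float(loss)
        return None
    chain = detect_serial_losses(spectrum, rule.value, rule.tolerance)
    if chain - 1 >= rule.series_count:
        return float(chain - 1)
    return None


def classify_spectrum(
    spectrum: Spectrum,
    rulebase: RuleBase | None = None,
    min_rules: int = 2,
    min_margin: float = 1.0,
) -> ClassificationResult:
    """Assign a compound class from diagnostic-ion / neutral-loss evidence.

    Per class the score sums the weights of satisfied same-polarity
    rules; the top class is returned when at least ``min_rules`` of its
    rules fire and its score exceeds the runner-up by ``min_margin``,
    otherwise "unclassified" (with both scores reported).
    """
    rulebase = rulebase or default_rulebase()
    losses = detect_neutral_losses(spectrum)
    per_class: dict[str, tuple[float, int, list[tuple[str, float]]]] = {}
    for rule in rulebase.for_polarity(spectrum.polarity):
        obs = _satisfied(rule, spectrum, losses)
        if obs is None:
            continue
        score, count, matched = per_class.get(rule.compound_class, (0.0, 0, []))
        per_class[rule.compound_class] = (
            score + rule.weight,
            count + 1,
            matched + [(rule.rule_id, obs)],
        )
    if not per_class:
        return ClassificationResult("unclassified", 0.0, [])
    ranking = sorted(per_class.items(), key=lambda kv: (-kv[1][0], kv[0]))
    best_class, (best_score, best_count, best_matched) = ranking[0]
    runner_class, runner_score = ("", 0.0)
    if len(ranking) > 1:
        runner_class, runner_score = ranking[1][0], ranking[1][1][0]
    if best_count >= min_rules and best_score - runner_score >= min_margin:
        return ClassificationResult(
            best_class, best_score, best_matched, runner_class, runner_score
        )
    return ClassificationResult(
        "unclassified", best_score,
        [], best_class, best_score,
    )


def validate_annotation(
    spectrum: Spectrum | None,
    proposed_class: str,
    rulebase: RuleBase | None = None,
) -> tuple[bool, str]:
    """Accept or reject a proposed class against the rule evidence.

    Accept when the rule engine agrees, or when it is unclassified but
    the proposed class is its top-scoring candidate (compatible
    evidence).  Reject with the conflicting class when the engine
    confidently assigns something else, or with "no evidence" when no
    spectrum is available.  This is the pruning step that removes
    spectral-library false positives from the network.
    """
    if spectrum is None or len(spectrum) == 0:
        return False, "no evidence"
    result = classify_spectrum(spectrum, rulebase)
    if result.compound_class == proposed_class:
        return True, (
            f"class confirmed (score {result.score:g}, "
            f"rules {[r for r, _ in result.matched_rules]})"
        )
    if result.compound_class == "unclassified":
        if result.runner_up_class == proposed_class and result.runner_up_score > 0:
            return True, (
                f"compatible: top candidate {proposed_class} "
                f"(score {result.runner_up_score:g}, below decision margin)"
            )
        return False, (
            f"no supporting evidence for {proposed_class}; "
            f"top candidate {result.runner_up_class or 'none'}"
        )
    return False, (
        f"conflicting evidence: rules assign {result.compound_class} "
        f"(score {result.score:g}) not {proposed_class}"
    )
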