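"""Hard pre-filters applied to guide candidates before SVM scoring.

Each rule excludes a guide property strongly enriched among non-functional
guides, so most unpromising candidates are discarded cheaply before the
model runs:

========== ==============================================================
SELF_FOLD  guide self-folding dG below -8 kcal/mol (stable self-structure)
DUPLEX     guide:target hybrid dG below -22 kcal/mol (over-stable duplex)
GC         GC content above 80 %
UUU_SEED   UUU within the last six guide bases (pol-III termination signal)
REPETITIVE AAAAA / CCCCC / GGGG / UUUU run anywhere in the guide
POS19_U    U at guide position 19
POS20_CU   C or U at guide position 20 (pairs with scaffold AAG at 51-53)
========== ==============================================================

Thresholds print as strict inequalities, so boundary values pass
(dG = -8.0 exactly passes SELF_FOLD; GC = 0.80 exactly passes GC).  All
rules are evaluated — the decision lists every failed rule, which makes
class-level audits of the filters informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from ._seq import validate_guide
from .screen_io import LabeledScreen
from .sequence_features import gc_content, motif_flags
from .structure_features import duplex_dg, guide_self_fold_dg

RULES = ("SELF_FOLD", "DUPLEX", "GC", "UUU_SEED", "REPETITIVE", "POS19_U", "POS20_CU")

#: Default exclusion thresholds (strict inequalities).
DEFAULT_THRESHOLDS = {
    "self_fold_dg": -8.0,  # exclude if self-fold dG < this (kcal/mol)
    "duplex_dg": -22.0,  # exclude if hybrid dG < this (kcal/mol)
    "gc_max": 0.80,  # exclude if GC fraction > this
}


@dataclass(frozen=True)
class PrefilterDecision:
    passed: bool
    failed_rules: tuple[str, ...] = field(default_factory=tuple)


def load_thresholds(path) -> dict:
    """Read a YAML config; returns the ``thresholds`` block merged over defaults."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = dict(DEFAULT_THRESHOLDS)
    merged.update(cfg.get("thresholds", {}))
    return merged


def apply_prefilters(guide: str, thresholds: dict | None = None) -> PrefilterDecision:
    """Evaluate every exclusion rule on one guide (no short-circuiting)."""
    g = validate_guide(guide)
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    failed = []
    if guide_self_fold_dg(g) < th["self_fold_dg"]:
        failed.append("SELF_FOLD")
    if duplex_dg(g) < th["duplex_dg"]:
        failed.append("DUPLEX")
    if gc_content(g) > th["gc_max"]:
        failed.append("GC")
    flags = motif_flags(g)
    if flags["uuu_seed"]:
        failed.append("UUU_SEED")
    if flags["repetitive"]:
        failed.append("REPETITIVE")
    if g[18] == "U":
        failed.append("POS19_U")
    if g[19] in "CU":
        failed.append("POS20_CU")
    return PrefilterDecision(passed=not failed, failed_rules=tuple(failed))


def audit_prefilters(screen: LabeledScreen, thresholds: dict | None = None) -> dict:
    """Per-class pass/exclusion fractions of the filters on a labeled screen.

    Returns fractions of functional guides retained and non-functional
    guides excluded, plus per-rule failure counts by class.
    """
    per_rule = {rule: {"functional": 0, "non-functional": 0} for rule in RULES}
    counts = {"functional": 0, "non-functional": 0}
    passed = {"functional": 0, "non-functional": 0}
    for rec, label in zip(screen.records, screen.labels):
        if label not in counts:
            continue
        counts[label] += 1
        decision = apply_prefilters(rec.guide_seq, thresholds)
        if decision.passed:
            passed[label] += 1
        for rule in decision.failed_rules:
            per_rule[rule][label] += 1
    if not counts["functional"] or not counts["non-functional"]:
        raise ValueError("audit requires both labeled classes")
    return {
        "n_functional": counts["functional"],
        "n_nonfunctional": counts["non-functional"],
        "functional_retained": passed["functional"] / counts["functional"],
        "nonfunctional_excluded": 1.0 - passed["non-functional"] / counts["non-functional"],
        "per_rule_failures": per_rule,
    }
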