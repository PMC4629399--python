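"""Guide-sequence features and functional-vs-non-functional enrichment tests.

All features are computed on the 20-nt guide in RNA spelling, positions
numbered 1-20 from the 5' end (position 20 abuts the PAM).  Besides the raw
features, :func:`feature_stats` provides the enrichment-ratio + significance
machinery used to compare feature distributions between functional and
non-functional guides (Welch t-test for counts/continuous features,
chi-squared for binary flags).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._seq import RNA_BASES, validate_guide

#: Homopolymer runs correlated with poor oligo synthesis / transcription:
#: AAAAA, CCCCC, GGGG, UUUU.  GGGG additionally favors guanine-tetrad
#: structures that occlude the guide.
REPETITIVE_MOTIFS = ("AAAAA", "CCCCC", "GGGG", "UUUU")

#: UUU within the last six guide bases (positions 15-20) can act as a
#: premature pol-III termination signal in the seed region.
UUU_SEED_WINDOW_START = 15  # 1-based


def kmer_names(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(RNA_BASES, repeat=k)]


def gc_content(guide: str) -> float:
    """(#G + #C) / 20."""
    g = validate_guide(guide)
    return (g.count("G") + g.count("C")) / len(g)


def kmer_counts(guide: str, k: int) -> np.ndarray:
    """Overlapping k-mer counts over the 4^k k-mers in lexicographic (ACGU) order.

    The vector sums to 21 - k.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    g = validate_guide(guide)
    index = {name: i for i, name in enumerate(kmer_names(k))}
    counts = np.zeros(4**k, dtype=int)
    for i in range(len(g) - k + 1):
        counts[index[g[i : i + k]]] += 1
    return counts


def motif_flags(guide: str) -> dict[str, bool]:
    """Synthesis/transcription motif flags.

    repetitive: any of AAAAA / CCCCC / GGGG / UUUU present anywhere;
    gggg: GGGG present (implies repetitive);
    uuu_seed: UUU present within positions 15-20.
    """
    g = validate_guide(guide)
    return {
        "repetitive": any(m in g for m in REPETITIVE_MOTIFS),
        "gggg": "GGGG" in g,
        "uuu_seed": "UUU" in g[UUU_SEED_WINDOW_START - 1 :],
    }


def position_onehot(guide: str) -> np.ndarray:
    """20x4 one-hot matrix; row i (0-based) encodes the base at position i+1."""
    g = validate_guide(guide)
    mat = np.zeros((20, 4), dtype=int)
    for i, b in enumerate(g):
        mat[i, RNA_BASES.index(b)] = 1
    return mat


@dataclass(frozen=True)
class SequenceFeatureSet:
    """All sequence-level features for one guide."""

    gc: float
    mono_counts: np.ndarray  # 4
    di_counts: np.ndarray  # 16
    tri_counts: np.ndarray  # 64
    repetitive: bool
    gggg: bool
    uuu_seed: bool
    pos_onehot: np.ndarray  # 20x4

    @classmethod
    def from_guide(cls, guide: str) -> "SequenceFeatureSet":
        g = validate_guide(guide)
        flags = motif_flags(g)
        return cls(
            gc=gc_content(g),
            mono_counts=kmer_counts(g, 1),
            di_counts=kmer_counts(g, 2),
            tri_counts=kmer_counts(g, 3),
            repetitive=flags["repetitive"],
            gggg=flags["gggg"],
            uuu_seed=flags["uuu_seed"],
            pos_onehot=position_onehot(g),
        )


@dataclass(frozen=True)
class EnrichmentStat:
    """Enrichment of a feature in functional vs non-functional guides."""

    feature_name: str
    enrichment_ratio: float
    p_value: float
    test: str  # "t-test" or "chi-squared"


def feature_stats(
    functional, nonfunctional, feature_name: str = "", binary: bool | None = None
) -> EnrichmentStat:
    """Enrichment ratio and two-sided significance for one feature.

    Continuous/count features are compared with Welch's t-test and the ratio
    of class means; binary flags with a Pearson chi-squared test (no
    continuity correction) and the ratio of class proportions.  ``binary`` is
    inferred from the values when not given.
    """
    f = np.asarray(functional, dtype=float)
    nf = np.asarray(nonfunctional, dtype=float)
    if f.size == 0 or nf.size == 0:
        raise ValueError("both groups must be non-empty")
    if binary is None:
        binary = set(np.unique(np.concatenate([f, nf]))) <= {0.0, 1.0}

    mean_nf = nf.mean()
    if mean_nf == 0:
        raise ValueError(
            f"non-functional mean is zero for {feature_name!r}; enrichment ratio undefined"
        )
    ratio = f.mean() / mean_nf

    if binary:
        table = np.array(
            [
                [f.sum(), f.size - f.sum()],
                [nf.sum(), nf.size - nf.sum()],
            ]
        )
        if np.any(table.sum(axis=0) == 0):
            p = 1.0
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
        test = "chi-squared"
    else:
        if f.std() == 0 and nf.std() == 0 and f.mean() == nf.mean():
            p = 1.0  # identical degenerate groups
        else:
            _, p = stats.ttest_ind(f, nf, equal_var=False)
        test = "t-test"
    return EnrichmentStat(
        feature_name=feature_name,
        enrichment_ratio=float(ratio),
        p_value=float(min(max(p, np.nextafter(0, 1)), 1.0)),
        test=test,
    )
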