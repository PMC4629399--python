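"""Screen-table I/O, percentile labeling, and the synthetic screen generator.

A "screen" is a table of 20-nt guides with a per-guide activity measure
(higher = more active) and the gene each guide targets, in the style of
large flow-cytometry knockout screens.  Training data for the potency model
are the activity extremes: guides at or above the 80th percentile are
labeled functional, those at or below the 20th percentile non-functional,
and the middle is excluded.

The synthetic generator produces screens with a planted sequence/structure
signal so the whole pipeline (feature recovery, SVM cross-validation) is
testable without downloading a published screen.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import RNA_BASES, normalize_rna, validate_guide
from .structure_features import guide_self_fold_dg

FUNCTIONAL = "functional"
NON_FUNCTIONAL = "non-functional"
EXCLUDED = "excluded-middle"

#: Number of genes in the synthetic screen; leave-one-gene-out CV therefore
#: trains on eight genes and tests on the ninth in each fold.
SYNTHETIC_GENE_COUNT = 9


@dataclass(frozen=True)
class ScreenRecord:
    """One guide from an activity screen."""

    guide_seq: str  # 20-nt RNA
    gene_id: str
    activity: float
    context_seq: str | None = None  # optional 30-nt genomic context

    def __post_init__(self):
        object.__setattr__(self, "guide_seq", validate_guide(self.guide_seq))
        if not np.isfinite(self.activity):
            raise ValueError(f"activity must be finite, got {self.activity}")


@dataclass
class LabeledScreen:
    """Screen records with functional / non-functional / excluded-middle labels."""

    records: list[ScreenRecord]
    labels: list[str] = field(default_factory=list)

    def subset(self, label: str) -> list[ScreenRecord]:
        return [r for r, l in zip(self.records, self.labels) if l == label]

    @property
    def functional(self) -> list[ScreenRecord]:
        return self.subset(FUNCTIONAL)

    @property
    def nonfunctional(self) -> list[ScreenRecord]:
        return self.subset(NON_FUNCTIONAL)

    def training_records(self) -> tuple[list[ScreenRecord], np.ndarray]:
        """Extreme-class records and their binary labels (functional = 1)."""
        recs, ys = [], []
        for r, l in zip(self.records, self.labels):
            if l == FUNCTIONAL:
                recs.append(r)
                ys.append(1)
            elif l == NON_FUNCTIONAL:
                recs.append(r)
                ys.append(0)
        return recs, np.asarray(ys, dtype=int)


def read_screen_table(path, column_map: dict[str, str] | None = None) -> list[ScreenRecord]:
    """Read a TSV/CSV screen table (header row required).

    ``column_map`` maps the canonical names ``guide_seq``, ``gene_id``,
    ``activity`` (and optionally ``context_seq``) to the file's column names;
    by default the canonical names are used directly.  T is normalized to U
    in guide sequences.  Malformed rows raise with their line number.
    """
    cmap = {k: k for k in ("guide_seq", "gene_id", "activity", "context_seq")}
    if column_map:
        cmap.update(column_map)
    # dtype=str + explicit float() keeps activity exact through round trips
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for canon in ("guide_seq", "gene_id", "activity"):
        if cmap[canon] not in df.columns:
            raise ValueError(f"missing required column {cmap[canon]!r} in {path}")
    records = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            ctx = None
            if cmap["context_seq"] in df.columns:
                raw = row[cmap["context_seq"]]
                if isinstance(raw, str) and raw.strip():
                    ctx = raw.strip().upper()
            records.append(
                ScreenRecord(
                    guide_seq=str(row[cmap["guide_seq"]]),
                    gene_id=str(row[cmap["gene_id"]]),
                    activity=float(row[cmap["activity"]]),
                    context_seq=ctx,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {line_no}: {exc}") from exc
    return records


def write_screen_table(records: list[ScreenRecord], path) -> None:
    """Write records as TSV (canonical column names)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["guide_seq", "gene_id", "activity", "context_seq"])
        for r in records:
            w.writerow([r.guide_seq, r.gene_id, repr(r.activity), r.context_seq or ""])


def label_by_percentile(
    records: list[ScreenRecord], top: float = 0.2, bottom: float = 0.2
) -> LabeledScreen:
    """Label activity extremes: top fraction functional, bottom non-functional.

    Thresholds are empirical quantiles (linear interpolation) with inclusive
    comparisons, so records tied exactly at a boundary fall into the extreme
    class.  Everything between is labeled excluded-middle.
    """
    if not records:
        raise ValueError("no records to label")
    if not (0 < bottom and 0 < top and bottom + top <= 1):
        raise ValueError(f"invalid fractions top={top} bottom={bottom}")
    acts = np.array([r.activity for r in records], dtype=float)
    if np.all(acts == acts[0]):
        raise ValueError("all activities identical; percentile stratification undefined")
    lo = np.quantile(acts, bottom)
    hi = np.quantile(acts, 1.0 - top)
    labels = [
        FUNCTIONAL if a >= hi else NON_FUNCTIONAL if a <= lo else EXCLUDED for a in acts
    ]
    return LabeledScreen(records=list(records), labels=labels)


def _planted_score(guide: str) -> float:
    """Linear potency signal planted by the synthetic generator.

    More adenines help; a GGGG run, guide self-structure, and a pyrimidine
    at position 20 hurt — the same directions the potency features measure,
    so parameter-recovery tests are meaningful.
    """
    a_count = guide.count("A")
    gggg = 1.0 if "GGGG" in guide else 0.0
    self_dg = guide_self_fold_dg(guide)
    pos20_pyr = 1.0 if guide[19] in "CU" else 0.0
    return a_count - 4.0 * gggg - abs(self_dg) - 2.0 * pos20_pyr


def generate_synthetic_screen(
    n: int, seed: int, effect_size: float = 2.0
) -> list[ScreenRecord]:
    """Generate a synthetic activity screen with a planted signal.

    Guides are uniform over {A,C,G,U}^20 with UUUU-containing guides rejected
    (screens driven by the pol-III U6 promoter preselect those out).
    Activity is ``effect_size`` times the z-scored planted signal plus
    standard-normal noise; ``effect_size=0`` yields pure noise.  Gene ids are
    assigned round-robin over nine synthetic genes.  Fixed seed gives a
    bit-reproducible table.
    """
    if n < 20:
        raise ValueError(f"n must be >= 20, got {n}")
    rng = np.random.default_rng(seed)
    guides: list[str] = []
    while len(guides) < n:
        g = "".join(rng.choice(list(RNA_BASES), size=20))
        if "UUUU" in g:
            continue
        guides.append(g)
    signal = np.array([_planted_score(g) for g in guides])
    sd = signal.std()
    z = (signal - signal.mean()) / sd if sd > 0 else np.zeros(n)
    activity = effect_size * z + rng.standard_normal(n)
    return [
        ScreenRecord(
            guide_seq=g,
            gene_id=f"gene{(i % SYNTHETIC_GENE_COUNT) + 1}",
            activity=float(activity[i]),
        )
        for i, g in enumerate(guides)
    ]


# ---------------------------------------------------------------------------
# design report I/O

REPORT_COLUMNS = [
    "source_id",
    "start",  # 1-based protospacer start in the input record
    "strand",
    "guide",  # RNA spelling
    "pam",
    "gc",
    "self_fold_dg",
    "duplex_dg",
    "prefilter_failures",
    "seed_pam_hits",
    "similarity_hits",
    "svm_score",
    "rank",
]


def write_design_report(rows: list[dict], path) -> None:
    """Write design-report rows as TSV with the fixed column order.

    Rows are sorted by descending SVM score, then ascending start coordinate
    (unscored rows sort after scored ones).  Round-trips through
    :func:`read_design_report`.
    """
    def sort_key(row):
        score = row.get("svm_score")
        return (
            -(score if score is not None and score == score else float("-inf")),
            row.get("source_id", ""),
            row.get("start", 0),
        )

    ordered = sorted(rows, key=sort_key)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REPORT_COLUMNS)
        for row in ordered:
            w.writerow(["" if row.get(c) is None else row.get(c) for c in REPORT_COLUMNS])


def read_design_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
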