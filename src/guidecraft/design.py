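"""End-to-end guide design: PAM scan -> pre-filter -> SVM score -> off-target filter.

Candidates are every 20-mer adjacent to an NGG PAM on either strand of the
user's target sequence.  Cheap hard pre-filters run first so the SVM only
scores promising candidates; candidates surviving the off-target screen are
ranked by descending potency score.  Every enumerated candidate appears in
the report, either with a rank or with its elimination reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import SeqIO

from ._seq import dna_revcomp, normalize_rna
from .activity_model import TrainedModel
from .offtarget import ExonIndex, seed_pam_hits, similarity_hits
from .prefilter import PrefilterDecision, apply_prefilters
from .screen_io import write_design_report
from .sequence_features import gc_content
from .structure_features import duplex_dg, guide_self_fold_dg


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt protospacer-matching guide found next to an NGG PAM.

    ``start`` is the 0-based offset of the protospacer 20-mer in the input
    record's + strand coordinates.  On the + strand the PAM occupies
    [start+20, start+23); on the - strand the guide is the reverse
    complement of input[start:start+20] and the PAM maps to [start-3, start).
    """

    guide_seq: str  # RNA spelling
    start: int
    strand: str
    pam: str  # DNA, NGG
    source_id: str


@dataclass
class DesignReportRow:
    candidate: GuideCandidate
    svm_score: float | None  # None when pre-filtered out
    prefilter: PrefilterDecision
    seed_pam_hits: int | None  # None when off-target screening disabled
    similarity_hits: int | None
    rank: int | None  # dense from 1 over surviving candidates

    @property
    def status(self) -> str:
        if not self.prefilter.passed:
            return "excluded-prefilter"
        if (self.seed_pam_hits or 0) or (self.similarity_hits or 0):
            return "excluded-offtarget"
        return "ok"


def scan_pam_sites(seq: str, source_id: str = "target") -> list[GuideCandidate]:
    """Enumerate all NGG-adjacent 20-mers on both strands.

    Candidates whose guide or PAM contains N are dropped.  Sequences shorter
    than 23 nt yield an empty list with a warning.
    """
    s = seq.upper()
    L = len(s)
    if L < 23:
        warnings.warn(f"{source_id}: sequence shorter than 23 nt, no candidates")
        return []
    candidates = []
    for strand in "+-":
        scan = s if strand == "+" else dna_revcomp(s)
        for i in range(L - 22):
            pam = scan[i + 20 : i + 23]
            if pam[1:3] != "GG":
                continue
            proto = scan[i : i + 20]
            if "N" in proto or "N" in pam:
                continue
            start = i if strand == "+" else L - i - 20
            candidates.append(
                GuideCandidate(
                    guide_seq=normalize_rna(proto),
                    start=start,
                    strand=strand,
                    pam=pam,
                    source_id=source_id,
                )
            )
    candidates.sort(key=lambda c: (c.start, c.strand))
    return candidates


def design_guides(
    records,
    model: TrainedModel,
    index: ExonIndex | None = None,
    exons: dict[str, str] | None = None,
    thresholds: dict | None = None,
    max_mismatches: int = 3,
) -> list[DesignReportRow]:
    """Run the full design pipeline over (id, sequence) target records.

    Stages, in order: PAM scan, hard pre-filters, SVM scoring of surviving
    candidates, off-target screen (when an exon index is supplied), then
    ranking of clean candidates by score (ties: fewer similarity near-misses,
    then 5'-most start).  The report contains every scanned candidate.
    """
    rows: list[DesignReportRow] = []
    for source_id, seq in records:
        for cand in scan_pam_sites(seq, source_id):
            decision = apply_prefilters(cand.guide_seq, thresholds)
            rows.append(
                DesignReportRow(
                    candidate=cand,
                    svm_score=None,
                    prefilter=decision,
                    seed_pam_hits=None,
                    similarity_hits=None,
                    rank=None,
                )
            )
    scored = [r for r in rows if r.prefilter.passed]
    if scored:
        scores = model.predict_scores([r.candidate.guide_seq for r in scored])
        for r, s in zip(scored, scores):
            r.svm_score = float(s)
    if index is not None:
        exon_seqs = exons if exons is not None else index.sequences
        for r in scored:
            r.seed_pam_hits = len(seed_pam_hits(r.candidate.guide_seq, index))
            r.similarity_hits = len(
                similarity_hits(r.candidate.guide_seq, exon_seqs, max_mismatches)
            )
    clean = [r for r in scored if r.status == "ok"]
    clean.sort(
        key=lambda r: (-r.svm_score, r.similarity_hits or 0, r.candidate.start, r.candidate.strand)
    )
    for i, r in enumerate(clean, start=1):
        r.rank = i
    return rows


def rows_to_dicts(rows: list[DesignReportRow]) -> list[dict]:
    """Flatten report rows for TSV export (1-based start coordinates)."""
    out = []
    for r in rows:
        c = r.candidate
        out.append(
            {
                "source_id": c.source_id,
                "start": c.start + 1,
                "strand": c.strand,
                "guide": c.guide_seq,
                "pam": c.pam,
                "gc": round(gc_content(c.guide_seq), 3),
                "self_fold_dg": guide_self_fold_dg(c.guide_seq),
                "duplex_dg": duplex_dg(c.guide_seq),
                "prefilter_failures": ";".join(r.prefilter.failed_rules) or "none",
                "seed_pam_hits": r.seed_pam_hits,
                "similarity_hits": r.similarity_hits,
                "svm_score": None if r.svm_score is None else round(r.svm_score, 6),
                "rank": r.rank,
            }
        )
    return out


def read_fasta_records(path) -> list[tuple[str, str]]:
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def run_design(
    targets_path,
    model: TrainedModel,
    out_path,
    index: ExonIndex | None = None,
    thresholds: dict | None = None,
    max_mismatches: int = 3,
) -> list[DesignReportRow]:
    """FASTA in, ranked TSV report out."""
    rows = design_guides(
        read_fasta_records(targets_path),
        model,
        index=index,
        thresholds=thresholds,
        max_mismatches=max_mismatches,
    )
    write_design_report(rows_to_dicts(rows), out_path)
    return rows
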