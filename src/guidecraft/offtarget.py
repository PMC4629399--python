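"""Exon-restricted off-target screening.

Off-target analysis is deliberately confined to exon sequences (coding and
noncoding genes): small indels in intergenic/intronic space rarely have
functional consequences, and the much smaller exonic search space permits
stringent filters.  Two complementary rules exclude a candidate:

* seed+PAM: the guide's PAM-proximal 3' 13 nt occurring anywhere in an
  unintended exon immediately followed by an NGG or NAG PAM;
* similarity: any ungapped exonic 20-mer (either strand) matching the guide
  at >= 17/20 positions, i.e. over 85 % identity (<= 3 substitutions).

Windows containing ambiguity codes (N) never match.  Coordinates are
0-based half-open internally; BED export keeps that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from ._seq import as_dna, dna_revcomp, validate_guide

SEED_LENGTH = 13
PAM_SUFFIXES = ("GG", "AG")  # NGG (targeting) and NAG (tolerated)


@dataclass(frozen=True)
class OffTargetHit:
    exon_id: str
    offset: int  # 0-based start of the matched seed (seed_pam) or 20-mer (similarity)
    strand: str  # '+' or '-'
    kind: str  # 'seed_pam' or 'similarity'
    mismatches: int = 0  # similarity kind only


@dataclass
class ExonIndex:
    """Exact-lookup index of 13-nt-seed + 3-nt-PAM windows over both strands."""

    index: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)

    def lookup(self, key: str) -> list[tuple[str, int, str]]:
        return self.index.get(key, [])


def read_exons(path) -> dict[str, str]:
    exons = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not exons:
        raise ValueError(f"no FASTA records in {path}")
    return exons


def _index_strand(index, exon_id, seq, strand, source_len):
    win = SEED_LENGTH + 3
    for i in range(len(seq) - win + 1):
        window = seq[i : i + win]
        if "N" in window:
            continue
        if window[SEED_LENGTH + 1 :] not in PAM_SUFFIXES:
            continue
        # report the window start in + (source) coordinates on either strand
        offset = i if strand == "+" else source_len - i - win
        index.setdefault(window, []).append((exon_id, offset, strand))


def build_exon_index(exons) -> ExonIndex:
    """Index every seed+PAM window of every exon, both strands.

    ``exons`` is a FASTA path or a mapping id -> DNA sequence.
    """
    if not isinstance(exons, dict):
        exons = read_exons(exons)
    if not exons:
        raise ValueError("empty exon set")
    idx = ExonIndex(sequences=dict(exons))
    for exon_id, seq in exons.items():
        seq = seq.upper()
        _index_strand(idx.index, exon_id, seq, "+", len(seq))
        _index_strand(idx.index, exon_id, dna_revcomp(seq), "-", len(seq))
    return idx


def guide_seed_dna(guide: str) -> str:
    """The guide's 3' 13 nt in DNA spelling (the protospacer seed)."""
    return as_dna(validate_guide(guide))[20 - SEED_LENGTH :]


def seed_pam_hits(
    guide: str, index: ExonIndex, on_target: tuple | None = None
) -> list[OffTargetHit]:
    """All exonic occurrences of seed + NGG/NAG, minus the declared on-target.

    ``on_target`` is an (exon_id, offset, strand) triple in the same
    coordinates a hit reports (offset = seed start).
    """
    seed = guide_seed_dna(guide)
    hits = []
    for n in "ACGT":
        for suffix in PAM_SUFFIXES:
            for exon_id, offset, strand in index.lookup(seed + n + suffix):
                if on_target is not None and (exon_id, offset, strand) == tuple(on_target):
                    continue
                hits.append(
                    OffTargetHit(exon_id=exon_id, offset=offset, strand=strand, kind="seed_pam")
                )
    hits.sort(key=lambda h: (h.exon_id, h.offset, h.strand))
    return hits


def _window_mismatches(seq: str, query: str) -> np.ndarray:
    """Mismatch count of ``query`` against every window of ``seq`` (ungapped)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    if len(arr) < len(q):
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(arr, len(q))
    return (windows != q).sum(axis=1)


def similarity_hits(
    guide: str,
    exons: dict[str, str],
    max_mismatches: int = 3,
    on_target: tuple | None = None,
) -> list[OffTargetHit]:
    """Ungapped near-matches of the full 20-mer on either exon strand.

    A window counts as a hit at <= ``max_mismatches`` substitutions (the
    default 3 corresponds to >= 17/20 = 85 % identity).  Windows containing
    N never match.  ``on_target`` is an (exon_id, offset, strand) triple
    with offset = 20-mer start in + coordinates.
    """
    query = as_dna(validate_guide(guide))
    hits = []
    for exon_id, seq in exons.items():
        seq = seq.upper()
        for strand in "+-":
            scan = seq if strand == "+" else dna_revcomp(seq)
            mm = _window_mismatches(scan, query)
            for i in np.nonzero(mm <= max_mismatches)[0]:
                window = scan[i : i + 20]
                if "N" in window:
                    continue
                offset = int(i) if strand == "+" else len(seq) - int(i) - 20
                if on_target is not None and (exon_id, offset, strand) == tuple(on_target):
                    continue
                hits.append(
                    OffTargetHit(
                        exon_id=exon_id,
                        offset=offset,
                        strand=strand,
                        kind="similarity",
                        mismatches=int(mm[i]),
                    )
                )
    hits.sort(key=lambda h: (h.exon_id, h.offset, h.strand))
    return hits


def find_on_target(guide: str, pam: str, exons: dict[str, str]) -> tuple | None:
    """Locate the unique exact protospacer+PAM occurrence, if there is exactly one.

    Returns (exon_id, protospacer_offset, strand) or None if the target is
    absent or ambiguous (more than one exact occurrence).
    """
    query = as_dna(validate_guide(guide)) + as_dna(pam)
    found = []
    for exon_id, seq in exons.items():
        seq = seq.upper()
        for strand in "+-":
            scan = seq if strand == "+" else dna_revcomp(seq)
            start = scan.find(query)
            while start != -1:
                offset = start if strand == "+" else len(seq) - start - len(query)
                found.append((exon_id, offset, strand))
                start = scan.find(query, start + 1)
    return found[0] if len(found) == 1 else None


def filter_offtargets(
    candidates,
    index: ExonIndex,
    exons: dict[str, str] | None = None,
    max_mismatches: int = 3,
    on_targets: dict | None = None,
):
    """Split candidates into survivors and excluded, with per-candidate hits.

    A candidate is excluded on >= 1 seed+PAM hit or >= 1 similarity hit.
    ``candidates`` is a mapping name -> 20-nt guide (or an iterable of
    guides, keyed by themselves); ``on_targets`` optionally maps the same
    names to (exon_id, offset, strand) on-target declarations, where the
    offset is the protospacer start (converted internally per hit kind).
    """
    if exons is None:
        exons = index.sequences
    if not isinstance(candidates, dict):
        candidates = {g: g for g in candidates}
    on_targets = on_targets or {}
    survivors, report = [], {}
    for name, guide in candidates.items():
        ot = on_targets.get(name)
        seed_ot = sim_ot = None
        if ot is not None:
            exon_id, start, strand = ot
            # seed window start: 7 nt into the protospacer on +, 3 nt left of it on -
            seed_start = start + (20 - SEED_LENGTH) if strand == "+" else start - 3
            seed_ot = (exon_id, seed_start, strand)
            sim_ot = (exon_id, start, strand)
        sp = seed_pam_hits(guide, index, on_target=seed_ot)
        sim = similarity_hits(guide, exons, max_mismatches, on_target=sim_ot)
        report[name] = {"seed_pam": sp, "similarity": sim}
        if not sp and not sim:
            survivors.append(name)
    return survivors, report


def hits_to_bed(hits, path, span_by_kind={"seed_pam": SEED_LENGTH + 3, "similarity": 20}) -> None:
    """Export hits as BED (0-based half-open) with kind and mismatch columns."""
    with open(path, "w") as fh:
        for h in hits:
            span = span_by_kind[h.kind]
            fh.write(
                f"{h.exon_id}\t{h.offset}\t{h.offset + span}\t{h.kind}\t{h.mismatches}\t{h.strand}\n"
            )
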