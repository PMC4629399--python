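"""Small shared sequence helpers (alphabet normalization, complements)."""

from __future__ import annotations

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T->U; raise on anything outside {A,C,G,U}."""
    s = seq.strip().upper().replace("T", "U")
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise ValueError(f"invalid RNA characters {sorted(bad)} in {seq!r}")
    return s


def validate_guide(guide: str) -> str:
    """Normalize a 20-nt guide to RNA alphabet, enforcing length 20."""
    s = normalize_rna(guide)
    if len(s) != 20:
        raise ValueError(f"guide must be 20 nt, got {len(s)}: {guide!r}")
    return s


def as_dna(seq: str) -> str:
    """RNA->DNA spelling (U->T)."""
    return seq.upper().replace("U", "T")


def dna_revcomp(seq: str) -> str:
    return seq.upper().translate(_DNA_COMPLEMENT)[::-1]
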