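"""Secondary-structure and thermodynamic features of sgRNAs.

Three quantities drive the potency features in this package:

* the minimum-free-energy (MFE) fold of the full sgRNA (guide + scaffold),
  from which per-nucleotide accessibility is read off the dot-bracket string;
* the self-folding free energy of the isolated 20-nt guide, a proxy for
  intramolecular structure that can occlude target recognition;
* the nearest-neighbor free energy of the guide-RNA:target-DNA hybrid.

Folding uses the ViennaRNA (RNAfold) engine at its default 37 C parameter
set.  Hybrid duplex energies use the Sugimoto et al. (1995) RNA/DNA
nearest-neighbor table bundled with the package, so tests and the
implementation share one parameter source.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import RNA

from ._seq import as_dna, normalize_rna, validate_guide

#: Canonical S. pyogenes sgRNA scaffold (tracrRNA-derived constant region),
#: appended 3' of the 20-nt guide.  With this scaffold the assembled sgRNA is
#: 100 nt and carries AAG at positions 51-53, the bases that can pair with a
#: C/U-rich guide 3' end to extend the first stem-loop.
DEFAULT_SCAFFOLD = (
    "GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGGCACCGAGUCGGUGCUUUU"
)

#: sgRNA positions (1-based from the guide 5' end) whose accessibility is a
#: potency feature: the 3' end of the guide seed (18-20) and the scaffold
#: bases they tend to pair with (51-53).
ACCESSIBILITY_POSITIONS = (18, 19, 20, 51, 52, 53)

NN_PARAM_FILE = "rna_dna_nn_sugimoto1995.tsv"


@dataclass(frozen=True)
class FoldResult:
    """MFE secondary structure of one RNA sequence."""

    structure: str  # dot-bracket, same length as the input
    mfe: float  # kcal/mol, <= 0

    def is_paired(self, position: int) -> bool:
        """Whether the base at 1-based ``position`` is paired in the MFE fold."""
        return self.structure[position - 1] != "."


@dataclass(frozen=True)
class SgRNA:
    """A guide fused to a scaffold, with 1-based position bookkeeping.

    Positions 1-20 are the guide (position 20 abuts the PAM on the target);
    positions 21.. are the scaffold.
    """

    guide: str
    scaffold: str

    @property
    def full_seq(self) -> str:
        return self.guide + self.scaffold


@dataclass(frozen=True)
class AccessibilityVector:
    """Binary accessibility (unpaired = accessible) at the positions of interest."""

    positions: tuple[int, ...]
    accessible: tuple[bool, ...]

    def as_dict(self) -> dict[int, bool]:
        return dict(zip(self.positions, self.accessible))


@functools.lru_cache(maxsize=200_000)
def fold_rna(seq: str) -> FoldResult:
    """MFE fold of an RNA sequence with RNAfold at 37 C.

    A sequence with no stable structure folds to all dots at 0.0 kcal/mol;
    the MFE is clamped to <= 0 so an unfoldable input never reports a
    positive free energy.
    """
    s = normalize_rna(seq)
    structure, mfe = RNA.fold(s)
    mfe = min(round(float(mfe), 2), 0.0)
    if mfe == 0.0:
        structure = "." * len(s)
        mfe = 0.0
    return FoldResult(structure=structure, mfe=mfe)


def assemble_sgrna(guide: str, scaffold: str = DEFAULT_SCAFFOLD) -> SgRNA:
    """Fuse a 20-nt guide to a scaffold.

    The scaffold must cover sgRNA positions 51-53 (i.e. be at least 33 nt)
    because accessibility at those positions is part of the feature set.
    """
    g = validate_guide(guide)
    sc = normalize_rna(scaffold)
    if len(sc) < 33:
        raise ValueError(
            f"scaffold must be >= 33 nt so sgRNA positions 51-53 exist; got {len(sc)}"
        )
    return SgRNA(guide=g, scaffold=sc)


def sgrna_accessibility(sgrna: SgRNA) -> AccessibilityVector:
    """Accessibility flags at guide-seed positions 18-20 and scaffold 51-53.

    Read directly off the dot-bracket MFE structure of the full sgRNA: a
    position is accessible iff it is unpaired.
    """
    fold = fold_rna(sgrna.full_seq)
    flags = tuple(not fold.is_paired(p) for p in ACCESSIBILITY_POSITIONS)
    return AccessibilityVector(positions=ACCESSIBILITY_POSITIONS, accessible=flags)


def guide_self_fold_dg(guide: str) -> float:
    """Self-folding free energy (kcal/mol, <= 0) of the isolated 20-mer."""
    return fold_rna(validate_guide(guide)).mfe


@functools.lru_cache(maxsize=1)
def load_nn_table() -> dict[str, float]:
    """RNA/DNA hybrid nearest-neighbor dG37 terms keyed by RNA dimer, plus 'init'."""
    text = (
        resources.files("guidecraft.data").joinpath(NN_PARAM_FILE).read_text()
    )
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("dimer"):
            continue
        dimer, dg = line.split("\t")
        table[dimer] = float(dg)
    return table


_RNA_DNA_PAIR = {"A": "T", "C": "G", "G": "C", "U": "A"}


def perfect_target(guide: str) -> str:
    """The perfectly complementary DNA target strand, 5'->3'.

    Position i of the guide pairs with position 20-i of the returned strand.
    """
    g = validate_guide(guide)
    return "".join(_RNA_DNA_PAIR[b] for b in g)[::-1]


def duplex_dg(guide: str, target: str | None = None) -> float:
    """Nearest-neighbor free energy (kcal/mol) of the guide:target DNA hybrid.

    ``target`` is the DNA strand 5'->3'; it must be the perfect Watson-Crick
    complement of the guide (mismatch energetics are out of scope).  When
    omitted it is derived from the guide.  The energy is the sum of the 19
    stacking terms (keyed by the RNA dimer) plus duplex initiation.
    """
    g = validate_guide(guide)
    if target is None:
        target = perfect_target(g)
    t = target.strip().upper()
    if len(t) != len(g):
        raise ValueError("target length must match guide length")
    for i, b in enumerate(g):
        if t[len(g) - 1 - i] != _RNA_DNA_PAIR[b]:
            raise ValueError(
                f"guide position {i + 1} ({b}) does not pair with target base "
                f"{t[len(g) - 1 - i]}"
            )
    table = load_nn_table()
    dg = table["init"]
    for i in range(len(g) - 1):
        dg += table[g[i : i + 2]]
    return round(dg, 2)
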