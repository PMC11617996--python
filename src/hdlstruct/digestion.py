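"""In-silico proteolysis and peptide-to-protein bookkeeping.

Limited proteolysis (LiP) couples a brief, nonspecific digest of the folded
protein (here Proteinase K) with an exhaustive tryptic digest after
denaturation. Peptides with one trypsin-consistent terminus and one
nonspecific terminus ("semi-tryptic") carry the structural signal: their
nonspecific boundary was cut while the protein was still folded, so their
abundance tracks local protease accessibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

from .proteins import AMINO_ACIDS, ProteinRecord

PeptideClass = Literal["tryptic", "semi_tryptic", "non_tryptic"]


@dataclass(frozen=True)
class ProteaseRule:
    name: str
    cleave_after: frozenset[str]
    blocked_next: frozenset[str] = frozenset()
    max_missed: int = 0

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")

    def cuts_after(self, sequence: str, i: int) -> bool:
        """True if the rule cleaves between 0-based positions i and i+1."""
        if sequence[i] not in self.cleave_after:
            return False
        if i + 1 < len(sequence) and sequence[i + 1] in self.blocked_next:
            return False
        return True


def trypsin(max_missed: int = 0, block_proline: bool = True) -> ProteaseRule:
    """Classical trypsin: after K/R, blocked before P unless disabled."""
    return ProteaseRule(
        name="trypsin" if block_proline else "trypsin/P",
        cleave_after=frozenset("KR"),
        blocked_next=frozenset("P") if block_proline else frozenset(),
        max_missed=max_missed,
    )


def proteinase_k(max_missed: int = 20) -> ProteaseRule:
    """Nonspecific Proteinase K, modelled as cleavage after ten residue
    types (A, G, I, L, M, P, V, F, W, Y) with no blocking residues."""
    return ProteaseRule(
        name="proteinase_k",
        cleave_after=frozenset("AGILMPVFWY"),
        max_missed=max_missed,
    )


def lysc(max_missed: int = 0) -> ProteaseRule:
    return ProteaseRule(name="lysc", cleave_after=frozenset("K"),
                        max_missed=max_missed)


@dataclass(frozen=True)
class LocatedPeptide:
    """A peptide anchored on a protein, 1-based inclusive coordinates."""

    protein_id: str
    sequence: str
    start: int
    end: int
    nterm_specific: bool = True
    cterm_specific: bool = True

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("span length disagrees with sequence length")

    @property
    def peptide_class(self) -> PeptideClass:
        if self.nterm_specific and self.cterm_specific:
            return "tryptic"
        if self.nterm_specific or self.cterm_specific:
            return "semi_tryptic"
        return "non_tryptic"

    @property
    def key(self) -> str:
        return f"{self.protein_id}|{self.start}-{self.end}|{self.sequence}"


def parse_peptide_key(key: str) -> tuple[str, int, int, str]:
    protein_id, span, sequence = key.split("|")
    start, end = span.split("-")
    return protein_id, int(start), int(end), sequence


def cleavage_sites(sequence: str, rule: ProteaseRule) -> list[int]:
    """0-based indices i such that the rule cuts between i and i+1."""
    return [i for i in range(len(sequence) - 1) if rule.cuts_after(sequence, i)]


def digest(protein: ProteinRecord | str, rule: ProteaseRule,
           protein_id: str | None = None) -> list[LocatedPeptide]:
    """Fully specific digest with up to ``rule.max_missed`` missed cleavages.

    Boundaries are cleavage sites or the protein termini; enumeration is
    exhaustive over consecutive boundary pairs.
    """
    if isinstance(protein, ProteinRecord):
        sequence, pid = protein.sequence, protein.id
    else:
        sequence, pid = protein, (protein_id or "protein")
        bad = set(sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid residue letter(s): {sorted(bad)}")
    sites = cleavage_sites(sequence, rule)
    bounds = [0] + [i + 1 for i in sites] + [len(sequence)]
    peptides = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, len(bounds)):
            missed = b - a - 1
            if missed > rule.max_missed:
                break
            lo, hi = bounds[a], bounds[b]
            peptides.append(
                LocatedPeptide(
                    protein_id=pid,
                    sequence=sequence[lo:hi],
                    start=lo + 1,
                    end=hi,
                )
            )
    return peptides


def locate_peptide(peptide_sequence: str, protein: ProteinRecord
                   ) -> tuple[int, int]:
    """1-based inclusive span of the first occurrence in the protein.

    Multi-mapping within the protein triggers a warning; the first span wins.
    """
    if not peptide_sequence:
        raise ValueError("empty peptide")
    idx = protein.sequence.find(peptide_sequence)
    if idx < 0:
        raise ValueError(
            f"peptide {peptide_sequence!r} not found in {protein.id}"
        )
    if protein.sequence.find(peptide_sequence, idx + 1) >= 0:
        warnings.warn(
            f"peptide {peptide_sequence!r} occurs more than once in "
            f"{protein.id}; first occurrence used"
        )
    return idx + 1, idx + len(peptide_sequence)


def map_site(peptide: LocatedPeptide, offset_in_peptide: int) -> int:
    """Protein residue index of the ``offset_in_peptide``-th peptide residue
    (both 1-based)."""
    if not 1 <= offset_in_peptide <= len(peptide.sequence):
        raise ValueError(
            f"offset {offset_in_peptide} outside peptide of length "
            f"{len(peptide.sequence)}"
        )
    return peptide.start + offset_in_peptide - 1


def classify_termini(start: int, end: int, protein: ProteinRecord,
                     rule: ProteaseRule | None = None) -> LocatedPeptide:
    """Locate a span on a protein and classify its termini against a
    protease rule (trypsin by default). Protein termini count as specific."""
    if rule is None:
        rule = trypsin()
    if not (1 <= start <= end <= len(protein.sequence)):
        raise ValueError(f"span {start}-{end} outside {protein.id}")
    seq = protein.sequence
    nterm = start == 1 or rule.cuts_after(seq, start - 2)
    cterm = end == len(seq) or rule.cuts_after(seq, end - 1)
    return LocatedPeptide(
        protein_id=protein.id,
        sequence=seq[start - 1:end],
        start=start,
        end=end,
        nterm_specific=nterm,
        cterm_specific=cterm,
    )
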