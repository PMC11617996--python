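"""Protein registry, mass arithmetic, mutants, and helix-repeat annotation.

All residue coordinates in this package are mature-chain positions: the
secreted chain after removal of signal and propeptides, numbered from 1.
This is the coordinate system in which cross-link sites (K59, K182, ...)
and helix repeats of apolipoprotein A-I are conventionally reported, so
FASTA inputs carrying precursor sequences must be trimmed by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Monoisotopic residue (i.e. water-free) masses, Da.
MONOISOTOPIC = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# Average residue masses, Da.
AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONO = 18.010565
WATER_AVG = 18.01528
PROTON = 1.0072765
HYDROGEN_MONO = 1.007825
HYDROGEN_AVG = 1.00794
# Mass excess of one deuterium over one protium; heavy/light cross-linker
# doublets differ by an integer multiple of this.
DEUTERIUM_MINUS_HYDROGEN = 1.006277

MassMode = Literal["monoisotopic", "average"]


@dataclass(frozen=True)
class ProteinRecord:
    """A mature protein chain with 1-based residue numbering.

    ``role`` distinguishes targets from "dummy" (decoy) proteins that are
    present in a cross-link search space only to calibrate score thresholds.
    """

    id: str
    sequence: str
    name: str = ""
    accession: str = ""
    role: Literal["target", "decoy"] = "target"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid residue letter(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based mature-chain position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"residue {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class HelixAnnotation:
    """Ordered, non-overlapping residue intervals labelling helix repeats."""

    protein_id: str
    repeats: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for label, start, end in self.repeats:
            if not (1 <= start <= end):
                raise ValueError(f"bad interval for {label}: {start}-{end}")
            if start <= prev_end:
                raise ValueError(f"overlapping/unordered repeat {label}")
            prev_end = end


# Consensus 11/22-mer decomposition of mature APOA1: ten amphipathic
# helical repeats. Residues 1-43 are the globular N-terminal segment (G0),
# deliberately left unlabeled so that annotate_residue reports "unassigned"
# outside the helical region. Coordinates are the standard decomposition
# and can be overridden by constructing another annotation.
APOA1_HELIX_REPEATS = HelixAnnotation(
    protein_id="APOA1",
    repeats=(
        ("H1", 44, 65),
        ("H2", 66, 87),
        ("H3", 88, 98),
        ("H4", 99, 120),
        ("H5", 121, 142),
        ("H6", 143, 164),
        ("H7", 165, 186),
        ("H8", 187, 208),
        ("H9", 209, 219),
        ("H10", 220, 243),
    ),
)


def _residue_table(mode: MassMode) -> dict[str, float]:
    if mode == "monoisotopic":
        return MONOISOTOPIC
    if mode == "average":
        return AVERAGE
    raise ValueError(f"unknown mass mode {mode!r}")


def peptide_mass(sequence: str, mode: MassMode = "monoisotopic") -> float:
    """Neutral peptide mass: sum of residue masses plus one water, Da."""
    if not sequence:
        raise ValueError("empty peptide")
    table = _residue_table(mode)
    total = WATER_MONO if mode == "monoisotopic" else WATER_AVG
    for letter in sequence:
        try:
            total += table[letter]
        except KeyError:
            raise ValueError(f"unknown residue letter {letter!r}") from None
    return total


def disulfide_dimer_mass(
    sequence: str, n_disulfides: int = 1, mode: MassMode = "average"
) -> float:
    """Mass of a homodimer of ``sequence`` joined by disulfide bonds.

    Each disulfide bond removes two hydrogens from the summed chain masses.
    Human APOA2 circulates as such a homodimer (one inter-chain disulfide).
    """
    if n_disulfides < 0:
        raise ValueError("n_disulfides must be >= 0")
    if sequence.count("C") < n_disulfides:
        raise ValueError("each disulfide requires one cysteine per chain")
    hydrogen = HYDROGEN_MONO if mode == "monoisotopic" else HYDROGEN_AVG
    return 2.0 * peptide_mass(sequence, mode) - n_disulfides * 2.0 * hydrogen


def apply_deletion(record: ProteinRecord, start: int, end: int) -> ProteinRecord:
    """Excise residues ``start..end`` (1-based inclusive) from a protein."""
    if not (1 <= start <= end <= len(record.sequence)):
        raise ValueError(
            f"deletion {start}-{end} outside 1..{len(record.sequence)}"
        )
    new_seq = record.sequence[: start - 1] + record.sequence[end:]
    return replace(
        record,
        id=f"{record.id}(d{start}-{end})",
        name=f"{record.name or record.id} Δ{start}-{end}",
        sequence=new_seq,
    )


def tandem_fusion(record: ProteinRecord, linker: str = "AAA") -> ProteinRecord:
    """Head-to-tail covalent dimer: sequence + linker + sequence."""
    bad = set(linker) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid linker letter(s): {sorted(bad)}")
    return replace(
        record,
        id=f"d{record.id}(C-N)",
        name=f"tandem dimer of {record.name or record.id}",
        sequence=record.sequence + linker + record.sequence,
    )


def annotate_residue(annotation: HelixAnnotation, position: int,
                     protein_length: int | None = None) -> str:
    """Label of the repeat containing ``position``, or ``"unassigned"``."""
    if position < 1 or (protein_length is not None and position > protein_length):
        raise IndexError(f"position {position} out of range")
    for label, start, end in annotation.repeats:
        if start <= position <= end:
            return label
    return "unassigned"


# ---------------------------------------------------------------------------
# FASTA I/O and the bundled registry


def read_fasta(path: str | Path, role: Literal["target", "decoy"] = "target"
               ) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = ""
        for token in rec.description.split():
            if token.startswith("accession="):
                accession = token.split("=", 1)[1]
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                name=rec.description,
                accession=accession,
                role=role,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.name or "")
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def _bundled(name: str) -> Path:
    return Path(str(resources.files("hdlstruct") / "data" / name))


def load_apoa1() -> ProteinRecord:
    """Bundled mature human apolipoprotein A-I chain (243 residues)."""
    rec = read_fasta(_bundled("apoa1_mature.fasta"))[0]
    return replace(rec, id="APOA1", name="apolipoprotein A-I, mature chain")


def load_apoa2() -> ProteinRecord:
    """Bundled mature human apolipoprotein A-II chain (77 residues)."""
    rec = read_fasta(_bundled("apoa2_mature.fasta"))[0]
    return replace(rec, id="APOA2", name="apolipoprotein A-II, mature chain")


class ProteinRegistry:
    """Id-addressable collection of target and decoy proteins."""

    def __init__(self, records: Iterable[ProteinRecord] = ()) -> None:
        self._records: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.id in self._records:
            warnings.warn(f"replacing protein {record.id} in registry")
        self._records[record.id] = record

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        try:
            return self._records[protein_id]
        except KeyError:
            raise KeyError(f"protein {protein_id!r} not in registry") from None

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def decoy_ids(self) -> set[str]:
        return {r.id for r in self if r.role == "decoy"}


def default_registry() -> ProteinRegistry:
    """Registry holding the two bundled apolipoprotein chains."""
    return ProteinRegistry([load_apoa1(), load_apoa2()])
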