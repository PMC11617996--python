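"""Cross-linking mass spectrometry: chemistry, validation, and consensus.

Covers the arithmetic and bookkeeping downstream of a cross-link search
engine: theoretical masses of cross-linked species, light/heavy
isotope-doublet validation for isotope-coded linkers, decoy("dummy")-protein
score-threshold calibration, peptide-to-residue site mapping with ambiguous
alternatives, multi-evidence consensus, and helix-repeat annotation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import proteins as prot
from .digestion import LocatedPeptide, classify_termini, locate_peptide, map_site
from .proteins import (DEUTERIUM_MINUS_HYDROGEN, PROTON, WATER_MONO,
                       HelixAnnotation, ProteinRegistry, annotate_residue,
                       peptide_mass)

log = logging.getLogger(__name__)

# Mass difference between one D12 and one H12 cross-link (12 deuteriums).
H12_D12_DELTA = 12 * DEUTERIUM_MINUS_HYDROGEN  # 12.075324 Da


@dataclass(frozen=True)
class CrosslinkerSpec:
    """Chemistry of one cross-linking reagent.

    ``crosslink_delta`` is the monoisotopic mass added to the sum of the two
    peptide masses by an intact link; a mono-link (one end hydrolyzed) adds
    ``crosslink_delta`` plus one water.
    """

    name: str
    crosslink_delta: float
    isotope_partner_delta: float = 0.0
    reactive_residues: frozenset[str] = frozenset("K")

    def __post_init__(self) -> None:
        if self.crosslink_delta <= 0:
            raise ValueError("crosslink_delta must be positive")

    @property
    def monolink_delta(self) -> float:
        return self.crosslink_delta + WATER_MONO


# Spacer compositions: BS3 leaves C8H10O2 after amide formation at both
# ends; the D12 form carries 12 deuteriums. DSBU leaves C9H12N2O3, DSSO
# C6H6O3S. All amine-reactive (Lys and protein N-terminus; S/T/Y side
# reactions occur and appear as secondary sites).
LINKERS: dict[str, CrosslinkerSpec] = {
    spec.name: spec
    for spec in (
        CrosslinkerSpec("BS3-H12", 138.06808, isotope_partner_delta=H12_D12_DELTA,
                        reactive_residues=frozenset("KSTY")),
        CrosslinkerSpec("BS3-D12", 138.06808 + H12_D12_DELTA,
                        isotope_partner_delta=-H12_D12_DELTA,
                        reactive_residues=frozenset("KSTY")),
        CrosslinkerSpec("DSBU", 196.08479, reactive_residues=frozenset("KSTY")),
        CrosslinkerSpec("DSSO", 158.00376, reactive_residues=frozenset("KSTY")),
    )
}

for _spec in LINKERS.values():
    # hydrolysis self-consistency of the registry
    assert math.isclose(_spec.monolink_delta - _spec.crosslink_delta,
                        WATER_MONO, abs_tol=1e-9)


def get_linker(name: str) -> CrosslinkerSpec:
    try:
        return LINKERS[name]
    except KeyError:
        raise KeyError(
            f"unknown cross-linker {name!r}; registered: {sorted(LINKERS)}"
        ) from None


def crosslinked_species_mass(peptide_a: str, peptide_b: str,
                             linker: CrosslinkerSpec | str,
                             charge: int = 0) -> float:
    """Monoisotopic mass (Da) of the cross-linked species.

    ``charge`` protons are added to the neutral mass; charge 0 returns the
    neutral mass itself (the value is a mass, not m/z).
    """
    if isinstance(linker, str):
        linker = get_linker(linker)
    if charge < 0:
        raise ValueError("charge must be >= 0")
    return (peptide_mass(peptide_a) + peptide_mass(peptide_b)
            + linker.crosslink_delta + charge * PROTON)


def monolink_mass_delta(linker: CrosslinkerSpec | str) -> float:
    """Mass added to a peptide by a hydrolyzed single-ended link."""
    if isinstance(linker, str):
        linker = get_linker(linker)
    return linker.monolink_delta


def validate_isotope_doublet(mass_light: float, mass_heavy: float,
                             tolerance_da: float = 0.02) -> bool:
    """True iff the two masses differ by the 12-deuterium doublet spacing."""
    if mass_light <= 0 or mass_heavy <= 0:
        raise ValueError("masses must be positive")
    return abs((mass_heavy - mass_light) - H12_D12_DELTA) <= tolerance_da


# ---------------------------------------------------------------------------
# Candidates, score adapters, calibration


@dataclass(frozen=True)
class CrosslinkCandidate:
    """One scored peptide-pair identification from a search engine.

    ``site_offset_*`` are 1-based offsets of the linked residue within each
    peptide; ambiguous alternatives are extra offsets. ``score`` is on the
    internal higher-is-better scale (engine adapters convert on import).
    """

    peptide_a: str
    site_offset_a: int
    protein_a: str
    peptide_b: str
    site_offset_b: int
    protein_b: str
    engine: str = ""
    experiment_id: str = ""
    score: float = 0.0
    observed_species_mass: float = 0.0
    charge: int = 0
    alt_offsets_a: tuple[int, ...] = ()
    alt_offsets_b: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for pep, off in ((self.peptide_a, self.site_offset_a),
                         (self.peptide_b, self.site_offset_b)):
            if not 1 <= off <= len(pep):
                raise ValueError(f"site offset {off} outside peptide {pep!r}")
        if self.charge < 0:
            raise ValueError("charge must be >= 0")

    def involves(self, protein_ids: set[str]) -> bool:
        return self.protein_a in protein_ids or self.protein_b in protein_ids


# score adapters: map an engine's native score to higher-is-better
SCORE_ADAPTERS = {
    "sim-xl": lambda s: float(s),
    "scout": lambda s: float(s),
    "xlinkx": lambda s: float(s),
    "plink": lambda s: -math.log10(float(s)) if float(s) > 0 else math.inf,
}

# per-engine acceptance presets on the native scale (config, not hard-coded
# into any operation)
ENGINE_THRESHOLD_PRESETS = {"sim-xl": 3.0, "xlinkx": 100.0}


def adapt_score(engine: str, native_score: float) -> float:
    adapter = SCORE_ADAPTERS.get(engine.lower())
    if adapter is None:
        raise KeyError(
            f"unknown engine {engine!r}; registered adapters: "
            f"{sorted(SCORE_ADAPTERS)}"
        )
    return adapter(native_score)


def calibrate_threshold(candidates: list[CrosslinkCandidate],
                        decoy_protein_ids: set[str],
                        max_decoy_hits: int = 0
                        ) -> tuple[float, list[CrosslinkCandidate]]:
    """Lowest score threshold admitting at most ``max_decoy_hits`` decoys.

    Scans candidate score values from high to low and returns the minimal
    value t such that candidates scoring >= t include <= ``max_decoy_hits``
    involving a decoy protein, together with the accepted target-only
    candidates. If even the strictest threshold fails, returns +inf and an
    empty list with a warning.
    """
    if not candidates:
        raise ValueError("no candidates to calibrate on")
    best_threshold = math.inf
    for t in sorted({c.score for c in candidates}, reverse=True):
        n_decoy = sum(1 for c in candidates
                      if c.score >= t and c.involves(decoy_protein_ids))
        if n_decoy <= max_decoy_hits:
            best_threshold = t
        else:
            break
    if math.isinf(best_threshold):
        warnings.warn(
            "no score threshold satisfies the decoy budget; nothing accepted"
        )
        return best_threshold, []
    accepted = [c for c in candidates
                if c.score >= best_threshold
                and not c.involves(decoy_protein_ids)]
    return best_threshold, accepted


# ---------------------------------------------------------------------------
# Residue pairs, consensus, annotation


@dataclass(frozen=True)
class ResiduePair:
    """A cross-linked residue pair in canonical (protein, residue) order,
    with ambiguous site alternatives per end."""

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    alternatives_a: tuple[int, ...] = ()
    alternatives_b: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if (self.protein_a, self.residue_a) > (self.protein_b, self.residue_b):
            raise ValueError("pair not in canonical order; use make_pair")

    @property
    def all_a(self) -> tuple[int, ...]:
        return (self.residue_a,) + self.alternatives_a

    @property
    def all_b(self) -> tuple[int, ...]:
        return (self.residue_b,) + self.alternatives_b

    def expand(self) -> list["ResiduePair"]:
        """All concrete pairs implied by the ambiguity alternatives."""
        return [make_pair(self.protein_a, ra, self.protein_b, rb)
                for ra in self.all_a for rb in self.all_b]


def make_pair(protein_a: str, residue_a: int, protein_b: str, residue_b: int,
              alternatives_a: tuple[int, ...] = (),
              alternatives_b: tuple[int, ...] = ()) -> ResiduePair:
    if (protein_a, residue_a) > (protein_b, residue_b):
        protein_a, residue_a, protein_b, residue_b = (
            protein_b, residue_b, protein_a, residue_a)
        alternatives_a, alternatives_b = alternatives_b, alternatives_a
    return ResiduePair(protein_a, residue_a, protein_b, residue_b,
                       tuple(alternatives_a), tuple(alternatives_b))


def to_residue_pair(candidate: CrosslinkCandidate,
                    registry: ProteinRegistry) -> ResiduePair:
    """Map a peptide-pair candidate to protein residue coordinates."""

    def side(peptide: str, protein_id: str, offset: int,
             alts: tuple[int, ...]) -> tuple[int, tuple[int, ...]]:
        record = registry[protein_id]
        start, end = locate_peptide(peptide, record)
        located = LocatedPeptide(protein_id=protein_id, sequence=peptide,
                                 start=start, end=end)
        return (map_site(located, offset),
                tuple(map_site(located, a) for a in alts))

    res_a, alts_a = side(candidate.peptide_a, candidate.protein_a,
                         candidate.site_offset_a, candidate.alt_offsets_a)
    res_b, alts_b = side(candidate.peptide_b, candidate.protein_b,
                         candidate.site_offset_b, candidate.alt_offsets_b)
    return make_pair(candidate.protein_a, res_a, candidate.protein_b, res_b,
                     alts_a, alts_b)


def _pairs_match(p: ResiduePair, q: ResiduePair, tol: int) -> bool:
    if (p.protein_a, p.protein_b) != (q.protein_a, q.protein_b):
        return False
    return any(
        abs(ra - qa) <= tol and abs(rb - qb) <= tol
        for ra in p.all_a for rb in p.all_b
        for qa in q.all_a for qb in q.all_b
    )


@dataclass(frozen=True)
class ConsensusPair:
    pair: ResiduePair
    evidence_ids: tuple[str, ...]


def consensus(pair_sets: list[tuple[str, list[ResiduePair]]],
              min_evidence: int = 2, site_tolerance: int = 0
              ) -> list[ConsensusPair]:
    """Pairs supported by >= ``min_evidence`` distinct evidence ids.

    Candidate concrete pairs (ambiguity expanded) from all evidence sets are
    compared pairwise; a concrete pair is kept when pairs within ±``site
    tolerance`` on both ends occur in enough distinct evidence sets, and
    kept pairs that match each other within tolerance are merged into one
    consensus entry (smallest coordinates as representative).
    """
    if not pair_sets:
        raise ValueError("no evidence sets")
    concrete: list[tuple[str, ResiduePair]] = [
        (evidence_id, cp)
        for evidence_id, pairs in pair_sets
        for p in pairs
        for cp in p.expand()
    ]
    sort_key = lambda p: (p.protein_a, p.residue_a, p.protein_b, p.residue_b)
    supported: dict[ResiduePair, set[str]] = {}
    for _, cp in concrete:
        if cp in supported:
            continue
        ids = {eid for eid, other in concrete
               if _pairs_match(cp, other, site_tolerance)}
        if len(ids) >= min_evidence:
            supported[cp] = ids
    # merge within-tolerance survivors into connected components
    clusters: list[tuple[list[ResiduePair], set[str]]] = []
    for cp in sorted(supported, key=sort_key):
        ids = supported[cp]
        hits = [cl for cl in clusters
                if any(_pairs_match(cp, member, site_tolerance)
                       for member in cl[0])]
        if hits:
            base = hits[0]
            base[0].append(cp)
            base[1].update(ids)
            for other in hits[1:]:
                base[0].extend(other[0])
                base[1].update(other[1])
                clusters.remove(other)
        else:
            clusters.append(([cp], set(ids)))
    return [
        ConsensusPair(pair=min(members, key=sort_key),
                      evidence_ids=tuple(sorted(ids)))
        for members, ids in clusters
    ]


def annotate_pairs(pairs: list[ResiduePair],
                   annotations: dict[str, HelixAnnotation]
                   ) -> list[tuple[ResiduePair, str, str]]:
    """Tag each pair end with its helix-repeat label ("unassigned" when the
    protein carries no annotation or the residue falls between repeats)."""

    def label(protein_id: str, residue: int) -> str:
        ann = annotations.get(protein_id)
        if ann is None:
            return "unassigned"
        return annotate_residue(ann, residue)

    return [(p, label(p.protein_a, p.residue_a), label(p.protein_b, p.residue_b))
            for p in pairs]


# ---------------------------------------------------------------------------
# Candidate CSV I/O and the bundled published-table transcriptions


def _parse_offsets(cell: str | int) -> tuple[int, tuple[int, ...]]:
    parts = str(cell).replace("|", "/").split("/")
    offsets = [int(p) for p in parts]
    return offsets[0], tuple(offsets[1:])


def read_candidates(path: str | Path) -> list[CrosslinkCandidate]:
    """Read the candidate CSV schema: engine, experiment_id, peptide_a,
    offset_a, protein_a, peptide_b, offset_b, protein_b, score,
    observed_mass, charge. Offsets may list ambiguous alternatives
    separated by ``/``. Engine scores are converted to the internal
    higher-is-better scale."""
    frame = pd.read_csv(path)
    candidates = []
    for _, row in frame.iterrows():
        off_a, alts_a = _parse_offsets(row["offset_a"])
        off_b, alts_b = _parse_offsets(row["offset_b"])
        candidates.append(
            CrosslinkCandidate(
                peptide_a=row["peptide_a"], site_offset_a=off_a,
                protein_a=row["protein_a"], peptide_b=row["peptide_b"],
                site_offset_b=off_b, protein_b=row["protein_b"],
                engine=str(row["engine"]),
                experiment_id=str(row["experiment_id"]),
                score=adapt_score(str(row["engine"]), row["score"]),
                observed_species_mass=float(row["observed_mass"]),
                charge=int(row["charge"]),
                alt_offsets_a=alts_a, alt_offsets_b=alts_b,
            )
        )
    return candidates


def write_candidates(candidates: list[CrosslinkCandidate],
                     path: str | Path) -> None:
    rows = []
    for c in candidates:
        rows.append(
            {
                "engine": c.engine, "experiment_id": c.experiment_id,
                "peptide_a": c.peptide_a,
                "offset_a": "/".join(map(str, (c.site_offset_a,) + c.alt_offsets_a)),
                "protein_a": c.protein_a, "peptide_b": c.peptide_b,
                "offset_b": "/".join(map(str, (c.site_offset_b,) + c.alt_offsets_b)),
                "protein_b": c.protein_b, "score": c.score,
                "observed_mass": c.observed_species_mass, "charge": c.charge,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_consensus(entries: list[ConsensusPair],
                    annotations: dict[str, HelixAnnotation],
                    path: str | Path) -> pd.DataFrame:
    annotated = annotate_pairs([e.pair for e in entries], annotations)
    rows = []
    for entry, (pair, label_a, label_b) in zip(entries, annotated):
        rows.append(
            {
                "protein_a": pair.protein_a, "residue_a": pair.residue_a,
                "protein_b": pair.protein_b, "residue_b": pair.residue_b,
                "alternatives_a": "/".join(map(str, pair.alternatives_a)),
                "alternatives_b": "/".join(map(str, pair.alternatives_b)),
                "helix_a": label_a, "helix_b": label_b,
                "evidence": ";".join(entry.evidence_ids),
                "n_evidence": len(entry.evidence_ids),
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


def _parse_site(label: str) -> tuple[int, tuple[int, ...]]:
    """'K208' -> (208, ()); 'K30/S31/K39' -> (30, (31, 39))."""
    sites = [int(part[1:]) for part in label.split("/")]
    return sites[0], tuple(sites[1:])


def _site_letters(label: str) -> list[str]:
    return [part[0] for part in label.split("/")]


def load_published_bs3_table() -> pd.DataFrame:
    """Bundled transcription of the published BS3-H12/D12 cross-link table
    (light and heavy species masses per APOA1-APOA2 link)."""
    return pd.read_csv(prot._bundled("crosslinks_bs3.csv"))


def load_published_cleavable_table() -> pd.DataFrame:
    """Bundled transcription of the published DSBU/DSSO cross-link table."""
    return pd.read_csv(prot._bundled("crosslinks_dsbu_dsso.csv"))


def table_residue_pairs(frame: pd.DataFrame) -> list[ResiduePair]:
    """Residue pairs of a published-table transcription, one per row, with
    ambiguous site labels kept as alternatives."""
    pairs = []
    for _, row in frame.iterrows():
        res_a, alts_a = _parse_site(row["residue_a"])
        res_b, alts_b = _parse_site(row["residue_b"])
        pairs.append(make_pair(row["protein_a"], res_a, row["protein_b"],
                               res_b, alts_a, alts_b))
    return pairs


def count_expanded_links(frame: pd.DataFrame) -> int:
    """Number of concrete cross-links after ambiguity expansion."""
    return sum(len(p.expand()) for p in table_residue_pairs(frame))
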