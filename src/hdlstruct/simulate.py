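"""Synthetic datasets with the statistical structure the pipeline assumes.

Every generator is a pure function of its configuration (seed included),
so tests and reproductions need no external data. The LiP generator
emulates two-condition label-free tables: log-normal peptide intensities,
intensity-dependent (left-censored) dropout, dose-dependent exponential
displacement of APOA1 from the particle, and planted residue windows of
increased or decreased protease accessibility. The cross-link generator
emits target candidates with correct theoretical masses plus lower-scoring
decoy-protein candidates; the efflux generator produces a unimodal
transporter-dependent dose-response with count noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crosslinks as xl
from .digestion import LocatedPeptide, cleavage_sites, digest, proteinase_k, trypsin
from .efflux import EffluxWell
from .proteins import AMINO_ACIDS, ProteinRecord, ProteinRegistry, load_apoa1, load_apoa2
from .quantify import QuantTable

LOG2E = math.log2(math.e)


@dataclass(frozen=True)
class PlantedWindow:
    protein_id: str
    start: int
    end: int
    direction: str  # "exposed" or "shielded"
    effect_log2: float = 2.0

    @property
    def sign(self) -> int:
        if self.direction == "exposed":
            return 1
        if self.direction == "shielded":
            return -1
        raise ValueError(f"unknown direction {self.direction!r}")


# Defaults emulate the observed conformational response of particle-bound
# APOA1 to APOA2: exposure of the globular N-terminal segment, helix 1 and
# helix 10, shielding of helix 7.
DEFAULT_WINDOWS = (
    PlantedWindow("APOA1", 1, 43, "exposed"),
    PlantedWindow("APOA1", 44, 65, "exposed"),
    PlantedWindow("APOA1", 165, 186, "shielded"),
    PlantedWindow("APOA1", 220, 243, "exposed"),
)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_replicates: int = 5
    doses: tuple[float, ...] = (0.0, 20.0, 40.0, 80.0, 160.0)
    # APOA1 remaining on the particle decays as exp(-k * dose); the default
    # rate puts 5% remaining at the top dose of 160%.
    displacement_rate: float = math.log(20.0) / 160.0
    planted_windows: tuple[PlantedWindow, ...] = DEFAULT_WINDOWS
    noise_sd: float = 0.25
    mnar_midpoint: float = 19.0
    mnar_steepness: float = 1.2
    # cross-link simulation
    n_true_pairs: int = 8
    decoy_fraction: float = 0.5
    n_decoy_proteins: int = 4
    # efflux simulation
    efflux_doses: tuple[float, ...] = (0.0, 10.0, 20.0, 40.0, 100.0)
    efflux_peak_dose: float = 20.0
    efflux_baseline_pct: float = 4.0
    efflux_amplitude_pct: float = 3.0
    efflux_replicates: int = 3
    total_dpm: float = 20000.0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")
        if not all(math.isfinite(w.effect_log2) for w in self.planted_windows):
            raise ValueError("effect sizes must be finite")


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline on a simulated dataset."""

    seed: int
    protein_log2fc: dict = field(default_factory=dict)   # (protein, dose) -> fc
    windows: list = field(default_factory=list)
    true_pairs: list = field(default_factory=list)       # (prot_a, res_a, prot_b, res_b)
    efflux_means: dict = field(default_factory=dict)     # (condition, dose) -> pct

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "protein_log2fc": {f"{k[0]}@{k[1]}": v
                               for k, v in self.protein_log2fc.items()},
            "windows": [asdict(w) if isinstance(w, PlantedWindow) else w
                        for w in self.windows],
            "true_pairs": [list(p) for p in self.true_pairs],
            "efflux_means": {f"{k[0]}@{k[1]}": v
                             for k, v in self.efflux_means.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _semi_tryptic_peptides(protein: ProteinRecord, min_len: int = 6,
                           max_len: int = 30) -> list[LocatedPeptide]:
    """Semi-tryptic peptides: a tryptic parent truncated at an internal
    Proteinase K site on exactly one side."""
    protk = proteinase_k()
    out: dict[str, LocatedPeptide] = {}
    for parent in digest(protein, trypsin(max_missed=2)):
        if len(parent.sequence) < min_len:
            continue
        seq = parent.sequence
        for i in cleavage_sites(seq, protk):
            nterm_trunc = seq[i + 1:]  # keeps the tryptic C-terminus
            if min_len <= len(nterm_trunc) <= max_len:
                pep = LocatedPeptide(protein.id, nterm_trunc,
                                     parent.start + i + 1, parent.end,
                                     nterm_specific=False, cterm_specific=True)
                out.setdefault(pep.key, pep)
            cterm_trunc = seq[:i + 1]  # keeps the tryptic N-terminus
            if min_len <= len(cterm_trunc) <= max_len:
                pep = LocatedPeptide(protein.id, cterm_trunc, parent.start,
                                     parent.start + i,
                                     nterm_specific=True, cterm_specific=False)
                out.setdefault(pep.key, pep)
    return list(out.values())


def _window_effect(pep: LocatedPeptide, windows: tuple[PlantedWindow, ...]
                   ) -> float:
    total = 0.0
    length = pep.end - pep.start + 1
    for w in windows:
        if w.protein_id != pep.protein_id:
            continue
        overlap = min(pep.end, w.end) - max(pep.start, w.start) + 1
        if overlap > 0:
            total += w.sign * w.effect_log2 * overlap / length
    return total


def _apply_mnar(rng: np.random.Generator, matrix: pd.DataFrame,
                midpoint: float, steepness: float) -> pd.DataFrame:
    p_missing = 1.0 / (1.0 + np.exp(steepness * (matrix.to_numpy() - midpoint)))
    drop = rng.random(matrix.shape) < p_missing
    out = matrix.mask(drop)
    return out


def _design(doses: tuple[float, ...], n_replicates: int) -> pd.DataFrame:
    rows = []
    for dose in doses:
        for r in range(1, n_replicates + 1):
            rows.append({"sample_id": f"dose{dose:g}_r{r}",
                         "group": f"dose_{dose:g}", "dose": dose})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_lip_dataset(config: SimulationConfig = SimulationConfig()
                         ) -> tuple[QuantTable, QuantTable, GroundTruth]:
    """Global (protein-level) and LiP (peptide-level) log2 tables.

    The global table carries APOA1 displacement (exponential in dose) and a
    saturating APOA2 increase on a background of stable proteins. The LiP
    table holds tryptic and semi-tryptic APOA1 peptides; semi-tryptic
    peptides overlapping a planted window are shifted by the window's
    effect (scaled by overlap fraction) on top of the protein-level change.
    """
    apoa1 = load_apoa1()
    for w in config.planted_windows:
        if w.protein_id == apoa1.id and not (1 <= w.start <= w.end <= len(apoa1)):
            raise ValueError(f"window {w.start}-{w.end} outside {apoa1.id}")
    rng = np.random.default_rng(config.seed)
    design = _design(config.doses, config.n_replicates)
    k = config.displacement_rate

    def apoa1_shift(dose: float) -> float:
        return -k * dose * LOG2E

    def apoa2_shift(dose: float) -> float:
        return math.log2(1.0 + dose / 40.0)

    truth = GroundTruth(seed=config.seed,
                        windows=list(config.planted_windows))
    base_levels = {"APOA1": 27.0, "APOA2": 24.0, "APOE": 23.0,
                   "APOM": 22.5, "SAA1": 22.0, "SAA4": 21.8}
    shifts = {"APOA1": apoa1_shift, "APOA2": apoa2_shift}
    global_rows = {}
    for pid, base in base_levels.items():
        row = []
        for sample_id, meta in design.iterrows():
            shift = shifts.get(pid, lambda d: 0.0)(meta["dose"])
            row.append(base + shift + rng.normal(0.0, config.noise_sd))
        global_rows[pid] = row
    for pid in base_levels:
        for dose in config.doses:
            if dose == 0:
                continue
            truth.protein_log2fc[(pid, dose)] = (
                shifts.get(pid, lambda d: 0.0)(dose))
    global_values = pd.DataFrame.from_dict(global_rows, orient="index",
                                           columns=design.index)
    global_values = _apply_mnar(rng, global_values, config.mnar_midpoint,
                                config.mnar_steepness)
    global_table = QuantTable(values=global_values, design=design.copy())

    tryptic = [p for p in digest(apoa1, trypsin(max_missed=2))
               if 6 <= len(p.sequence) <= 30]
    semi = _semi_tryptic_peptides(apoa1)
    lip_rows = {}
    for pep in tryptic + semi:
        is_semi = pep.peptide_class == "semi_tryptic"
        base = rng.normal(24.0 if is_semi else 25.5, 1.0)
        effect = _window_effect(pep, config.planted_windows) if is_semi else 0.0
        row = []
        for sample_id, meta in design.iterrows():
            dose = meta["dose"]
            x = base + apoa1_shift(dose)
            if dose > 0:
                x += effect
            row.append(x + rng.normal(0.0, config.noise_sd))
        lip_rows[pep.key] = row
    lip_values = pd.DataFrame.from_dict(lip_rows, orient="index",
                                        columns=design.index)
    lip_values = _apply_mnar(rng, lip_values, config.mnar_midpoint,
                             config.mnar_steepness)
    lip_table = QuantTable(values=lip_values, design=design.copy())
    return global_table, lip_table, truth


def evaluate_window_recovery(config: SimulationConfig,
                             doses: tuple[float, ...] = (20.0, 40.0)) -> dict:
    """Run the full LiP chain on a simulated dataset and score how well the
    structural barcode recovers the planted windows.

    For each requested dose (compared against dose 0) returns whether every
    planted window's mean barcode value has the planted sign, plus the mean
    |value| inside windows and the |mean| outside all windows.
    """
    from .barcode import build_barcode
    from .pipeline import compare_groups, prepare_table

    apoa1 = load_apoa1()
    registry = ProteinRegistry([apoa1, load_apoa2()])
    global_table, lip_table, truth = simulate_lip_dataset(config)
    global_prepared = prepare_table(global_table, seed=config.seed)
    lip_prepared = prepare_table(lip_table, seed=config.seed + 1)
    out: dict = {}
    for dose in doses:
        group = f"dose_{dose:g}"
        _, corrected = compare_groups(global_prepared, lip_prepared,
                                      "dose_0", group, registry)
        bc = build_barcode(corrected, apoa1, dose=group)
        signs, inside_abs = [], []
        mask = np.ones(len(bc.values), dtype=bool)
        for w in truth.windows:
            inside = bc.values[w.start - 1:w.end]
            mask[w.start - 1:w.end] = False
            signs.append(bool(np.sign(inside.mean()) == w.sign))
            inside_abs.append(abs(float(inside.mean())))
        out[dose] = {
            "window_signs": signs,
            "inside_mean_abs": float(np.mean(inside_abs)),
            "outside_mean_abs": abs(float(bc.values[mask].mean())),
        }
    return out


# ---------------------------------------------------------------------------
# cross-link candidates


def _random_protein(rng: np.random.Generator, pid: str, length: int = 120
                    ) -> ProteinRecord:
    letters = rng.choice(list(AMINO_ACIDS), size=length)
    return ProteinRecord(id=pid, sequence="".join(letters),
                         name=f"synthetic decoy protein {pid}", role="decoy")


def _peptide_covering(protein: ProteinRecord, residue: int
                      ) -> LocatedPeptide | None:
    for pep in digest(protein, trypsin(max_missed=2)):
        if pep.start <= residue <= pep.end and 4 <= len(pep.sequence) <= 30:
            return pep
    return None


def simulate_xlink_candidates(config: SimulationConfig = SimulationConfig()
                              ) -> tuple[list[xl.CrosslinkCandidate],
                                         ProteinRegistry, GroundTruth]:
    """Decoy-containing candidate lists over two independent experiments.

    True APOA1-APOA2 lysine pairs are emitted in both evidence sets as
    H12/D12 twins with correct theoretical masses at charges 3-5 and high
    scores; decoy candidates sit on synthetic decoy proteins with scores
    from a clearly lower distribution.
    """
    rng = np.random.default_rng(config.seed)
    apoa1, apoa2 = load_apoa1(), load_apoa2()
    registry = ProteinRegistry([apoa1, apoa2])
    decoys = [_random_protein(rng, f"DUMMY{i + 1}")
              for i in range(config.n_decoy_proteins)]
    for d in decoys:
        registry.add(d)

    lys_a = [i + 1 for i, aa in enumerate(apoa1.sequence) if aa == "K"]
    lys_b = [i + 1 for i, aa in enumerate(apoa2.sequence) if aa == "K"]
    pairs: list[tuple[int, int]] = []
    attempts = 0
    while len(pairs) < config.n_true_pairs and attempts < 1000:
        attempts += 1
        ra = int(rng.choice(lys_a))
        rb = int(rng.choice(lys_b))
        if (ra, rb) in pairs:
            continue
        if _peptide_covering(apoa1, ra) and _peptide_covering(apoa2, rb):
            pairs.append((ra, rb))
    truth = GroundTruth(seed=config.seed,
                        true_pairs=[("APOA1", ra, "APOA2", rb)
                                    for ra, rb in pairs])

    candidates: list[xl.CrosslinkCandidate] = []
    for experiment in ("exp1", "exp2"):
        for ra, rb in pairs:
            pep_a = _peptide_covering(apoa1, ra)
            pep_b = _peptide_covering(apoa2, rb)
            charge = int(rng.integers(3, 6))
            score = float(rng.normal(5.0, 0.4))
            for linker_name in ("BS3-H12", "BS3-D12"):
                mass = xl.crosslinked_species_mass(
                    pep_a.sequence, pep_b.sequence, linker_name, charge)
                candidates.append(
                    xl.CrosslinkCandidate(
                        peptide_a=pep_a.sequence,
                        site_offset_a=ra - pep_a.start + 1,
                        protein_a="APOA1",
                        peptide_b=pep_b.sequence,
                        site_offset_b=rb - pep_b.start + 1,
                        protein_b="APOA2",
                        engine="sim-xl", experiment_id=experiment,
                        score=score, observed_species_mass=mass,
                        charge=charge,
                    )
                )
        n_decoy = int(round(config.decoy_fraction * len(pairs)))
        for _ in range(n_decoy):
            decoy = decoys[int(rng.integers(len(decoys)))]
            peps = [p for p in digest(decoy, trypsin(max_missed=1))
                    if 4 <= len(p.sequence) <= 30]
            if not peps:
                continue
            pep_a = peps[int(rng.integers(len(peps)))]
            target_peps = [p for p in digest(apoa1, trypsin(max_missed=1))
                           if 4 <= len(p.sequence) <= 30]
            pep_b = target_peps[int(rng.integers(len(target_peps)))]
            charge = int(rng.integers(3, 6))
            mass = xl.crosslinked_species_mass(
                pep_a.sequence, pep_b.sequence, "BS3-H12", charge)
            candidates.append(
                xl.CrosslinkCandidate(
                    peptide_a=pep_a.sequence, site_offset_a=1,
                    protein_a=decoy.id,
                    peptide_b=pep_b.sequence, site_offset_b=1,
                    protein_b="APOA1",
                    engine="sim-xl", experiment_id=experiment,
                    score=float(rng.normal(2.5, 0.5)),
                    observed_species_mass=mass, charge=charge,
                )
            )
    return candidates, registry, truth


# ---------------------------------------------------------------------------
# efflux counts


def efflux_response(dose: float, peak: float, baseline: float,
                    amplitude: float) -> float:
    """Unimodal dose-response: baseline + amplitude*(d/peak)*exp(1 - d/peak),
    maximal exactly at ``peak``."""
    if dose <= 0:
        return baseline
    x = dose / peak
    return baseline + amplitude * x * math.exp(1.0 - x)


def simulate_efflux_counts(config: SimulationConfig = SimulationConfig()
                           ) -> tuple[list[EffluxWell], GroundTruth]:
    """Scintillation wells: transporter-positive cells show a unimodal
    dose-response peaking at ``efflux_peak_dose``; transporter-negative
    cells are flat; no-acceptor wells define the background."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(seed=config.seed)
    wells: list[EffluxWell] = []
    background_pct = 1.0
    for condition in ("plus_transporter", "minus_transporter"):
        for rep in range(1, config.efflux_replicates + 1):
            total = float(rng.normal(config.total_dpm, 0.02 * config.total_dpm))
            medium = float(rng.poisson(background_pct / 100.0 * total))
            wells.append(EffluxWell("none", condition, 0.0, medium, total, rep))
        for dose in config.efflux_doses:
            if condition == "plus_transporter":
                pct = efflux_response(dose, config.efflux_peak_dose,
                                      config.efflux_baseline_pct,
                                      config.efflux_amplitude_pct)
            else:
                pct = config.efflux_baseline_pct
            truth.efflux_means[(condition, dose)] = pct - background_pct
            pct += background_pct
            for rep in range(1, config.efflux_replicates + 1):
                total = float(rng.normal(config.total_dpm,
                                         0.02 * config.total_dpm))
                medium = float(rng.poisson(pct / 100.0 * total))
                wells.append(EffluxWell("HDL", condition, dose, medium,
                                        total, rep))
    return wells, truth
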