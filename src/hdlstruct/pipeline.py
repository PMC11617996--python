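"""End-to-end runs: configuration, stage ordering, manifests, file I/O.

The LiP run executes the fixed stage order
log2 -> filter -> normalize -> impute -> test -> correct -> barcode,
once per experimental group against the control group. The cross-link run
executes calibrate -> map -> consensus -> annotate per evidence set. Every
output directory contains the serialized configuration, the seed, and a
manifest with package versions and a config hash, so a run is reproducible
from its own outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import crosslinks as xl
from .barcode import build_barcode, correct_lip_foldchanges, export_barcode
from .digestion import parse_peptide_key
from .proteins import (APOA1_HELIX_REPEATS, HelixAnnotation, ProteinRegistry,
                       default_registry, read_fasta)
from .quantify import (QuantTable, differential, filter_missingness,
                       impute_downshift, log2_transform, median_normalize)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated, serializable configuration for a pipeline run."""

    output_dir: str = "hdlstruct_run"
    # LiP inputs
    global_values: str = ""
    lip_values: str = ""
    design: str = ""
    fasta: str = ""
    control_group: str = ""
    protein_alpha: float = 0.05
    peptide_alpha: float = 0.01
    max_missing_fraction: float = 0.5
    impute_width: float = 0.3
    impute_shift: float = 1.8
    barcode_mode: str = "share"
    # cross-link inputs: evidence id -> candidate CSV path
    candidates: dict = field(default_factory=dict)
    min_evidence: int = 2
    site_tolerance: int = 0
    max_decoy_hits: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_quant_table(values_path: str | Path, design_path: str | Path,
                     space: str = "log2") -> QuantTable:
    """Values TSV: ``feature_id`` column then one column per sample.
    Design TSV: ``sample_id``, ``group``, optional ``dose``."""
    values = pd.read_csv(values_path, sep="\t").set_index("feature_id")
    design = pd.read_csv(design_path, sep="\t").set_index("sample_id")
    return QuantTable(values=values[list(design.index)], design=design,
                      space=space)


def write_quant_table(table: QuantTable, values_path: str | Path,
                      design_path: str | Path) -> None:
    table.values.rename_axis("feature_id").to_csv(
        values_path, sep="\t", float_format="%.6f")
    table.design.rename_axis("sample_id").to_csv(design_path, sep="\t")


def _manifest(config: RunConfig, stage_log: dict, out_dir: Path) -> None:
    import numpy, scipy  # noqa: local import for version reporting

    manifest = {
        "hdlstruct": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": stage_log,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out_dir / "config.yaml").write_text(yaml.safe_dump(asdict(config)))


def prepare_table(table: QuantTable, max_missing_fraction: float = 0.5,
                  impute_width: float = 0.3, impute_shift: float = 1.8,
                  seed: int = 0, stage_log: dict | None = None,
                  label: str = "table") -> QuantTable:
    """log2 -> missingness filter -> median normalize -> impute, in order."""
    table = log2_transform(table)
    n0 = len(table.values)
    table = filter_missingness(table, max_missing_fraction)
    if stage_log is not None:
        stage_log[f"{label}.filter"] = {"in": n0, "out": len(table.values)}
    table = median_normalize(table)
    table = impute_downshift(table, width=impute_width, shift=impute_shift,
                             seed=seed)
    return table


def compare_groups(global_prepared: QuantTable, lip_prepared: QuantTable,
                   control: str, group: str, registry: ProteinRegistry,
                   protein_alpha: float = 0.05, peptide_alpha: float = 0.01
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein-level differential results and corrected LiP peptide fold
    changes for one experimental group versus the control."""
    prot_res = differential(global_prepared, control, group,
                            alpha=protein_alpha)
    pep_res = differential(lip_prepared, control, group, alpha=peptide_alpha)
    pep_res["peptide_class"] = [
        _peptide_class_of_key(k, registry) for k in pep_res["feature_id"]]
    corrected = correct_lip_foldchanges(pep_res, prot_res,
                                        protein_alpha=protein_alpha)
    return prot_res, corrected


def run_lip_pipeline(config: RunConfig,
                     global_table: QuantTable | None = None,
                     lip_table: QuantTable | None = None) -> dict:
    """Differential tables and structural barcodes for every experimental
    group versus the control group. Returns paths and in-memory results."""
    out_dir = Path(config.output_dir)
    # pre-flight: resolve all inputs before writing anything
    if global_table is None or lip_table is None:
        for path in (config.global_values, config.lip_values, config.design):
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"[pre-flight] missing input: {path!r}")
        global_table = read_quant_table(config.global_values, config.design)
        lip_table = read_quant_table(config.lip_values, config.design)
    if config.fasta:
        registry = ProteinRegistry(read_fasta(config.fasta))
    else:
        registry = default_registry()
    groups = global_table.groups
    control = config.control_group or groups[0]
    if control not in groups:
        raise ValueError(f"[pre-flight] control group {control!r} not in design")

    out_dir.mkdir(parents=True, exist_ok=True)
    stage_log: dict = {}
    global_prepared = prepare_table(
        global_table, config.max_missing_fraction, config.impute_width,
        config.impute_shift, seed=config.seed, stage_log=stage_log,
        label="global")
    lip_prepared = prepare_table(
        lip_table, config.max_missing_fraction, config.impute_width,
        config.impute_shift, seed=config.seed + 1, stage_log=stage_log,
        label="lip")

    annotations = {"APOA1": APOA1_HELIX_REPEATS}
    results: dict = {"barcodes": {}, "differential": {}}
    for group in groups:
        if group == control:
            continue
        prot_res, corrected = compare_groups(
            global_prepared, lip_prepared, control, group, registry,
            protein_alpha=config.protein_alpha,
            peptide_alpha=config.peptide_alpha)
        tag = group.replace("/", "_")
        prot_res.to_csv(out_dir / f"proteins_{tag}.tsv", sep="\t",
                        index=False, float_format="%.6f")
        corrected.to_csv(out_dir / f"peptides_{tag}.tsv", sep="\t",
                         index=False, float_format="%.6f")
        results["differential"][group] = {"protein": prot_res,
                                          "peptide": corrected}
        stage_log[f"test.{group}"] = {
            "proteins_significant": int(prot_res["significant"].sum()),
            "peptides_significant": int((corrected["p_value"]
                                         < config.peptide_alpha).sum()),
        }
        for protein in registry:
            if not (corrected["protein_id"] == protein.id).any():
                continue
            bc = build_barcode(corrected, protein,
                               peptide_alpha=config.peptide_alpha,
                               mode=config.barcode_mode, dose=group)
            export_barcode(bc, out_dir / f"barcode_{protein.id}_{tag}.tsv",
                           out_dir / f"barcode_{protein.id}_{tag}.png",
                           annotation=annotations.get(protein.id))
            results["barcodes"][(protein.id, group)] = bc
    _manifest(config, stage_log, out_dir)
    results["output_dir"] = out_dir
    return results


def _peptide_class_of_key(key: str, registry: ProteinRegistry) -> str:
    from .digestion import classify_termini

    protein_id, start, end, _ = parse_peptide_key(key)
    if protein_id not in registry:
        return "non_tryptic"
    located = classify_termini(start, end, registry[protein_id])
    return located.peptide_class


def run_xl_pipeline(config: RunConfig,
                    registry: ProteinRegistry | None = None,
                    annotations: dict[str, HelixAnnotation] | None = None
                    ) -> dict:
    """Per-evidence threshold calibration, site mapping, consensus, and
    helix annotation over the configured candidate files."""
    if not config.candidates:
        raise ValueError("[pre-flight] no candidate files configured")
    for path in config.candidates.values():
        if not Path(path).exists():
            raise FileNotFoundError(f"[pre-flight] missing candidates: {path}")
    if registry is None:
        registry = default_registry()
    if annotations is None:
        annotations = {"APOA1": APOA1_HELIX_REPEATS}
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage_log: dict = {}
    pair_sets: list[tuple[str, list[xl.ResiduePair]]] = []
    for evidence_id, path in config.candidates.items():
        candidates = xl.read_candidates(path)
        if not candidates:
            log.warning("evidence %s: empty candidate file", evidence_id)
            pair_sets.append((evidence_id, []))
            stage_log[f"calibrate.{evidence_id}"] = {"in": 0, "accepted": 0}
            continue
        threshold, accepted = xl.calibrate_threshold(
            candidates, registry.decoy_ids, config.max_decoy_hits)
        pairs = [xl.to_residue_pair(c, registry) for c in accepted]
        pair_sets.append((evidence_id, pairs))
        stage_log[f"calibrate.{evidence_id}"] = {
            "in": len(candidates), "accepted": len(accepted),
            "threshold": threshold,
        }
    entries = xl.consensus(pair_sets, min_evidence=config.min_evidence,
                           site_tolerance=config.site_tolerance)
    frame = xl.write_consensus(entries, annotations,
                               out_dir / "consensus.csv")
    stage_log["consensus"] = {"pairs": len(entries)}
    _manifest(config, stage_log, out_dir)
    return {"consensus": entries, "frame": frame, "output_dir": out_dir}
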