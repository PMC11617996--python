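"""Per-residue structural barcodes from LiP peptide fold changes.

A structural barcode is a residue-level track along a protein: the log2
fold change of each significant semi-tryptic peptide, after correction for
the parent protein's abundance change, is distributed over the residues the
peptide covers, and contributions from different peptides are summed.
Positive values mean the region became more accessible to the nonspecific
protease under treatment (exposed); negative values mean it was shielded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .digestion import parse_peptide_key
from .proteins import HelixAnnotation, ProteinRecord

log = logging.getLogger(__name__)

BarcodeMode = Literal["share", "spread"]


def correct_lip_foldchanges(peptide_results: pd.DataFrame,
                            protein_results: pd.DataFrame,
                            protein_alpha: float = 0.05) -> pd.DataFrame:
    """Correct peptide fold changes for parent-protein abundance changes.

    Peptide feature ids are keys ``protein|start-end|SEQUENCE``; protein
    feature ids are protein ids. When the parent protein changed
    significantly (p < ``protein_alpha``) its log2 fold change is
    subtracted from the peptide's (division in linear space), so that the
    corrected value reflects structure, not copy number. Peptides whose
    parent is absent from the protein table pass through with a warning.
    """
    prot = protein_results.set_index("feature_id")
    rows = []
    missing_parents: set[str] = set()
    for _, rec in peptide_results.iterrows():
        protein_id, start, end, sequence = parse_peptide_key(rec["feature_id"])
        raw = float(rec["log2fc"])
        corrected, applied = raw, False
        if protein_id in prot.index:
            parent = prot.loc[protein_id]
            if float(parent["p_value"]) < protein_alpha:
                corrected = raw - float(parent["log2fc"])
                applied = True
        else:
            missing_parents.add(protein_id)
        rows.append(
            {
                "feature_id": rec["feature_id"],
                "protein_id": protein_id,
                "start": start,
                "end": end,
                "sequence": sequence,
                "peptide_class": rec.get("peptide_class", "semi_tryptic"),
                "raw_log2fc": raw,
                "corrected_log2fc": corrected,
                "p_value": float(rec["p_value"]),
                "correction_applied": applied,
            }
        )
    if missing_parents:
        log.warning("no protein-level result for parent(s) %s; "
                    "peptide fold changes passed through", sorted(missing_parents))
    return pd.DataFrame(rows)


@dataclass
class StructuralBarcode:
    protein_id: str
    sequence: str
    values: np.ndarray       # signed, summed corrected log2fc per residue
    coverage: np.ndarray     # number of contributing significant peptides
    dose: str = ""
    mode: BarcodeMode = "share"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if len(self.values) != n or len(self.coverage) != n:
            raise ValueError("values/coverage length must equal protein length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": np.arange(1, len(self.sequence) + 1),
                "letter": list(self.sequence),
                "value": self.values,
                "coverage": self.coverage,
            }
        )


def build_barcode(corrected: pd.DataFrame, protein: ProteinRecord,
                  peptide_alpha: float = 0.01, mode: BarcodeMode = "share",
                  dose: str = "") -> StructuralBarcode:
    """Sum corrected fold changes of significant semi-tryptic peptides onto
    residues.

    ``share`` divides each peptide's corrected log2fc equally over its
    residues (per-peptide contributions then sum to the fold change);
    ``spread`` writes the full value onto every covered residue. Only
    semi-tryptic peptides with p < ``peptide_alpha`` contribute.
    """
    n = len(protein.sequence)
    values = np.zeros(n)
    coverage = np.zeros(n, dtype=int)
    sub = corrected[corrected["protein_id"] == protein.id]
    n_skipped_class = 0
    for _, rec in sub.iterrows():
        if rec["peptide_class"] != "semi_tryptic":
            n_skipped_class += 1
            continue
        if float(rec["p_value"]) >= peptide_alpha:
            continue
        start, end = int(rec["start"]), int(rec["end"])
        if not (1 <= start <= end <= n):
            raise ValueError(
                f"peptide span {start}-{end} outside {protein.id} (length {n})"
            )
        length = end - start + 1
        fc = float(rec["corrected_log2fc"])
        per_residue = fc / length if mode == "share" else fc
        values[start - 1:end] += per_residue
        coverage[start - 1:end] += 1
    if n_skipped_class:
        log.info("%d non-semi-tryptic peptides excluded from barcode",
                 n_skipped_class)
    return StructuralBarcode(protein_id=protein.id, sequence=protein.sequence,
                             values=values, coverage=coverage, dose=dose,
                             mode=mode)


def export_barcode(barcode: StructuralBarcode, tsv_path: str | Path,
                   figure_path: str | Path | None = None,
                   annotation: HelixAnnotation | None = None) -> pd.DataFrame:
    """Write the residue-level TSV and, optionally, a heatmap strip.

    The rendering uses a diverging red/blue scale centred at zero (red =
    exposed, blue = shielded), aligned under the helix-repeat track when an
    annotation is given.
    """
    frame = barcode.to_frame()
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.6f")
    if figure_path is not None:
        render_barcode(barcode, figure_path, annotation=annotation)
    return frame


def import_barcode(tsv_path: str | Path, protein_id: str = "",
                   dose: str = "") -> StructuralBarcode:
    frame = pd.read_csv(tsv_path, sep="\t")
    return StructuralBarcode(
        protein_id=protein_id,
        sequence="".join(frame["letter"]),
        values=frame["value"].to_numpy(dtype=float),
        coverage=frame["coverage"].to_numpy(dtype=int),
        dose=dose,
    )


def render_barcode(barcode: StructuralBarcode, figure_path: str | Path,
                   annotation: HelixAnnotation | None = None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(barcode.sequence)
    vmax = float(np.max(np.abs(barcode.values))) or 1.0
    fig, ax = plt.subplots(figsize=(max(6, n / 25), 1.8))
    ax.imshow(barcode.values[np.newaxis, :], cmap="bwr", vmin=-vmax,
              vmax=vmax, aspect="auto", extent=(0.5, n + 0.5, 0, 1))
    if annotation is not None:
        for label, start, end in annotation.repeats:
            ax.axvline(start - 0.5, 0.95, 1.0, color="k", lw=0.5)
            ax.text((start + end) / 2, 1.08, label, ha="center", va="bottom",
                    fontsize=7, transform=ax.get_xaxis_transform())
    ax.set_yticks([])
    ax.set_xlabel(f"{barcode.protein_id} residue")
    title = f"structural barcode ({barcode.mode})"
    if barcode.dose:
        title += f", dose {barcode.dose}"
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(figure_path, dpi=150)
    plt.close(fig)
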