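"""Cholesterol-efflux summarization from scintillation counts.

Percent efflux for one well is 100 x (counts released into the medium /
total internalized counts), background-corrected against no-acceptor
control wells and, when cells with and without transporter expression are
assayed in parallel, reduced to the transporter-specific component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Condition = Literal["plus_transporter", "minus_transporter"]


@dataclass(frozen=True)
class EffluxWell:
    """Scintillation counts for one acceptor/condition/dose/replicate."""

    acceptor: str
    condition: Condition
    dose: float
    medium_dpm: float
    total_internalized_dpm: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.medium_dpm < 0:
            raise ValueError("negative medium counts")
        if self.total_internalized_dpm <= 0:
            raise ValueError("total internalized counts must be positive")


def percent_efflux(medium_dpm: float, total_internalized_dpm: float) -> float:
    """100 x medium counts / total internalized counts."""
    if total_internalized_dpm <= 0:
        raise ValueError("total internalized counts must be positive")
    if medium_dpm < 0:
        raise ValueError("negative medium counts")
    return 100.0 * medium_dpm / total_internalized_dpm


def normalize_to_no_acceptor(values: np.ndarray | list[float],
                             no_acceptor_control_values: np.ndarray | list[float]
                             ) -> np.ndarray:
    """Subtract the mean no-acceptor control efflux from each value."""
    controls = np.asarray(no_acceptor_control_values, dtype=float)
    if controls.size == 0:
        raise ValueError("empty no-acceptor control set")
    net = np.asarray(values, dtype=float) - controls.mean()
    if (net < 0).any():
        log.info("%d net efflux value(s) below the no-acceptor baseline",
                 int((net < 0).sum()))
    return net


def wells_to_frame(wells: list[EffluxWell]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(w) for w in wells])
    frame["percent_efflux"] = 100.0 * frame["medium_dpm"] / frame[
        "total_internalized_dpm"]
    return frame


def summarize(wells: list[EffluxWell] | pd.DataFrame,
              no_acceptor_label: str = "none") -> pd.DataFrame:
    """Mean/SD/n of net percent efflux per (acceptor, condition, dose).

    Wells whose acceptor equals ``no_acceptor_label`` define the background
    per condition; their mean is subtracted from every other well of the
    same condition before summarizing.
    """
    frame = wells_to_frame(wells) if isinstance(wells, list) else wells.copy()
    if "percent_efflux" not in frame.columns:
        frame["percent_efflux"] = 100.0 * frame["medium_dpm"] / frame[
            "total_internalized_dpm"]
    out_rows = []
    for condition, sub in frame.groupby("condition"):
        controls = sub.loc[sub["acceptor"] == no_acceptor_label,
                           "percent_efflux"]
        baseline = float(controls.mean()) if len(controls) else 0.0
        acceptors = sub[sub["acceptor"] != no_acceptor_label]
        for (acceptor, dose), grp in acceptors.groupby(["acceptor", "dose"]):
            net = grp["percent_efflux"].to_numpy(dtype=float) - baseline
            out_rows.append(
                {
                    "acceptor": acceptor, "condition": condition,
                    "dose": float(dose),
                    "mean_percent_efflux": float(net.mean()),
                    "sd": float(net.std(ddof=1)) if len(net) > 1 else 0.0,
                    "n": int(len(net)),
                }
            )
    return pd.DataFrame(out_rows).sort_values(
        ["acceptor", "condition", "dose"]).reset_index(drop=True)


def transporter_specific_efflux(summary: pd.DataFrame) -> pd.DataFrame:
    """Difference of condition means per (acceptor, dose).

    The uncertainty is the propagated standard error
    sqrt(sd+^2/n+ + sd-^2/n-). Keys missing one condition are skipped with
    a warning.
    """
    rows = []
    for (acceptor, dose), grp in summary.groupby(["acceptor", "dose"]):
        by_cond = {row["condition"]: row for _, row in grp.iterrows()}
        if not {"plus_transporter", "minus_transporter"} <= set(by_cond):
            warnings.warn(
                f"missing condition for acceptor={acceptor!r} dose={dose}; skipped"
            )
            continue
        plus, minus = by_cond["plus_transporter"], by_cond["minus_transporter"]
        sem = np.sqrt(plus["sd"] ** 2 / plus["n"] + minus["sd"] ** 2 / minus["n"])
        rows.append(
            {
                "acceptor": acceptor, "dose": float(dose),
                "specific_efflux": float(plus["mean_percent_efflux"]
                                         - minus["mean_percent_efflux"]),
                "sem": float(sem),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["acceptor", "dose", "specific_efflux",
                                     "sem"])
    return pd.DataFrame(rows).sort_values(["acceptor", "dose"]).reset_index(
        drop=True)


def dose_table(apoa1_conc: float, dose_fractions: list[float]) -> list[float]:
    """Acceptor concentrations for doses given as fractions of the APOA1
    mass concentration (e.g. 0.10 of 1.5 mg/ml -> 0.15 mg/ml)."""
    if apoa1_conc <= 0:
        raise ValueError("reference concentration must be positive")
    if any(f < 0 for f in dose_fractions):
        raise ValueError("negative dose fraction")
    return [f * apoa1_conc for f in dose_fractions]


def read_wells(path: str | Path) -> list[EffluxWell]:
    frame = pd.read_csv(path, sep="\t")
    return [
        EffluxWell(
            acceptor=str(r["acceptor"]), condition=r["condition"],
            dose=float(r["dose"]), medium_dpm=float(r["medium_dpm"]),
            total_internalized_dpm=float(r["total_internalized_dpm"]),
            replicate=int(r.get("replicate", 1)),
        )
        for _, r in frame.iterrows()
    ]


def write_wells(wells: list[EffluxWell], path: str | Path) -> None:
    pd.DataFrame([vars(w) for w in wells]).to_csv(path, sep="\t", index=False)
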