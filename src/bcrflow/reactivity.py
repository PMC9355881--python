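"""Polyreactivity, HEp-2 reactivity and autoantibody z-score calling.

Cloned antibodies are screened by ELISA against dsDNA, insulin and LPS
in serial dilution.  Per antigen, the positivity threshold is the mean
of the positive controls minus two standard deviations at the 1 µg/ml
antibody concentration; an antibody is polyreactive when it recognizes
at least two of the three antigens.  HEp-2 lysate reactivity at 5 µg/ml
is normalized by the same control-derived quantity, values above 1
positive.  Plasma autoantibody levels are expressed as z-scores against
healthy-control absorbances, positive above 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import mean, stdev

import pandas as pd

__all__ = [
    "ElisaPanel",
    "ANTIGENS",
    "CONCENTRATIONS",
    "call_polyreactivity",
    "hep2_reactivity",
    "autoantibody_zscores",
]

ANTIGENS = ("dsDNA", "insulin", "LPS")
CONCENTRATIONS = (1.0, 0.25, 0.0625, 0.0156)
HEP2_CONCENTRATION = 5.0
THRESHOLD_CONCENTRATION = 1.0


@dataclass
class ElisaPanel:
    """Long-format ELISA absorbances.

    ``data`` columns: clone_id, antigen, concentration, od, is_control.
    ODs are blank-corrected, clamped at 0.  HEp-2 rows use antigen
    'HEp-2' at 5 µg/ml.
    """

    data: pd.DataFrame
    mutated: dict = field(default_factory=dict)  # clone_id -> bool annotation

    def __post_init__(self):
        required = {"clone_id", "antigen", "concentration", "od", "is_control"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing ELISA columns: {sorted(missing)}")
        self.data = self.data.copy()
        self.data["od"] = self.data["od"].clip(lower=0.0)

    def _controls(self, antigen: str, concentration: float) -> list[float]:
        d = self.data
        sel = d[
            d["is_control"]
            & (d["antigen"] == antigen)
            & (d["concentration"] == concentration)
        ]
        return sel["od"].tolist()

    def _sample_od(self, clone_id: str, antigen: str, concentration: float) -> float | None:
        d = self.data
        sel = d[
            (~d["is_control"])
            & (d["clone_id"] == clone_id)
            & (d["antigen"] == antigen)
            & (d["concentration"] == concentration)
        ]
        if sel.empty:
            return None
        return float(sel["od"].iloc[0])

    def clone_ids(self) -> list[str]:
        d = self.data
        return sorted(d.loc[~d["is_control"], "clone_id"].unique())


def _control_threshold(controls: list[float], antigen: str) -> float:
    if len(controls) < 2:
        raise ValueError(
            f"{antigen}: need >= 2 positive controls to define a threshold (sd undefined)"
        )
    return mean(controls) - 2.0 * stdev(controls)


def call_polyreactivity(panel: ElisaPanel) -> pd.DataFrame:
    """Per-antigen positivity and the polyreactivity call for each clone.

    Positive for an antigen iff the blank-corrected OD at 1 µg/ml meets
    or exceeds mean(controls) - 2 sd(controls) at 1 µg/ml; polyreactive
    iff positive for at least two of the three antigens.
    """
    thresholds = {
        ag: _control_threshold(panel._controls(ag, THRESHOLD_CONCENTRATION), ag)
        for ag in ANTIGENS
    }
    rows = []
    for cid in panel.clone_ids():
        row: dict = {"clone_id": cid}
        n_pos = 0
        for ag in ANTIGENS:
            od = panel._sample_od(cid, ag, THRESHOLD_CONCENTRATION)
            pos = od is not None and od >= thresholds[ag]
            row[f"{ag}_od"] = od
            row[f"{ag}_positive"] = pos
            n_pos += int(pos)
        row["n_antigens_positive"] = n_pos
        row["polyreactive"] = n_pos >= 2
        row["mutated"] = panel.mutated.get(cid)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["thresholds"] = thresholds
    return df


def hep2_reactivity(panel: ElisaPanel, antigen: str = "HEp-2") -> pd.DataFrame:
    """Normalized HEp-2 lysate reactivity per clone.

    Normalizer = mean(positive controls) - 2 sd at 5 µg/ml; positive iff
    the normalized value is strictly above 1.
    """
    controls = panel._controls(antigen, HEP2_CONCENTRATION)
    normalizer = _control_threshold(controls, antigen)
    if normalizer <= 0:
        raise ValueError("degenerate control distribution")
    rows = []
    for cid in panel.clone_ids():
        od = panel._sample_od(cid, antigen, HEP2_CONCENTRATION)
        if od is None:
            continue
        norm = od / normalizer
        rows.append(
            {"clone_id": cid, "od": od, "normalized": norm, "positive": norm > 1.0}
        )
    df = pd.DataFrame(rows)
    df.attrs["normalizer"] = normalizer
    return df


def autoantibody_zscores(
    sample_ods: dict[str, float], hc_ods: dict[str, list[float]]
) -> pd.DataFrame:
    """Autoantibody z-scores against healthy-control absorbances.

    z = (x - mean(HC)) / sd(HC) with the sample (n-1) standard
    deviation; positive iff z > 2.  Antigens with fewer than 3 HC values
    raise; zero HC spread leaves z undefined and flags the row.
    """
    rows = []
    for antigen, x in sample_ods.items():
        hc = hc_ods.get(antigen, [])
        if len(hc) < 3:
            raise ValueError(f"{antigen}: need >= 3 healthy-control values")
        mu, sd = mean(hc), stdev(hc)
        if sd == 0:
            rows.append(
                {"antigen": antigen, "od": x, "z": math.nan,
                 "positive": False, "flagged": True}
            )
            continue
        z = (x - mu) / sd
        rows.append(
            {"antigen": antigen, "od": x, "z": z, "positive": z > 2.0, "flagged": False}
        )
    return pd.DataFrame(rows)
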