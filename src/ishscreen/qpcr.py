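"""Relative qPCR quantification for candidate validation.

Expression is quantified with the 2^-dCt method against the Fmr1 reference
(present at equal levels in synaptosomes and total brain), and neuropil
association is summarized as the ratio of relative expression between the
synaptosomal and total-brain compartments.  Not-detected (ND) measurements
propagate as ND; they are never coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ND = None  # not detected


@dataclass(frozen=True)
class QpcrMeasurement:
    target_ct: float | None  # None = not detected
    reference_ct: float | None
    compartment: str = "synaptosome"  # "synaptosome" | "total-brain"
    replicate: int = 0

    def validate(self) -> None:
        for ct in (self.target_ct, self.reference_ct):
            if ct is not None and not (np.isfinite(ct) and ct > 0):
                raise ValueError("Ct values must be positive and finite, or ND")


def relative_expression(m: QpcrMeasurement) -> float | None:
    """``2 ** -(Ct_target - Ct_reference)`` in arbitrary units; ND propagates."""
    m.validate()
    if m.target_ct is None or m.reference_ct is None:
        return ND
    return float(2.0 ** -(m.target_ct - m.reference_ct))


def enrichment_ratio(synaptosomal: float | None, brain: float | None) -> float | None:
    """Synaptosome / total-brain ratio of relative expression; ND propagates."""
    if synaptosomal is None or brain is None:
        return ND
    if brain <= 0:
        raise ValueError("total-brain expression must be positive")
    return float(synaptosomal / brain)


def aggregate_replicates(values: list[float | None]) -> tuple[float | None, float | None]:
    """Mean and sample SD over detected replicates; all-ND propagates ND."""
    detected = [v for v in values if v is not None]
    if not detected:
        return ND, ND
    arr = np.asarray(detected, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def quantify_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene synaptosomal/brain relative expression and enrichment ratio.

    Input columns: gene, compartment ("synaptosome"/"total-brain"), replicate,
    ct_target, ct_reference (empty/NaN cells are ND).  The ratio column is
    rounded to 2 decimals alongside the full-precision value.
    """
    rows = []
    for gene, group in ct_table.groupby("gene", sort=False):
        by_comp: dict[str, float | None] = {}
        for comp in ("synaptosome", "total-brain"):
            sub = group[group["compartment"] == comp]
            vals = [
                relative_expression(
                    QpcrMeasurement(
                        None if pd.isna(r.ct_target) else float(r.ct_target),
                        None if pd.isna(r.ct_reference) else float(r.ct_reference),
                        comp,
                        int(r.replicate),
                    )
                )
                for r in sub.itertuples()
            ]
            by_comp[comp], _ = aggregate_replicates(vals)
        ratio = (
            enrichment_ratio(by_comp["synaptosome"], by_comp["total-brain"])
            if by_comp["total-brain"] not in (None, 0)
            else ND
        )
        rows.append(
            {
                "gene": gene,
                "synaptosomal_au": by_comp["synaptosome"],
                "brain_au": by_comp["total-brain"],
                "ratio": ratio,
                "ratio_2dp": None if ratio is None else round(ratio, 2),
            }
        )
    return pd.DataFrame(rows)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_quantification(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="ND", float_format="%.6g")
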