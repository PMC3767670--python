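"""Prototype-correlation ranking of candidate genes.

The prototype vector is the mean of the positive training genes' feature
vectors restricted to the selected features (z-scored with the training-set
parameters).  Every candidate probe is scored by the Pearson correlation of
its selected-feature vector against the prototype, after the same z-scoring;
probes are ranked by descending correlation.  An expression pre-filter
removes probes whose reported hippocampal expression level and density are
both at or below a background threshold (default 20).  The report exposes the
candidate cut lines r >= 0.8 and r >= 0.7 as columns, not as hard-coded
filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_selection import SelectionMask, TrainingSet

EXPRESSION_THRESHOLD = 20.0
REPORT_CUTS = (0.8, 0.7)


@dataclass
class PrototypeVector:
    values: np.ndarray  # z-scored mean of the positives on selected features
    feature_names: list[str]
    mu: np.ndarray  # training z-score parameters (selected features)
    sd: np.ndarray


def expression_filter(
    metadata: pd.DataFrame, threshold: float = EXPRESSION_THRESHOLD
) -> list:
    """Probe ids whose expression level OR density is strictly above threshold.

    ``metadata`` must have a ``probe`` column plus ``expression_level`` and/or
    ``expression_density``.  A probe missing both values is excluded with a
    warning.
    """
    cols = [c for c in ("expression_level", "expression_density") if c in metadata.columns]
    if not cols:
        raise ValueError("metadata has neither expression_level nor expression_density")
    retained = []
    for _, row in metadata.iterrows():
        vals = [row[c] for c in cols if pd.notna(row[c])]
        if not vals:
            warnings.warn(f"probe {row['probe']} has no expression values; excluded")
            continue
        if max(vals) > threshold:
            retained.append(row["probe"])
    return retained


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Product-moment correlation; ``(0.0, True)`` flag on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson needs two equal-length vectors of size >= 2")
    if x.std() == 0 or y.std() == 0:
        return 0.0, True
    return float(np.corrcoef(x, y)[0, 1]), False


def build_prototype(train: TrainingSet, mask: SelectionMask) -> PrototypeVector:
    """Mean z-scored positive vector on the selected features."""
    names = mask.selected_names
    sub = train.subset(names)
    mu, sd = sub.zscore_params()
    Z = (sub.matrix - mu) / sd
    return PrototypeVector(Z[sub.positive].mean(axis=0), names, mu, sd)


def rank_genes(
    features: pd.DataFrame,
    prototype: PrototypeVector,
    metadata: pd.DataFrame | None = None,
    threshold: float = EXPRESSION_THRESHOLD,
    cuts: tuple[float, ...] = REPORT_CUTS,
) -> pd.DataFrame:
    """Ranked table of probes by Pearson similarity to the prototype.

    ``features`` must carry ``gene``/``probe``/``level`` id columns plus (at
    least) the selected feature columns in canonical naming.  Rows are sorted
    by descending r with ties broken by probe id; ranks are contiguous from 1.
    """
    missing = [n for n in prototype.feature_names if n not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks selected columns: {missing[:5]}")
    table = features
    if metadata is not None:
        keep = set(expression_filter(metadata, threshold))
        table = table[table["probe"].isin(keep)]

    X = table[prototype.feature_names].to_numpy(dtype=float)
    Z = (X - prototype.mu) / prototype.sd
    rs = np.array([pearson(z, prototype.values)[0] for z in Z])

    out = table[["gene", "probe", "level"]].copy()
    out["r"] = rs
    out = out.sort_values(["r", "probe"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    for cut in cuts:
        out[f"pass_{cut:g}"] = (out["r"] >= cut).astype(int)
    return out.reset_index(drop=True)


def stability_profile(
    section_rs: dict[str, list[float]],
) -> pd.DataFrame:
    """Per-gene summary of prototype correlations across atlas levels.

    ``section_rs`` maps gene id to the r values of its accepted sections.
    Genes with fewer than two accepted sections get a flagged single-value
    summary.
    """
    rows = []
    for gene, rs in section_rs.items():
        rs = np.asarray(rs, dtype=float)
        if rs.size == 0:
            continue
        q1, med, q3 = np.percentile(rs, [25, 50, 75])
        rows.append(
            {
                "gene": gene,
                "n_sections": rs.size,
                "min": rs.min(),
                "median": med,
                "max": rs.max(),
                "iqr": q3 - q1,
                "flagged": rs.size < 2,
            }
        )
    return pd.DataFrame(rows)
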