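"""End-to-end orchestration: simulate -> localize -> segment -> extract ->
select -> rank.

A single master seed drives every stochastic stage through named children of
a :class:`numpy.random.SeedSequence`, so two runs with the same configuration
produce byte-identical artifacts.  Every per-gene decision (accept, QC
reject, discard and its reason) is recorded in the run log.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data as synth
from .feature_selection import (
    GAParams,
    SelectionMask,
    TrainingSet,
    consensus_select,
    dedup_features,
    write_mask,
)
from .localization import DEFAULT_ATLAS_LEVEL, build_shape_model, fit_shape, preprocess_roi
from .optimizers import DEParams, PSOParams
from .ranking import (
    EXPRESSION_THRESHOLD,
    REPORT_CUTS,
    build_prototype,
    rank_genes,
)
from .segmentation import (
    SegmentationError,
    qc_segmentation,
    segment_from_localization,
    train_accept_forest,
    train_inside_forest,
)
from .texture import assemble_feature_vector, canonical_feature_names, write_feature_table

logger = logging.getLogger("ishscreen")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters of one screening run.

    Thresholds: feature dedup at |r| > 0.99, expression pre-filter at 20,
    report cut lines at r >= 0.8 and r >= 0.7, atlas levels 117-175 with 145
    as the default slice.
    """

    seed: int = 0
    n_pos: int = 3
    n_neg: int = 17
    e_pos: tuple[float, float] = (1.2, 1.6)
    e_neg: tuple[float, float] = (0.0, 0.3)
    n_screen: int = 30
    e_screen: tuple[float, float] = (0.0, 2.0)
    band_width: float = 8.0
    dedup_threshold: float = 0.99
    expression_threshold: float = EXPRESSION_THRESHOLD
    report_cuts: tuple[float, ...] = REPORT_CUTS
    atlas_range: tuple[int, int] = (117, 175)
    default_level: int = DEFAULT_ATLAS_LEVEL
    n_model_shapes: int = 30
    de: DEParams = field(default_factory=DEParams)
    pso: PSOParams = field(default_factory=PSOParams)
    ga: GAParams = field(default_factory=GAParams)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key, sub in (("de", DEParams), ("pso", PSOParams), ("ga", GAParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        for key in ("e_pos", "e_neg", "e_screen", "atlas_range", "report_cuts"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GeneRecord:
    gene_id: str
    label: str  # positive / negative / screen
    enrichment: float
    image: np.ndarray
    truth: synth.GroundTruth
    expression_level: float = 100.0
    expression_density: float = 100.0


@dataclass
class RunResult:
    ranking: pd.DataFrame
    mask: SelectionMask
    features: pd.DataFrame
    discarded: dict[str, str]
    log: list[str]
    config: PipelineConfig
    prototype: object | None = None


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def simulate_inputs(config: PipelineConfig) -> list[GeneRecord]:
    """Training cohort plus graded screen genes, with expression metadata.

    Screen enrichments are an even grid over ``e_screen``; expression level
    and density increase with the rendered signal so that every simulated
    probe clears the background filter (the filter's reject path is exercised
    by the unit suite on explicit metadata tables).
    """
    ss = np.random.SeedSequence(config.seed)
    s_cohort, s_screen = ss.spawn(2)
    records: list[GeneRecord] = []
    cohort = synth.generate_cohort(
        config.n_pos, config.n_neg, config.e_pos, config.e_neg, _child_seed(s_cohort)
    )
    for item in cohort:
        e = item.truth.enrichment
        records.append(
            GeneRecord(item.gene_id, item.label, e, item.image, item.truth,
                       expression_level=25.0 + 30.0 * e, expression_density=21.0 + 25.0 * e)
        )
    rng = np.random.default_rng(s_screen)
    base = synth.SectionParams()
    es = np.linspace(config.e_screen[0], config.e_screen[1], config.n_screen)
    for i, e in enumerate(es):
        params = synth.jitter_params(
            base, rng, enrichment=float(e), seed=int(rng.integers(0, 2**31 - 1))
        )
        image, truth = synth.generate_section(params)
        records.append(
            GeneRecord(f"screen{i:03d}", "screen", float(e), image, truth,
                       expression_level=25.0 + 30.0 * e, expression_density=21.0 + 25.0 * e)
        )
    return records


def training_shape_model(config: PipelineConfig):
    """Point-distribution model from jittered template geometries."""
    ss = np.random.SeedSequence(config.seed).spawn(3)[2]
    rng = np.random.default_rng(ss)
    base = synth.SectionParams()
    shapes = []
    from .geometry import resample_arclength

    for _ in range(config.n_model_shapes):
        p = synth.jitter_params(base, rng)
        shapes.append(
            np.vstack(
                [
                    resample_arclength(p.ah_curve.polyline(600), synth.N_AH_POINTS),
                    resample_arclength(p.dg_curve.polyline(600), synth.N_DG_POINTS),
                ]
            )
        )
    return build_shape_model(shapes)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute the full screen; writes artifacts when ``outdir`` is given."""
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    ss = np.random.SeedSequence(config.seed)
    _, _, _, s_forest, s_qc, s_fit, s_ga = ss.spawn(7)

    say(f"master seed {config.seed}")
    records = simulate_inputs(config)
    say(f"simulated {len(records)} gene images "
        f"({config.n_pos} pos / {config.n_neg} neg / {config.n_screen} screen)")

    model = training_shape_model(config)
    cohort = [r for r in records if r.label in ("positive", "negative")]
    rf_inside = train_inside_forest(cohort, seed=_child_seed(s_forest))
    rf_accept = train_accept_forest(cohort, rf_inside, seed=_child_seed(s_forest) + 1,
                                    band_width=config.band_width)
    say("trained QC forests on the training cohort")

    fit_seeds = s_fit.spawn(len(records))
    qc_seeds = s_qc.spawn(len(records))
    rows = []
    discarded: dict[str, str] = {}
    for rec, fs, qs in zip(records, fit_seeds, qc_seeds):
        pre = preprocess_roi(rec.image)
        if not pre.ok:
            discarded[rec.gene_id] = "preprocessing failure (constant image)"
            say(f"{rec.gene_id}: DISCARD ({discarded[rec.gene_id]})")
            continue
        de = replace(config.de, seed=_child_seed(fs))
        loc = fit_shape(pre.image, model, de, foreground=pre.foreground,
                        band_width=config.band_width)
        if not loc.ok:
            discarded[rec.gene_id] = f"localization failure: {loc.reason}"
            say(f"{rec.gene_id}: DISCARD ({discarded[rec.gene_id]})")
            continue
        try:
            regions = segment_from_localization(rec.image, loc, config.band_width)
        except SegmentationError as exc:
            discarded[rec.gene_id] = f"segmentation failure: {exc}"
            say(f"{rec.gene_id}: DISCARD ({discarded[rec.gene_id]})")
            continue
        qc = qc_segmentation(rec.image, regions, rf_inside, rf_accept, _child_seed(qs))
        if not qc.accepted:
            discarded[rec.gene_id] = (
                f"QC reject on all slices (point accuracy {qc.point_accuracy:.2f})"
            )
            say(f"{rec.gene_id}: DISCARD ({discarded[rec.gene_id]})")
            continue
        fv = assemble_feature_vector(rec.image, regions)
        row = {"gene": rec.gene_id, "probe": rec.gene_id, "level": config.default_level,
               "label": rec.label, "enrichment": rec.enrichment,
               "expression_level": rec.expression_level,
               "expression_density": rec.expression_density}
        row.update(fv.to_dict())
        rows.append(row)
        say(f"{rec.gene_id}: accepted (QC point accuracy {qc.point_accuracy:.2f})")

    features = pd.DataFrame(rows)
    train_mask = features["label"].isin(["positive", "negative"])
    train_df = features[train_mask]
    n_pos_ok = int((train_df["label"] == "positive").sum())
    if n_pos_ok < 2 or len(train_df) - n_pos_ok < 2:
        raise RuntimeError("too many training genes discarded to fit the model")

    names = canonical_feature_names()
    train = TrainingSet(
        train_df[names].to_numpy(float),
        (train_df["label"] == "positive").to_numpy(),
        names,
        train_df["gene"].tolist(),
    )
    kept, dropped = dedup_features(train, config.dedup_threshold)
    say(f"dedup: kept {len(kept)} of {len(names)} features "
        f"({len(dropped)} near-duplicates removed at |r| > {config.dedup_threshold})")
    train_red = train.subset(kept)
    ga = replace(config.ga, seed=_child_seed(s_ga))
    mask = consensus_select(train_red, ga)
    say(f"GA consensus ({ga.runs} runs, >= {int(np.ceil(ga.runs * ga.consensus_threshold))} "
        f"required): {int(mask.bits.sum())} features selected")

    prototype = build_prototype(train_red, mask)
    screen_df = features[features["label"] == "screen"]
    metadata = screen_df[["probe", "expression_level", "expression_density"]]
    ranking = rank_genes(screen_df, prototype, metadata, config.expression_threshold,
                         config.report_cuts)
    filtered = set(screen_df["probe"]) - set(ranking["probe"])
    for probe in sorted(filtered):
        discarded[probe] = "expression filter (level and density <= threshold)"
        say(f"{probe}: DISCARD ({discarded[probe]})")
    say(f"ranked {len(ranking)} screen probes")

    result = RunResult(ranking, mask, features, discarded, log, config, prototype)
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def write_artifacts(result: RunResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "config.yaml")
    feat = result.features.copy()
    write_feature_table(outdir / "features.tsv",
                        feat.drop(columns=["label", "enrichment",
                                           "expression_level", "expression_density"]))
    feat[["gene", "label", "enrichment", "expression_level", "expression_density"]].to_csv(
        outdir / "genes.tsv", sep="\t", index=False, float_format="%.10g")
    write_mask(outdir / "mask.tsv", result.mask)
    result.ranking.to_csv(outdir / "ranked.tsv", sep="\t", index=False, float_format="%.10g")
    (outdir / "run.log").write_text("\n".join(result.log) + "\n")
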