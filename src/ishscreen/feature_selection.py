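"""Consensus feature selection separating prototype genes from negatives.

The pipeline reduces the 220-feature texture descriptor in three steps:

1. *Correlation dedup* — features whose absolute Pearson correlation with an
   already-kept feature exceeds 0.99 on the training set are treated as the
   same measurement and dropped (greedy pass in canonical feature order).
2. *Binary GA* — individuals encode feature subsets; fitness is the mean
   silhouette index of the positive vs negative groups computed with
   Euclidean distance on z-scored selected features.  Population 50,
   300 generations, one-point crossover at 0.8, per-bit mutation at 0.06,
   tournament selection of size 4, single-individual elitism.
3. *Consensus* — the GA is repeated 15 times; features selected in at least
   50% of the runs (>= 8 of 15) form the final subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class TrainingSet:
    """Feature matrix plus positive/negative labels of the training genes."""

    matrix: np.ndarray  # (n_genes, n_features)
    positive: np.ndarray  # boolean, (n_genes,)
    feature_names: list[str]
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.positive = np.asarray(self.positive, dtype=bool)
        if self.matrix.shape[0] != len(self.positive):
            raise ValueError("labels do not match the number of training vectors")

    def validate_groups(self) -> None:
        if self.positive.sum() < 2 or (~self.positive).sum() < 2:
            raise ValueError("silhouette needs at least 2 positives and 2 negatives")

    def zscore_params(self) -> tuple[np.ndarray, np.ndarray]:
        mu = self.matrix.mean(axis=0)
        sd = self.matrix.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return mu, sd

    def subset(self, names: list[str]) -> "TrainingSet":
        idx = [self.feature_names.index(n) for n in names]
        return TrainingSet(self.matrix[:, idx], self.positive, list(names), self.gene_ids)


@dataclass(frozen=True)
class GAParams:
    population: int = 50
    generations: int = 300
    crossover_rate: float = 0.8
    mutation_rate: float = 0.06
    tournament_size: int = 4
    runs: int = 15
    consensus_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for rate in (self.crossover_rate, self.mutation_rate, self.consensus_threshold):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.tournament_size > self.population:
            raise ValueError("tournament_size must not exceed the population")


@dataclass
class SelectionMask:
    bits: np.ndarray  # boolean inclusion flags, one per surviving feature
    feature_names: list[str]
    frequency: np.ndarray | None = None  # per-feature count across runs
    flagged: bool = False

    @property
    def selected_names(self) -> list[str]:
        return [n for n, b in zip(self.feature_names, self.bits) if b]


def dedup_features(
    train: TrainingSet, threshold: float = 0.99
) -> tuple[list[str], dict[str, str]]:
    """Drop near-duplicate features (|r| > threshold with a kept feature).

    Returns the surviving feature names (canonical order preserved) and a map
    from each dropped feature to the kept feature that absorbed it.
    Zero-variance features are undefined under Pearson correlation and are
    treated as duplicates of the first zero-variance feature kept.
    """
    if train.matrix.shape[0] < 2:
        raise ValueError("dedup needs at least 2 training vectors")
    X = train.matrix
    sd = X.std(axis=0)
    kept: list[int] = []
    dropped: dict[str, str] = {}
    first_constant: int | None = None
    for j in range(X.shape[1]):
        name = train.feature_names[j]
        if sd[j] == 0:
            if first_constant is None:
                first_constant = j
                kept.append(j)
            else:
                dropped[name] = train.feature_names[first_constant]
            continue
        absorbed = None
        for k in kept:
            if sd[k] == 0:
                continue
            r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            if abs(r) > threshold:
                absorbed = k
                break
        if absorbed is None:
            kept.append(j)
        else:
            dropped[name] = train.feature_names[absorbed]
    return [train.feature_names[j] for j in kept], dropped


def silhouette_fitness(bits: np.ndarray, train: TrainingSet) -> float:
    """Mean two-group silhouette of the training set on the selected features.

    For each element, ``s = (b - a) / max(a, b)`` with ``a`` the mean distance
    to its own group (excluding itself) and ``b`` the mean distance to the
    other group; distances are Euclidean over z-scored selected features.
    An element with ``max(a, b) = 0`` contributes 0; an empty mask scores -1.
    """
    bits = np.asarray(bits, dtype=bool)
    if not bits.any():
        return -1.0
    train.validate_groups()
    mu, sd = train.zscore_params()
    Z = ((train.matrix - mu) / sd)[:, bits]
    diff = Z[:, None, :] - Z[None, :, :]
    D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    pos = train.positive
    n = len(pos)
    s = np.zeros(n)
    for i in range(n):
        own = pos == pos[i]
        own_others = own.copy()
        own_others[i] = False
        a = D[i, own_others].mean()
        b = D[i, ~own].mean()
        m = max(a, b)
        s[i] = (b - a) / m if m > 0 else 0.0
    return float(s.mean())


def _zscored(train: TrainingSet) -> np.ndarray:
    mu, sd = train.zscore_params()
    return (train.matrix - mu) / sd


def _fitness_fast(bits: np.ndarray, Z: np.ndarray, pos: np.ndarray) -> float:
    """Silhouette fitness on pre-z-scored data (GA inner loop)."""
    if not bits.any():
        return -1.0
    X = Z[:, bits]
    sq = np.einsum("ij,ij->i", X, X)
    D2 = np.clip(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0, None)
    D = np.sqrt(D2)
    n = len(pos)
    own = pos[:, None] == pos[None, :]
    np.fill_diagonal(own, False)
    other = pos[:, None] != pos[None, :]
    a = (D * own).sum(axis=1) / own.sum(axis=1)
    b = (D * other).sum(axis=1) / other.sum(axis=1)
    m = np.maximum(a, b)
    s = np.where(m > 0, (b - a) / np.where(m > 0, m, 1.0), 0.0)
    return float(s.mean())


def ga_run(train: TrainingSet, ga: GAParams, run_seed: int) -> SelectionMask:
    """One binary-GA run; returns the best-ever mask (deterministic per seed)."""
    ga.validate()
    train.validate_groups()
    rng = np.random.default_rng(run_seed)
    Z = _zscored(train)
    pos = train.positive
    d = Z.shape[1]
    npop = ga.population

    pop = rng.uniform(size=(npop, d)) < 0.5
    fit = np.array([_fitness_fast(ind, Z, pos) for ind in pop])
    best_idx = int(np.argmax(fit))
    best_bits, best_fit = pop[best_idx].copy(), float(fit[best_idx])

    for _ in range(ga.generations):
        children = np.empty_like(pop)
        # elitism: carry the current best through unchanged
        elite = int(np.argmax(fit))
        children[0] = pop[elite]
        for slot in range(1, npop):
            contenders = rng.integers(0, npop, size=ga.tournament_size)
            p1 = pop[contenders[np.argmax(fit[contenders])]]
            contenders = rng.integers(0, npop, size=ga.tournament_size)
            p2 = pop[contenders[np.argmax(fit[contenders])]]
            if rng.uniform() < ga.crossover_rate and d > 1:
                cut = int(rng.integers(1, d))
                child = np.concatenate([p1[:cut], p2[cut:]])
            else:
                child = p1.copy()
            flip = rng.uniform(size=d) < ga.mutation_rate
            child = child ^ flip
            children[slot] = child
        pop = children
        fit = np.array([_fitness_fast(ind, Z, pos) for ind in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_bits = pop[gen_best].copy()
    return SelectionMask(best_bits, list(train.feature_names))


def consensus_select(train: TrainingSet, ga: GAParams) -> SelectionMask:
    """Features selected in at least ``consensus_threshold`` of the GA runs."""
    ga.validate()
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(ga.seed).spawn(ga.runs)]
    freq = np.zeros(len(train.feature_names), dtype=int)
    for run_seed in seeds:
        mask = ga_run(train, ga, run_seed)
        freq += mask.bits
    need = int(np.ceil(ga.runs * ga.consensus_threshold))
    bits = freq >= need
    flagged = False
    if not bits.any():
        bits = freq == freq.max()
        flagged = True
    return SelectionMask(bits, list(train.feature_names), frequency=freq, flagged=flagged)


# ---------------------------------------------------------------------------
# Mask I/O


def write_mask(path: str | Path, mask: SelectionMask) -> None:
    freq = mask.frequency if mask.frequency is not None else np.full(len(mask.bits), -1)
    pd.DataFrame(
        {"feature": mask.feature_names, "frequency": freq, "selected": mask.bits.astype(int)}
    ).to_csv(path, sep="\t", index=False)


def read_mask(path: str | Path) -> SelectionMask:
    df = pd.read_csv(path, sep="\t")
    return SelectionMask(
        df["selected"].to_numpy(bool), df["feature"].tolist(), df["frequency"].to_numpy()
    )
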