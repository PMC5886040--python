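"""Cross-validation harness for binary-comparison decision models.

Generalization is measured the way the heuristics-versus-regression
literature measures it: sample a training set of comparisons, fit each
model to it, and score its choices on the held-out comparisons.  A correct
choice scores 1, a wrong one 0, and a guess 0.5 (the expectation of a fair
coin, without the Monte-Carlo noise of actually flipping one).

Two experiment designs are provided:

* ``sweep_prior`` traces generalization accuracy along a grid of prior
  strengths for the half-ridge or COR model, averaging over replications
  (fresh environment and split per replication, paired across grid points).
* ``compare_models`` pits any set of models (heuristics, OLS, half-ridge,
  COR) against each other at several training-set sizes with paired
  replication seeds, the design behind training-size crossover effects.

Splitting is at the level of comparisons (pairs), the sampling unit used
when counting "object pairs"; replications are seeded end-to-end, so the
same configuration and seed reproduce results bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cor as cor_mod
from . import half_ridge as hr
from .comparisons import InputError, PairedComparisons, make_pairs
from .envgen import EnvironmentSpec, generate_environment
from .heuristics import cue_validity, take_the_best, tally_directed, tally_undirected

__all__ = [
    "ComparisonResult",
    "Model",
    "SweepCurve",
    "accuracy",
    "compare_models",
    "log_grid",
    "replication_split",
    "split_pairs",
    "sweep_prior",
]

MAX_RESAMPLE = 100


# ---------------------------------------------------------------------------
# Splitting and scoring
# ---------------------------------------------------------------------------

def split_pairs(pc: PairedComparisons, train_size: int, seed: int):
    """Uniform pair-level split without replacement into (train, test)."""
    if not 1 <= train_size < pc.n:
        raise InputError(
            f"train_size must be in [1, {pc.n - 1}] (need a nonempty test set), "
            f"got {train_size}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pc.n)
    return pc.subset(np.sort(perm[:train_size])), pc.subset(np.sort(perm[train_size:]))


def accuracy(choices, y) -> float:
    """Mean score over items: 1 if choice == y, 0.5 for a guess, else 0."""
    choices = np.asarray(choices)
    y = np.asarray(y)
    if choices.shape != y.shape:
        raise InputError("choices and y must have equal length")
    scores = np.where(choices == 0, 0.5, (choices == y).astype(float))
    return float(scores.mean())


def log_grid(lo: float, hi: float, n_points: int = 25) -> np.ndarray:
    """Log-spaced grid of prior strengths (default resolution 25 points)."""
    if not (lo > 0 and hi > lo and n_points >= 2):
        raise InputError("need 0 < lo < hi and at least 2 grid points")
    return np.geomspace(lo, hi, n_points)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass
class Model:
    """A named decision model to be fit on training comparisons.

    kind: one of 'ttb', 'tally_directed', 'tally_undirected', 'ols',
    'half_ridge' (requires eta), 'cor' (requires lmbda and rule).
    """

    kind: str
    eta: float | None = None
    lmbda: float | None = None
    rule: str = "ttb_rule"
    theta: float = 0.0          # ridge penalty of the 'ols' comparator
    label: str | None = None

    KINDS = ("ttb", "tally_directed", "tally_undirected", "ols", "half_ridge", "cor")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise InputError(f"unknown model kind {self.kind!r}")
        if self.kind == "half_ridge" and self.eta is None:
            raise InputError("half_ridge model needs eta")
        if self.kind == "cor" and self.lmbda is None:
            raise InputError("cor model needs lmbda")
        if self.label is None:
            suffix = {
                "half_ridge": f"(eta={self.eta:g})" if self.eta is not None else "",
                "cor": f"({self.rule},lambda={self.lmbda:g})" if self.lmbda is not None else "",
            }.get(self.kind, "")
            self.label = self.kind + suffix


def fit_predictor(model: Model, train: PairedComparisons, directions, seed: int):
    """Fit a model on training pairs; return a choice function x -> {-1,0,+1}."""
    if model.kind == "ttb":
        profile = cue_validity(train)
        return lambda x: take_the_best(x, profile)
    if model.kind == "tally_undirected":
        profile = cue_validity(train)
        return lambda x: tally_undirected(x, profile)
    if model.kind == "tally_directed":
        if directions is None:
            raise InputError("tally_directed needs known cue directions")
        d = np.asarray(directions)
        return lambda x: tally_directed(x, d)
    if model.kind == "ols":
        try:
            w = hr.ridge_weights(train, model.theta)
        except np.linalg.LinAlgError:
            w = hr.ridge_weights(train, 1e-8)
        return lambda x: hr.half_ridge_predict(x, w, rel_tol=0.0)
    if model.kind == "half_ridge":
        if directions is None:
            directions = cue_validity(train).directions
        cfg = hr.HalfRidgeConfig(eta=model.eta, directions=np.asarray(directions), seed=seed)
        post = hr.half_ridge_posterior(train, cfg)
        return lambda x: hr.half_ridge_predict(x, post)
    # cor
    w = cor_mod.cor_weights(train, model.lmbda)
    return lambda x: cor_mod.cor_predict(x, w, model.rule)


def score_on(test: PairedComparisons, predict) -> float:
    return accuracy([predict(x) for x in test.X], test.y)


# ---------------------------------------------------------------------------
# Replication plumbing
# ---------------------------------------------------------------------------

def _child_seeds(master_seed: int, rep: int, n: int) -> list[int]:
    ss = np.random.SeedSequence((int(master_seed), int(rep)))
    return [int(s % (2**31 - 1)) for s in ss.generate_state(n, dtype=np.uint64)]


def replication_split(source, train_size: int, rep: int, seed: int):
    """Deterministic (train, test, sampler_seed, n_resampled) for one replication.

    ``source`` is a fixed :class:`PairedComparisons` or an
    :class:`EnvironmentSpec` (a fresh environment is generated per
    replication).  Degenerate draws whose training set never discriminates
    on any cue are resampled with fresh derived seeds, up to a cap, and the
    number of resamples is reported.
    """
    env_seed, split_seed, sampler_seed = _child_seeds(seed, rep, 3)
    n_resampled = 0
    for attempt in range(MAX_RESAMPLE):
        if isinstance(source, EnvironmentSpec):
            spec = EnvironmentSpec(**{**source.to_dict(), "seed": env_seed + attempt})
            pc = make_pairs(generate_environment(spec))
            if pc.n <= train_size:       # too many criterion ties this draw
                n_resampled += 1
                continue
        else:
            pc = source
        train, test = split_pairs(pc, train_size, split_seed + attempt)
        if np.count_nonzero(train.X) > 0:
            return train, test, sampler_seed, n_resampled
        n_resampled += 1
    raise InputError(
        f"no usable training set after {MAX_RESAMPLE} resamples; "
        "environment appears degenerate"
    )


# ---------------------------------------------------------------------------
# Experiment designs
# ---------------------------------------------------------------------------

@dataclass
class SweepCurve:
    """Generalization accuracy along a grid of prior strengths."""

    strength_grid: np.ndarray
    mean_accuracy: np.ndarray
    sem: np.ndarray
    n_reps: int
    train_size: int
    model: str
    accuracy_matrix: np.ndarray = field(repr=False, default=None)  # (n_reps, n_grid)
    n_resampled: int = 0

    def peak_index(self) -> int:
        return int(np.argmax(self.mean_accuracy))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strength": self.strength_grid,
                "mean_accuracy": self.mean_accuracy,
                "sem": self.sem,
            }
        )

    def save(self, csv_path, json_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(
                    {
                        "model": self.model,
                        "train_size": self.train_size,
                        "n_reps": self.n_reps,
                        "n_resampled": self.n_resampled,
                        "peak_strength": float(self.strength_grid[self.peak_index()]),
                        "peak_accuracy": float(self.mean_accuracy[self.peak_index()]),
                    },
                    fh,
                    indent=2,
                )


SWEEP_MODELS = ("half_ridge", "cor_ttb", "cor_tally")


def _sweep_model_at(model: str, strength: float) -> Model:
    if model == "half_ridge":
        return Model("half_ridge", eta=strength)
    rule = "ttb_rule" if model == "cor_ttb" else "tally_rule"
    return Model("cor", lmbda=strength, rule=rule)


def sweep_prior(source, model: str, grid, train_size: int, n_reps: int,
                seed: int = 0) -> SweepCurve:
    """Mean +/- SEM generalization accuracy over a grid of prior strengths.

    For ``model='half_ridge'`` the grid is eta (weak prior to the right);
    for ``'cor_ttb'``/``'cor_tally'`` it is lambda = 1/eta^2.  Every
    replication draws a fresh split (and fresh environment if ``source`` is
    a spec) and evaluates the whole grid on it, so grid points are paired.
    """
    if model not in SWEEP_MODELS:
        raise InputError(f"model must be one of {SWEEP_MODELS}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 1 or np.any(np.diff(grid) <= 0):
        raise InputError("grid must be strictly increasing")
    if n_reps < 2:
        raise InputError("need at least 2 replications for a SEM")
    acc = np.empty((n_reps, len(grid)))
    n_resampled = 0
    directions = getattr(source, "directions", None)
    for rep in range(n_reps):
        train, test, sampler_seed, nr = replication_split(source, train_size, rep, seed)
        n_resampled += nr
        d = train.directions if train.directions is not None else directions
        for g, strength in enumerate(grid):
            predict = fit_predictor(_sweep_model_at(model, strength), train, d, sampler_seed)
            acc[rep, g] = score_on(test, predict)
    return SweepCurve(
        strength_grid=grid,
        mean_accuracy=acc.mean(axis=0),
        sem=acc.std(axis=0, ddof=1) / np.sqrt(n_reps),
        n_reps=n_reps,
        train_size=train_size,
        model=model,
        accuracy_matrix=acc,
        n_resampled=n_resampled,
    )


@dataclass
class ComparisonResult:
    """Per-model accuracy across training sizes under paired replication seeds."""

    models: list[Model]
    train_sizes: list[int]
    accuracy: dict            # label -> array (n_sizes, n_reps)
    n_reps: int
    seed: int
    n_resampled: int = 0

    def mean(self, label: str) -> np.ndarray:
        return self.accuracy[label].mean(axis=1)

    def sem(self, label: str) -> np.ndarray:
        return self.accuracy[label].std(axis=1, ddof=1) / np.sqrt(self.n_reps)

    def paired_difference(self, label_a: str, label_b: str):
        """Mean and SEM of the per-replication accuracy difference a - b."""
        diff = self.accuracy[label_a] - self.accuracy[label_b]
        return diff.mean(axis=1), diff.std(axis=1, ddof=1) / np.sqrt(self.n_reps)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mdl in self.models:
            for i, ts in enumerate(self.train_sizes):
                rows.append(
                    {
                        "model": mdl.label,
                        "train_size": ts,
                        "mean_accuracy": self.mean(mdl.label)[i],
                        "sem": self.sem(mdl.label)[i],
                    }
                )
        return pd.DataFrame(rows)


def compare_models(source, models: list[Model], train_sizes, n_reps: int,
                   seed: int = 0) -> ComparisonResult:
    """Evaluate several models on identical splits at each training size.

    The same replication seeds (environments, splits, sampler seeds) are
    used for every model — a paired design, so model differences are not
    confounded with sampling noise of the splits.
    """
    if len(models) < 2:
        raise InputError("need at least 2 models to compare")
    train_sizes = [int(t) for t in train_sizes]
    acc = {mdl.label: np.empty((len(train_sizes), n_reps)) for mdl in models}
    n_resampled = 0
    directions = getattr(source, "directions", None)
    for si, ts in enumerate(train_sizes):
        for rep in range(n_reps):
            # seed stream offset by train size so sizes are independent draws
            train, test, sampler_seed, nr = replication_split(
                source, ts, rep, seed + 7919 * si
            )
            n_resampled += nr
            d = train.directions if train.directions is not None else directions
            for mdl in models:
                predict = fit_predictor(mdl, train, d, sampler_seed)
                acc[mdl.label][si, rep] = score_on(test, predict)
    return ComparisonResult(
        models=models,
        train_sizes=train_sizes,
        accuracy=acc,
        n_reps=n_reps,
        seed=seed,
        n_resampled=n_resampled,
    )
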