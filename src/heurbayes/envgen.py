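"""Synthetic binary-comparison environments.

The generator draws a linear environment whose structure matches the
generative assumptions of the half-ridge model: true cue weights are
half-Gaussian magnitudes with known signs (cues differ in predictiveness,
but not arbitrarily so), cue values are correlated binary attributes, and
the criterion is a noisy linear function of the cues.

Mechanism per environment:

* true weights  ``w*_j = direction_j * |N(0, tau^2)|``
* cue values    latent equicorrelated Gaussians (pairwise correlation rho)
  thresholded at zero, giving {0,1} attributes with one-parameter control
  of cue-cue covariance
* criterion     ``c_i = cues_i . w* + N(0, sigma_e^2)``

The realized weights are recorded on the returned table so that
parameter-recovery and peak-location tests can compare against the truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .comparisons import ConfigError, InputError, ObjectTable, PairedComparisons, make_pairs

__all__ = ["EnvironmentSpec", "generate_environment", "generate_pairs"]


@dataclass
class EnvironmentSpec:
    """Parameters of a synthetic binary-comparison environment.

    Attributes
    ----------
    m : number of cues.
    n_objects : number of objects in the table.
    weight_scale : tau, the standard deviation of the half-Gaussian from
        which true weight magnitudes are drawn.
    cue_correlation : rho, pairwise correlation of the latent Gaussians
        behind the binary cues, in [0, 1).
    noise_sd : sigma_e, standard deviation of the Gaussian criterion noise.
    directions : length-m sign vector of the true weights (default all +1).
    seed : integer seed; identical seeds give bit-identical environments.
    """

    m: int
    n_objects: int
    weight_scale: float = 1.0
    cue_correlation: float = 0.0
    noise_sd: float = 0.0
    directions: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if self.n_objects < 2:
            raise ConfigError("n_objects must be >= 2")
        if self.weight_scale < 0:
            raise ConfigError("weight_scale (tau) must be >= 0")
        if not 0 <= self.cue_correlation < 1:
            raise ConfigError("cue_correlation (rho) must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.directions is None:
            self.directions = [1] * self.m
        self.directions = [int(d) for d in self.directions]
        if len(self.directions) != self.m or any(d not in (-1, 1) for d in self.directions):
            raise ConfigError("directions must be a length-m vector of +/-1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentSpec":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "EnvironmentSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


def generate_environment(spec: EnvironmentSpec) -> ObjectTable:
    """Draw one object table from the spec's generative model."""
    rng = np.random.default_rng(spec.seed)
    d = np.asarray(spec.directions, dtype=int)
    w_true = d * np.abs(rng.normal(0.0, 1.0, size=spec.m)) * spec.weight_scale
    # Latent one-factor equicorrelated Gaussians: z_ij = sqrt(rho)*g_i
    # + sqrt(1-rho)*e_ij has corr(z_j, z_k) = rho for j != k.
    rho = spec.cue_correlation
    g = rng.normal(size=(spec.n_objects, 1))
    e = rng.normal(size=(spec.n_objects, spec.m))
    latent = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e
    cues = (latent > 0.0).astype(float)
    criterion = cues @ w_true + rng.normal(0.0, spec.noise_sd, size=spec.n_objects)
    return ObjectTable(
        object_ids=[f"obj{i}" for i in range(spec.n_objects)],
        criterion=criterion,
        cues=cues,
        cue_names=[f"cue{j + 1}" for j in range(spec.m)],
        true_weights=w_true,
        directions=d.copy(),
    )


def generate_pairs(spec: EnvironmentSpec, n_pairs: int | None = None,
                   seed: int | None = None) -> PairedComparisons:
    """Generate an environment, pair it up, and optionally subsample pairs.

    ``seed`` controls only the subsampling; the environment itself is drawn
    from ``spec.seed``.  Subsampling is uniform without replacement.
    """
    pc = make_pairs(generate_environment(spec))
    if n_pairs is None:
        return pc
    if n_pairs > pc.n:
        raise InputError(f"requested {n_pairs} pairs but only {pc.n} are available")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    idx = np.sort(rng.choice(pc.n, size=n_pairs, replace=False))
    return pc.subset(idx)
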