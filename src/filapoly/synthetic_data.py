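"""Synthetic particle tables with known latent polymorph structure.

The clustering method rests on one statistical premise: filaments of the
same polymorph distribute their particles similarly over 2D classes, and
filaments of different polymorphs do not.  The generator emulates exactly
that premise — and nothing about images:

* each latent polymorph has a true class-usage profile, drawn from a
  symmetric Dirichlet (low concentration → sharp, sparse profiles, the way
  a polymorph populates a handful of characteristic class averages);
  profile sets are redrawn until all pairwise cosine distances reach
  ``min_profile_separation``, so "well separated" is an explicit, testable
  property rather than a hope;
* each filament belongs to one polymorph and contributes a variable number
  of overlapping segments (particles);
* each particle draws its class from its polymorph's profile, except with
  probability ``assignment_noise`` it draws uniformly from all classes
  (misassignment by the classifier);
* optional unassignable particles (picking false positives) carry a
  non-positive class id and their own filament keys.

A simulated re-classifier stands in for running a real 2D classification on
one cluster's particles: it redraws classes from the true profiles with the
noise scaled down per round (classifying a more homogeneous subset
separates better).  It is a model of the *effect* of re-classification, not
of the algorithm.

Everything is reproducible from the config seed; per-dataset and per-round
seeds are derived with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .particle_io import FilamentProfile, ParticleRecord, group_filaments

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_polymorph_dataset",
    "simulated_reclassify",
    "make_reclassifier",
    "generate_timecourse",
]

FilamentKey = tuple[str, int]

_TUBES_PER_MICROGRAPH = 5


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    n_polymorphs            latent filament types
    n_classes               2D classes (K)
    profile_concentration   symmetric-Dirichlet α for true profiles; small
                            values give sharp profiles
    min_profile_separation  minimum pairwise cosine distance between true
                            profiles (rejection resampling)
    filaments_per_polymorph int, or one int per polymorph
    particles_min/max       uniform range of segments per filament
    assignment_noise        probability a particle's class is uniform noise
    unassignable_fraction   fraction of picked particles that are false
                            positives (class id −1, own filaments)
    """

    n_polymorphs: int = 3
    n_classes: int = 24
    profile_concentration: float = 0.2
    min_profile_separation: float = 0.5
    filaments_per_polymorph: int | tuple[int, ...] = 60
    particles_min: int = 30
    particles_max: int = 120
    assignment_noise: float = 0.1
    unassignable_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_polymorphs < 1:
            raise ValueError("n_polymorphs must be >= 1")
        if self.n_classes < self.n_polymorphs:
            raise ValueError("need at least one class per polymorph")
        if self.profile_concentration <= 0:
            raise ValueError("profile_concentration must be positive")
        if not 0.0 <= self.assignment_noise < 1.0:
            raise ValueError("assignment_noise must be in [0, 1)")
        if not 0.0 <= self.unassignable_fraction < 1.0:
            raise ValueError("unassignable_fraction must be in [0, 1)")
        if self.particles_min < 1 or self.particles_max < self.particles_min:
            raise ValueError("invalid particles_per_filament range")
        counts = self.filament_counts()
        if any(c < 0 for c in counts):
            raise ValueError("filament counts must be >= 0")

    def filament_counts(self) -> tuple[int, ...]:
        f = self.filaments_per_polymorph
        if isinstance(f, int):
            return (f,) * self.n_polymorphs
        if len(f) != self.n_polymorphs:
            raise ValueError("filaments_per_polymorph list length mismatch")
        return tuple(int(c) for c in f)


@dataclass(frozen=True)
class GroundTruth:
    """Latent labels behind a generated dataset."""

    polymorph_of: Mapping[FilamentKey, int]
    profiles_true: np.ndarray  # (n_polymorphs, n_classes)
    noise: float
    particle_counts: Mapping[FilamentKey, int] = field(default_factory=dict)

    def labels_for(self, keys: Sequence[FilamentKey]) -> list[int]:
        return [self.polymorph_of[k] for k in keys]


def _draw_separated_profiles(
    rng: np.random.Generator, config: GeneratorConfig, max_tries: int = 1000
) -> np.ndarray:
    """Dirichlet profile set conditioned on pairwise cosine separation."""
    alpha = np.full(config.n_classes, config.profile_concentration)
    P = rng.dirichlet(alpha, size=config.n_polymorphs)
    for _ in range(max_tries):
        norms = np.linalg.norm(P, axis=1)
        C = (P @ P.T) / np.outer(norms, norms)
        D = 1.0 - C
        np.fill_diagonal(D, np.inf)
        worst = np.unravel_index(np.argmin(D), D.shape)
        if D[worst] >= config.min_profile_separation:
            return P
        # redraw the higher-indexed offender only, keeping accepted draws
        P[max(worst)] = rng.dirichlet(alpha)
    raise RuntimeError(
        "could not draw sufficiently separated polymorph profiles; "
        "lower min_profile_separation or profile_concentration"
    )


def _noisy_profile(true: np.ndarray, noise: float) -> np.ndarray:
    k = true.size
    return (1.0 - noise) * true + noise / k


def generate_polymorph_dataset(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    micrograph_prefix: str = "sim",
) -> tuple[list[ParticleRecord], GroundTruth]:
    """Generate one particle table plus its ground truth.

    Filaments are laid out over synthetic micrographs
    (``{prefix}_{i:04d}.mrc``, 5 tubes each) so grouping by
    (micrograph, tube) is exercised.  Particle classes are 1-based;
    unassignable particles carry class id −1.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    P = _draw_separated_profiles(rng, config)
    counts = config.filament_counts()

    records: list[ParticleRecord] = []
    polymorph_of: dict[FilamentKey, int] = {}
    particle_counts: dict[FilamentKey, int] = {}
    fil_idx = 0

    def next_key() -> FilamentKey:
        nonlocal fil_idx
        key = (
            f"{micrograph_prefix}_{fil_idx // _TUBES_PER_MICROGRAPH:04d}.mrc",
            fil_idx % _TUBES_PER_MICROGRAPH + 1,
        )
        fil_idx += 1
        return key

    for poly, n_fil in enumerate(counts):
        mix = _noisy_profile(P[poly], config.assignment_noise)
        for _ in range(n_fil):
            key = next_key()
            n = int(rng.integers(config.particles_min, config.particles_max + 1))
            classes = rng.choice(config.n_classes, size=n, p=mix) + 1
            polymorph_of[key] = poly
            particle_counts[key] = n
            for c in classes:
                records.append(
                    ParticleRecord(key[0], key[1], int(c),
                                   source_row=len(records))
                )

    n_real = len(records)
    if config.unassignable_fraction > 0 and n_real > 0:
        n_bad = int(round(
            n_real * config.unassignable_fraction
            / (1.0 - config.unassignable_fraction)
        ))
        while n_bad > 0:
            key = next_key()
            n = min(n_bad, int(rng.integers(config.particles_min,
                                            config.particles_max + 1)))
            for _ in range(n):
                records.append(
                    ParticleRecord(key[0], key[1], -1, source_row=len(records))
                )
            n_bad -= n

    truth = GroundTruth(polymorph_of, P, config.assignment_noise,
                        particle_counts)
    return records, truth


def simulated_reclassify(
    cluster_keys: Sequence[FilamentKey],
    truth: GroundTruth,
    round_index: int,
    seed: int,
    noise_reduction: float = 0.5,
    n_classes: int | None = None,
) -> tuple[dict[FilamentKey, np.ndarray], int]:
    """Stand-in for a 2D re-classification of one cluster's particles.

    Each particle's class is redrawn from its filament's true polymorph
    profile, with the generator's noise scaled by
    ``noise_reduction ** round_index``.  ``noise_reduction`` 1.0 leaves the
    expected profiles unchanged; 0 gives noise-free draws.  Reproducible
    from (seed, round_index).
    """
    if not cluster_keys:
        raise ValueError("cluster is empty")
    K = n_classes if n_classes is not None else truth.profiles_true.shape[1]
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(round_index,))
    )
    noise = truth.noise * noise_reduction**round_index
    out: dict[FilamentKey, np.ndarray] = {}
    for key in cluster_keys:
        poly = truth.polymorph_of[key]
        mix = _noisy_profile(truth.profiles_true[poly], noise)
        n = truth.particle_counts[key]
        out[key] = rng.choice(K, size=n, p=mix) + 1
    return out, K


def make_reclassifier(
    truth: GroundTruth, seed: int, noise_reduction: float = 0.5
):
    """Bind a ground truth into the callback signature the iterator expects."""

    def _reclassify(keys: Sequence[FilamentKey], round_index: int):
        return simulated_reclassify(
            keys, truth, round_index, seed, noise_reduction
        )

    return _reclassify


def generate_timecourse(
    schedule: Mapping[tuple[str, int, float], Sequence[float]],
    config: GeneratorConfig,
    total_filaments: int | None = None,
) -> dict[tuple[str, int, float], tuple[list[ParticleRecord], GroundTruth]]:
    """One dataset per (condition, replicate, time_min) with given mixture.

    Each schedule entry gives polymorph weights, either ``n_polymorphs``
    values, or ``n_polymorphs + 1`` where the extra final weight is the
    unassignable (false-positive / unsolved) particle fraction.  Weights
    must sum to 1 within 1e-9.  Filament counts per polymorph are
    multinomial in the weights over ``total_filaments`` (default: the
    config's total).  Each dataset draws fresh profiles and records its own
    truth; seeds are derived per dataset from the config seed, so datasets
    are distinct but reproducible.
    """
    n_total = (
        total_filaments
        if total_filaments is not None
        else sum(config.filament_counts())
    )
    out: dict[tuple[str, int, float], tuple[list[ParticleRecord], GroundTruth]] = {}
    for i, (key, weights) in enumerate(sorted(schedule.items())):
        w = np.asarray(weights, dtype=float)
        if w.size == config.n_polymorphs:
            unassign = 0.0
        elif w.size == config.n_polymorphs + 1:
            unassign = float(w[-1])
            w = w[:-1]
        else:
            raise ValueError(
                f"dataset {key}: expected {config.n_polymorphs} or "
                f"{config.n_polymorphs + 1} weights, got {w.size}"
            )
        if abs(w.sum() + unassign - 1.0) > 1e-9:
            raise ValueError(f"dataset {key}: weights must sum to 1")
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        )
        w_fil = w / w.sum() if w.sum() > 0 else w
        fil_counts = rng.multinomial(n_total, w_fil) if w.sum() > 0 else \
            np.zeros(config.n_polymorphs, dtype=int)
        ds_config = replace(
            config,
            filaments_per_polymorph=tuple(int(c) for c in fil_counts),
            unassignable_fraction=unassign,
        )
        prefix = f"{key[0]}_r{key[1]}_t{key[2]:g}"
        out[key] = generate_polymorph_dataset(ds_config, rng, prefix)
    return out


def profiles_from_records(
    records: Sequence[ParticleRecord], n_classes: int
) -> list[FilamentProfile]:
    """Convenience: group records and build their class distributions."""
    from .particle_io import class_distribution_matrix

    return class_distribution_matrix(group_filaments(records), n_classes)
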