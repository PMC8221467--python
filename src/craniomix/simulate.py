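"""Synthetic landmark studies with known ground truth.

The generator emulates the statistical structure the analysis chain
assumes: two source populations (Danish-like and British-like) with
distinct symmetric mean shapes, two target populations drawn as mixtures
of the sources, sexual dimorphism, individual bilateral asymmetry and
landmark-wise digitization noise, all wrapped in random similarity
transforms (rotation, translation, scale) that the Procrustes stage must
remove.  Default group sizes follow the four-group study design
(27/20, 13/29, 45/56, 14/32 females/males); noise scales are expressed in
Procrustes units on a centroid-size-1 base shape.

Everything is driven by one integer seed and reproduces bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import (
    Group,
    LandmarkConfiguration,
    Sex,
    ShapeDataset,
    SpecimenMetadata,
)
from .symmetry import SymmetryScheme, antisymmetric_component, symmetric_component

TABLE1_GROUP_SIZES: dict[Group, tuple[int, int]] = {
    Group.EARLY_AS: (27, 20),
    Group.MIDDLE_AS: (13, 29),
    Group.PREMED_BRITISH: (45, 56),
    Group.DANISH: (14, 32),
}

DEFAULT_MIXTURE_FRACTIONS: dict[Group, float] = {
    Group.EARLY_AS: 0.65,  # Danish-derived majority in the earlier period
    Group.MIDDLE_AS: 0.35,  # reversal: British-derived majority later
}


@dataclass
class SimulationParams:
    """Study-scale defaults; noise scales are per-coordinate standard deviations
    in Procrustes units (base shape has centroid size 1)."""

    k: int = 34
    scheme: SymmetryScheme | None = None
    group_sizes: dict = field(default_factory=lambda: dict(TABLE1_GROUP_SIZES))
    source_separation: float = 3.0  # Mahalanobis-scale multiple of within_sd; calibrated so source LOOCV ~ 0.9
    mixture_fractions: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE_FRACTIONS))
    dimorphism_scale: float = 0.04
    within_sd: float = 0.015
    asymmetry_sd: float = 0.005
    digitization_sd: float = 0.002
    blended_admixture: bool = False  # specimen mean = convex mix instead of hard origin
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme is None:
            self.scheme = SymmetryScheme.default(self.k)
        if self.scheme.k != self.k:
            raise ValueError(f"scheme is for k={self.scheme.k}, params say k={self.k}")
        for name in ("within_sd", "asymmetry_sd", "digitization_sd", "dimorphism_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for g, f in self.mixture_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"mixture fraction for {g} outside [0,1]")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruth:
    """Per-specimen origins and per-group realised mixture fractions."""

    origins: dict  # specimen_id -> "DANISH_DERIVED" | "BRITISH_DERIVED"
    group_fractions: dict  # Group -> realised fraction of Danish-derived specimens


def _unit_symmetric_direction(rng, k: int, scheme: SymmetryScheme) -> np.ndarray:
    v = symmetric_component(rng.standard_normal((k, 3)), scheme)
    v -= v.mean(axis=0)  # keep offsets translation-free
    return v / np.linalg.norm(v)


def make_mean_shapes(params: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric British and Danish source mean shapes.

    A deterministic pseudo-anatomical symmetric base (midline landmarks on
    the plane x=0, bilateral pairs mirrored) is scaled to unit centroid
    size; the two means sit at +/- half a symmetric offset whose Procrustes
    magnitude is ``source_separation * within_sd``.
    """
    if params.k < 4:
        raise ValueError("need k >= 4 landmarks")
    rng = np.random.default_rng(params.seed)
    scheme = params.scheme
    base = rng.standard_normal((params.k, 3))
    base = symmetric_component(base, scheme)
    # push landmarks off the symmetry plane a little so pairs are distinct
    for l, r in scheme.paired:
        if abs(base[l, 0]) < 0.3:
            shift = np.sign(base[l, 0]) or 1.0
            base[l, 0] += 0.3 * shift
            base[r, 0] -= 0.3 * shift
    base -= base.mean(axis=0)
    base /= np.sqrt(np.sum(base**2))

    offset = _unit_symmetric_direction(rng, params.k, scheme)
    half = 0.5 * params.source_separation * params.within_sd
    british = base - half * offset
    danish = base + half * offset
    return british, danish


def _random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1.0
    return Q


def simulate_study(params: SimulationParams) -> tuple[ShapeDataset, GroundTruth]:
    """Draw a full four-group, two-sex landmark study with known origins."""
    # distinct streams for the means (consumed inside make_mean_shapes) and
    # for the per-specimen draws, so the two never share bits
    rng = np.random.default_rng([params.seed, 17])
    scheme = params.scheme
    british_mean, danish_mean = make_mean_shapes(params)
    sex_dir = _unit_symmetric_direction(np.random.default_rng([params.seed, 29]), params.k, scheme)

    configs: list[LandmarkConfiguration] = []
    meta: list[SpecimenMetadata] = []
    origins: dict[str, str] = {}
    group_fractions: dict[Group, float] = {}

    for group, (n_f, n_m) in params.group_sizes.items():
        group = Group(group)
        danish_count = 0
        total = 0
        for sex, n_sex in ((Sex.F, n_f), (Sex.M, n_m)):
            for i in range(n_sex):
                sid = f"{group.value}_{sex.value}_{i + 1:03d}"
                if group is Group.DANISH:
                    from_danish, pi = True, 1.0
                elif group is Group.PREMED_BRITISH:
                    from_danish, pi = False, 0.0
                else:
                    pi = float(params.mixture_fractions.get(group, 0.5))
                    from_danish = bool(rng.random() < pi)
                if params.blended_admixture and group in params.mixture_fractions:
                    mean = pi * danish_mean + (1.0 - pi) * british_mean
                else:
                    mean = danish_mean if from_danish else british_mean
                sex_sign = 0.5 if sex is Sex.M else -0.5
                shape = (
                    mean
                    + sex_sign * params.dimorphism_scale * sex_dir
                    + symmetric_component(
                        rng.standard_normal((params.k, 3)) * params.within_sd, scheme
                    )
                    + antisymmetric_component(
                        rng.standard_normal((params.k, 3)) * params.asymmetry_sd, scheme
                    )
                    + rng.standard_normal((params.k, 3)) * params.digitization_sd
                )
                # bury the shape in an arbitrary similarity transform (mm-ish scale)
                scale = 100.0 * np.exp(rng.normal(0.0, 0.05))
                R = _random_rotation(rng)
                t = rng.uniform(-50.0, 50.0, size=3)
                coords = scale * (shape @ R.T) + t
                configs.append(LandmarkConfiguration(sid, coords))
                meta.append(SpecimenMetadata(sid, group, sex))
                origins[sid] = "DANISH_DERIVED" if from_danish else "BRITISH_DERIVED"
                danish_count += int(from_danish)
                total += 1
        group_fractions[group] = danish_count / total if total else float("nan")

    dataset = ShapeDataset(configs, meta, scheme)
    return dataset, GroundTruth(origins=origins, group_fractions=group_fractions)


def simulate_repeats(
    base_config: LandmarkConfiguration,
    n_repeats: int = 10,
    digitization_sd: float = 0.002,
    seed: int = 0,
) -> ShapeDataset:
    """Repeated digitizations of one cranium with landmark-wise noise.

    ``digitization_sd`` is expressed per unit centroid size (the study
    generator's Procrustes-scale convention), so the noise level is
    independent of the configuration's absolute size in mm.
    """
    if n_repeats < 2:
        raise ValueError("need n_repeats >= 2")
    rng = np.random.default_rng(seed)
    from .procrustes import centroid_size

    sd = digitization_sd * centroid_size(base_config)
    configs = [
        LandmarkConfiguration(
            f"{base_config.specimen_id}_rep{i + 1:02d}",
            base_config.coords + rng.standard_normal(base_config.coords.shape) * sd,
            list(base_config.landmark_labels),
        )
        for i in range(n_repeats)
    ]
    return ShapeDataset(configs, [])
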