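"""Object-symmetry handling: reflect, relabel, and extract symmetric shape.

A bilaterally symmetric structure digitised as one landmark configuration
("object symmetry") has paired left/right landmarks and unpaired midline
landmarks.  Its symmetric component is obtained by superimposing each
configuration jointly with its mirror image (reflection across a fixed
plane followed by left/right relabelling) and averaging the two aligned
copies; the asymmetric component cancels in the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .io import LandmarkConfiguration, ShapeDataset
from .procrustes import gpa


@dataclass
class SymmetryScheme:
    """Bilateral pairing and midline partition of landmark indices (0-based)."""

    paired: list[tuple[int, int]]
    midline: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.paired = [(int(l), int(r)) for l, r in self.paired]
        self.midline = [int(i) for i in self.midline]
        seen: list[int] = list(self.midline)
        for l, r in self.paired:
            if l == r:
                raise ValueError(f"pair ({l},{r}) maps a landmark to itself")
            seen += [l, r]
        k = self.k
        if sorted(seen) != list(range(k)):
            raise ValueError(
                "paired + midline indices must partition 0..k-1 with no repeats"
            )

    @property
    def k(self) -> int:
        return len(self.midline) + 2 * len(self.paired)

    def permutation(self) -> np.ndarray:
        """Row permutation that swaps left and right labels."""
        perm = np.arange(self.k)
        for l, r in self.paired:
            perm[l], perm[r] = r, l
        return perm

    @classmethod
    def default(cls, k: int = 34) -> "SymmetryScheme":
        """Default scheme: 6 midline landmarks then left/right pairs interleaved.

        For k = 34 this is 6 midline + 14 bilateral pairs, matching a
        basicranial landmark set in which the anatomical pairing is supplied
        by configuration rather than hard-coded.
        """
        n_mid = 6 if k >= 8 and (k - 6) % 2 == 0 else k % 2
        if (k - n_mid) % 2 != 0:
            raise ValueError(f"cannot build a default scheme for k={k}")
        midline = list(range(n_mid))
        paired = [(n_mid + 2 * i, n_mid + 2 * i + 1) for i in range((k - n_mid) // 2)]
        return cls(paired=paired, midline=midline)

    def to_dict(self) -> dict:
        return {"midline": list(self.midline), "pairs": [list(p) for p in self.paired]}

    @classmethod
    def from_dict(cls, d: dict) -> "SymmetryScheme":
        return cls(paired=[tuple(p) for p in d["pairs"]], midline=list(d.get("midline", [])))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "SymmetryScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def reflect_coords(coords: np.ndarray, scheme: SymmetryScheme) -> np.ndarray:
    """Mirror across the plane x=0 and swap left/right rows (a linear involution)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-2] != scheme.k:
        raise ValueError(f"scheme is for k={scheme.k}, configuration has k={coords.shape[-2]}")
    mirrored = coords.copy()
    mirrored[..., 0] *= -1.0
    return mirrored[..., scheme.permutation(), :]


def reflect_relabel(
    config: LandmarkConfiguration, scheme: SymmetryScheme
) -> LandmarkConfiguration:
    """Reflected, relabelled copy of one configuration."""
    return LandmarkConfiguration(
        config.specimen_id,
        reflect_coords(config.coords, scheme),
        list(config.landmark_labels),
    )


def symmetric_component(coords: np.ndarray, scheme: SymmetryScheme) -> np.ndarray:
    """Orthogonal projection onto the reflection-invariant subspace."""
    return 0.5 * (np.asarray(coords, dtype=float) + reflect_coords(coords, scheme))


def antisymmetric_component(coords: np.ndarray, scheme: SymmetryScheme) -> np.ndarray:
    """Orthogonal projection onto the reflection-antiinvariant subspace."""
    return 0.5 * (np.asarray(coords, dtype=float) - reflect_coords(coords, scheme))


def symmetrize(
    dataset: ShapeDataset, scheme: SymmetryScheme | None = None
) -> ShapeDataset:
    """Symmetric shape component of every specimen.

    The n original configurations and their n reflected-relabelled copies
    are superimposed in one joint GPA (2n configurations); each specimen's
    symmetric component is the landmark-wise average of its two aligned
    copies.  The returned dataset holds aligned Procrustes coordinates.
    """
    scheme = scheme or dataset.scheme
    if scheme is None:
        raise ValueError("no SymmetryScheme supplied and dataset carries none")
    orig = dataset.coords_array()
    reflected = reflect_coords(orig, scheme)
    result = gpa(np.concatenate([orig, reflected], axis=0))
    n = len(dataset)
    sym = 0.5 * (result.aligned[:n] + result.aligned[n:])
    sym = sym @ _canonical_symmetry_rotation(sym.mean(axis=0), scheme)
    out = dataset.with_coords(sym)
    out.scheme = scheme
    return out


def _canonical_symmetry_rotation(consensus: np.ndarray, scheme: SymmetryScheme) -> np.ndarray:
    """Rotation taking a symmetric-up-to-rotation consensus into the frame
    whose mirror plane is x = 0.

    The consensus satisfies reflect(C) = C Q for a rotation Q; G = Q M
    (M negating the first axis) is then an orthogonal involution whose
    -1 eigenvector is the mirror normal.  Rotating by the eigenbasis of G
    makes the reflection operator act exactly as M plus the relabelling,
    so the symmetric subspace of the scheme contains the data.
    """
    from .procrustes import optimal_rotation

    M = np.diag([-1.0, 1.0, 1.0])
    Q = optimal_rotation(consensus, reflect_coords(consensus, scheme))
    G = Q @ M
    G = 0.5 * (G + G.T)  # exact involutions are symmetric; clean round-off
    _, evecs = np.linalg.eigh(G)  # ascending eigenvalues: mirror normal first
    U = evecs.copy()
    if np.linalg.det(U) < 0:
        U[:, 1] *= -1.0
    return U
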