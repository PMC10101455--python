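"""Rigid and affine world-space transforms and transform chains.

All transforms map world coordinates (mm, RAS) to world coordinates. A
:class:`RigidTransform` is parameterized by three Euler angles in degrees
(extrinsic x-y-z order) and a translation in mm, optionally rotating about a
center point instead of the world origin — rotating about the image center
keeps rotation and translation parameters decoupled, which matters for
optimization and for comparing recovered motion against ground truth.

Chains compose into a single 4x4 matrix so that resampling through a chain
costs one interpolation pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import TransformError

__all__ = ["RigidTransform", "AffineTransform", "TransformChain"]


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid-body map: rotate by Euler angles about ``center``, then translate.

    Parameters
    ----------
    rotation : (3,) float
        Euler angles in degrees, applied in extrinsic x, y, z order.
    translation : (3,) float
        Offsets in mm.
    center : (3,) float
        World point (mm) the rotation pivots about.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def as_matrix(self) -> np.ndarray:
        """Return the homogeneous 4x4 world→world matrix."""
        rot = Rotation.from_euler("xyz", self.rotation, degrees=True).as_matrix()
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        mat = np.eye(4)
        mat[:3, :3] = rot
        # x' = R (x - c) + c + t
        mat[:3, 3] = c - rot @ c + t
        return mat

    def inverse(self) -> "RigidTransform":
        rot = Rotation.from_euler("xyz", self.rotation, degrees=True)
        inv = rot.inv()
        angles = inv.as_euler("xyz", degrees=True)
        # solve x = R^-1 (x' - c - t) + c  ==  R^-1 (x' - c') + c' + t'
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        t_inv = inv.as_matrix() @ (-t)
        return RigidTransform(tuple(angles), tuple(t_inv), tuple(c))

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation, 0, atol=1e-12) and np.allclose(
            self.translation, 0, atol=1e-12
        )


@dataclass(frozen=True)
class AffineTransform:
    """General invertible affine world→world map as a homogeneous 4x4 matrix."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape != (4, 4):
            raise TransformError(f"affine matrix must be 4x4, got {mat.shape}")
        if not np.allclose(mat[3], [0, 0, 0, 1], atol=1e-9):
            raise TransformError("last row of an affine matrix must be (0, 0, 0, 1)")
        if not np.isfinite(np.linalg.cond(mat[:3, :3])):
            raise TransformError("affine matrix is singular")
        object.__setattr__(self, "matrix", mat)

    def as_matrix(self) -> np.ndarray:
        return self.matrix.copy()

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))


def _as_matrix(transform) -> np.ndarray:
    if isinstance(transform, (RigidTransform, AffineTransform)):
        return transform.as_matrix()
    mat = np.asarray(transform, dtype=float)
    if mat.shape == (4, 4):
        return AffineTransform(mat).as_matrix()
    raise TransformError(f"cannot interpret {type(transform).__name__} as a transform")


@dataclass
class TransformChain:
    """Ordered list of transforms with space labels, composed into one map.

    ``links[i]`` maps ``spaces[i]`` coordinates into ``spaces[i+1]``
    coordinates; adjacent labels must match for the chain to connect.
    """

    links: list = field(default_factory=list)
    spaces: list[str] = field(default_factory=lambda: ["native"])

    def __post_init__(self) -> None:
        if len(self.spaces) != len(self.links) + 1:
            raise TransformError(
                "a chain of k links needs k+1 space labels "
                f"(got {len(self.links)} links, {len(self.spaces)} labels)"
            )

    @classmethod
    def identity(cls, space: str = "native") -> "TransformChain":
        return cls(links=[], spaces=[space])

    @property
    def source_space(self) -> str:
        return self.spaces[0]

    @property
    def target_space(self) -> str:
        return self.spaces[-1]

    def append(self, transform, target_space: str) -> "TransformChain":
        return TransformChain(self.links + [transform], self.spaces + [target_space])

    def composed_matrix(self) -> np.ndarray:
        """Compose every link into a single world→world 4x4 matrix."""
        mat = np.eye(4)
        for link in self.links:
            mat = _as_matrix(link) @ mat
        return mat

    def require_connects(self, source: str, target: str) -> None:
        if self.source_space != source or self.target_space != target:
            raise TransformError(
                f"chain maps {self.source_space!r}→{self.target_space!r}, "
                f"need {source!r}→{target!r}"
            )

    def to_json_dict(self) -> dict:
        out = {"spaces": list(self.spaces), "links": []}
        for link in self.links:
            if isinstance(link, RigidTransform):
                out["links"].append(
                    {
                        "kind": "rigid",
                        "rotation_deg": list(link.rotation),
                        "translation_mm": list(link.translation),
                        "center_mm": list(link.center),
                    }
                )
            else:
                out["links"].append(
                    {"kind": "affine", "matrix": _as_matrix(link).tolist()}
                )
        return out

    @classmethod
    def from_json_dict(cls, payload: dict) -> "TransformChain":
        links = []
        for entry in payload.get("links", []):
            if entry["kind"] == "rigid":
                links.append(
                    RigidTransform(
                        tuple(entry["rotation_deg"]),
                        tuple(entry["translation_mm"]),
                        tuple(entry.get("center_mm", (0, 0, 0))),
                    )
                )
            elif entry["kind"] == "affine":
                links.append(AffineTransform(np.asarray(entry["matrix"], dtype=float)))
            else:
                raise TransformError(f"unknown transform kind {entry['kind']!r}")
        return cls(links=links, spaces=list(payload["spaces"]))
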