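"""Discrete audio-visual stimulus grids and latent ground-truth surfaces.

The experiment parameter space is a 2-D grid of stimulus conditions:
one axis varies visual complexity, the other auditory complexity, each
in 10 discrete levels.  Study 1 uses the plain 10x10 grid (position =
level).  Study 2 expands it to 19x19 by mirroring both axes, so that
the hypothesized optimal combination (most complex visual stimulus, no
auditory input) sits at the grid center.

Coordinates are 1-based ``[visual_position, auditory_position]`` pairs
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "GroundTruthSurface",
    "build_space",
    "hypothesized_optimum",
    "build_ground_truth",
]


@dataclass(frozen=True)
class GridSpec:
    """A discrete 2-D stimulus space.

    Attributes
    ----------
    n_visual, n_auditory:
        Number of grid positions along the visual / auditory axis.
    mirrored:
        True for the Study-2 style grid whose axes fold back on
        themselves (levels rise toward the center on the visual axis
        and fall toward the center on the auditory axis).
    """

    n_visual: int
    n_auditory: int
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.n_visual < 1 or self.n_auditory < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_visual, self.n_auditory)

    @property
    def n_positions(self) -> int:
        return self.n_visual * self.n_auditory

    def positions(self) -> np.ndarray:
        """All grid coordinates as an (n_positions, 2) int array, 1-based."""
        vv, aa = np.meshgrid(
            np.arange(1, self.n_visual + 1),
            np.arange(1, self.n_auditory + 1),
            indexing="ij",
        )
        return np.column_stack([vv.ravel(), aa.ravel()])

    def contains(self, coord) -> bool:
        v, a = int(coord[0]), int(coord[1])
        return 1 <= v <= self.n_visual and 1 <= a <= self.n_auditory

    def level_of_position(self, coord) -> tuple[int, int]:
        """Map a grid position to its (visual_level, auditory_level) pair.

        Levels run 1-10.  On a mirrored grid the visual level peaks at
        the center column while the auditory level is lowest at the
        center row, so the center position carries the most complex
        visual stimulus with no auditory input.
        """
        v, a = int(coord[0]), int(coord[1])
        if not self.contains((v, a)):
            raise ValueError(f"position {(v, a)} outside {self.shape} grid")
        if not self.mirrored:
            return (v, a)
        c = (self.n_visual + 1) // 2  # center index (10 on the 19-grid)
        return (c - abs(v - c), 1 + abs(a - c))

    def clip(self, coord) -> tuple[int, int]:
        """Project an integer coordinate componentwise onto the grid."""
        v = min(max(int(round(coord[0])), 1), self.n_visual)
        a = min(max(int(round(coord[1])), 1), self.n_auditory)
        return (v, a)


def build_space(study: int) -> GridSpec:
    """Return the stimulus space of the given study.

    Study 1 is the 10x10 grid with identity position->level mapping;
    Study 2 is the mirrored 19x19 grid (361 combinations).
    """
    if study == 1:
        return GridSpec(10, 10, mirrored=False)
    if study == 2:
        return GridSpec(19, 19, mirrored=True)
    raise ValueError(f"unknown study index {study!r}; expected 1 or 2")


def hypothesized_optimum(spec: GridSpec, target_state: int) -> tuple[int, int]:
    """Coordinate of the a-priori optimal stimulus combination.

    Target state 1 maximizes occipital over temporal activity and is
    evoked by (visual level 10, auditory level 1); state 2 is the
    reverse, (visual 1, auditory 10).  State 2 is only defined on the
    non-mirrored Study-1 grid, where every level pair is unique.
    """
    if target_state not in (1, 2):
        raise ValueError(f"target_state must be 1 or 2, got {target_state!r}")
    if target_state == 2 and spec.mirrored:
        raise ValueError("target state 2 is not defined on the mirrored grid")
    want = (10, 1) if target_state == 1 else (1, 10)
    for pos in spec.positions():
        if spec.level_of_position(pos) == want:
            return (int(pos[0]), int(pos[1]))
    raise ValueError(f"no grid position carries levels {want}")


@dataclass(frozen=True)
class GroundTruthSurface:
    """Latent objective surface over a grid, used to simulate responses.

    ``values`` holds one latent response amplitude per grid position
    (same ordering as ``GridSpec.positions()``); ``optimum`` is its
    argmax coordinate and ``mean_abs_amplitude`` the mean of |values|,
    the signal term of the contrast-to-noise ratio.
    """

    spec: GridSpec
    values: np.ndarray
    optimum: tuple[int, int] = field(init=False)
    mean_abs_amplitude: float = field(init=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.spec.n_positions,):
            raise ValueError("values must have one entry per grid position")
        object.__setattr__(self, "values", values)
        best = self.spec.positions()[int(np.argmax(values))]
        object.__setattr__(self, "optimum", (int(best[0]), int(best[1])))
        object.__setattr__(self, "mean_abs_amplitude", float(np.mean(np.abs(values))))

    def value_at(self, coord) -> float:
        v, a = int(coord[0]), int(coord[1])
        if not self.spec.contains((v, a)):
            raise ValueError(f"coordinate {(v, a)} outside grid")
        return float(self.values[(v - 1) * self.spec.n_auditory + (a - 1)])

    def as_matrix(self) -> np.ndarray:
        return self.values.reshape(self.spec.shape)


def build_ground_truth(
    spec: GridSpec,
    mean_abs_amplitude: float = 0.606,
    center_width: float = 4.0,
    corner_width: float = 4.0,
    corner_depth: float = 1.0,
) -> GroundTruthSurface:
    """Smooth center-peak / corner-minima surface for simulation.

    The surface is a positive squared-exponential bump at the grid
    center minus one negative bump at each of the four corners, then
    rescaled so the mean absolute amplitude equals
    ``mean_abs_amplitude`` exactly.  Away from the center the value may
    be negative: the simulated contrast can carry either sign.

    The default amplitude 0.606 places the Gaussian-noise standard
    deviation at 6.06 for CNR 0.1 and 0.337 for CNR 1.8 (noise SD =
    mean_abs_amplitude / CNR).
    """
    if not spec.mirrored:
        raise ValueError("ground-truth surface is defined on the mirrored grid")
    if mean_abs_amplitude <= 0:
        raise ValueError("mean_abs_amplitude must be positive")
    pos = spec.positions().astype(float)
    center = np.array([(spec.n_visual + 1) / 2.0, (spec.n_auditory + 1) / 2.0])
    corners = np.array(
        [
            [1.0, 1.0],
            [1.0, spec.n_auditory],
            [spec.n_visual, 1.0],
            [spec.n_visual, spec.n_auditory],
        ]
    )

    def bump(centers: np.ndarray, width: float) -> np.ndarray:
        d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * width**2)).sum(axis=1)

    raw = bump(center[None, :], center_width) - corner_depth * bump(corners, corner_width)
    scale = mean_abs_amplitude / np.mean(np.abs(raw))
    return GroundTruthSurface(spec=spec, values=raw * scale)
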