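"""Random Jacobian ensembles for reaction-diffusion stability analysis.

The central object is the May-style random Jacobian

    J0 = G - I,

where ``G`` has zero-mean Gaussian off-diagonal entries with variance
``sigma2`` (zero diagonal) and the identity represents uniform first-order
degradation of every species.  Eigenvalues of ``G`` follow the circular law:
for large ``N`` they fill a disk of radius ``gamma = sigma * sqrt(N * C)``,
where the connectivity ``C`` is the probability that an off-diagonal
interaction is present at all.  Subtracting the identity shifts the disk so
it is centred at -1, which is what makes "stable without diffusion, unstable
with diffusion" a question about the disk's right edge.

Diffusion enters through a diagonal matrix with exactly two mobile species,
``D = diag(D1, D2, 0, ..., 0)`` — all remaining nodes are immobile.
"""

from __future__ import annotations

import dataclasses
import enum
import zlib
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DiagonalMode",
    "EnsembleSpec",
    "DiffusionSpec",
    "sample_jacobian",
    "sample_jacobians",
    "predicted_radius",
    "sigma2_for_radius",
    "substream",
]


class DiagonalMode(str, enum.Enum):
    """How the diagonal of the random Jacobian is constructed."""

    #: all diagonal entries fixed at -1 (uniform degradation; the default model)
    FIXED_MINUS_ONE = "fixed_minus_one"
    #: diagonal entries drawn from the same Gaussian as the off-diagonals
    GAUSSIAN = "gaussian"
    #: Gaussian diagonal entries shifted by -1 (self-interaction + degradation)
    GAUSSIAN_PLUS_FIXED = "gaussian_plus_fixed"
    #: antisymmetric off-diagonal part (g_ij = -g_ji), diagonal fixed at -1
    ANTISYMMETRIC_FIXED = "antisymmetric_fixed"


def _coerce_mode(mode: "DiagonalMode | str") -> DiagonalMode:
    try:
        return DiagonalMode(mode)
    except ValueError as exc:
        valid = ", ".join(m.value for m in DiagonalMode)
        raise ValueError(
            f"unknown diagonal_mode {mode!r}; expected one of: {valid}"
        ) from exc


@dataclasses.dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of a random-Jacobian ensemble.

    Parameters
    ----------
    n_nodes
        Network size ``N`` (number of molecular species), at least 2.
    sigma2
        Variance of the Gaussian interaction strengths ``g_ij``.
    connectivity
        Probability ``C`` in (0, 1] that an off-diagonal element is nonzero.
        Sparsity is ``1 - C``; each element is masked independently
        (Bernoulli) unless ``fix_mask`` is set.
    diagonal_mode
        See :class:`DiagonalMode`.
    seed
        Root seed used when no generator is passed to the samplers.
    fix_mask
        If true, one connectivity mask is drawn per ensemble and shared by
        every matrix instead of being resampled per matrix.
    """

    n_nodes: int
    sigma2: float
    connectivity: float = 1.0
    diagonal_mode: DiagonalMode = DiagonalMode.FIXED_MINUS_ONE
    seed: int = 0
    fix_mask: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "diagonal_mode", _coerce_mode(self.diagonal_mode))
        if int(self.n_nodes) != self.n_nodes or self.n_nodes < 2:
            raise ValueError(f"n_nodes must be an integer >= 2, got {self.n_nodes}")
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        if not 0.0 < self.connectivity <= 1.0:
            raise ValueError(
                f"connectivity must lie in (0, 1], got {self.connectivity}"
            )

    # -- flat-config round trip -------------------------------------------
    def to_config(self) -> dict:
        return {
            "n_nodes": int(self.n_nodes),
            "sigma2": float(self.sigma2),
            "connectivity": float(self.connectivity),
            "diagonal_mode": self.diagonal_mode.value,
            "seed": int(self.seed),
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "EnsembleSpec":
        known = {"n_nodes", "sigma2", "connectivity", "diagonal_mode", "seed",
                 "fix_mask"}
        kwargs = {k: cfg[k] for k in known if k in cfg}
        return cls(**kwargs)


@dataclasses.dataclass(frozen=True)
class DiffusionSpec:
    """Diffusion constants of the two mobile species.

    By convention the diffusers are always nodes 1 and 2 (array indices
    0 and 1); every other node is immobile (``D_i = 0``).
    """

    d1: float = 1.0
    d2: float = 10.0

    def __post_init__(self) -> None:
        if not (self.d1 > 0 and self.d2 > 0):
            raise ValueError(
                f"diffusion constants must be positive, got ({self.d1}, {self.d2})"
            )

    @property
    def diffuser_indices(self) -> tuple[int, int]:
        return (0, 1)

    def diagonal(self, n_nodes: int) -> np.ndarray:
        """Full diffusion diagonal ``(D1, D2, 0, ..., 0)`` of length n_nodes."""
        if n_nodes < 2:
            raise ValueError("need at least the two diffusing nodes")
        d = np.zeros(n_nodes)
        d[0], d[1] = self.d1, self.d2
        return d

    def swapped(self) -> "DiffusionSpec":
        return DiffusionSpec(self.d2, self.d1)

    def to_config(self) -> dict:
        return {"D1": float(self.d1), "D2": float(self.d2)}

    @classmethod
    def from_config(cls, cfg: Mapping) -> "DiffusionSpec":
        return cls(float(cfg.get("D1", 1.0)), float(cfg.get("D2", 10.0)))


def substream(seed: int, *key: "int | str") -> np.random.Generator:
    """Named reproducible RNG substream.

    One root seed spawns independent streams keyed by experiment name and
    grid-cell indices, so any single cell's sample set can be regenerated in
    isolation and results do not depend on execution order.
    """
    ints = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) & 0xFFFFFFFF
        for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=ints))


def sample_jacobians(
    spec: EnsembleSpec,
    n_matrices: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a stack of random Jacobians ``J0`` of shape (n_matrices, N, N).

    Off-diagonal entries are independent zero-mean Gaussians with variance
    ``spec.sigma2``, each zeroed independently with probability
    ``1 - spec.connectivity``; the diagonal follows ``spec.diagonal_mode``.
    Deterministic given the generator state (or ``spec.seed`` if none given).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    sigma = float(np.sqrt(spec.sigma2))
    mode = spec.diagonal_mode

    g = rng.normal(0.0, sigma, size=(n_matrices, n, n))
    eye = np.eye(n, dtype=bool)

    if mode is DiagonalMode.ANTISYMMETRIC_FIXED:
        upper = np.triu(g, k=1)
        g = upper - np.swapaxes(upper, -1, -2)
    else:
        g[:, eye] = 0.0

    if spec.connectivity < 1.0:
        if spec.fix_mask:
            mask = rng.random((1, n, n)) < spec.connectivity
            mask = np.broadcast_to(mask, g.shape).copy()
        else:
            mask = rng.random(g.shape) < spec.connectivity
        if mode is DiagonalMode.ANTISYMMETRIC_FIXED:
            # mask symmetric pairs together so antisymmetry is preserved
            um = np.triu(mask, k=1)
            mask = um | np.swapaxes(um, -1, -2)
        mask[:, eye] = True
        g = np.where(mask, g, 0.0)

    if mode in (DiagonalMode.FIXED_MINUS_ONE, DiagonalMode.ANTISYMMETRIC_FIXED):
        g[:, eye] = -1.0
    elif mode is DiagonalMode.GAUSSIAN:
        g[:, eye] = rng.normal(0.0, sigma, size=(n_matrices, n))
    elif mode is DiagonalMode.GAUSSIAN_PLUS_FIXED:
        g[:, eye] = rng.normal(0.0, sigma, size=(n_matrices, n)) - 1.0
    return g


def sample_jacobian(
    spec: EnsembleSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw a single random Jacobian ``J0`` (shape (N, N))."""
    return sample_jacobians(spec, 1, rng)[0]


def predicted_radius(spec: EnsembleSpec) -> float:
    """Circular-law radius ``gamma = sigma * sqrt(N * C)`` of the ensemble."""
    return float(np.sqrt(spec.sigma2 * spec.n_nodes * spec.connectivity))


def sigma2_for_radius(n_nodes: int, connectivity: float, gamma: float) -> float:
    """Invert the circular law: the variance giving radius ``gamma``.

    Round-trips with :func:`predicted_radius` to machine precision.
    """
    if not gamma > 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    nc = n_nodes * connectivity
    if nc <= 0:
        raise ValueError("n_nodes * connectivity must be positive")
    return float(gamma**2 / nc)
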