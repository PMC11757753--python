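"""Closed-form results used as independent cross-checks on the pipeline.

These are exact (or asymptotic) statements about the random-Jacobian model
that the numerical machinery must reproduce: the eigenvalue-sum (trace)
identity that pins the diffusion-driven outliers, the two-node determinant
argument ruling out Turing instabilities for N = 2 with uniform -1
diagonals, the finite-N expansion of the projected eigenvalue density at
the imaginary axis, and the super-exponential count of signed network
topologies.
"""

from __future__ import annotations

import numpy as np

from .ensembles import DiffusionSpec

__all__ = [
    "outlier_trace_bound",
    "two_node_determinant",
    "edge_density_rho0",
    "topology_count",
]


def outlier_trace_bound(n_nodes: int, diff: DiffusionSpec, k: float) -> float:
    """Eigenvalue sum of J(k) for the fixed -1 diagonal model.

    Tr J(k) = Tr J0 - k^2 Tr D = -N - k^2 (D1 + D2); the trace is invariant
    under diagonalization, so the sum of all eigenvalues must equal this at
    every wavenumber.  The outlier eigenvalues track it towards -infinity as
    k grows.
    """
    return float(-n_nodes - k**2 * (diff.d1 + diff.d2))


def two_node_determinant(g12: float, g21: float, diff: DiffusionSpec, k: float) -> float:
    """Determinant of the two-node Jacobian with -1 diagonals at wavenumber k.

    Det_k = (1 + D1 k^2)(1 + D2 k^2) - g12 g21
          = Det_0 + (D1 + D2) k^2 + D1 D2 k^4.

    Whenever the system is stable without diffusion (Det_0 = 1 - g12 g21 > 0)
    the determinant stays positive for every k > 0, so no saddle can appear
    and no Turing instability exists for N = 2 in this model.
    """
    k2 = k**2
    return float((1.0 + diff.d1 * k2) * (1.0 + diff.d2 * k2) - g12 * g21)


def edge_density_rho0(gamma: float, n_nodes: float) -> float:
    """Projected eigenvalue density at the imaginary axis, finite-N expansion.

    For gamma >= 1,

        rho(0) ~ (1/pi) sqrt(gamma^2 - 1) * (1 - 1/(2 gamma^2 N)),

    up to O(1/N^2).  For gamma < 1 the eigenvalue disk does not reach the
    axis and the density is zero.  The finite-N correction suppresses the
    density of marginally stable matrices in small networks — the mechanism
    behind the interior optimum of the Turing-I frequency in N.
    """
    if gamma < 1.0:
        return 0.0
    lead = np.sqrt(gamma**2 - 1.0) / np.pi
    return float(lead * (1.0 - 1.0 / (2.0 * gamma**2 * n_nodes)))


def topology_count(n_nodes: int) -> int:
    """Number of signed network topologies on N nodes: 3^N * 9^(N choose 2).

    Each of the N self-edges takes one of {+, -, absent}; each of the
    N(N-1)/2 unordered pairs carries two directed edges with 3 states each.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    n = int(n_nodes)
    return 3**n * 9 ** (n * (n - 1) // 2)
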