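"""Monte-Carlo surveys of Turing-instability frequency over parameter grids.

Each survey samples an ensemble of random Jacobians per grid cell, runs the
dispersion-relation classifier on every matrix, and records per-cell counts
of the five outcome classes.  The three experiment families are

* stability survey over (N, gamma) — how often systems are stable without
  diffusion, and how often previously-stable systems turn unstable with it;
* size-variance heat map over (N, sigma^2) — locating the network size
  that collects the largest share of Turing-I systems over an absolute
  variance axis (the optimal-size statistic);
* diffusion grid over (D1, D2) at fixed (N, sigma^2) — probing how many
  immobile nodes relax the differential-diffusivity requirement.

Default protocol: fixed -1 diagonals, full connectivity, D = (1, 10),
wavenumbers 0..10 in steps of 0.01, 10^3 matrices per cell.  Every cell
draws from its own named RNG substream, so results are independent of
execution order and any single cell can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dispersion import (
    CLASS_NAMES,
    KGrid,
    TURING_CLASSES,
    classify_batch,
    classify_batch_adaptive,
)
from .ensembles import DiagonalMode, DiffusionSpec, EnsembleSpec, sample_jacobians, substream

__all__ = [
    "SurveyGrid",
    "OptimalSizeResult",
    "run_cell",
    "run_stability_survey",
    "run_size_variance_heatmap",
    "run_diffusion_grid",
    "extract_optimal_size",
    "save_survey",
]

logger = logging.getLogger("turingrmt")

DEFAULT_GAMMA_SURVEY = np.arange(0.25, 1.51, 0.25)
#: absolute variance axis of the size-variance heat map: a linear grid wide
#: enough that the circular-law band gamma ~ 1 (sigma^2 ~ 1/N) is covered
#: for every network size from 2 up to ~50
DEFAULT_SIGMA2_GRID = np.linspace(0.02, 1.0, 25)


@dataclasses.dataclass
class SurveyGrid:
    """Per-cell outcome counts of a Monte-Carlo survey over a 2-D grid.

    ``counts[name]`` has shape (len(axis 0), len(axis 1)) for each of the
    five outcome classes; flagged (eigensolver-failure) samples are excluded
    from the counts and tallied separately.  ``n_samples`` may be a scalar
    or a per-cell array.
    """

    axis_names: tuple[str, str]
    axis_values: tuple[np.ndarray, np.ndarray]
    counts: dict[str, np.ndarray]
    n_samples: np.ndarray
    seed: int
    sigma2: np.ndarray | None = None  # per-cell variance actually used
    flagged: np.ndarray | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.axis_values[0]), len(self.axis_values[1]))

    def effective_n(self) -> np.ndarray:
        n = np.broadcast_to(np.asarray(self.n_samples), self.shape).astype(float)
        if self.flagged is not None:
            n = n - self.flagged
        return n

    def percentage(self, klass: str) -> np.ndarray:
        """Percentage of all (non-flagged) samples in a class, per cell."""
        return 100.0 * self.counts[klass] / self.effective_n()

    def turing_any_percentage(self) -> np.ndarray:
        tot = sum(self.counts[c] for c in TURING_CLASSES)
        return 100.0 * tot / self.effective_n()

    def stable_at_k0_percentage(self) -> np.ndarray:
        """Share of samples stable without diffusion (k = 0)."""
        stable0 = self.effective_n() - self.counts["unstable_without_diffusion"]
        return 100.0 * stable0 / self.effective_n()

    def conditional_turing_percentage(self) -> np.ndarray:
        """Among systems stable at k = 0, share turning unstable with diffusion."""
        stable0 = self.effective_n() - self.counts["unstable_without_diffusion"]
        tot = sum(self.counts[c] for c in TURING_CLASSES)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(stable0 > 0, 100.0 * tot / stable0, np.nan)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per cell per class."""
        a0, a1 = self.axis_values
        n = self.effective_n()
        rows = []
        for klass in CLASS_NAMES:
            c = self.counts[klass]
            for i, v0 in enumerate(a0):
                for j, v1 in enumerate(a1):
                    row = {
                        self.axis_names[0]: v0,
                        self.axis_names[1]: v1,
                        "class": klass,
                        "count": int(c[i, j]),
                        "n_samples": int(round(n[i, j])),
                        "percentage": 100.0 * c[i, j] / n[i, j] if n[i, j] else np.nan,
                    }
                    if self.sigma2 is not None:
                        row["sigma2"] = self.sigma2[i, j]
                    rows.append(row)
        return pd.DataFrame(rows)


@dataclasses.dataclass
class OptimalSizeResult:
    """Per-network-size Turing-I statistics extracted from a heat map.

    ``share_percentage`` is each network size's percentage share of all
    Turing-I occurrences across the heat map (rates are summed along the
    variance axis per N and normalised over N, so the shares sum to 100);
    this is the robustness statistic that defines the optimal size: the N
    whose row of the heat map collects the most Turing-I systems.  The
    per-cell peak percentage along the variance axis is reported alongside.
    """

    n_values: np.ndarray
    share_percentage: np.ndarray       # per-N share of all Turing-I cases
    peak_percentage: np.ndarray        # per-N max cell percentage
    peak_sigma2: np.ndarray            # variance attaining each per-N peak
    n_opt: int                         # argmax of share_percentage
    n_opt_percentage: float            # share at n_opt
    interior: bool                     # optimum not at a scanned boundary

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": self.n_values,
                "turing_I_share_percent": self.share_percentage,
                "peak_turing_I_percent": self.peak_percentage,
                "peak_sigma2": self.peak_sigma2,
            }
        )


def run_cell(
    n_nodes: int,
    sigma2: float,
    diff: DiffusionSpec,
    n_samples: int,
    rng: np.random.Generator,
    k_grid: KGrid = KGrid(),
    connectivity: float = 1.0,
    diagonal_mode: DiagonalMode | str = DiagonalMode.FIXED_MINUS_ONE,
    adaptive: bool = True,
) -> tuple[dict[str, int], int]:
    """Sample and classify one grid cell; returns (class counts, n flagged).

    With ``adaptive`` (default) the classifier screens on a coarse
    wavenumber grid and refines near-marginal samples on the full grid;
    the class labels are those of the full grid at a fraction of the cost.
    """
    spec = EnsembleSpec(
        n_nodes=n_nodes, sigma2=sigma2, connectivity=connectivity,
        diagonal_mode=diagonal_mode,
    )
    j0s = sample_jacobians(spec, n_samples, rng)
    classifier = classify_batch_adaptive if adaptive else classify_batch
    codes, flagged = classifier(j0s, diff, k_grid)
    counts = {
        name: int(np.count_nonzero(codes == i)) for i, name in enumerate(CLASS_NAMES)
    }
    return counts, int(flagged.sum())


def _run_grid(
    experiment: str,
    axis_names: tuple[str, str],
    axis_values: tuple[np.ndarray, np.ndarray],
    cell_sigma2: np.ndarray,
    cell_n_nodes,
    diff: DiffusionSpec,
    n_samples,
    seed: int,
    k_grid: KGrid,
    connectivity: float,
    diagonal_mode,
    cell_diff: "np.ndarray | None" = None,
) -> SurveyGrid:
    shape = (len(axis_values[0]), len(axis_values[1]))
    counts = {c: np.zeros(shape, dtype=np.int64) for c in CLASS_NAMES}
    flagged = np.zeros(shape, dtype=np.int64)
    n_arr = np.broadcast_to(np.asarray(n_samples), shape)

    for i in range(shape[0]):
        for j in range(shape[1]):
            s2 = cell_sigma2[i, j]
            if not np.isfinite(s2) or s2 <= 0:
                warnings.warn(f"cell ({i},{j}) skipped: sigma2={s2}")
                flagged[i, j] = n_arr[i, j]
                continue
            rng = substream(seed, experiment, i, j)
            d = diff if cell_diff is None else cell_diff[i][j]
            c, f = run_cell(
                int(np.broadcast_to(cell_n_nodes, shape)[i, j]), float(s2), d,
                int(n_arr[i, j]), rng, k_grid, connectivity, diagonal_mode,
            )
            for name, v in c.items():
                counts[name][i, j] = v
            flagged[i, j] = f
        logger.info(
            "%s: row %d/%d (%s=%s) done, %d flagged",
            experiment, i + 1, shape[0], axis_names[0], axis_values[0][i],
            int(flagged[i].sum()),
        )

    return SurveyGrid(
        axis_names=axis_names,
        axis_values=(np.asarray(axis_values[0]), np.asarray(axis_values[1])),
        counts=counts,
        n_samples=np.asarray(n_samples),
        seed=seed,
        sigma2=cell_sigma2,
        flagged=flagged,
        meta={
            "experiment": experiment,
            "diffusion": diff.to_config(),
            "k_grid": {"k_max": k_grid.k_max, "step": k_grid.step},
            "connectivity": connectivity,
            "diagonal_mode": DiagonalMode(diagonal_mode).value,
        },
    )


def run_stability_survey(
    n_values: Sequence[int],
    gamma_values: Sequence[float] = DEFAULT_GAMMA_SURVEY,
    diff: DiffusionSpec = DiffusionSpec(),
    n_samples=1000,
    seed: int = 0,
    k_grid: KGrid = KGrid(),
    connectivity: float = 1.0,
    diagonal_mode: DiagonalMode | str = DiagonalMode.FIXED_MINUS_ONE,
) -> SurveyGrid:
    """Survey stability classes over an (N, gamma) grid.

    Each cell uses the variance implied by the circular law,
    sigma^2 = gamma^2 / (N C).  ``n_samples`` may be an (len(N), 1) array to
    thin the sampling for expensive large-N rows.
    """
    n_vals = np.asarray(list(n_values), dtype=int)
    g_vals = np.asarray(list(gamma_values), dtype=float)
    s2 = (g_vals[None, :] ** 2) / (n_vals[:, None] * connectivity)
    return _run_grid(
        "stability", ("N", "gamma"), (n_vals, g_vals), s2, n_vals[:, None],
        diff, n_samples, seed, k_grid, connectivity, diagonal_mode,
    )


def run_size_variance_heatmap(
    n_values: Sequence[int],
    sigma2_values: Sequence[float] | None = None,
    diff: DiffusionSpec = DiffusionSpec(),
    n_samples=1000,
    seed: int = 0,
    k_grid: KGrid = KGrid(),
    connectivity: float = 1.0,
    diagonal_mode: DiagonalMode | str = DiagonalMode.FIXED_MINUS_ONE,
) -> SurveyGrid:
    """Turing-I frequency heat map over network size and interaction variance.

    All network sizes share one absolute variance axis (default
    ``DEFAULT_SIGMA2_GRID``, a linear grid on [0.02, 1.0]); on a linear
    sigma^2 axis the circular-law band gamma ~ 1 occupies a width
    proportional to 1/N, which is what makes the per-N share of Turing-I
    occurrences (see :func:`extract_optimal_size`) peak at a small network
    size.  Sparsity variants pass ``connectivity`` < 1 and keep the same
    axis.
    """
    n_vals = np.asarray(list(n_values), dtype=int)
    if sigma2_values is None:
        sigma2_values = DEFAULT_SIGMA2_GRID
    s2_axis = np.asarray(list(sigma2_values), dtype=float)
    s2 = np.broadcast_to(s2_axis[None, :], (len(n_vals), len(s2_axis))).copy()
    return _run_grid(
        "heatmap", ("N", "sigma2"), (n_vals, s2_axis), s2, n_vals[:, None],
        diff, n_samples, seed, k_grid, connectivity, diagonal_mode,
    )


def run_diffusion_grid(
    n_nodes: int,
    sigma2: float,
    d1_values: Sequence[float],
    d2_values: Sequence[float],
    n_samples=1000,
    seed: int = 0,
    k_grid: KGrid = KGrid(),
    connectivity: float = 1.0,
    diagonal_mode: DiagonalMode | str = DiagonalMode.FIXED_MINUS_ONE,
) -> SurveyGrid:
    """Turing-I frequency over a (D1, D2) grid at fixed network size/variance."""
    d1s = np.asarray(list(d1_values), dtype=float)
    d2s = np.asarray(list(d2_values), dtype=float)
    if np.any(d1s <= 0) or np.any(d2s <= 0):
        raise ValueError("diffusion constants must be strictly positive")
    s2 = np.full((len(d1s), len(d2s)), float(sigma2))
    cell_diff = [[DiffusionSpec(a, b) for b in d2s] for a in d1s]
    grid = _run_grid(
        "diffusion_grid", ("D1", "D2"), (d1s, d2s), s2, n_nodes,
        DiffusionSpec(d1s[0], d2s[0]), n_samples, seed, k_grid,
        connectivity, diagonal_mode, cell_diff=cell_diff,
    )
    grid.meta["n_nodes"] = int(n_nodes)
    grid.meta["diffusion"] = {"D1": "axis", "D2": "axis"}
    return grid


def extract_optimal_size(grid: SurveyGrid, klass: str = "turing_I") -> OptimalSizeResult:
    """Locate the network size collecting the largest share of Turing-I cases.

    Per-cell Turing-I rates (count / samples, so rows with different sample
    budgets are comparable) are summed along the variance axis for each N
    and normalised across N into percentage shares summing to 100.  The
    optimal size is the argmax of this share.  Turing II and Turing-Hopf
    counts are excluded from the robustness statistic.  A flat (all-zero)
    grid reports ``n_opt`` at the first scanned size with zero share and
    ``interior=False``.
    """
    if grid.axis_names[0] != "N":
        raise ValueError("grid's first axis must be network size N")
    pct = grid.percentage(klass)
    row_sum = pct.sum(axis=1)
    total = row_sum.sum()
    share = 100.0 * row_sum / total if total > 0 else np.zeros_like(row_sum)
    peak = pct.max(axis=1)
    arg = pct.argmax(axis=1)
    s2 = grid.sigma2 if grid.sigma2 is not None else np.broadcast_to(
        grid.axis_values[1][None, :], grid.shape
    )
    peak_s2 = s2[np.arange(len(peak)), arg]
    i_opt = int(np.argmax(share))
    interior = bool(0 < i_opt < len(share) - 1) and share[i_opt] > 0
    return OptimalSizeResult(
        n_values=grid.axis_values[0],
        share_percentage=share,
        peak_percentage=peak,
        peak_sigma2=peak_s2,
        n_opt=int(grid.axis_values[0][i_opt]),
        n_opt_percentage=float(share[i_opt]),
        interior=interior,
    )


def save_survey(grid: SurveyGrid, out_dir, name: str) -> tuple[Path, Path]:
    """Write a survey as long-format CSV plus a JSON run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{name}.csv"
    manifest_path = out_dir / f"{name}_manifest.json"
    grid.to_dataframe().to_csv(csv_path, index=False, float_format="%.17g")
    manifest = {
        "name": name,
        "seed": int(grid.seed),
        "axis_names": list(grid.axis_names),
        "axes": {
            grid.axis_names[0]: np.asarray(grid.axis_values[0]).tolist(),
            grid.axis_names[1]: np.asarray(grid.axis_values[1]).tolist(),
        },
        "n_samples": np.asarray(grid.n_samples).tolist(),
        "flagged": None if grid.flagged is None else grid.flagged.tolist(),
        "meta": grid.meta,
        "outputs": [csv_path.name],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return csv_path, manifest_path
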