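"""Selection of the dynamics-based consensus (DBC) network.

Every candidate on the consensus-threshold ladder gets a metastability
profile; for candidate G_T the deviation from the cohort is

    MSE_T = (1/n) sum_i mean_K ( MP[G_T](K) - MP[s_i](K) )^2,

the grand mean squared difference per grid point over subjects s_i.  The
DBC is the candidate minimising MSE_T.  The reduction over grid points
is a mean (rather than a sum) so that MSE values are comparable across
coupling grids of different length; ``grid_reduction="sum"`` preserves
the alternative convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .connectome import BinaryConnectome
from .consensus import ThresholdLadder
from .kuramoto import (
    CouplingGrid,
    MetastabilityProfile,
    SimulationConfig,
    metastability_profile,
)

__all__ = ["SelectionResult", "profile_mse", "profile_sq_euclid", "select_dbc"]


def _check_same_grid(a: MetastabilityProfile, b: MetastabilityProfile) -> None:
    if len(a.grid) != len(b.grid) or not np.allclose(a.grid.values, b.grid.values):
        raise ValueError("profiles are defined on different coupling grids")


def profile_mse(
    group_profile: MetastabilityProfile,
    subject_profiles: Sequence[MetastabilityProfile],
    grid_reduction: str = "mean",
) -> float:
    """Mean over subjects of the per-grid-point squared profile deviation."""
    if grid_reduction not in ("mean", "sum"):
        raise ValueError("grid_reduction must be 'mean' or 'sum'")
    reduce = np.mean if grid_reduction == "mean" else np.sum
    errs = []
    for sp in subject_profiles:
        _check_same_grid(group_profile, sp)
        errs.append(reduce((group_profile.values - sp.values) ** 2))
    return float(np.mean(errs))


def profile_sq_euclid(
    group_profile: MetastabilityProfile, subject_profile: MetastabilityProfile
) -> float:
    """Squared Euclidean distance between two profiles (sum over grid points)."""
    _check_same_grid(group_profile, subject_profile)
    return float(np.sum((group_profile.values - subject_profile.values) ** 2))


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the DBC selection over a threshold ladder."""

    mse: dict  # threshold (%) -> MSE_T
    dbc_threshold: float
    dbc_network: BinaryConnectome
    ladder_profiles: dict  # threshold (%) -> MetastabilityProfile
    subject_mean_profile: np.ndarray
    subject_sd_profile: np.ndarray

    @property
    def min_mse(self) -> float:
        return self.mse[self.dbc_threshold]


def select_dbc(
    ladder: ThresholdLadder,
    subject_profiles: Sequence[MetastabilityProfile],
    grid: CouplingGrid | None = None,
    config: SimulationConfig | None = None,
    grid_reduction: str = "mean",
) -> SelectionResult:
    """Pick the ladder network whose profile best matches the subjects'.

    Profiles for all ladder networks are computed under the one supplied
    ``config`` (hence with shared initial conditions and frequencies --
    common random numbers across candidates).  Exact MSE ties break
    toward the threshold nearest 50% consensus, then toward the lower
    threshold; deterministic given ``config.rng_seed``.
    """
    if grid is None:
        grid = CouplingGrid.default()
    if config is None:
        config = SimulationConfig()
    if not subject_profiles:
        raise ValueError("at least one subject profile is required")

    ladder_profiles = {
        t: metastability_profile(ladder[t], grid, config) for t in ladder
    }
    mse = {
        t: profile_mse(ladder_profiles[t], subject_profiles, grid_reduction)
        for t in ladder
    }
    best = min(mse, key=lambda t: (mse[t], abs(t - 50.0), t))

    subj_mat = np.stack([p.values for p in subject_profiles])
    return SelectionResult(
        mse=mse,
        dbc_threshold=best,
        dbc_network=ladder[best],
        ladder_profiles=ladder_profiles,
        subject_mean_profile=subj_mat.mean(axis=0),
        subject_sd_profile=subj_mat.std(axis=0, ddof=1) if len(subject_profiles) > 1
        else np.zeros(len(grid)),
    )
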