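"""Single-point external-standard quantitation of dissolution samples.

Chromatographic peak areas are converted to drug concentration by
comparison with a standard solution of known concentration, then to
cumulative percent of label claim released, with a mass-balance
correction for the drug removed with each sampling aliquot.

Cumulative release at the i-th sampling time (0-indexed) is

    %released_i = 100 * (C_i * V_i + w * sum_{j<i} C_j) / label_claim

where C_i is the measured concentration (mg/mL), w the withdrawal
volume (mL), and V_i the vessel volume at sampling: the full medium
volume when withdrawn medium is replaced, or medium - i*w when it is
not.  The sum restores drug that left the vessel in earlier aliquots.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import QuantitationError
from .profiles import DissolutionProfile, TimeGrid


class Replacement(str, Enum):
    """Whether withdrawn medium is replaced with fresh medium."""

    REPLACED = "replaced"
    NOT_REPLACED = "not_replaced"


@dataclass(frozen=True)
class QuantConfig:
    """Standard-preparation and dissolution-run constants.

    The standard is prepared by two-step dilution: ``std_mass_mg`` is
    dissolved to ``std_stock_vol_ml``, then ``std_aliquot_ml`` of the
    stock is diluted to ``std_final_vol_ml``.
    """

    std_mass_mg: float
    std_stock_vol_ml: float
    std_aliquot_ml: float
    std_final_vol_ml: float
    label_claim_mg: float
    medium_vol_ml: float
    withdrawal_vol_ml: float = 0.0
    std_purity_frac: float = 1.0
    replacement: Replacement = Replacement.REPLACED

    def __post_init__(self) -> None:
        for name in ("std_mass_mg", "std_stock_vol_ml", "std_aliquot_ml",
                     "std_final_vol_ml", "label_claim_mg", "medium_vol_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.withdrawal_vol_ml < 0:
            raise ValueError("withdrawal_vol_ml must be >= 0")
        if self.std_aliquot_ml > self.std_stock_vol_ml:
            raise ValueError("std_aliquot_ml cannot exceed std_stock_vol_ml")
        if not 0 < self.std_purity_frac <= 1:
            raise ValueError("std_purity_frac must be in (0, 1]")
        object.__setattr__(self, "replacement", Replacement(self.replacement))


@dataclass
class AreaTable:
    """Detector peak areas for one product: (time x replicate) sample areas
    plus the mean area of the external standard."""

    grid: TimeGrid
    sample_areas: np.ndarray
    std_area: float

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.sample_areas, dtype=float))
        if a.shape[0] != len(self.grid):
            if a.shape == (1, len(self.grid)):
                a = a.T
            else:
                raise ValueError(
                    f"area matrix has {a.shape[0]} rows for "
                    f"{len(self.grid)} time points"
                )
        if not np.all(np.isfinite(a)) or np.any(a <= 0):
            raise ValueError("all peak areas must be finite and > 0")
        self.sample_areas = a
        if self.std_area <= 0:
            raise QuantitationError("standard peak area must be > 0")


def standard_concentration(cfg: QuantConfig) -> float:
    """Concentration of the working standard solution in mg/mL.

    mass * purity / stock volume, diluted aliquot/final.
    """
    return (
        cfg.std_mass_mg * cfg.std_purity_frac / cfg.std_stock_vol_ml
        * cfg.std_aliquot_ml / cfg.std_final_vol_ml
    )


def vessel_volumes(cfg: QuantConfig, n_timepoints: int) -> np.ndarray:
    """Vessel volume at each sampling time, before that withdrawal."""
    i = np.arange(n_timepoints, dtype=float)
    if cfg.replacement is Replacement.REPLACED:
        return np.full(n_timepoints, cfg.medium_vol_ml)
    if cfg.withdrawal_vol_ml * n_timepoints >= cfg.medium_vol_ml:
        raise QuantitationError(
            "withdrawals exhaust the dissolution medium: "
            f"{n_timepoints} x {cfg.withdrawal_vol_ml} mL from "
            f"{cfg.medium_vol_ml} mL"
        )
    return cfg.medium_vol_ml - i * cfg.withdrawal_vol_ml


def concentrations(areas: AreaTable, cfg: QuantConfig) -> np.ndarray:
    """Measured concentration (mg/mL) per time point and replicate."""
    if areas.std_area <= 0:
        raise QuantitationError("standard peak area must be > 0")
    return standard_concentration(cfg) * areas.sample_areas / areas.std_area


def percent_released(
    areas: AreaTable,
    cfg: QuantConfig,
    product_label: str = "sample",
) -> DissolutionProfile:
    """Convert a peak-area table to a cumulative percent-released profile.

    Applies the aliquot-withdrawal correction in the configured
    replacement mode.  Cells above the plausibility ceiling are reported
    by the profile validation, not silently clipped.
    """
    conc = concentrations(areas, cfg)  # (n_times, n_reps)
    pct = cumulative_percent(conc, cfg)
    return DissolutionProfile(
        product_label=product_label, grid=areas.grid, replicates=pct,
        on_implausible="flag",
    )


def cumulative_percent(conc: np.ndarray, cfg: QuantConfig) -> np.ndarray:
    """Cumulative % label claim released from a concentration matrix."""
    conc = np.atleast_2d(np.asarray(conc, dtype=float))
    n_t = conc.shape[0]
    v = vessel_volumes(cfg, n_t)[:, None]
    prior = np.zeros_like(conc)
    prior[1:] = np.cumsum(conc, axis=0)[:-1]
    mass = conc * v + cfg.withdrawal_vol_ml * prior
    return 100.0 * mass / cfg.label_claim_mg
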