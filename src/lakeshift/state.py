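"""State-vector layout and nutrient bookkeeping for the lake model.

The full model state is a ``(N_VARS, n_layers)`` array.  Water-column
variables are concentrations (g/m^3); sediment variables are areal pools
(g/m^2) except porewater nutrients (g/m^3 of porewater); the trailing
"ledger" variables are cumulative masses (g) of nitrogen lost to
denitrification (as N2) and material buried below the active sediment
layer, carried per layer so that every internal transfer has an explicit
destination and the N and P cycles close exactly.

Layer index 0 is the bottom layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lakeshift.grid import VerticalGrid

__all__ = ["VAR_NAMES", "N_VARS", "V", "LakeState", "conversion_matrix"]


class V:
    """Integer indices of every state variable."""

    # --- water column (g/m^3) ---
    NH4 = 0
    NO3 = 1
    PO4 = 2
    DOM_N = 3
    DOM_P = 4
    POM_DM = 5
    POM_N = 6
    POM_P = 7
    IM = 8
    O2 = 9
    DIA_DM, DIA_N, DIA_P = 10, 11, 12
    CYA_DM, CYA_N, CYA_P = 13, 14, 15
    OTH_DM, OTH_N, OTH_P = 16, 17, 18
    ZOO_DM, ZOO_N, ZOO_P = 19, 20, 21
    JUV_DM, JUV_N, JUV_P = 22, 23, 24
    ADU_DM, ADU_N, ADU_P = 25, 26, 27
    PIS_DM, PIS_N, PIS_P = 28, 29, 30
    # --- sediment (areal g/m^2; porewater g/m^3) ---
    SPOM_DM, SPOM_N, SPOM_P = 31, 32, 33
    HUM_DM, HUM_N, HUM_P = 34, 35, 36
    SIM = 37
    PAIMS = 38
    PNH4, PNO3, PPO4 = 39, 40, 41
    ZB_DM, ZB_N, ZB_P = 42, 43, 44
    MAC_DM, MAC_N, MAC_P = 45, 46, 47
    # --- ledgers (cumulative g per layer) ---
    DENIT_N = 48
    BUR_DM, BUR_N, BUR_P = 49, 50, 51


VAR_NAMES = [
    "NH4", "NO3", "PO4", "DOM_N", "DOM_P", "POM_DM", "POM_N", "POM_P", "IM", "O2",
    "DIA_DM", "DIA_N", "DIA_P", "CYA_DM", "CYA_N", "CYA_P", "OTH_DM", "OTH_N", "OTH_P",
    "ZOO_DM", "ZOO_N", "ZOO_P",
    "JUV_DM", "JUV_N", "JUV_P", "ADU_DM", "ADU_N", "ADU_P", "PIS_DM", "PIS_N", "PIS_P",
    "SPOM_DM", "SPOM_N", "SPOM_P", "HUM_DM", "HUM_N", "HUM_P", "SIM", "PAIMS",
    "PNH4", "PNO3", "PPO4", "ZB_DM", "ZB_N", "ZB_P", "MAC_DM", "MAC_N", "MAC_P",
    "DENIT_N", "BUR_DM", "BUR_N", "BUR_P",
]
N_VARS = len(VAR_NAMES)

#: water-column concentration variables (mixed, flushed, settled subsets below)
WATER_VARS = np.arange(V.NH4, V.PIS_P + 1)
#: variables transported by mixing and in/outflow (fish are layer-bound)
MOBILE_VARS = np.arange(V.NH4, V.ZOO_P + 1)
FISH_VARS = np.arange(V.JUV_DM, V.PIS_P + 1)
SEDIMENT_VARS = np.arange(V.SPOM_DM, V.MAC_P + 1)
LEDGER_VARS = np.arange(V.DENIT_N, V.BUR_P + 1)
POREWATER_VARS = np.array([V.PNH4, V.PNO3, V.PPO4])

#: nitrogen content (g N per unit of the variable)
N_CONTENT = np.zeros(N_VARS)
for _i in [V.NH4, V.NO3, V.DOM_N, V.POM_N, V.DIA_N, V.CYA_N, V.OTH_N, V.ZOO_N,
           V.JUV_N, V.ADU_N, V.PIS_N, V.SPOM_N, V.HUM_N, V.PNH4, V.PNO3,
           V.ZB_N, V.MAC_N, V.DENIT_N, V.BUR_N]:
    N_CONTENT[_i] = 1.0

#: phosphorus content
P_CONTENT = np.zeros(N_VARS)
for _i in [V.PO4, V.DOM_P, V.POM_P, V.DIA_P, V.CYA_P, V.OTH_P, V.ZOO_P,
           V.JUV_P, V.ADU_P, V.PIS_P, V.SPOM_P, V.HUM_P, V.PAIMS, V.PPO4,
           V.ZB_P, V.MAC_P, V.BUR_P]:
    P_CONTENT[_i] = 1.0


def conversion_matrix(grid: VerticalGrid, *, sediment_depth: float = 0.1,
                      porosity: float = 0.8) -> np.ndarray:
    """(N_VARS, n_layers) factors converting state units to mass (g).

    Water concentrations scale by layer volume, areal sediment pools by
    benthic area, porewater concentrations by benthic area times the
    porewater depth, ledgers by 1.
    """
    conv = np.empty((N_VARS, grid.n_layers))
    conv[WATER_VARS] = grid.volumes
    conv[SEDIMENT_VARS] = grid.benthic_areas
    conv[POREWATER_VARS] = grid.benthic_areas * sediment_depth * porosity
    conv[LEDGER_VARS] = 1.0
    return conv


@dataclass
class LakeState:
    """Full model state plus boundary-flux accumulators.

    ``x`` is the (N_VARS, n_layers) state array.  ``boundary`` accumulates
    masses (g) crossing the lake boundary via inflow and outflow, so the
    nutrient budget can be audited:

        total_N(t) = total_N(0) + inflow_N - outflow_N

    (denitrified N2 and buried matter live in per-layer ledger variables
    inside ``x`` and therefore never leave the accounted total).
    """

    x: np.ndarray
    boundary: dict = field(default_factory=lambda: {
        "inflow_N": 0.0, "outflow_N": 0.0, "inflow_P": 0.0, "outflow_P": 0.0,
        "inflow_DM": 0.0, "outflow_DM": 0.0,
    })

    @property
    def n_layers(self) -> int:
        return self.x.shape[1]

    def copy(self) -> "LakeState":
        return LakeState(self.x.copy(), dict(self.boundary))

    def masses(self, conv: np.ndarray) -> np.ndarray:
        return self.x * conv

    def total_n(self, conv: np.ndarray) -> float:
        """Total nitrogen (g) in all pools including internal ledgers."""
        return float(N_CONTENT @ (self.x * conv).sum(axis=1))

    def total_p(self, conv: np.ndarray) -> float:
        return float(P_CONTENT @ (self.x * conv).sum(axis=1))

    def budget_residual_n(self, conv: np.ndarray, total_n0: float) -> float:
        """N budget residual (g): closes to ~0 when bookkeeping is exact."""
        return (self.total_n(conv) - total_n0
                - self.boundary["inflow_N"] + self.boundary["outflow_N"])

    def budget_residual_p(self, conv: np.ndarray, total_p0: float) -> float:
        return (self.total_p(conv) - total_p0
                - self.boundary["inflow_P"] + self.boundary["outflow_P"])

    def validate(self) -> None:
        if not np.all(np.isfinite(self.x)):
            raise FloatingPointError("non-finite value in lake state")
        if np.any(self.x < 0):
            raise ValueError("negative pool in lake state")
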