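"""Gas-exchange response curves and measurement protocols.

An ACi curve steps chamber CO2 at saturating light; an Ai curve steps
irradiance at ambient CO2.  The standard step sequences used throughout
the package follow a LI-6400 field protocol: CO2 at
200, 100, 50, 250, 400, 650, 800, 1000, 1200, 1400 ppm with PAR fixed at
1800 umol m-2 s-1, and light at 2000, 1500, 1000, 500, 250, 120, 60, 30,
15, 0 umol m-2 s-1 with CO2 fixed at 400 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "ACI_CO2_STEPS",
    "AI_LIGHT_STEPS",
    "ACI_LIGHT",
    "AI_CO2",
    "CurveStep",
    "CurveProtocol",
    "ResponseCurve",
    "read_curves_csv",
    "write_curves_csv",
]

ACI_CO2_STEPS: tuple[float, ...] = (200, 100, 50, 250, 400, 650, 800, 1000, 1200, 1400)
AI_LIGHT_STEPS: tuple[float, ...] = (2000, 1500, 1000, 500, 250, 120, 60, 30, 15, 0)
ACI_LIGHT: float = 1800.0
AI_CO2: float = 400.0

CurveKind = Literal["ACi", "Ai"]


@dataclass(frozen=True)
class CurveStep:
    """One equilibrated gas-exchange record."""

    A_obs: float
    Ca: float
    I_inc: float
    Ci: float | None = None


@dataclass(frozen=True)
class CurveProtocol:
    """Ordered (Ca, I_inc) set points of a response-curve protocol."""

    kind: CurveKind
    steps: tuple[tuple[float, float], ...]
    ci_over_ca: float = 0.4

    @classmethod
    def aci(cls, co2_steps: Iterable[float] = ACI_CO2_STEPS,
            light: float = ACI_LIGHT, ci_over_ca: float = 0.4) -> "CurveProtocol":
        return cls("ACi", tuple((float(c), float(light)) for c in co2_steps),
                   ci_over_ca)

    @classmethod
    def ai(cls, light_steps: Iterable[float] = AI_LIGHT_STEPS,
           co2: float = AI_CO2, ci_over_ca: float = 0.4) -> "CurveProtocol":
        return cls("Ai", tuple((float(co2), float(i)) for i in light_steps),
                   ci_over_ca)


@dataclass
class ResponseCurve:
    """One measured (or simulated) ACi or Ai series for a plot."""

    kind: CurveKind
    steps: list[CurveStep]
    plot_id: str = ""
    genotype: str = ""
    leaf_temperature: float | None = None

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def A_obs(self) -> np.ndarray:
        return np.array([s.A_obs for s in self.steps], dtype=float)

    @property
    def Ca(self) -> np.ndarray:
        return np.array([s.Ca for s in self.steps], dtype=float)

    @property
    def Ci(self) -> np.ndarray:
        """Measured Ci where present, NaN otherwise."""
        return np.array(
            [np.nan if s.Ci is None else s.Ci for s in self.steps], dtype=float
        )

    @property
    def I_inc(self) -> np.ndarray:
        return np.array([s.I_inc for s in self.steps], dtype=float)

    def validate_for_fitting(self) -> None:
        if len(self.steps) < 5:
            raise ValueError("need at least 5 steps to fit a response curve")
        if self.kind == "ACi" and np.ptp(self.Ca) == 0:
            raise ValueError("ACi curve must vary Ca")
        if self.kind == "Ai" and np.ptp(self.I_inc) == 0:
            raise ValueError("Ai curve must vary I_inc")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": self.plot_id,
                "genotype": self.genotype,
                "kind": self.kind,
                "step": np.arange(1, len(self) + 1),
                "A_obs": self.A_obs,
                "Ca": self.Ca,
                "Ci": self.Ci,
                "I_inc": self.I_inc,
                "Tleaf": self.leaf_temperature,
            }
        )


def write_curves_csv(curves: Iterable[ResponseCurve], path) -> None:
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(
        path, index=False
    )


def read_curves_csv(path) -> list[ResponseCurve]:
    """Load curves from the flat CSV layout written by write_curves_csv."""
    df = pd.read_csv(path)
    curves = []
    for (plot_id, kind), g in df.groupby(["plot_id", "kind"], sort=False):
        g = g.sort_values("step")
        steps = [
            CurveStep(
                A_obs=r.A_obs,
                Ca=r.Ca,
                I_inc=r.I_inc,
                Ci=None if pd.isna(r.Ci) else r.Ci,
            )
            for r in g.itertuples()
        ]
        tleaf = g["Tleaf"].iloc[0] if "Tleaf" in g else None
        curves.append(
            ResponseCurve(
                kind=kind,
                steps=steps,
                plot_id=str(plot_id),
                genotype=str(g["genotype"].iloc[0]),
                leaf_temperature=None if pd.isna(tleaf) else float(tleaf),
            )
        )
    return curves
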