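"""Reduced neuron morphology: a cylindrical soma plus a passive dendritic cable.

The full pipeline was designed for reconstructed cells with hundreds of
compartments; here the dendritic tree is collapsed to a single unbranched
passive cable, which preserves the soma/dendrite current split that the two
leak-conductance parameters control while keeping simulations desk-scale.
Compartment count is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Morphology"]

_UM_TO_CM = 1e-4


@dataclass(frozen=True)
class Morphology:
    """Geometry and passive cable constants.

    Lengths and diameters in µm; axial resistivity in Ω·cm; specific
    capacitance in µF/cm².  Compartment 0 is the soma; compartments 1..n
    form the dendritic cable attached to it.
    """

    soma_length: float = 20.0
    soma_diam: float = 20.0
    n_dend: int = 10
    dend_length: float = 100.0  # per compartment
    dend_diam: float = 2.0
    axial_resistivity: float = 150.0
    capacitance: float = 1.0

    def __post_init__(self):
        for name in ("soma_length", "soma_diam", "dend_length", "dend_diam",
                     "axial_resistivity", "capacitance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_dend < 0:
            raise ValueError("n_dend must be >= 0")

    @property
    def n_comp(self) -> int:
        return 1 + self.n_dend

    def areas_cm2(self) -> np.ndarray:
        """Lateral membrane area per compartment, cm²."""
        a = np.empty(self.n_comp)
        a[0] = np.pi * self.soma_diam * self.soma_length * _UM_TO_CM**2
        a[1:] = np.pi * self.dend_diam * self.dend_length * _UM_TO_CM**2
        return a

    def capacitances_nF(self) -> np.ndarray:
        # µF/cm² * cm² = µF; 1 µF = 1e3 nF
        return self.capacitance * self.areas_cm2() * 1e3

    def axial_conductances_uS(self) -> np.ndarray:
        """Axial conductance linking compartment i and i+1, µS (length n-1)."""
        if self.n_comp == 1:
            return np.empty(0)
        L = np.empty(self.n_comp)
        d = np.empty(self.n_comp)
        L[0], d[0] = self.soma_length, self.soma_diam
        L[1:], d[1:] = self.dend_length, self.dend_diam
        L_cm = L * _UM_TO_CM
        cross = np.pi * (d * _UM_TO_CM) ** 2 / 4.0
        half_R = self.axial_resistivity * (L_cm / 2.0) / cross  # Ω
        r = half_R[:-1] + half_R[1:]
        return 1e6 / r

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "soma_length", "soma_diam", "n_dend", "dend_length", "dend_diam",
            "axial_resistivity", "capacitance")}

    @classmethod
    def from_dict(cls, d: dict) -> "Morphology":
        return cls(**d)
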