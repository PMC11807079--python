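"""Rat CNS physiology and drug physicochemical parameters.

All quantities carry fixed internal units: volumes in mL, flows and
clearances in mL/min, surface areas in cm^2, times in minutes.  Parameter
sets are plain frozen dataclasses so they can be constructed directly in
code or loaded from YAML config (see :mod:`brainecf.datasets`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "PhysiologyParams",
    "DrugProperties",
    "fraction_unionized",
]

_SPECIES = ("acid", "base", "neutral")


@dataclass(frozen=True)
class PhysiologyParams:
    """Rat CNS physiological parameters.

    Attributes
    ----------
    sa_bbb : float
        Total surface area of the blood-brain barrier, cm^2.
    trans_fraction : float
        Fraction of ``sa_bbb`` available for transcellular transport
        (P-gp sits in the apical endothelial membrane, so efflux scales
        with the transcellular surface only).
    v_mv, v_ecf, v_bc : float
        Volumes of the brain microvascular, brain-extracellular-fluid and
        brain-cell-membrane compartments, mL.
    q_cbf : float
        Cerebral blood flow, mL/min.
    q_ecf : float
        BrainECF bulk flow towards the ventricles, mL/min.  Treated as a
        terminal sink here (no CSF compartments).
    ph_ecf : float
        pH of the brainECF, used for the unionized fraction.
    body_weight : float
        Typical rat body weight, kg; converts mg/kg doses to amounts.
    """

    sa_bbb: float
    trans_fraction: float
    v_mv: float
    v_ecf: float
    v_bc: float
    q_cbf: float
    q_ecf: float
    ph_ecf: float
    body_weight: float = 0.25

    def __post_init__(self) -> None:
        for name in ("sa_bbb", "v_mv", "v_ecf", "v_bc", "q_cbf", "body_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if self.q_ecf < 0:
            raise ValueError(f"q_ecf must be non-negative, got {self.q_ecf}")
        if not 0 < self.trans_fraction <= 1:
            raise ValueError(f"trans_fraction must be in (0, 1], got {self.trans_fraction}")
        if not 0 < self.ph_ecf < 14:
            raise ValueError(f"ph_ecf must be a physical pH, got {self.ph_ecf}")

    @property
    def sa_bbb_trans(self) -> float:
        """Transcellular BBB surface area, cm^2 (``trans_fraction * sa_bbb``)."""
        return self.trans_fraction * self.sa_bbb


@dataclass(frozen=True)
class DrugProperties:
    """Physicochemical and membrane-partitioning properties of one drug.

    ``cl_bc_in``/``cl_bc_out`` are the clearances into and out of brain
    cell membranes (mL/min); the default 0 disables the membrane
    compartment.  ``phf_override`` fixes the unionized fraction directly,
    bypassing the Henderson-Hasselbalch computation (useful for
    multiprotic drugs, which are otherwise out of scope).
    """

    name: str
    fup: float
    pka: Optional[float] = None
    species: str = "neutral"
    cl_bc_in: float = 0.0
    cl_bc_out: float = 0.0
    observed_kpuu_bbb: Optional[float] = None
    phf_override: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.fup <= 1:
            raise ValueError(f"fup must be in (0, 1], got {self.fup}")
        if self.species not in _SPECIES:
            raise ValueError(f"species must be one of {_SPECIES}, got {self.species!r}")
        if self.cl_bc_in < 0 or self.cl_bc_out < 0:
            raise ValueError("membrane-partitioning clearances must be non-negative")
        if self.observed_kpuu_bbb is not None and self.observed_kpuu_bbb <= 0:
            raise ValueError("observed_kpuu_bbb must be positive when present")
        if self.phf_override is not None and not 0 <= self.phf_override <= 1:
            raise ValueError("phf_override must be a fraction in [0, 1]")

    def phf_ecf(self, ph: float) -> float:
        """Unionized fraction of the drug at brainECF pH."""
        if self.phf_override is not None:
            return self.phf_override
        return fraction_unionized(self.pka, ph, self.species)


def fraction_unionized(pka: Optional[float], ph: float, species: str) -> float:
    """Monoprotic Henderson-Hasselbalch unionized fraction.

    Parameters
    ----------
    pka : float or None
        Dissociation constant; ignored (may be None) for neutral species.
    ph : float
        Medium pH, in (0, 14).
    species : {"acid", "base", "neutral"}
        Ionization class of the drug.

    Returns
    -------
    float
        Fraction of drug in the unionized form, in [0, 1].  Neutral
        species return 1; a base is half-ionized at ``ph == pka``
        (fraction 0.5), and progressively ionized below it.
    """
    if species not in _SPECIES:
        raise ValueError(f"species must be one of {_SPECIES}, got {species!r}")
    if not 0 < ph < 14:
        raise ValueError(f"ph must be in (0, 14), got {ph}")
    if species == "neutral":
        return 1.0
    if pka is None or not (pka == pka):  # None or NaN
        raise ValueError(f"pka must be finite for species {species!r}")
    if species == "base":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - pka))
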