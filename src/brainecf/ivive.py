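"""In vitro -> in vivo extrapolation of blood-brain-barrier clearances.

Transwell apparent permeabilities and corrected efflux ratios from
monolayer assays (Caco-2, MDCKII-MDR1, LLC-PK1 transfected lines) are
scaled to rat in vivo BBB clearances:

    CL_passive = P_app,A:B[I] * SA_BBB * 60
    CL_Pgp     = (ER_c - 1) * 2 * P_app,A:B[I] * SA_BBB,trans * REF * 60
    REF        = P-gp expression in vivo / P-gp expression in vitro

with P_app in 1e-6 cm/s (the conventional transwell unit; the 1e-6
factor is applied exactly once, inside the two clearance functions, so
that 1 cm^3 == 1 mL gives clearances in mL/min).  The REF assumes P-gp
activity is proportional to its proteomic abundance; REF = 1 is the
"no-REF" scenario in which in vitro efflux is taken at face value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

__all__ = [
    "CELL_LINES",
    "EXPRESSION_LEVELS",
    "TranswellRecord",
    "ExpressionRecord",
    "ClearanceSet",
    "efflux_ratio",
    "corrected_efflux_ratio",
    "relative_expression_factor",
    "passive_clearance",
    "pgp_clearance",
    "build_clearance_set",
    "summarize_values",
    "fold_range",
]

CELL_LINES = ("Caco-2", "MDCKII-MDR1", "LLC-PK1-mdr1a", "LLC-PK1-MDR1")
EXPRESSION_LEVELS = ("highest", "average", "lowest")


@dataclass(frozen=True)
class TranswellRecord:
    """One literature transwell measurement set for a drug.

    ``papp_ab_inh`` is the apical-to-basolateral apparent permeability
    with P-gp inhibited (or measured in the parental, non-transfected
    line), in 1e-6 cm/s — the passive-permeability input of the scaling.
    ``er_c`` is the corrected efflux ratio ER/ER[I], isolating P-gp from
    other transporters.  Raw ``papp_ab``/``papp_ba``/``er``/``er_inh``
    are optional: most sources report only the derived quantities and
    those are then stored verbatim.
    """

    drug: str
    cell_line: str
    papp_ab_inh: float
    er_c: float
    inhibitor: str = "parental"
    source: str = ""
    papp_ab: Optional[float] = None
    papp_ba: Optional[float] = None
    er: Optional[float] = None
    er_inh: Optional[float] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.cell_line not in CELL_LINES:
            raise ValueError(
                f"unknown cell line {self.cell_line!r} for drug {self.drug!r}; "
                f"expected one of {CELL_LINES}"
            )
        for name in ("papp_ab_inh", "er_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive on record {self.drug}/{self.source}")
        for name in ("papp_ab", "papp_ba", "er", "er_inh"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive on record {self.drug}/{self.source}")
        if self.papp_ab is not None and self.papp_ba is not None and self.er is not None:
            if not math.isclose(self.er, self.papp_ba / self.papp_ab, rel_tol=0.01):
                raise ValueError(
                    f"stored efflux ratio {self.er} inconsistent with "
                    f"papp_ba/papp_ab = {self.papp_ba / self.papp_ab:.4g} "
                    f"on record {self.drug}/{self.source}"
                )


@dataclass(frozen=True)
class ExpressionRecord:
    """P-gp abundance in one cell line at one reported extreme.

    ``level`` is one of highest/average/lowest; ``expression`` is in
    fmol P-gp per ug total protein.
    """

    cell_line: str
    level: str
    expression: float

    def __post_init__(self) -> None:
        if self.cell_line not in CELL_LINES:
            raise ValueError(f"unknown cell line {self.cell_line!r}")
        if self.level not in EXPRESSION_LEVELS:
            raise ValueError(f"unknown expression level {self.level!r}")
        if self.expression <= 0:
            raise ValueError("expression must be positive")


@dataclass(frozen=True)
class ClearanceSet:
    """Scaled in vivo BBB clearances and the REF that produced them."""

    cl_passive: float
    cl_pgp: float
    ref: float
    provenance: Tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if self.cl_passive <= 0:
            raise ValueError("cl_passive must be positive")
        if self.cl_pgp < 0:
            raise ValueError("cl_pgp must be non-negative")
        if self.ref <= 0:
            raise ValueError("ref must be positive")


def efflux_ratio(papp_ba: float, papp_ab: float) -> float:
    """Efflux ratio ER = P_app,B:A / P_app,A:B (both in 1e-6 cm/s)."""
    if papp_ba <= 0 or papp_ab <= 0:
        raise ValueError("permeabilities must be positive")
    return papp_ba / papp_ab


def corrected_efflux_ratio(er: float, er_inh: float) -> float:
    """Corrected efflux ratio ER_c = ER / ER[I].

    ER[I] is the efflux ratio with P-gp inhibited (or in the parental
    line); dividing out residual asymmetry isolates P-gp's contribution.
    """
    if er <= 0:
        raise ValueError("er must be positive")
    if er_inh <= 0:
        raise ValueError("er_inh must be positive")
    return er / er_inh


def relative_expression_factor(expr_in_vivo: float, expr_in_vitro: float) -> float:
    """REF = in vivo / in vitro P-gp abundance (both fmol/ug protein)."""
    if expr_in_vivo <= 0 or expr_in_vitro <= 0:
        raise ValueError("expression values must be positive")
    return expr_in_vivo / expr_in_vitro


def passive_clearance(papp_ab_inh: float, sa_bbb: float) -> float:
    """Passive BBB clearance, mL/min.

    ``papp_ab_inh`` in 1e-6 cm/s, ``sa_bbb`` in cm^2; the factor 60
    converts per-second permeability to per-minute clearance.
    """
    if papp_ab_inh is None:
        raise ValueError("record has no P_app,A:B[I] value")
    if papp_ab_inh <= 0 or sa_bbb <= 0:
        raise ValueError("papp_ab_inh and sa_bbb must be positive")
    return papp_ab_inh * 1e-6 * sa_bbb * 60.0


def pgp_clearance(er_c: float, papp_ab_inh: float, sa_bbb_trans: float, ref: float) -> float:
    """P-gp-mediated efflux clearance, mL/min (Kalvass-type scaling).

    ``(er_c - 1) * 2 * papp_ab_inh`` recovers the in vitro active efflux
    permeability from the corrected efflux ratio; it is scaled by the
    transcellular BBB surface and the relative expression factor.  An
    ``er_c`` below 1 (possible with noisy inputs) would imply net influx,
    which the efflux-only scaling cannot represent: the clearance is
    clamped at 0 with a warning.
    """
    if er_c <= 0 or papp_ab_inh <= 0 or sa_bbb_trans <= 0 or ref <= 0:
        raise ValueError("all pgp_clearance inputs must be positive")
    if er_c < 1.0:
        warnings.warn(
            f"er_c = {er_c} < 1 implies net influx; CL_Pgp clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return (er_c - 1.0) * 2.0 * papp_ab_inh * 1e-6 * sa_bbb_trans * ref * 60.0


def build_clearance_set(
    record: TranswellRecord,
    sa_bbb: float,
    sa_bbb_trans: float,
    expr_in_vivo: Optional[float] = None,
    expression: Optional[ExpressionRecord] = None,
    no_ref: bool = False,
    pgp_inhibited: bool = False,
) -> ClearanceSet:
    """Scale one transwell record to an in vivo :class:`ClearanceSet`.

    ``no_ref=True`` uses REF = 1 (in vitro efflux taken at face value);
    ``pgp_inhibited=True`` forces CL_Pgp = 0 (tariquidar co-administration
    scenario, passive pathway only).
    """
    cl_pass = passive_clearance(record.papp_ab_inh, sa_bbb)
    if pgp_inhibited:
        return ClearanceSet(cl_pass, 0.0, 1.0, (record.source, "inhibited"))
    if no_ref:
        ref = 1.0
        level = "no_ref"
    else:
        if expression is None or expr_in_vivo is None:
            raise ValueError("expression record and in vivo expression required unless no_ref")
        if expression.cell_line != record.cell_line:
            raise ValueError(
                f"expression record cell line {expression.cell_line!r} does not match "
                f"transwell record {record.cell_line!r}"
            )
        ref = relative_expression_factor(expr_in_vivo, expression.expression)
        level = expression.level
    cl_pgp = pgp_clearance(record.er_c, record.papp_ab_inh, sa_bbb_trans, ref)
    return ClearanceSet(cl_pass, cl_pgp, ref, (record.source, level))


def summarize_values(values: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and population standard deviation (divisor n).

    The population form reproduces the dispersion statistics conventionally
    printed with literature transport-parameter summaries.
    """
    if len(values) == 0:
        raise ValueError("cannot summarize an empty list")
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, math.sqrt(var)


def fold_range(values: Sequence[float]) -> float:
    """Max/min fold-range of a set of positive values."""
    if len(values) == 0:
        raise ValueError("cannot take the fold range of an empty list")
    if any(v <= 0 for v in values):
        raise ValueError("fold_range requires strictly positive values")
    return max(values) / min(values)
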