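"""Scenario assembly: resolve a bundle + run request into a model spec."""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

from .datasets import LiteratureBundle
from .ivive import build_clearance_set
from .model import CNSModelSpec

__all__ = ["build_spec", "resolve_record"]


def resolve_record(
    bundle: LiteratureBundle,
    drug: str,
    cell_line: Optional[str] = None,
    source: Optional[str] = None,
):
    """Resolve (drug, cell_line, source) to exactly one transwell record."""
    matches = bundle.transwell_records(drug=drug, cell_line=cell_line, source=source)
    if len(matches) == 0:
        keys = [(r.cell_line, r.source) for r in bundle.transwell_records(drug=drug)]
        raise KeyError(
            f"no transwell record for drug={drug!r}, cell_line={cell_line!r}, "
            f"source={source!r}; valid (cell_line, source) pairs: {keys}"
        )
    if len(matches) > 1:
        keys = [(r.cell_line, r.source) for r in matches]
        raise KeyError(
            f"transwell record for drug={drug!r} is ambiguous; "
            f"disambiguate among (cell_line, source): {keys}"
        )
    return matches[0]


def build_spec(
    bundle: LiteratureBundle,
    drug: str,
    regimen_class: str,
    cell_line: Optional[str] = None,
    source: Optional[str] = None,
    expression_level: str = "average",
    pgp_inhibited: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CNSModelSpec:
    """Build a full :class:`CNSModelSpec` for one prediction scenario.

    ``expression_level`` is highest/average/lowest, or ``no_ref`` for the
    REF = 1 scenario.  ``pgp_inhibited`` forces CL_Pgp = 0 (P-gp
    inhibitor co-administration, passive pathway only).
    """
    record = resolve_record(bundle, drug, cell_line, source)
    phys = bundle.physiology
    if pgp_inhibited:
        clearances = build_clearance_set(
            record, phys.sa_bbb, phys.sa_bbb_trans, pgp_inhibited=True
        )
    elif expression_level == "no_ref":
        clearances = build_clearance_set(record, phys.sa_bbb, phys.sa_bbb_trans, no_ref=True)
    else:
        expr = bundle.expression_record(record.cell_line, expression_level)
        clearances = build_clearance_set(
            record,
            phys.sa_bbb,
            phys.sa_bbb_trans,
            expr_in_vivo=bundle.expr_in_vivo,
            expression=expr,
        )
    return CNSModelSpec(
        physiology=phys,
        drug=bundle.drug_properties(drug),
        clearances=clearances,
        plasma=bundle.plasma_params(drug, regimen_class),
        regimen=bundle.regimen(drug, regimen_class),
        rtol=rtol,
        atol=atol,
    )
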