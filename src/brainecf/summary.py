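"""Summary statistics of the literature transport records.

Reproduces the per-drug and per-cell-line descriptive statistics of the
transwell inputs: arithmetic means, population standard deviations and
max/min fold-ranges of P_app,A:B[I] and ER_c, with optional cell-line
family grouping (Caco-2 / MDCKII / LLC-PK1, pooling mdr1a and MDR1
transfectants) and source exclusions.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .datasets import LiteratureBundle
from .ivive import TranswellRecord, fold_range, summarize_values

__all__ = ["CELL_LINE_FAMILY", "summarize_records", "literature_summary"]

CELL_LINE_FAMILY = {
    "Caco-2": "Caco-2",
    "MDCKII-MDR1": "MDCKII",
    "LLC-PK1-mdr1a": "LLC-PK1",
    "LLC-PK1-MDR1": "LLC-PK1",
}


def summarize_records(records: Sequence[TranswellRecord]) -> dict:
    """Mean, population SD and fold-range of P_app[I] and ER_c."""
    if not records:
        raise ValueError("no records to summarize")
    papp = [r.papp_ab_inh for r in records]
    erc = [r.er_c for r in records]
    papp_mean, papp_sd = summarize_values(papp)
    erc_mean, erc_sd = summarize_values(erc)
    return {
        "n": len(records),
        "papp_mean": papp_mean,
        "papp_sd": papp_sd,
        "papp_fold": fold_range(papp),
        "erc_mean": erc_mean,
        "erc_sd": erc_sd,
        "erc_fold": fold_range(erc),
    }


def _filtered(
    bundle: LiteratureBundle,
    drug: Optional[str],
    families: Optional[Iterable[str]],
    exclude_sources: Iterable[str],
):
    records = bundle.transwell_records(drug=drug)
    if families is not None:
        fams = set(families)
        records = [r for r in records if CELL_LINE_FAMILY[r.cell_line] in fams]
    if exclude_sources:
        excl = set(exclude_sources)
        records = [r for r in records if r.source not in excl]
    return records


def literature_summary(
    bundle: LiteratureBundle,
    drug: Optional[str] = None,
    grouping: str = "drug",
    families: Optional[Iterable[str]] = None,
    exclude_sources: Iterable[str] = (),
) -> pd.DataFrame:
    """Grouped summary table of the transport records.

    ``grouping``: "drug" (one row per drug over all cell lines),
    "cell_line" (per drug x cell line) or "family" (per drug x cell-line
    family).  ``families`` restricts the cell lines considered;
    ``exclude_sources`` drops records by citation key before summarizing.
    """
    if grouping not in ("drug", "cell_line", "family"):
        raise ValueError(f"unknown grouping {grouping!r}")
    records = _filtered(bundle, drug, families, exclude_sources)
    if not records:
        raise ValueError("no records match the requested filters")
    rows = []
    if grouping == "drug":
        keyfn = lambda r: (r.drug,)
        keynames = ["drug"]
    elif grouping == "cell_line":
        keyfn = lambda r: (r.drug, r.cell_line)
        keynames = ["drug", "cell_line"]
    else:
        keyfn = lambda r: (r.drug, CELL_LINE_FAMILY[r.cell_line])
        keynames = ["drug", "family"]
    seen = []
    for rec in records:
        key = keyfn(rec)
        if key not in seen:
            seen.append(key)
    for key in seen:
        group = [r for r in records if keyfn(r) == key]
        rows.append({**dict(zip(keynames, key)), **summarize_records(group)})
    return pd.DataFrame(rows)
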