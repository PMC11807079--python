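"""Packaged literature fixtures and their loader.

The bundle collects, as versioned plain-text files inside the package:
transwell transport records, in vitro P-gp expression extremes, the in
vivo expression mean, empirical plasma PK parameters, dosing regimens,
rat CNS physiology and drug physicochemical defaults.  Loading validates
closed vocabularies and referential integrity; failures name the file
and row.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from .ivive import ExpressionRecord, TranswellRecord
from .params import DrugProperties, PhysiologyParams
from .plasma import DoseRegimen, PlasmaPKParameters

__all__ = ["LiteratureBundle", "load_bundle", "default_data_dir"]

_FILES = {
    "transwell": "transwell.csv",
    "expression": "expression.csv",
    "plasma": "plasma_pk.csv",
    "regimens": "regimens.yaml",
    "physiology": "physiology.yaml",
    "drugs": "drugs.yaml",
}


def default_data_dir() -> Path:
    return Path(resources.files("brainecf") / "data")


@dataclass
class LiteratureBundle:
    """Validated in-memory view of the packaged literature tables."""

    transwell: List[TranswellRecord]
    expression: List[ExpressionRecord]
    expr_in_vivo: float
    plasma: Dict[Tuple[str, str], PlasmaPKParameters]
    regimens: Dict[Tuple[str, str], DoseRegimen]
    physiology: PhysiologyParams
    drugs: Dict[str, DrugProperties]
    loading_duration: float
    # raw frames kept for lossless round-tripping
    transwell_df: pd.DataFrame = field(repr=False, default=None)
    expression_df: pd.DataFrame = field(repr=False, default=None)
    plasma_df: pd.DataFrame = field(repr=False, default=None)

    def transwell_records(
        self,
        drug: Optional[str] = None,
        cell_line: Optional[str] = None,
        source: Optional[str] = None,
    ) -> List[TranswellRecord]:
        out = self.transwell
        if drug is not None:
            out = [r for r in out if r.drug == drug]
        if cell_line is not None:
            out = [r for r in out if r.cell_line == cell_line]
        if source is not None:
            out = [r for r in out if r.source == source]
        return out

    def expression_records(self, cell_line: str) -> List[ExpressionRecord]:
        return [r for r in self.expression if r.cell_line == cell_line]

    def expression_record(self, cell_line: str, level: str) -> ExpressionRecord:
        matches = [r for r in self.expression_records(cell_line) if r.level == level]
        if not matches:
            available = sorted(r.level for r in self.expression_records(cell_line))
            raise KeyError(
                f"no {level!r} expression value for {cell_line!r}; available: {available}"
            )
        return matches[0]

    def plasma_params(self, drug: str, regimen_class: str) -> PlasmaPKParameters:
        try:
            return self.plasma[(drug, regimen_class)]
        except KeyError:
            raise KeyError(
                f"no plasma PK parameters for ({drug!r}, {regimen_class!r}); "
                f"available: {sorted(self.plasma)}"
            ) from None

    def regimen(self, drug: str, regimen_class: str) -> DoseRegimen:
        try:
            return self.regimens[(drug, regimen_class)]
        except KeyError:
            raise KeyError(
                f"no regimen for ({drug!r}, {regimen_class!r}); "
                f"available: {sorted(self.regimens)}"
            ) from None

    def drug_properties(self, drug: str) -> DrugProperties:
        try:
            return self.drugs[drug]
        except KeyError:
            raise KeyError(f"unknown drug {drug!r}; available: {sorted(self.drugs)}") from None

    def serialize(self, out_dir) -> None:
        """Write the bundle back as the same set of fixture files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.transwell_df.to_csv(out / _FILES["transwell"], index=False)
        self.expression_df.to_csv(out / _FILES["expression"], index=False)
        self.plasma_df.to_csv(out / _FILES["plasma"], index=False)
        for name in ("regimens", "physiology", "drugs"):
            src = default_data_dir() / _FILES[name]
            (out / _FILES[name]).write_text(src.read_text())


def _read_yaml(path: Path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_bundle(path=None, loading_duration: Optional[float] = None) -> LiteratureBundle:
    """Load and validate the fixture bundle from ``path`` (default: packaged).

    ``loading_duration`` overrides the zero-order administration time (min)
    of loading doses whose infusion time the sources do not report.
    """
    data_dir = Path(path) if path is not None else default_data_dir()
    for key, fname in _FILES.items():
        if not (data_dir / fname).exists():
            raise FileNotFoundError(f"missing fixture file {fname} in {data_dir}")

    # raw frames are read as strings so serialization is byte-identical
    tw_df = pd.read_csv(data_dir / _FILES["transwell"], dtype=str).fillna("")
    transwell = []
    for i, row in tw_df.iterrows():
        try:
            transwell.append(
                TranswellRecord(
                    drug=row["drug"],
                    cell_line=row["cell_line"],
                    papp_ab_inh=float(row["papp_ab_inh"]),
                    er_c=float(row["er_c"]),
                    inhibitor=str(row["inhibitor"]),
                    source=str(row["source"]),
                    note=str(row["note"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{_FILES['transwell']} row {i + 2}: {exc}") from exc

    ex_df = pd.read_csv(data_dir / _FILES["expression"], dtype=str)
    expression = []
    for i, row in ex_df.iterrows():
        try:
            expression.append(
                ExpressionRecord(row["cell_line"], row["level"], float(row["expression"]))
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{_FILES['expression']} row {i + 2}: {exc}") from exc
    # per cell line: highest >= average >= lowest
    for cl in {r.cell_line for r in expression}:
        levels = {r.level: r.expression for r in expression if r.cell_line == cl}
        ordered = [levels[k] for k in ("highest", "average", "lowest") if k in levels]
        if any(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError(f"expression levels for {cl!r} are not ordered: {levels}")

    phys_raw = _read_yaml(data_dir / _FILES["physiology"])
    expr_in_vivo = float(phys_raw.pop("pgp_expression_in_vivo"))
    physiology = PhysiologyParams(**phys_raw)

    drugs_raw = _read_yaml(data_dir / _FILES["drugs"])
    drugs = {name: DrugProperties(name=name, **props) for name, props in drugs_raw.items()}

    pk_df = pd.read_csv(data_dir / _FILES["plasma"], dtype=str).fillna("")
    plasma: Dict[Tuple[str, str], PlasmaPKParameters] = {}
    for i, row in pk_df.iterrows():
        key = (row["drug"], row["regimen_class"])
        if key[0] not in drugs:
            raise ValueError(f"{_FILES['plasma']} row {i + 2}: unknown drug {key[0]!r}")
        ka = None if row["ka"] == "" else float(row["ka"])
        try:
            plasma[key] = PlasmaPKParameters(
                cl_cen=float(row["cl_cen"]),
                v_cen=float(row["v_cen"]),
                q_cen_per1=float(row["q_cen_per1"]),
                q_cen_per2=float(row["q_cen_per2"]),
                v_per1=float(row["v_per1"]),
                v_per2=float(row["v_per2"]),
                ka=ka,
            )
        except ValueError as exc:
            raise ValueError(f"{_FILES['plasma']} row {i + 2}: {exc}") from exc

    reg_raw = _read_yaml(data_dir / _FILES["regimens"])
    load_dur = (
        float(loading_duration)
        if loading_duration is not None
        else float(reg_raw.get("loading_duration_min", 1.0))
    )
    regimens: Dict[Tuple[str, str], DoseRegimen] = {}
    for drug, classes in reg_raw["regimens"].items():
        if drug not in drugs:
            raise ValueError(f"{_FILES['regimens']}: unknown drug {drug!r}")
        for cls_name, cfg in classes.items():
            doses = [
                (
                    float(d["mg_per_kg"]),
                    float(d["start"]),
                    load_dur if d["duration"] is None else float(d["duration"]),
                )
                for d in cfg["doses"]
            ]
            regimens[(drug, cls_name)] = DoseRegimen.from_mg_per_kg(
                cfg["route"], doses, body_weight=physiology.body_weight
            )
            if (drug, cls_name) not in plasma:
                raise ValueError(
                    f"regimen ({drug!r}, {cls_name!r}) has no plasma PK parameters"
                )

    for rec in transwell:  # referential integrity
        if rec.drug not in drugs:
            raise ValueError(f"transwell record references unknown drug {rec.drug!r}")

    return LiteratureBundle(
        transwell=transwell,
        expression=expression,
        expr_in_vivo=expr_in_vivo,
        plasma=plasma,
        regimens=regimens,
        physiology=physiology,
        drugs=drugs,
        loading_duration=load_dur,
        transwell_df=tw_df,
        expression_df=ex_df,
        plasma_df=pk_df,
    )
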