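"""CSV/YAML schemas, readers, writers and input validation.

Schemas
-------
prevalence.csv   wave,ses,age_years,category,prevalence   (ages 0-64)
tr_table.csv     ses,age_group,tau1,tau2,tau3,tau4        (rates in
                 6-significant-digit scientific notation)
population.csv   age_group,pop
mortality.csv    age_group,R
fertility.csv    year,f
params.yaml      mu, theta: [n, w, o], Y, childbearing: [15, 49]
scenario.yaml    label, overrides: [{groups, tau, value, from, to, mode}]
projection.csv   year,ses,age_group,category,count,prevalence
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    AGE_GROUP_LABELS,
    CATEGORY_LABELS,
    MAX_SURVEY_AGE,
    DemographicParams,
    SESGroup,
    SurveyPrevalence,
    TransferenceRateTable,
)
from .scenarios import Override, ScenarioSpec

__all__ = [
    "read_prevalence",
    "write_prevalence",
    "read_tr_tables",
    "write_tr_tables",
    "read_demography",
    "write_demography",
    "read_scenario",
    "write_projection",
    "ValidationReport",
    "validate_prevalence_file",
    "validate_tr_file",
    "validate_inputs",
]


# ---------------------------------------------------------------- prevalence

def read_prevalence(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"wave", "ses", "age_years", "category", "prevalence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_prevalence(waves, path) -> None:
    """Write one or more SurveyPrevalence objects to the long CSV schema."""
    if isinstance(waves, SurveyPrevalence):
        waves = [waves]
    pd.concat([w.to_frame() for w in waves], ignore_index=True).to_csv(
        path, index=False
    )


# ----------------------------------------------------------------- TR tables

def read_tr_tables(path) -> dict[SESGroup, TransferenceRateTable]:
    df = pd.read_csv(path)
    out = {}
    for ses_label in df["ses"].unique():
        ses = SESGroup(ses_label)
        out[ses] = TransferenceRateTable.from_frame(df, ses=ses)
    return out


def write_tr_tables(
    tables: Mapping[SESGroup, TransferenceRateTable] | TransferenceRateTable, path
) -> None:
    """Serialise TR tables with 6-significant-digit scientific notation."""
    if isinstance(tables, TransferenceRateTable):
        tables = {tables.ses: tables}
    frame = pd.concat([t.to_frame() for t in tables.values()], ignore_index=True)
    frame.to_csv(path, index=False, float_format="%.5E")


# ---------------------------------------------------------------- demography

def read_demography(directory) -> tuple[DemographicParams, np.ndarray]:
    """Read the demography CSV set + params.yaml from ``directory``.

    Returns the parameter object and the population-by-age-group vector.
    """
    d = Path(directory)
    pop = pd.read_csv(d / "population.csv").set_index("age_group")
    mort = pd.read_csv(d / "mortality.csv").set_index("age_group")
    fert = pd.read_csv(d / "fertility.csv")
    with open(d / "params.yaml") as fh:
        params = yaml.safe_load(fh)
    pop = pop.reindex(list(AGE_GROUP_LABELS))["pop"]
    mort = mort.reindex(list(AGE_GROUP_LABELS))["R"]
    if pop.isna().any() or mort.isna().any():
        raise ValueError("population/mortality tables missing age-group rows")
    demo = DemographicParams(
        mortality=mort.to_numpy(),
        fertility=dict(zip(fert["year"].astype(int), fert["f"].astype(float))),
        mu=float(params["mu"]),
        theta=np.asarray(params["theta"], dtype=float),
        Y=float(params.get("Y", 5.0)),
        childbearing=tuple(params.get("childbearing", (15, 49))),
    )
    return demo, pop.to_numpy(dtype=float)


def write_demography(
    demo: DemographicParams, populations: np.ndarray, directory
) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"age_group": list(AGE_GROUP_LABELS), "pop": populations}
    ).to_csv(d / "population.csv", index=False)
    pd.DataFrame(
        {"age_group": list(AGE_GROUP_LABELS), "R": demo.mortality}
    ).to_csv(d / "mortality.csv", index=False)
    years = sorted(demo.fertility)
    pd.DataFrame(
        {"year": years, "f": [demo.fertility[y] for y in years]}
    ).to_csv(d / "fertility.csv", index=False)
    with open(d / "params.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "mu": float(demo.mu),
                "theta": [float(x) for x in demo.theta],
                "Y": float(demo.Y),
                "childbearing": list(demo.childbearing),
            },
            fh,
        )


# ------------------------------------------------------------------ scenario

def read_scenario(path) -> ScenarioSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    overrides = []
    for o in raw.get("overrides", []):
        overrides.append(
            Override(
                age_groups=tuple(o["groups"]),
                tau_index=int(o["tau"]),
                value=float(o["value"]),
                start=float(o["from"]),
                end=float(o["to"]),
                mode=o.get("mode", "floor"),
            )
        )
    return ScenarioSpec(label=raw.get("label", Path(path).stem), overrides=tuple(overrides))


# ---------------------------------------------------------------- projection

def write_projection(result, path) -> None:
    result.frame.to_csv(path, index=False)


# ---------------------------------------------------------------- validation

@dataclass
class ValidationReport:
    """Accumulated schema violations, each tagged file/row/rule."""

    violations: list[dict] = field(default_factory=list)

    def add(self, file: str, row, rule: str, message: str) -> None:
        self.violations.append(
            {"file": str(file), "row": row, "rule": rule, "message": message}
        )

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "all inputs valid"
        lines = [f"{len(self.violations)} violation(s):"]
        for v in self.violations:
            lines.append(
                f"  {v['file']}:{v['row']}: [{v['rule']}] {v['message']}"
            )
        return "\n".join(lines)


def validate_prevalence_file(path, report: ValidationReport | None = None):
    """Schema, range and simplex checks for a prevalence CSV."""
    report = report if report is not None else ValidationReport()
    try:
        df = read_prevalence(path)
    except Exception as exc:
        report.add(path, "-", "schema", str(exc))
        return report
    bad_cat = df[~df["category"].isin(CATEGORY_LABELS)]
    for idx in bad_cat.index:
        report.add(path, int(idx), "category", f"unknown category {df.loc[idx, 'category']!r}")
    bad_age = df[(df["age_years"] < 0) | (df["age_years"] > MAX_SURVEY_AGE)]
    for idx in bad_age.index:
        report.add(path, int(idx), "age", f"age {df.loc[idx, 'age_years']} outside 0-{MAX_SURVEY_AGE}")
    bad_p = df[(df["prevalence"] < 0) | (df["prevalence"] > 1)]
    for idx in bad_p.index:
        report.add(path, int(idx), "range", f"prevalence {df.loc[idx, 'prevalence']} outside [0, 1]")
    sums = df.groupby(["wave", "ses", "age_years"])["prevalence"].sum()
    for key, s in sums.items():
        if abs(s - 1.0) > 1e-6:
            report.add(path, str(key), "simplex", f"prevalences sum to {s:.6f}, not 1")
    return report


def validate_tr_file(path, report: ValidationReport | None = None):
    report = report if report is not None else ValidationReport()
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        report.add(path, "-", "schema", str(exc))
        return report
    required = {"ses", "age_group", "tau1", "tau2", "tau3", "tau4"}
    missing = required - set(df.columns)
    if missing:
        report.add(path, "-", "schema", f"missing columns {sorted(missing)}")
        return report
    for idx, row in df.iterrows():
        taus = [row[f"tau{k}"] for k in range(1, 5)]
        if any(t < 0 or t > 1 for t in taus):
            report.add(path, int(idx), "range", f"tau outside [0, 1]: {taus}")
        if row["tau2"] + row["tau4"] > 1.0 + 1e-12:
            report.add(path, int(idx), "feasibility", "tau2 + tau4 > 1")
        if row["age_group"] not in AGE_GROUP_LABELS:
            report.add(path, int(idx), "age_group", f"unknown age group {row['age_group']!r}")
    return report


def validate_inputs(
    *,
    prevalence=None,
    tr_tables=None,
    demography=None,
) -> ValidationReport:
    """Validate a set of input files; every violation is reported with its
    file, row and rule."""
    report = ValidationReport()
    for path in np.atleast_1d(prevalence if prevalence is not None else []):
        validate_prevalence_file(path, report)
    for path in np.atleast_1d(tr_tables if tr_tables is not None else []):
        validate_tr_file(path, report)
    if demography is not None:
        try:
            demo, pop = read_demography(demography)
            if np.any(pop < 0):
                report.add(demography, "-", "range", "negative population")
        except Exception as exc:
            report.add(demography, "-", "schema", str(exc))
    return report
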