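"""Long-format cohort reading/writing and rule-based label derivation.

The on-disk interchange format is a delimiter-separated UTF-8 table with one
row per patient-visit: columns ``patient_id``, ``time`` (years since the
patient's first visit), then one column per schema variable.  Empty cells
mean "not observed".  Static variables are repeated on each of the patient's
rows; the first observed value wins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import Cohort, CohortSchema, LabelRule, PatientRecord, SchemaError


class DialectError(ValueError):
    """The table violates the long-format contract (e.g. duplicate visits)."""


def read_cohort(path_or_df, schema: CohortSchema, sep: str = ",") -> Cohort:
    """Read a long-format table into a :class:`Cohort`.

    Accepts a file path or an already-loaded DataFrame.  Visits are sorted by
    time within each patient; cells missing from the table are flagged
    unobserved.  Unknown variable columns raise :class:`SchemaError`,
    duplicated (patient, time) rows raise :class:`DialectError`.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep=sep)
    required = {"patient_id", "time"}
    if not required <= set(df.columns):
        raise DialectError("table must have patient_id and time columns")
    extra = set(df.columns) - required - set(
        v.name for v in schema.variables)
    if extra:
        raise SchemaError(f"unknown columns not in schema: {sorted(extra)}")

    dup = df.duplicated(subset=["patient_id", "time"], keep=False)
    if dup.any():
        rows = df.loc[dup, ["patient_id", "time"]].head(10)
        raise DialectError(
            f"duplicated (patient_id, time) rows:\n{rows.to_string(index=False)}")

    tnames = schema.temporal_names
    snames = schema.static_names
    patients = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("time")
        T = len(grp)
        values = np.full((T, schema.D), np.nan)
        observed = np.zeros((T, schema.D), dtype=bool)
        for j, name in enumerate(tnames):
            if name in grp.columns:
                col = pd.to_numeric(grp[name], errors="coerce").to_numpy()
                obs = ~np.isnan(col)
                values[obs, j] = col[obs]
                observed[:, j] = obs
        svals = np.full(schema.N, np.nan)
        sobs = np.zeros(schema.N, dtype=bool)
        for j, name in enumerate(snames):
            if name in grp.columns:
                col = pd.to_numeric(grp[name], errors="coerce").dropna()
                if len(col):
                    svals[j] = col.iloc[0]
                    sobs[j] = True
        patients.append(PatientRecord(
            patient_id=str(pid), static_values=svals, static_observed=sobs,
            times=grp["time"].to_numpy(float), values=values,
            observed=observed))
    return Cohort(schema, patients)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Inverse of :func:`read_cohort`: emit the long-format table."""
    schema = cohort.schema
    rows = []
    for p in cohort:
        for i in range(p.T):
            row: dict = {"patient_id": p.patient_id, "time": p.times[i]}
            for j, name in enumerate(schema.temporal_names):
                row[name] = p.values[i, j] if p.observed[i, j] else np.nan
            for j, name in enumerate(schema.static_names):
                row[name] = (p.static_values[j]
                             if p.static_observed[j] else np.nan)
            rows.append(row)
    cols = ["patient_id", "time"] + schema.temporal_names + schema.static_names
    return pd.DataFrame(rows, columns=cols)


def write_cohort(cohort: Cohort, path, sep: str = ",") -> None:
    cohort_to_frame(cohort).to_csv(path, sep=sep, index=False)


def derive_labels(cohort: Cohort, rules: list[LabelRule]) -> Cohort:
    """Fill guided-label columns per visit by evaluating clinical rules.

    A label is set only where every variable the rule references is observed
    at that visit; otherwise it stays unobserved, so rule-derived labels
    propagate missingness instead of guessing.
    """
    schema = cohort.schema
    tnames = schema.temporal_names
    col = {n: j for j, n in enumerate(tnames)}
    for rule in rules:
        if rule.target not in schema:
            raise SchemaError(f"rule targets unknown variable {rule.target!r}")
        if schema[rule.target].role != "guided_label":
            raise SchemaError(f"rule target {rule.target!r} is not a guided label")
        for name in rule.referenced():
            if name not in col:
                raise SchemaError(
                    f"rule for {rule.target!r} references unknown or "
                    f"non-temporal variable {name!r}")

    out_patients = []
    for p in cohort:
        values = p.values.copy()
        observed = p.observed.copy()
        for rule in rules:
            tj = col[rule.target]
            refs = sorted(rule.referenced())
            ref_idx = [col[n] for n in refs]
            for i in range(p.T):
                if all(p.observed[i, k] for k in ref_idx):
                    row = {n: p.values[i, col[n]] for n in refs}
                    values[i, tj] = rule.evaluate(row)
                    observed[i, tj] = True
                else:
                    values[i, tj] = np.nan
                    observed[i, tj] = False
        out_patients.append(PatientRecord(
            patient_id=p.patient_id, static_values=p.static_values,
            static_observed=p.static_observed, times=p.times,
            values=values, observed=observed))
    return Cohort(schema, out_patients)


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-variable missingness plus cohort-level visit statistics.

    Returns a tidy frame with one row per temporal variable (fraction of
    unobserved patient-visit cells) and attaches cohort totals in ``attrs``:
    number of patients, number of visits, and mean visits per patient.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n_visits = sum(p.T for p in cohort)
    obs = np.concatenate([p.observed for p in cohort], axis=0)
    frac_missing = 1.0 - obs.mean(axis=0)
    df = pd.DataFrame({
        "variable": cohort.schema.temporal_names,
        "missing_fraction": frac_missing,
    })
    df.attrs["n_patients"] = len(cohort)
    df.attrs["n_visits"] = n_visits
    df.attrs["mean_visits_per_patient"] = n_visits / len(cohort)
    return df
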