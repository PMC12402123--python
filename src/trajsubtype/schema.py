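"""Cohort data model: variable schema, patient records and label rules.

A cohort is a set of irregularly sampled multi-organ patient trajectories.
Each variable is continuous, binary or ordinal and plays one of three roles:

* ``temporal_input`` — fed to the encoder (the input set X),
* ``guided_label`` — an organ involvement/severity outcome (the guided set
  G); guided variables are *also* fed to the encoder, so G is a subset of X,
* ``static`` — per-patient demographics (the static set S).

Guided labels are usually not recorded directly but derived per visit from
raw variables by clinician-authored :class:`LabelRule` expressions
(comparators ``<, <=, ==, >, >=`` combined with ``any``/``all``/``not``),
mirroring how consensus clinical definitions turn raw measurements into
organ involvement and severity stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

ORGANS = (
    "skin", "digital_ulcers", "joints", "muscles",
    "lungs", "heart", "kidneys", "gastrointestinal",
)

KINDS = ("continuous", "binary", "ordinal")
ROLES = ("temporal_input", "guided_label", "static")
LABEL_TYPES = ("involvement", "severity")


class SchemaError(ValueError):
    """A variable specification or rule violates the schema contract."""


@dataclass(frozen=True)
class VariableSpec:
    name: str
    kind: str
    role: str
    organ: Optional[str] = None
    n_levels: Optional[int] = None
    label_type: Optional[str] = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.organ is not None and self.organ not in ORGANS:
            raise SchemaError(f"unknown organ {self.organ!r} for {self.name!r}")
        if self.role == "guided_label":
            if self.organ is None or self.label_type is None:
                raise SchemaError(
                    f"guided label {self.name!r} needs organ and label_type")
            if self.label_type not in LABEL_TYPES:
                raise SchemaError(f"bad label_type for {self.name!r}")
        if self.kind == "ordinal":
            if self.n_levels is None or self.n_levels < 2:
                raise SchemaError(
                    f"ordinal {self.name!r} needs n_levels >= 2")
        if self.kind == "binary" and self.n_levels not in (None, 2):
            raise SchemaError(f"binary {self.name!r} has fixed n_levels=2")

    @property
    def levels(self) -> int:
        if self.kind == "binary":
            return 2
        if self.kind == "ordinal":
            return int(self.n_levels)
        raise SchemaError(f"{self.name!r} is continuous, has no levels")


@dataclass
class CohortSchema:
    """Variable list plus derived dimension counts.

    ``temporal_names`` covers both plain inputs and guided labels (G ⊆ X):
    a guided variable's observed value is an encoder input *and* a guidance
    target.  D counts temporal variables, P guided variables, N statics.
    """

    variables: list[VariableSpec]

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("variable names must be unique")
        if self.P < 1:
            raise SchemaError("schema needs at least one guided label")
        if self.D < self.P:
            raise SchemaError("temporal variable count must cover guided set")

    # -- dimension accessors ----------------------------------------------
    @property
    def temporal(self) -> list[VariableSpec]:
        return [v for v in self.variables
                if v.role in ("temporal_input", "guided_label")]

    @property
    def guided(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.role == "guided_label"]

    @property
    def static(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.role == "static"]

    @property
    def D(self) -> int:
        return len(self.temporal)

    @property
    def P(self) -> int:
        return len(self.guided)

    @property
    def N(self) -> int:
        return len(self.static)

    @property
    def temporal_names(self) -> list[str]:
        return [v.name for v in self.temporal]

    @property
    def guided_names(self) -> list[str]:
        return [v.name for v in self.guided]

    @property
    def static_names(self) -> list[str]:
        return [v.name for v in self.static]

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"variables": [
            {k: getattr(v, k) for k in
             ("name", "kind", "role", "organ", "n_levels", "label_type")
             if getattr(v, k) is not None}
            for v in self.variables]}

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSchema":
        return cls([VariableSpec(**spec) for spec in d["variables"]])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        import hashlib
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PatientRecord:
    """One patient's longitudinal record.

    ``times`` are years since the first recorded visit, strictly increasing;
    ``values``/``observed`` are (T, D) over the schema's temporal variables
    (observed=True means the cell was measured).
    """

    patient_id: str
    static_values: np.ndarray          # (N,)
    static_observed: np.ndarray        # (N,) bool
    times: np.ndarray                  # (T,)
    values: np.ndarray                 # (T, D)
    observed: np.ndarray               # (T, D) bool

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.times.size < 1:
            raise SchemaError(f"{self.patient_id}: needs at least one visit")
        if np.any(np.diff(self.times) <= 0):
            raise SchemaError(
                f"{self.patient_id}: visit times must strictly increase")
        if self.values.shape != self.observed.shape or \
                self.values.shape[0] != self.times.size:
            raise SchemaError(f"{self.patient_id}: shape mismatch")

    @property
    def T(self) -> int:
        return int(self.times.size)


@dataclass
class Cohort:
    schema: CohortSchema
    patients: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self):
        D, N = self.schema.D, self.schema.N
        for p in self.patients:
            if p.values.shape[1] != D or p.static_values.shape[0] != N:
                raise SchemaError(f"{p.patient_id}: does not conform to schema")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def subset(self, ids) -> "Cohort":
        wanted = set(ids)
        return Cohort(self.schema,
                      [p for p in self.patients if p.patient_id in wanted])


# ---------------------------------------------------------------------------
# Label rules
# ---------------------------------------------------------------------------

_OPS = {
    "<": np.less, "<=": np.less_equal, "==": np.equal,
    ">": np.greater, ">=": np.greater_equal,
}


def _rule_vars(expr) -> set[str]:
    if "var" in expr:
        return {expr["var"]}
    for comb in ("any", "all"):
        if comb in expr:
            return set().union(*(_rule_vars(e) for e in expr[comb]))
    if "not" in expr:
        return _rule_vars(expr["not"])
    raise SchemaError(f"malformed rule expression: {expr!r}")


def _eval_expr(expr, row: dict) -> bool:
    if "var" in expr:
        op = expr["op"]
        if op not in _OPS:
            raise SchemaError(f"unknown comparator {op!r}")
        return bool(_OPS[op](row[expr["var"]], expr["value"]))
    if "any" in expr:
        return any(_eval_expr(e, row) for e in expr["any"])
    if "all" in expr:
        return all(_eval_expr(e, row) for e in expr["all"])
    if "not" in expr:
        return not _eval_expr(expr["not"], row)
    raise SchemaError(f"malformed rule expression: {expr!r}")


@dataclass
class LabelRule:
    """Derives one guided label per visit from raw temporal variables.

    Involvement rules hold a single boolean expression.  Severity staging
    rules hold an ordered list of ``(expression, level)`` stages evaluated
    first-match-wins, with ``default_level`` when no stage matches.
    The label is set only when every referenced variable is observed at the
    visit; otherwise the label is unobserved there.
    """

    target: str
    expr: Optional[dict] = None
    stages: Optional[list] = None          # list of {"when": expr, "level": int}
    default_level: Optional[int] = None

    def referenced(self) -> set[str]:
        if self.expr is not None:
            return _rule_vars(self.expr)
        out: set[str] = set()
        for stage in self.stages:
            out |= _rule_vars(stage["when"])
        return out

    def evaluate(self, row: dict) -> float:
        if self.expr is not None:
            return float(_eval_expr(self.expr, row))
        for stage in self.stages:
            if _eval_expr(stage["when"], row):
                return float(stage["level"])
        if self.default_level is None:
            raise SchemaError(f"rule for {self.target!r}: no stage matched "
                              "and no default level")
        return float(self.default_level)

    def to_dict(self) -> dict:
        d: dict = {"target": self.target}
        if self.expr is not None:
            d["expr"] = self.expr
        else:
            d["stages"] = self.stages
            if self.default_level is not None:
                d["default_level"] = self.default_level
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LabelRule":
        return cls(target=d["target"], expr=d.get("expr"),
                   stages=d.get("stages"),
                   default_level=d.get("default_level"))


def load_rules(path) -> list[LabelRule]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [LabelRule.from_dict(d) for d in doc["rules"]]


def save_rules(rules: list[LabelRule], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"rules": [r.to_dict() for r in rules]}, fh,
                       sort_keys=False)
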