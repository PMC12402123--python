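"""Inclusion filtering, train-split normalization, encoding and CV splits.

Encoding follows registry-modelling convention: continuous variables are
standardized with train-split mean/sd, binary and ordinal variables are
one-hot expanded, and unobserved cells are filled with the train-derived
placeholder (0 for a standardized continuous variable, the training class
frequency vector for a one-hot block) while a boolean mask records true
observedness.  The model later consumes value and mask channels side by side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .schema import Cohort, CohortSchema, PatientRecord, VariableSpec


# ---------------------------------------------------------------------------
# Inclusion filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str     # one of: min_visits, max_visits, min_age


def apply_inclusion_filters(
    cohort: Cohort,
    min_visits: int = 2,
    max_visits: int = 14,
    min_age: float = 18.0,
    outlier_sd: float = 5.0,
    age_variable: str = "age",
    stats: "NormalizationStats | None" = None,
) -> tuple[Cohort, list[Exclusion]]:
    """Apply the registry inclusion window and outlier masking.

    Patients with fewer than ``min_visits`` or more than ``max_visits``
    visits are excluded (heavily sampled trajectories would otherwise bias
    training), as are patients younger than ``min_age`` at their first
    recorded visit.  Continuous temporal values more than ``outlier_sd``
    standard deviations from the mean are set to unobserved rather than
    dropping the patient.  ``stats`` supplies the means/sds; when omitted
    they are estimated once from the cohort passed in (passing fixed stats
    makes the operation idempotent).
    """
    schema = cohort.schema
    if stats is None:
        stats = fit_normalization(cohort, _warn=False)

    age_static_idx = (schema.static_names.index(age_variable)
                      if age_variable in schema.static_names else None)
    age_temporal_idx = (schema.temporal_names.index(age_variable)
                        if age_variable in schema.temporal_names else None)

    kept: list[PatientRecord] = []
    log: list[Exclusion] = []
    for p in cohort:
        if p.T < min_visits:
            log.append(Exclusion(p.patient_id, "min_visits"))
            continue
        if p.T > max_visits:
            log.append(Exclusion(p.patient_id, "max_visits"))
            continue
        age = None
        if age_static_idx is not None and p.static_observed[age_static_idx]:
            age = p.static_values[age_static_idx]
        elif age_temporal_idx is not None and p.observed[0, age_temporal_idx]:
            age = p.values[0, age_temporal_idx]
        if age is not None and age < min_age:
            log.append(Exclusion(p.patient_id, "min_age"))
            continue
        values = p.values.copy()
        observed = p.observed.copy()
        for j, v in enumerate(schema.temporal):
            if v.kind != "continuous":
                continue
            mean, sd = stats.mean[v.name], stats.sd[v.name]
            z = np.abs((values[:, j] - mean) / sd)
            bad = observed[:, j] & (z > outlier_sd)
            observed[bad, j] = False
            values[bad, j] = np.nan
        kept.append(PatientRecord(
            patient_id=p.patient_id, static_values=p.static_values,
            static_observed=p.static_observed, times=p.times,
            values=values, observed=observed))
    if not kept:
        raise ValueError("no patients remain after inclusion filtering")
    return Cohort(schema, kept), log


def write_exclusion_log(log: list[Exclusion], path) -> None:
    with open(path, "w") as fh:
        for e in log:
            fh.write(f"{e.patient_id}\t{e.reason}\n")


# ---------------------------------------------------------------------------
# Normalization statistics
# ---------------------------------------------------------------------------

@dataclass
class NormalizationStats:
    """Train-split statistics used for encoding.

    Continuous variables carry (mean, sd); a variable constant in training
    gets sd=1 and a degeneracy flag so standardization stays defined.
    Categorical variables carry their schema level set and training class
    frequencies (the soft one-hot placeholder for unobserved cells).
    """

    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    levels: dict = field(default_factory=dict)      # name -> list of ints
    freqs: dict = field(default_factory=dict)       # name -> ndarray
    degenerate: set = field(default_factory=set)
    never_observed: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "levels": {k: list(map(int, v)) for k, v in self.levels.items()},
            "freqs": {k: list(map(float, v)) for k, v in self.freqs.items()},
            "degenerate": sorted(self.degenerate),
            "never_observed": sorted(self.never_observed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]),
                   levels={k: list(v) for k, v in d["levels"].items()},
                   freqs={k: np.asarray(v, float)
                          for k, v in d["freqs"].items()},
                   degenerate=set(d["degenerate"]),
                   never_observed=set(d["never_observed"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NormalizationStats":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_normalization(train: Cohort, _warn: bool = True) -> NormalizationStats:
    """Compute means/sds and class frequencies over observed train entries."""
    if len(train) == 0:
        raise ValueError("cannot fit normalization on an empty cohort")
    schema = train.schema
    stats = NormalizationStats()

    def pooled(var_list, get_cols):
        vals, obs = get_cols()
        for j, v in enumerate(var_list):
            col = vals[:, j][obs[:, j]]
            if col.size == 0:
                stats.never_observed.add(v.name)
                if _warn:
                    warnings.warn(
                        f"variable {v.name!r} never observed in training; "
                        "placeholder statistics used", stacklevel=3)
            if v.kind == "continuous":
                mean = float(col.mean()) if col.size else 0.0
                sd = float(col.std(ddof=0)) if col.size else 1.0
                if sd == 0.0:
                    sd = 1.0
                    stats.degenerate.add(v.name)
                stats.mean[v.name] = mean
                stats.sd[v.name] = sd
            else:
                lv = list(range(v.levels))
                counts = np.array([(col == l).sum() for l in lv], float)
                if counts.sum() == 0:
                    freqs = np.full(len(lv), 1.0 / len(lv))
                else:
                    freqs = counts / counts.sum()
                stats.levels[v.name] = lv
                stats.freqs[v.name] = freqs

    pooled(schema.temporal, lambda: (
        np.concatenate([p.values for p in train], axis=0),
        np.concatenate([p.observed for p in train], axis=0)))
    pooled(schema.static, lambda: (
        np.stack([p.static_values for p in train], axis=0),
        np.stack([p.static_observed for p in train], axis=0)))
    return stats


# ---------------------------------------------------------------------------
# Encoded cohort
# ---------------------------------------------------------------------------

@dataclass
class EncodingLayout:
    """Column bookkeeping for the one-hot-expanded encoder input."""

    schema: CohortSchema
    col_slices: list[slice]          # per temporal variable
    static_slices: list[slice]       # per static variable
    D_enc: int
    S_enc: int
    placeholder: np.ndarray          # (D_enc,) train-mean placeholder row
    static_placeholder: np.ndarray   # (S_enc,)
    guided_idx: list[int]            # guided variables' indices in temporal order

    @property
    def guided_specs(self) -> list[VariableSpec]:
        return [self.schema.temporal[j] for j in self.guided_idx]


@dataclass
class EncodedPatient:
    patient_id: str
    x: np.ndarray        # (T, D_enc) encoder input with placeholders
    m: np.ndarray        # (T, D_enc) bool, True = observed
    t_val: np.ndarray    # (T, D) per-variable target (std value / level index)
    t_obs: np.ndarray    # (T, D) bool
    s: np.ndarray        # (S_enc,)
    times: np.ndarray    # (T,)

    @property
    def T(self) -> int:
        return int(self.times.size)

    def g_val(self, layout: EncodingLayout) -> np.ndarray:
        return self.t_val[:, layout.guided_idx]

    def g_obs(self, layout: EncodingLayout) -> np.ndarray:
        return self.t_obs[:, layout.guided_idx]


@dataclass
class EncodedCohort:
    layout: EncodingLayout
    stats: NormalizationStats
    patients: list[EncodedPatient]

    def __len__(self):
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def subset(self, ids) -> "EncodedCohort":
        wanted = set(ids)
        return EncodedCohort(self.layout, self.stats,
                             [p for p in self.patients
                              if p.patient_id in wanted])


def build_layout(schema: CohortSchema, stats: NormalizationStats) -> EncodingLayout:
    col_slices, off = [], 0
    placeholder = []
    for v in schema.temporal:
        w = 1 if v.kind == "continuous" else v.levels
        col_slices.append(slice(off, off + w))
        placeholder.extend([0.0] if v.kind == "continuous"
                           else list(stats.freqs[v.name]))
        off += w
    D_enc = off
    static_slices, soff = [], 0
    s_placeholder = []
    for v in schema.static:
        w = 1 if v.kind == "continuous" else v.levels
        static_slices.append(slice(soff, soff + w))
        s_placeholder.extend([0.0] if v.kind == "continuous"
                             else list(stats.freqs[v.name]))
        soff += w
    guided_idx = [j for j, v in enumerate(schema.temporal)
                  if v.role == "guided_label"]
    return EncodingLayout(
        schema=schema, col_slices=col_slices, static_slices=static_slices,
        D_enc=D_enc, S_enc=soff,
        placeholder=np.array(placeholder),
        static_placeholder=np.array(s_placeholder),
        guided_idx=guided_idx)


def _encode_cell(v: VariableSpec, value: float, stats: NormalizationStats):
    if v.kind == "continuous":
        return np.array([(value - stats.mean[v.name]) / stats.sd[v.name]])
    level = int(round(value))
    if level not in stats.levels[v.name]:
        raise ValueError(
            f"variable {v.name!r}: category level {level} unseen in training")
    out = np.zeros(len(stats.levels[v.name]))
    out[stats.levels[v.name].index(level)] = 1.0
    return out


def encode(cohort: Cohort, stats: NormalizationStats) -> EncodedCohort:
    """Standardize/one-hot a cohort using train-derived statistics."""
    schema = cohort.schema
    layout = build_layout(schema, stats)
    patients = []
    for p in cohort:
        T = p.T
        x = np.tile(layout.placeholder, (T, 1))
        m = np.zeros((T, layout.D_enc), dtype=bool)
        t_val = np.full((T, schema.D), np.nan)
        for j, v in enumerate(schema.temporal):
            sl = layout.col_slices[j]
            for i in range(T):
                if p.observed[i, j]:
                    x[i, sl] = _encode_cell(v, p.values[i, j], stats)
                    m[i, sl] = True
                    t_val[i, j] = ((p.values[i, j] - stats.mean[v.name])
                                   / stats.sd[v.name]
                                   if v.kind == "continuous"
                                   else int(round(p.values[i, j])))
        s = layout.static_placeholder.copy()
        for j, v in enumerate(schema.static):
            if p.static_observed[j]:
                s[layout.static_slices[j]] = _encode_cell(
                    v, p.static_values[j], stats)
        patients.append(EncodedPatient(
            patient_id=p.patient_id, x=x, m=m, t_val=t_val,
            t_obs=p.observed.copy(), s=s, times=p.times.copy()))
    return EncodedCohort(layout, stats, patients)


# ---------------------------------------------------------------------------
# Train/test split and CV folds
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    folds: list[list[str]]
    seed: int

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"train_ids": self.train_ids, "test_ids": self.test_ids,
                       "folds": self.folds, "seed": self.seed}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SplitPlan":
        with open(path) as fh:
            d = json.load(fh)
        return cls(train_ids=d["train_ids"], test_ids=d["test_ids"],
                   folds=[list(f) for f in d["folds"]], seed=d["seed"])


def make_split(ids, test_frac: float = 0.15, k_folds: int = 5,
               seed: int = 0) -> SplitPlan:
    """Reproducible held-out split plus k disjoint CV validation folds.

    The test count is floored (remainder goes to training); folds partition
    the training ids.
    """
    ids = list(ids)
    if len(ids) < k_folds + 1:
        raise ValueError(f"need at least {k_folds + 1} ids, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_test = int(np.floor(len(ids) * test_frac))
    test_ids = sorted(shuffled[:n_test])
    train_shuffled = shuffled[n_test:]
    folds = [sorted(f) for f in np.array_split(train_shuffled, k_folds)]
    return SplitPlan(train_ids=sorted(train_shuffled), test_ids=test_ids,
                     folds=[list(map(str, f)) for f in folds], seed=seed)
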