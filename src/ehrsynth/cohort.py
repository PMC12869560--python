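"""Cohort handling: linked-table I/O, code aggregation, tokenization, splits.

The on-disk layout is three delimited-text tables sharing ``patient_id``
keys — ``patients`` (statics), ``visits`` (timestamps, event type,
categorical and continuous values) and ``diagnoses`` (one row per visit
code).  In memory a cohort is a list of :class:`~ehrsynth.records.PatientRecord`.
For the generator, records are discretized into a :class:`TokenizedCohort`:
per-patient binary vectors over a flat vocabulary of code, band, static,
label and special tokens.
"""

from __future__ import annotations

import hashlib
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import PatientRecord, PatientSkeleton, Visit, VisitSkeleton
from .schema import (
    BINARY_LABEL,
    CATEGORICAL,
    CONTINUOUS,
    CodeSystemSpec,
    CohortSchema,
    SchemaError,
)

SOR, EOR, EOV = "<sor>", "<eor>", "<eov>"


class IntegrityError(ValueError):
    """A token vector violates a structural invariant."""


# ---------------------------------------------------------------------------
# linked-table I/O
# ---------------------------------------------------------------------------


@dataclass
class LoadReport:
    n_patients: int = 0
    n_visits: int = 0
    orphan_visits: int = 0
    unparseable_rows: int = 0
    capped_patients: int = 0


def _parse_ts(x):
    if x is None or (isinstance(x, float) and np.isnan(x)) or x == "":
        return None
    ts = pd.to_datetime(x, errors="coerce")
    return None if pd.isna(ts) else ts.to_pydatetime()


def load_cohort(
    patients_table,
    visits_table,
    diagnoses_table,
    schema: CohortSchema,
) -> tuple[list[PatientRecord], LoadReport]:
    """Assemble patient records from the three linked tables.

    Tables may be paths (comma- or tab-separated, sniffed from suffix) or
    DataFrames.  Visits are grouped per patient and chronologically sorted;
    visits beyond ``schema.max_visits`` are dropped from the end; visit rows
    whose patient is absent from the patients table are skipped and counted.
    """
    pat = _as_df(patients_table)
    vis = _as_df(visits_table)
    dx = _as_df(diagnoses_table)

    for df, cols, name in (
        (pat, ["patient_id"], "patients"),
        (vis, ["patient_id", "visit_id", "start_time"], "visits"),
        (dx, ["patient_id", "visit_id", "code"], "diagnoses"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{name} table missing key columns: {missing}")

    report = LoadReport()
    codes_by_visit: dict[tuple[str, str], set[str]] = defaultdict(set)
    for row in dx.itertuples(index=False):
        codes_by_visit[(str(row.patient_id), str(row.visit_id))].add(str(row.code))

    records: dict[str, PatientRecord] = {}
    static_names = [f.name for f in schema.static_fields]
    for row in pat.to_dict("records"):
        pid = str(row["patient_id"])
        statics = {}
        for f in schema.static_fields:
            val = row.get(f.name)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                continue
            if f.kind == CONTINUOUS:
                statics[f.name] = float(val)
            elif f.kind == BINARY_LABEL:
                statics[f.name] = bool(int(val))
            else:
                statics[f.name] = str(val)
        records[pid] = PatientRecord(patient_id=pid, statics=statics)

    cat_names = [f.name for f in schema.categorical_visit_fields]
    cont_names = [f.name for f in schema.continuous_visit_fields]
    for row in vis.to_dict("records"):
        pid = str(row["patient_id"])
        rec = records.get(pid)
        if rec is None:
            report.orphan_visits += 1
            continue
        start = _parse_ts(row.get("start_time"))
        if start is None:
            report.unparseable_rows += 1
            continue
        v = Visit(
            start_time=start,
            end_time=_parse_ts(row.get("end_time")) if schema.has_end_times else None,
            event_type=str(row["event_type"]) if row.get("event_type") is not None else None,
            codes=codes_by_visit.get((pid, str(row["visit_id"])), set()),
        )
        for name in cat_names:
            val = row.get(name)
            if val is not None and not (isinstance(val, float) and np.isnan(val)) and val != "":
                v.categoricals[name] = str(val)
        for name in cont_names:
            val = row.get(name)
            if val is not None and not (isinstance(val, float) and np.isnan(val)) and val != "":
                v.continuous[name] = float(val)
        rec.visits.append(v)
        report.n_visits += 1

    out = []
    for rec in records.values():
        rec.sort_visits()
        if len(rec.visits) > schema.max_visits:
            rec.visits = rec.visits[: schema.max_visits]
            report.capped_patients += 1
        out.append(rec)
    report.n_patients = len(out)
    if report.orphan_visits:
        warnings.warn(f"skipped {report.orphan_visits} orphan visit rows")
    return out, report


def _as_df(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    path = Path(table)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def write_cohort(records: Sequence[PatientRecord], schema: CohortSchema, outdir) -> None:
    """Write a cohort back in the identical three-table layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prows, vrows, drows = [], [], []
    for rec in records:
        prow = {"patient_id": rec.patient_id}
        for f in schema.static_fields:
            val = rec.statics.get(f.name)
            if f.kind == BINARY_LABEL and val is not None:
                val = int(val)
            prow[f.name] = val
        prows.append(prow)
        for i, v in enumerate(rec.visits):
            vrow = {
                "patient_id": rec.patient_id,
                "visit_id": f"{rec.patient_id}-v{i}",
                "start_time": v.start_time.isoformat() if v.start_time else "",
                "event_type": v.event_type,
            }
            if schema.has_end_times:
                vrow["end_time"] = v.end_time.isoformat() if v.end_time else ""
            for f in schema.categorical_visit_fields:
                vrow[f.name] = v.categoricals.get(f.name)
            for f in schema.continuous_visit_fields:
                vrow[f.name] = v.continuous.get(f.name)
            vrows.append(vrow)
            for code in sorted(v.codes):
                drows.append(
                    {"patient_id": rec.patient_id, "visit_id": vrow["visit_id"], "code": code}
                )
    pd.DataFrame(prows).to_csv(outdir / "patients.csv", index=False)
    pd.DataFrame(vrows).to_csv(outdir / "visits.csv", index=False)
    pd.DataFrame(drows, columns=["patient_id", "visit_id", "code"]).to_csv(
        outdir / "diagnoses.csv", index=False
    )


# ---------------------------------------------------------------------------
# value iterators used for band resolution and gap computation
# ---------------------------------------------------------------------------


def iter_field_values(records, name: str):
    for rec in records:
        if name in rec.statics and isinstance(rec.statics[name], (int, float)):
            yield float(rec.statics[name])
        for v in rec.visits:
            if name in v.continuous:
                yield float(v.continuous[name])


def gap_days(prev: Visit, cur: Visit, schema: CohortSchema) -> Optional[float]:
    """Inter-visit interval in days.

    Measured from the previous discharge when the schema carries end times
    (admission-style data, allowing small negative overlaps), otherwise
    between consecutive start times.
    """
    anchor = prev.end_time if (schema.has_end_times and prev.end_time) else prev.start_time
    if anchor is None or cur.start_time is None:
        return None
    return (cur.start_time - anchor).total_seconds() / 86400.0


def iter_gap_values(records, schema: CohortSchema):
    for rec in records:
        for prev, cur in zip(rec.visits, rec.visits[1:]):
            g = gap_days(prev, cur, schema)
            if g is not None:
                yield g


# ---------------------------------------------------------------------------
# code aggregation
# ---------------------------------------------------------------------------


@dataclass
class CodeAggregationMap:
    """Full-code -> aggregated-code map plus empirical re-expansion tables.

    ``empirical[(agg, stratum)]`` is a frequency table over full codes; the
    ``"__pooled__"`` stratum is always present and serves as fallback.
    """

    forward: dict[str, str] = field(default_factory=dict)
    empirical: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def aggregate(self, code: str) -> str:
        return self.forward.get(code, code)

    def to_dict(self) -> dict:
        return {
            "forward": self.forward,
            "empirical": {
                f"{agg}\t{stratum}": table for (agg, stratum), table in self.empirical.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodeAggregationMap":
        emp = {}
        for key, table in d["empirical"].items():
            agg, stratum = key.split("\t", 1)
            emp[(agg, stratum)] = {k: float(v) for k, v in table.items()}
        return cls(forward=dict(d["forward"]), empirical=emp)


POOLED = "__pooled__"


def aggregate_codes(
    records: Sequence[PatientRecord],
    min_count: int = 50,
    prefix_lengths: Sequence[int] = (3, 2),
    stratum_field: str = "gender",
) -> tuple[list[PatientRecord], CodeAggregationMap]:
    """Collapse rare codes to their shortest sufficient prefix.

    A code occurring fewer than ``min_count`` times cohort-wide is replaced
    by the longest candidate prefix whose aggregated count reaches
    ``min_count``; if none does, the shortest candidate is used.  Empirical
    per-stratum distributions of full codes within each aggregated category
    are recorded for later re-expansion.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    lengths = sorted(set(int(x) for x in prefix_lengths), reverse=True)
    if not lengths:
        raise ValueError("prefix_lengths must be nonempty")

    counts: Counter[str] = Counter()
    for rec in records:
        for v in rec.visits:
            counts.update(v.codes)

    prefix_counts: dict[int, Counter] = {
        L: Counter() for L in lengths
    }
    for code, c in counts.items():
        for L in lengths:
            prefix_counts[L][code[:L]] += c

    amap = CodeAggregationMap()
    for code, c in counts.items():
        if c >= min_count:
            continue
        chosen = code[: lengths[-1]]  # shortest-candidate fallback
        for L in lengths:  # descending: longest sufficient prefix wins
            if prefix_counts[L][code[:L]] >= min_count:
                chosen = code[:L]
                break
        amap.forward[code] = chosen

    # empirical re-expansion tables, stratified plus pooled
    strat_counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for rec in records:
        stratum = str(rec.statics.get(stratum_field, POOLED))
        for v in rec.visits:
            for code in v.codes:
                agg = amap.aggregate(code)
                if agg != code:
                    strat_counts[(agg, stratum)][code] += 1
                    strat_counts[(agg, POOLED)][code] += 1
    for key, table in strat_counts.items():
        total = sum(table.values())
        amap.empirical[key] = {k: v / total for k, v in sorted(table.items())}

    new_records = []
    for rec in records:
        nr = PatientRecord(rec.patient_id, dict(rec.statics))
        for v in rec.visits:
            nv = Visit(
                start_time=v.start_time,
                end_time=v.end_time,
                event_type=v.event_type,
                codes={amap.aggregate(c) for c in v.codes},
                categoricals=dict(v.categoricals),
                continuous=dict(v.continuous),
            )
            nr.visits.append(nv)
        new_records.append(nr)
    return new_records, amap


def schema_with_observed_codes(schema: CohortSchema, records) -> CohortSchema:
    """Replace code-system vocabularies with the codes observed in ``records``
    (call after :func:`aggregate_codes`, which shrinks the code set)."""
    import dataclasses

    observed = sorted({c for rec in records for v in rec.visits for c in v.codes})
    systems = []
    for cs in schema.code_systems:
        base = set(cs.vocabulary)
        prefixes = {c for c in observed if c not in base}
        kept = sorted((base & set(observed)) | prefixes)
        systems.append(CodeSystemSpec(cs.name, kept))
    return dataclasses.replace(schema, code_systems=systems)


# ---------------------------------------------------------------------------
# token vocabulary and tokenized cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Token:
    name: str
    kind: str  # special | static_cat | static_band | label | visit_cat | band | gap | code
    field: Optional[str] = None
    value: object = None


@dataclass
class TokenVocab:
    tokens: list[Token]

    def __post_init__(self):
        self.index = {t.name: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise SchemaError("duplicate token names in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    def __getitem__(self, i: int) -> Token:
        return self.tokens[i]

    def idx(self, name: str) -> int:
        return self.index[name]

    @property
    def sor(self) -> int:
        return self.index[SOR]

    @property
    def eor(self) -> int:
        return self.index[EOR]

    @property
    def eov(self) -> int:
        return self.index[EOV]

    def group(self, kind: str, fieldname: str) -> list[int]:
        return [
            i
            for i, t in enumerate(self.tokens)
            if t.kind == kind and t.field == fieldname
        ]

    def kind_indices(self, *kinds: str) -> list[int]:
        return [i for i, t in enumerate(self.tokens) if t.kind in kinds]

    def static_groups(self) -> dict[str, list[int]]:
        groups: dict[str, list[int]] = defaultdict(list)
        for i, t in enumerate(self.tokens):
            if t.kind in ("static_cat", "static_band"):
                groups[t.field].append(i)
        return dict(groups)

    def visit_groups(self) -> dict[str, list[int]]:
        groups: dict[str, list[int]] = defaultdict(list)
        for i, t in enumerate(self.tokens):
            if t.kind in ("visit_cat", "band", "gap"):
                groups[t.field].append(i)
        return dict(groups)

    def label_indices(self) -> list[int]:
        return self.kind_indices("label")

    def fingerprint(self) -> str:
        h = hashlib.sha256("\n".join(t.name for t in self.tokens).encode())
        return h.hexdigest()[:16]


def build_vocab(schema: CohortSchema) -> TokenVocab:
    """Flat token vocabulary: specials, statics/labels, visit tokens, codes."""
    tokens: list[Token] = [
        Token(SOR, "special"),
        Token(EOR, "special"),
        Token(EOV, "special"),
    ]
    # label tokens first: conditional generation clamps them, and the
    # within-visit head lets earlier tokens inform later draws
    for f in schema.static_fields:
        if f.kind == BINARY_LABEL:
            tokens.append(Token(f"label:{f.name}", "label", f.name, True))
    for f in schema.static_fields:
        if f.kind == CATEGORICAL:
            for lvl in f.levels:
                tokens.append(Token(f"static:{f.name}={lvl}", "static_cat", f.name, lvl))
        elif f.kind == CONTINUOUS:
            for b in range(f.n_defined_bands):
                tokens.append(Token(f"static:{f.name}:band{b}", "static_band", f.name, b))
    for f in schema.visit_fields:
        if f.kind == CATEGORICAL:
            for lvl in f.levels:
                tokens.append(Token(f"visit:{f.name}={lvl}", "visit_cat", f.name, lvl))
        elif f.kind == CONTINUOUS:
            for b in range(f.n_defined_bands):
                tokens.append(Token(f"band:{f.name}:band{b}", "band", f.name, b))
    g = schema.gap_field
    for b in range(g.n_defined_bands):
        tokens.append(Token(f"gap:{g.name}:band{b}", "gap", g.name, b))
    for cs in schema.code_systems:
        for code in cs.vocabulary:
            tokens.append(Token(f"code:{cs.name}:{code}", "code", cs.name, code))
    return TokenVocab(tokens)


@dataclass
class TokenizedPatient:
    patient_id: str
    label: np.ndarray            # active token indices, sorted
    visits: list[np.ndarray]     # per-visit active token indices, sorted


@dataclass
class TokenizedCohort:
    vocab: TokenVocab
    patients: list[TokenizedPatient]
    clamped_values: int = 0      # out-of-range continuous values clamped

    def __len__(self) -> int:
        return len(self.patients)


def discretize(records: Sequence[PatientRecord], schema: CohortSchema,
               vocab: Optional[TokenVocab] = None) -> TokenizedCohort:
    """Map records onto the flat token representation.

    Each observed discretized variable activates exactly one band token per
    visit; missing values activate none.  The gap variable is derived from
    consecutive visits (no token on the first visit).  Codes become code
    tokens; statics become static/label tokens.
    """
    vocab = vocab or build_vocab(schema)
    clamped = 0
    patients = []
    code_index = {
        (cs.name, code): vocab.idx(f"code:{cs.name}:{code}")
        for cs in schema.code_systems
        for code in cs.vocabulary
    }
    systems = [cs.name for cs in schema.code_systems]
    for rec in records:
        label: list[int] = []
        for f in schema.static_fields:
            val = rec.statics.get(f.name)
            if val is None:
                continue
            if f.kind == CATEGORICAL:
                if str(val) in (f.levels or []):
                    label.append(vocab.idx(f"static:{f.name}={val}"))
            elif f.kind == BINARY_LABEL:
                if val:
                    label.append(vocab.idx(f"label:{f.name}"))
            else:
                b, cl = f.band_of(float(val))
                clamped += cl
                label.append(vocab.idx(f"static:{f.name}:band{b}"))
        visits = []
        for i, v in enumerate(rec.visits):
            active: list[int] = [vocab.eov]
            for f in schema.categorical_visit_fields:
                lvl = v.categoricals.get(f.name)
                if f.name == "event_type" and lvl is None:
                    lvl = v.event_type
                if lvl is not None and str(lvl) in (f.levels or []):
                    active.append(vocab.idx(f"visit:{f.name}={lvl}"))
            for f in schema.continuous_visit_fields:
                if f.name in v.continuous:
                    b, cl = f.band_of(float(v.continuous[f.name]))
                    clamped += cl
                    active.append(vocab.idx(f"band:{f.name}:band{b}"))
            if i > 0:
                gval = gap_days(rec.visits[i - 1], v, schema)
                if gval is not None:
                    b, cl = schema.gap_field.band_of(gval)
                    clamped += cl
                    active.append(vocab.idx(f"gap:{schema.gap_field.name}:band{b}"))
            for code in v.codes:
                for sysname in systems:
                    key = (sysname, code)
                    if key in code_index:
                        active.append(code_index[key])
                        break
            visits.append(np.array(sorted(set(active)), dtype=np.int64))
        patients.append(
            TokenizedPatient(rec.patient_id, np.array(sorted(set(label)), np.int64), visits)
        )
    return TokenizedCohort(vocab, patients, clamped)


def detokenize_structure(tokenized: TokenizedCohort, schema: CohortSchema
                         ) -> list[PatientSkeleton]:
    """Inverse token map: banded skeletons with timestamps unset.

    A vector with two active band tokens for one variable raises an
    :class:`IntegrityError` naming the variable.
    """
    vocab = tokenized.vocab
    skeletons = []
    for tp in tokenized.patients:
        sk = PatientSkeleton(patient_id=tp.patient_id)
        seen_static: dict[str, object] = {}
        for i in tp.label:
            t = vocab[i]
            if t.kind == "static_cat":
                if t.field in seen_static:
                    raise IntegrityError(f"two levels for static {t.field!r}")
                seen_static[t.field] = t.value
                sk.static_levels[t.field] = t.value
            elif t.kind == "static_band":
                if t.field in seen_static:
                    raise IntegrityError(f"two bands for static {t.field!r}")
                seen_static[t.field] = t.value
                sk.static_bands[t.field] = int(t.value)
            elif t.kind == "label":
                sk.labels[t.field] = True
        for f in schema.static_fields:
            if f.kind == BINARY_LABEL:
                sk.labels.setdefault(f.name, False)
        for vec in tp.visits:
            vs = VisitSkeleton()
            seen: dict[str, object] = {}
            for i in vec:
                t = vocab[i]
                if t.kind == "visit_cat":
                    if t.field in seen:
                        raise IntegrityError(f"two levels for {t.field!r}")
                    seen[t.field] = t.value
                    vs.categoricals[t.field] = t.value
                    if t.field == "event_type":
                        vs.event_type = t.value
                elif t.kind == "band":
                    if t.field in seen:
                        raise IntegrityError(f"two bands for variable {t.field!r}")
                    seen[t.field] = t.value
                    vs.bands[t.field] = int(t.value)
                elif t.kind == "gap":
                    if t.field in seen:
                        raise IntegrityError(f"two gap bands ({t.field!r})")
                    seen[t.field] = t.value
                    vs.gap_band = int(t.value)
                elif t.kind == "code":
                    vs.codes.add(str(t.value))
            sk.visits.append(vs)
        skeletons.append(sk)
    return skeletons


def save_tokenized(tok: TokenizedCohort, path) -> None:
    """Single-file npz serialization (token table stored as JSON header)."""
    import json

    token_table = [
        {"name": t.name, "kind": t.kind, "field": t.field, "value": t.value}
        for t in tok.vocab.tokens
    ]
    ids, lab_flat, lab_off = [], [], [0]
    vis_flat, vis_off, vis_counts = [], [0], []
    for tp in tok.patients:
        ids.append(tp.patient_id)
        lab_flat.extend(tp.label.tolist())
        lab_off.append(len(lab_flat))
        vis_counts.append(len(tp.visits))
        for vec in tp.visits:
            vis_flat.extend(vec.tolist())
            vis_off.append(len(vis_flat))
    np.savez_compressed(
        path,
        __vocab__=json.dumps(token_table),
        ids=np.array(ids),
        lab_flat=np.array(lab_flat, np.int64),
        lab_off=np.array(lab_off, np.int64),
        vis_flat=np.array(vis_flat, np.int64),
        vis_off=np.array(vis_off, np.int64),
        vis_counts=np.array(vis_counts, np.int64),
        clamped=np.array([tok.clamped_values]),
    )


def load_tokenized(path) -> TokenizedCohort:
    import json

    d = np.load(path, allow_pickle=False)
    table = json.loads(str(d["__vocab__"]))
    vocab = TokenVocab([Token(t["name"], t["kind"], t["field"], t["value"])
                        for t in table])
    patients = []
    vi = 0
    for i, pid in enumerate(d["ids"]):
        label = d["lab_flat"][d["lab_off"][i] : d["lab_off"][i + 1]]
        visits = []
        for _ in range(int(d["vis_counts"][i])):
            visits.append(d["vis_flat"][d["vis_off"][vi] : d["vis_off"][vi + 1]])
            vi += 1
        patients.append(TokenizedPatient(str(pid), label.copy(),
                                         [v.copy() for v in visits]))
    return TokenizedCohort(vocab, patients, int(d["clamped"][0]))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_cohort(records: Sequence[PatientRecord], fractions=(0.8, 0.1, 0.1),
                 seed: int = 0) -> tuple[list, ...]:
    """Deterministic patient-level split (floor sizes, remainder by largest
    fractional part)."""
    fracs = np.asarray(fractions, dtype=float)
    if np.any(fracs <= 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n = len(records)
    if n < len(fracs):
        raise ValueError(f"cannot split {n} patients into {len(fracs)} partitions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    raw = fracs * n
    sizes = np.floor(raw).astype(int)
    rem = n - sizes.sum()
    for i in np.argsort(-(raw - sizes), kind="stable")[:rem]:
        sizes[i] += 1
    # every partition gets at least one patient
    while np.any(sizes == 0):
        sizes[np.argmin(sizes)] += 1
        sizes[np.argmax(sizes)] -= 1
    parts, start = [], 0
    for s in sizes:
        parts.append([records[i] for i in order[start : start + s]])
        start += s
    return tuple(parts)
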