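"""Reading, validation and pre-processing of participant-level survey microdata.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row per
survey participant and the columns listed in :data:`CANONICAL_COLUMNS`. Cholesterol
is serum total cholesterol in mmol/L. Two survey periods are supported: the
unweighted 1991-92 baseline (social class I-V as its socioeconomic indicator) and
the weighted 2011-12 sample (QIMD quintiles, 1 = most affluent).
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PERIOD_1991 = "1991-92"
PERIOD_2011 = "2011-12"
PERIODS = (PERIOD_1991, PERIOD_2011)

SEXES = ("male", "female")

SOCIAL_CLASSES = ("I", "II", "IIIN", "IIIM", "IV", "V", "Other")

#: canonical column -> (dtype kind, mandatory)
CANONICAL_COLUMNS = OrderedDict(
    [
        ("id", ("object", True)),
        ("age", ("int", True)),
        ("sex", ("category", True)),
        ("period", ("category", True)),
        ("qimd", ("float", False)),          # 1-5, NaN when absent (1991-92)
        ("social_class", ("object", False)),  # I..V/Other, None when absent (2011-12)
        ("weight", ("float", True)),
        ("psu", ("object", True)),
        ("stratum", ("object", True)),
        ("statin_user", ("bool", True)),
        ("tc_mmol", ("float", False)),       # NaN = missing measurement
        ("measured_post_2010_04", ("bool", True)),
    ]
)

#: DataFrame.attrs key guarding against double application of the equipment offset
OFFSET_ATTR = "tc_equipment_offset_applied"


class SchemaError(ValueError):
    """A mandatory column is missing from the input file or mapping."""


class ValidationError(ValueError):
    """One or more rows violate the participant invariants."""

    def __init__(self, problems: Sequence[tuple[int, str]]):
        self.problems = list(problems)
        lines = ", ".join(f"row {i}: {msg}" for i, msg in self.problems[:20])
        more = "" if len(self.problems) <= 20 else f" (+{len(self.problems) - 20} more)"
        super().__init__(f"{len(self.problems)} invalid row(s): {lines}{more}")


_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        if value in (0, 1):
            return bool(value)
        raise ValueError(f"cannot interpret {value!r} as a flag")
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret {value!r} as a flag")


def read_participants(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    sep: str = ",",
    min_age: int = 18,
    errors: str = "raise",
) -> pd.DataFrame:
    """Read a delimited participant file into the canonical DataFrame.

    Parameters
    ----------
    path : str or path-like
        Delimited text file with one row per participant.
    schema : mapping, optional
        Maps canonical column names to the file's column names. Unmapped
        canonical names are assumed to appear verbatim in the file.
    min_age : int
        Participants younger than this are excluded (the survey protocol
        analyses adults only; default 18).
    errors : {"raise", "report"}
        With ``"raise"`` any malformed row aborts with :class:`ValidationError`;
        with ``"report"`` malformed rows are dropped and returned as a report.

    Returns
    -------
    DataFrame, or (DataFrame, list of (row index, message)) when ``errors="report"``.
    """
    if errors not in ("raise", "report"):
        raise ValueError("errors must be 'raise' or 'report'")
    schema = dict(schema or {})
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")

    colmap = {name: schema.get(name, name) for name in CANONICAL_COLUMNS}
    missing = [
        colmap[name]
        for name, (_, mandatory) in CANONICAL_COLUMNS.items()
        if mandatory and colmap[name] not in raw.columns
    ]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    n = len(raw)
    problems: list[tuple[int, str]] = []
    out: dict[str, np.ndarray] = {}

    def _col(name):
        src = colmap[name]
        if src in raw.columns:
            return raw[src]
        return pd.Series([""] * n, dtype=str)

    # row-wise parse; files are small enough that clarity beats vectorisation here
    parsed_rows = []
    for i in range(n):
        row = {}
        ok = True

        def fail(msg):
            nonlocal ok
            problems.append((i, msg))
            ok = False

        try:
            row["id"] = str(_col("id").iloc[i])
            try:
                age = int(float(_col("age").iloc[i]))
                if age < 0:
                    raise ValueError
                row["age"] = age
            except ValueError:
                fail(f"unparseable age {_col('age').iloc[i]!r}")

            sex = str(_col("sex").iloc[i]).strip().lower()
            sex = {"m": "male", "f": "female", "1": "male", "2": "female"}.get(sex, sex)
            if sex not in SEXES:
                fail(f"unknown sex {sex!r}")
            row["sex"] = sex

            period = str(_col("period").iloc[i]).strip()
            period = {"1991": PERIOD_1991, "2011": PERIOD_2011}.get(period, period)
            if period not in PERIODS:
                fail(f"unknown period {period!r}")
            row["period"] = period

            q = str(_col("qimd").iloc[i]).strip()
            if q == "":
                row["qimd"] = np.nan
            else:
                try:
                    qv = int(float(q))
                    if not 1 <= qv <= 5:
                        raise ValueError
                    row["qimd"] = float(qv)
                except ValueError:
                    fail(f"qimd {q!r} not in 1..5")

            sc = str(_col("social_class").iloc[i]).strip()
            if sc == "":
                row["social_class"] = None
            elif sc in SOCIAL_CLASSES:
                row["social_class"] = sc
            else:
                fail(f"unknown social class {sc!r}")

            try:
                w = float(_col("weight").iloc[i]) if str(_col("weight").iloc[i]).strip() else 1.0
                if not np.isfinite(w) or w < 0:
                    raise ValueError
                row["weight"] = w
            except ValueError:
                fail(f"invalid weight {_col('weight').iloc[i]!r}")

            row["psu"] = str(_col("psu").iloc[i])
            row["stratum"] = str(_col("stratum").iloc[i])

            try:
                row["statin_user"] = _as_bool(_col("statin_user").iloc[i])
            except ValueError as exc:
                fail(str(exc))

            tc = str(_col("tc_mmol").iloc[i]).strip()
            if tc == "" or tc.lower() in ("na", "nan"):
                row["tc_mmol"] = np.nan
            else:
                try:
                    tcv = float(tc)
                    if not np.isfinite(tcv) or tcv <= 0:
                        raise ValueError
                    row["tc_mmol"] = tcv
                except ValueError:
                    fail(f"total cholesterol {tc!r} is not a positive number")

            try:
                row["measured_post_2010_04"] = _as_bool(_col("measured_post_2010_04").iloc[i])
            except ValueError as exc:
                fail(str(exc))
        except Exception as exc:  # pragma: no cover - defensive
            fail(str(exc))

        parsed_rows.append(row if ok else None)

    if problems and errors == "raise":
        raise ValidationError(problems)

    df = pd.DataFrame([r for r in parsed_rows if r is not None])
    if len(df) == 0:
        df = pd.DataFrame({k: pd.Series(dtype=object) for k in CANONICAL_COLUMNS})
    df = df[list(CANONICAL_COLUMNS)].reset_index(drop=True)
    if len(df):
        df = df[df["age"] >= min_age].reset_index(drop=True)
        bad_w = (df["period"] == PERIOD_1991) & (df["weight"] != 1.0)
        if bad_w.any():
            # the 1991-92 design is unweighted; tolerate but normalise
            df.loc[bad_w, "weight"] = 1.0
    df.attrs[OFFSET_ATTR] = False
    if errors == "report":
        return df, problems
    return df


def adjust_equipment_offset(participants: pd.DataFrame, offset: float = 0.1) -> pd.DataFrame:
    """Correct for the April-2010 analyser change by subtracting ``offset`` mmol/L.

    Applies exactly once, to records flagged ``measured_post_2010_04`` only, and
    marks the returned frame so a second application raises.
    """
    if participants.attrs.get(OFFSET_ATTR, False):
        raise ValueError(
            "equipment offset already applied to this dataset; refusing to re-apply"
        )
    out = participants.copy()
    mask = out["measured_post_2010_04"].astype(bool) & out["tc_mmol"].notna()
    out.loc[mask, "tc_mmol"] = out.loc[mask, "tc_mmol"] - offset
    if (out.loc[mask, "tc_mmol"] <= 0).any():
        raise ValueError("offset adjustment produced non-positive cholesterol values")
    out.attrs[OFFSET_ATTR] = True
    return out


def exclude_missing(
    participants: pd.DataFrame, require: Iterable[str] = ("tc_mmol",)
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop records missing any of the required fields.

    Counting is per record: each excluded record is tallied once, under the
    first required field (in ``require`` order) that it lacks, so that
    ``len(kept) + sum(report.values()) == len(input)``.
    """
    require = list(require)
    report: dict[str, int] = {f: 0 for f in require}
    if not require:
        kept = participants.copy()
        kept.attrs.update(participants.attrs)
        return kept, report
    missing_first = np.full(len(participants), "", dtype=object)
    for field in reversed(require):
        if field not in participants.columns:
            raise KeyError(f"unknown field {field!r}")
        col = participants[field]
        miss = col.isna().to_numpy() if col.dtype != object else col.isna().to_numpy()
        missing_first[miss] = field
    for field in require:
        report[field] = int((missing_first == field).sum())
    kept = participants.loc[missing_first == ""].reset_index(drop=True)
    kept.attrs.update(participants.attrs)
    return kept, report
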