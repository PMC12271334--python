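"""Canonical data model for CGM study participants and readers/writers.

The internal unit for glucose is mg/dL throughout; meal quantities are grams
per food group using the seven food groups commonly distinguished in Chinese
dietary surveys; glucose-lowering agents are reduced to four pharmacodynamic
classes (basal, intermediate and bolus insulin, and non-insulin hypoglycemic
agents).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Food groups, fixed order.
FOOD_GROUPS: tuple[str, ...] = (
    "staples",
    "vegetables",
    "fruits",
    "animal_foods",
    "dairy",
    "legumes_nuts_seeds",
    "sweets",
)

#: Glucose-lowering agent classes.
AGENT_CLASSES: tuple[str, ...] = (
    "basal_insulin",
    "intermediate_insulin",
    "bolus_insulin",
    "non_insulin_agent",
)

#: mg/dL per mmol/L for glucose (molar mass 180.18 g/mol).
MMOL_TO_MGDL = 18.018

_DATA_DIR = Path(__file__).parent / "data"


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


@dataclass
class GlucoseSeries:
    """One participant's timestamped CGM trace in mg/dL.

    Timestamps must be strictly increasing; values positive and physiologic
    (< 1000 mg/dL after unit normalization).
    """

    participant_id: str
    timestamps: np.ndarray  # datetime64[ns], strictly increasing
    values: np.ndarray  # mg/dL
    nominal_interval: float = 15.0  # minutes

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")
        if len(self.timestamps) > 1 and not (np.diff(self.timestamps) > np.timedelta64(0, "ns")).all():
            raise ValueError("timestamps must be strictly increasing (no duplicates)")
        if len(self.values) and not ((self.values > 0) & (self.values < 1000)).all():
            raise ValueError("glucose values must lie in (0, 1000) mg/dL")

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlucoseSeries):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and np.array_equal(self.timestamps, other.timestamps)
            and np.allclose(self.values, other.values, rtol=0, atol=1e-9)
            and self.nominal_interval == other.nominal_interval
        )


@dataclass
class MealEvent:
    """A logged meal: grams per food group (NaN = unrecorded) plus the total."""

    participant_id: str
    timestamp: datetime
    grams_by_group: dict[str, float]
    total_grams: float
    raw_text: str | None = None

    def __post_init__(self) -> None:
        if set(self.grams_by_group) != set(FOOD_GROUPS):
            raise ValueError(f"grams_by_group keys must be exactly {FOOD_GROUPS}")
        for g, v in self.grams_by_group.items():
            if not math.isnan(v) and v < 0:
                raise ValueError(f"negative grams for {g}")
        if not math.isnan(self.total_grams) and self.total_grams < 0:
            raise ValueError("negative total_grams")
        if all(not math.isnan(v) for v in self.grams_by_group.values()) and not math.isnan(self.total_grams):
            s = sum(self.grams_by_group.values())
            if abs(s - self.total_grams) > 1e-6 and self.total_grams < s - 1e-6:
                # total may exceed the group sum (unmapped items), never undershoot
                raise ValueError("total_grams below sum of group grams")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MealEvent):
            return NotImplemented
        same_grams = all(
            (math.isnan(self.grams_by_group[g]) and math.isnan(other.grams_by_group[g]))
            or abs(self.grams_by_group[g] - other.grams_by_group[g]) <= 1e-9
            for g in FOOD_GROUPS
        )
        same_total = (math.isnan(self.total_grams) and math.isnan(other.total_grams)) or abs(
            self.total_grams - other.total_grams
        ) <= 1e-9
        return (
            self.participant_id == other.participant_id
            and self.timestamp == other.timestamp
            and same_grams
            and same_total
            and (self.raw_text or "") == (other.raw_text or "")
        )


@dataclass(eq=True)
class MedicationEvent:
    """A logged glucose-lowering agent dose."""

    participant_id: str
    timestamp: datetime
    agent_class: str
    dose: float
    dose_unit: str = "IU"

    def __post_init__(self) -> None:
        if self.agent_class not in AGENT_CLASSES:
            raise ValueError(f"agent_class must be one of {AGENT_CLASSES}")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")


@dataclass
class ParticipantRecord:
    """All of one participant's data: CGM trace, meals, medications, demographics."""

    participant_id: str
    glucose: GlucoseSeries
    meals: list[MealEvent] = field(default_factory=list)
    meds: list[MedicationEvent] = field(default_factory=list)
    demographics: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.glucose.participant_id != self.participant_id:
            raise ValueError("glucose participant_id mismatch")
        for ev in list(self.meals) + list(self.meds):
            if ev.participant_id != self.participant_id:
                raise ValueError("child record participant_id mismatch")
        # stable sort preserves insertion order among equal timestamps
        self.meals = sorted(self.meals, key=lambda m: m.timestamp)
        self.meds = sorted(self.meds, key=lambda m: m.timestamp)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParticipantRecord):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.glucose == other.glucose
            and self.meals == other.meals
            and self.meds == other.meds
            and (self.demographics or {}) == (other.demographics or {})
        )


# ---------------------------------------------------------------------------
# unit handling


def normalize_glucose_units(values: np.ndarray, unit_hint: str = "auto") -> np.ndarray:
    """Return glucose in mg/dL.

    With ``unit_hint='auto'`` a series whose median is below 30 is taken to be
    mmol/L and converted (physiologic mg/dL and mmol/L ranges do not overlap).
    Idempotent: converting an mg/dL series changes nothing.
    """
    values = np.asarray(values, dtype=float)
    if unit_hint not in ("auto", "mg_dl", "mmol_l"):
        raise ValueError("unit_hint must be auto, mg_dl or mmol_l")
    if unit_hint == "mg_dl":
        return values
    if unit_hint == "mmol_l":
        return values * MMOL_TO_MGDL
    if len(values) and np.nanmedian(values) < 30:
        return values * MMOL_TO_MGDL
    return values


# ---------------------------------------------------------------------------
# lexicons


def load_food_lexicon(path: str | Path | None = None) -> dict[str, str]:
    """Keyword → food-group table (packaged default, user-overridable)."""
    p = Path(path) if path is not None else _DATA_DIR / "food_lexicon.csv"
    df = pd.read_csv(p)
    lex = {str(k).strip().lower(): str(g).strip() for k, g in zip(df["keyword"], df["group"])}
    bad = set(lex.values()) - set(FOOD_GROUPS)
    if bad:
        raise ValueError(f"food lexicon contains unknown groups: {bad}")
    return lex


def load_medication_lexicon(path: str | Path | None = None) -> dict[str, str]:
    """Drug-name keyword → agent-class table (packaged default)."""
    p = Path(path) if path is not None else _DATA_DIR / "medication_lexicon.csv"
    df = pd.read_csv(p)
    lex = {str(k).strip().lower(): str(c).strip() for k, c in zip(df["keyword"], df["agent_class"])}
    bad = set(lex.values()) - set(AGENT_CLASSES)
    if bad:
        raise ValueError(f"medication lexicon contains unknown classes: {bad}")
    return lex


_ITEM_GRAM_RE = re.compile(r"([^,;+\d]+?)\s*[,:]?\s*(\d+(?:\.\d+)?)\s*g(?:rams?)?\b", re.IGNORECASE)


def map_food_text(raw_text: str, lexicon: Mapping[str, str]) -> tuple[dict[str, float], float]:
    """Parse free-text diet entries ("noodles 200g, egg 50g") into group grams.

    Returns ``(grams_by_group, unmapped_grams)``.  Items whose name matches no
    lexicon keyword accumulate in the unmapped total; parsing never fails.
    Keyword matching is longest-substring-wins on the lowercased item name.
    """
    grams = {g: 0.0 for g in FOOD_GROUPS}
    unmapped = 0.0
    if not raw_text or not raw_text.strip():
        return grams, unmapped
    for m in _ITEM_GRAM_RE.finditer(raw_text):
        item = m.group(1).strip().lower()
        amount = float(m.group(2))
        best_kw = ""
        for kw in lexicon:
            if kw in item and len(kw) > len(best_kw):
                best_kw = kw
        if best_kw:
            grams[lexicon[best_kw]] += amount
        else:
            unmapped += amount
    return grams, unmapped


def classify_agent(name: str, lexicon: Mapping[str, str]) -> str:
    """Map a drug name to one of the four agent classes.

    Unknown names fall back to non_insulin_agent with a warning, unless the
    name mentions insulin, in which case bolus is the least-wrong default.
    """
    low = name.strip().lower()
    best_kw = ""
    for kw in lexicon:
        if kw in low and len(kw) > len(best_kw):
            best_kw = kw
    if best_kw:
        return lexicon[best_kw]
    fallback = "bolus_insulin" if "insulin" in low else "non_insulin_agent"
    logger.warning("unknown agent %r mapped to %s", name, fallback)
    return fallback


# ---------------------------------------------------------------------------
# readers / writers


def _find_column(columns: Sequence[str], needles: Sequence[str]) -> str | None:
    for col in columns:
        low = str(col).lower()
        if any(n in low for n in needles):
            return str(col)
    return None


_MED_DOSE_RE = re.compile(r"([A-Za-z][A-Za-z0-9 \-/]*?)\s*[,:]?\s*(\d+(?:\.\d+)?)\s*(iu|u|mg|g)?\b", re.IGNORECASE)


def _parse_med_text(text: str, lexicon: Mapping[str, str]) -> list[tuple[str, float, str]]:
    out = []
    for m in _MED_DOSE_RE.finditer(text):
        name = m.group(1).strip()
        dose = float(m.group(2))
        unit = (m.group(3) or "IU").upper().replace("U", "IU") if m.group(3) else "IU"
        if unit == "MG":
            unit = "mg"
        elif unit not in ("IU",):
            unit = "IU"
        out.append((classify_agent(name, lexicon), dose, unit))
    return out


def read_shanghai_participant(
    path: str | Path,
    unit_hint: str = "auto",
    food_lexicon: Mapping[str, str] | None = None,
    med_lexicon: Mapping[str, str] | None = None,
) -> ParticipantRecord:
    """Read one participant spreadsheet (ShanghaiT2DM layout) into the data model.

    The reader locates columns by name fragments: a timestamp column
    (date/time), a CGM column, a dietary-intake free-text column, and insulin
    / non-insulin agent columns.  Glucose is normalized to mg/dL; diet rows
    become :class:`MealEvent` via :func:`map_food_text`; medication rows
    become :class:`MedicationEvent` via the agent-class lexicon.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    cols = list(df.columns)

    ts_col = _find_column(cols, ["date", "time"])
    cgm_col = _find_column(cols, ["cgm"])
    if ts_col is None:
        raise FormatError("missing timestamp column (no column name contains 'date' or 'time')")
    if cgm_col is None:
        raise FormatError("missing CGM column (no column name contains 'cgm')")
    diet_col = _find_column(cols, ["diet"])
    insulin_cols = [c for c in cols if "insulin" in str(c).lower() and "non-insulin" not in str(c).lower()]
    noninsulin_col = _find_column(cols, ["non-insulin", "hypoglycemic"])

    pid = path.stem
    food_lexicon = food_lexicon if food_lexicon is not None else load_food_lexicon()
    med_lexicon = med_lexicon if med_lexicon is not None else load_medication_lexicon()

    ts = pd.to_datetime(df[ts_col], errors="coerce")
    n_bad = int(ts.isna().sum())
    if n_bad:
        logger.warning("%s: skipped %d rows with unparseable timestamps", pid, n_bad)
    df = df.loc[ts.notna()].copy()
    df["_ts"] = ts[ts.notna()]

    cgm = pd.to_numeric(df[cgm_col], errors="coerce")
    gmask = cgm.notna()
    gts = df.loc[gmask, "_ts"]
    gv = normalize_glucose_units(cgm[gmask].to_numpy(), unit_hint)
    order = np.argsort(gts.to_numpy(), kind="stable")
    gts_arr = gts.to_numpy()[order]
    gv = gv[order]
    keep = np.ones(len(gts_arr), dtype=bool)
    keep[1:] = np.diff(gts_arr) > np.timedelta64(0, "ns")
    glucose = GlucoseSeries(pid, gts_arr[keep], gv[keep])

    meals: list[MealEvent] = []
    if diet_col is not None:
        for _, row in df.loc[df[diet_col].notna()].iterrows():
            text = str(row[diet_col]).strip()
            if not text:
                continue
            grams, unmapped = map_food_text(text, food_lexicon)
            total = sum(grams.values()) + unmapped
            meals.append(
                MealEvent(pid, row["_ts"].to_pydatetime(), grams, total, raw_text=text)
            )

    meds: list[MedicationEvent] = []
    med_cols = insulin_cols + ([noninsulin_col] if noninsulin_col else [])
    for col in med_cols:
        for _, row in df.loc[df[col].notna()].iterrows():
            text = str(row[col]).strip()
            if not text or text.lower() in ("nan", "none", "0"):
                continue
            for agent_class, dose, unit in _parse_med_text(text, med_lexicon):
                meds.append(MedicationEvent(pid, row["_ts"].to_pydatetime(), agent_class, dose, unit))

    return ParticipantRecord(pid, glucose, meals, meds)


_GLUCOSE_COLS = ["timestamp", "glucose_mg_dl"]
_MEAL_COLS = ["timestamp", *[f"{g}_g" for g in FOOD_GROUPS], "total_grams", "raw_text"]
_MED_COLS = ["timestamp", "agent_class", "dose", "dose_unit"]


def write_canonical(record: ParticipantRecord, out_dir: str | Path) -> dict[str, Path]:
    """Write a participant to three flat CSV tables + a small JSON sidecar.

    Tables: ``glucose.csv``, ``meals.csv``, ``meds.csv`` with ISO-8601
    timestamps.  Round-trips exactly through :func:`read_canonical`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = pd.DataFrame(
        {
            "timestamp": pd.Series(record.glucose.timestamps).dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "glucose_mg_dl": record.glucose.values,
        }
    )
    g.to_csv(out / "glucose.csv", index=False)

    meal_rows = []
    for m in record.meals:
        row: dict[str, object] = {"timestamp": m.timestamp.isoformat()}
        for grp in FOOD_GROUPS:
            row[f"{grp}_g"] = m.grams_by_group[grp]
        row["total_grams"] = m.total_grams
        row["raw_text"] = m.raw_text or ""
        meal_rows.append(row)
    pd.DataFrame(meal_rows, columns=_MEAL_COLS).to_csv(out / "meals.csv", index=False)

    med_rows = [
        {"timestamp": m.timestamp.isoformat(), "agent_class": m.agent_class, "dose": m.dose, "dose_unit": m.dose_unit}
        for m in record.meds
    ]
    pd.DataFrame(med_rows, columns=_MED_COLS).to_csv(out / "meds.csv", index=False)

    import json

    meta = {
        "participant_id": record.participant_id,
        "nominal_interval": record.glucose.nominal_interval,
        "demographics": record.demographics,
    }
    (out / "participant.json").write_text(json.dumps(meta, indent=1))
    return {k: out / f"{k}.csv" for k in ("glucose", "meals", "meds")}


def read_canonical(in_dir: str | Path) -> ParticipantRecord:
    """Inverse of :func:`write_canonical`."""
    import json

    d = Path(in_dir)
    meta = json.loads((d / "participant.json").read_text())
    pid = meta["participant_id"]

    g = pd.read_csv(d / "glucose.csv", parse_dates=["timestamp"])
    glucose = GlucoseSeries(
        pid, g["timestamp"].to_numpy(), g["glucose_mg_dl"].to_numpy(), nominal_interval=meta["nominal_interval"]
    )

    meals = []
    mdf = pd.read_csv(d / "meals.csv", parse_dates=["timestamp"])
    for _, row in mdf.iterrows():
        grams = {grp: float(row[f"{grp}_g"]) for grp in FOOD_GROUPS}
        raw = row.get("raw_text")
        raw = None if (raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "") else str(raw)
        meals.append(MealEvent(pid, row["timestamp"].to_pydatetime(), grams, float(row["total_grams"]), raw_text=raw))

    meds = []
    ddf = pd.read_csv(d / "meds.csv", parse_dates=["timestamp"])
    for _, row in ddf.iterrows():
        meds.append(
            MedicationEvent(pid, row["timestamp"].to_pydatetime(), str(row["agent_class"]), float(row["dose"]), str(row["dose_unit"]))
        )

    return ParticipantRecord(pid, glucose, meals, meds, demographics=meta.get("demographics"))
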