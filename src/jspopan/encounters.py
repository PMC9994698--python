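"""Encounter-history data structures, readers/writers, and study-design assembly.

The study monitored a headstarted Blanding's Turtle population over six annual
occasions (2015-2020).  Juveniles were released in known cohorts, a subset
carried radio transmitters (and were therefore detected with certainty while
tracked), and live-trapping surveys ran only in 2018-2020.  These facts turn
into *parameter fixing* for an open-population Jolly-Seber model: entry is
deterministic at the release occasion, the per-group superpopulation equals the
number released, and detection probability is fixed at 1 during telemetry and
at 0 wherever an animal was unavailable or no survey took place.

This module holds the canonical in-memory types (:class:`EncounterHistory`,
:class:`CohortGroup`, :class:`StudyDesign`), readers/writers for a tabular CSV
dialect and a MARK-style ``.inp`` dialect, the published inclusion rules, and
the builder that expands a group table into the full detection mask.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Annual occasions of the study, in order.
YEARS: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019, 2020)
#: Years with live-trapping survey effort (untracked animals detectable).
SURVEY_YEARS: tuple[int, ...] = (2018, 2019, 2020)
#: Number of occasions.
N_OCCASIONS: int = len(YEARS)

#: Headstarted juveniles released per year, including the 2014 cohort that is
#: excluded from the mark-recapture analysis (missing data) — totals 270.
RELEASE_SCHEDULE: dict[int, int] = {
    2014: 10, 2015: 21, 2016: 36, 2017: 49, 2018: 49, 2019: 48, 2020: 57,
}

#: (cohort, telemetry occasions) -> number of turtles; the 23-group structure
#: used in the analysis.  Cohort totals are 21/36/49/49/48/57 (260 turtles).
TELEMETRY_PLAN: dict[tuple[int, int], int] = {
    (2015, 6): 3, (2015, 5): 4, (2015, 4): 2, (2015, 2): 11, (2015, 1): 1,
    (2016, 5): 5, (2016, 4): 4, (2016, 3): 1, (2016, 2): 8, (2016, 1): 6,
    (2016, 0): 12,
    (2017, 4): 2, (2017, 3): 4, (2017, 2): 10, (2017, 0): 33,
    (2018, 3): 2, (2018, 2): 19, (2018, 1): 1, (2018, 0): 27,
    (2019, 2): 18, (2019, 1): 5, (2019, 0): 25,
    (2020, 0): 57,
}


class MaskState(enum.Enum):
    """Detection availability of one (group, occasion) cell."""

    FREE = "free"          # detection probability estimated
    FIXED_0 = "fixed_0"    # unavailable (pre-release or no survey effort)
    FIXED_1 = "fixed_1"    # certain detection (radio-tracked)


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass(frozen=True)
class EncounterHistory:
    """One individual's release cohort, telemetry duration, and detections.

    ``detections`` is the binary encounter history over the six annual
    occasions 2015-2020; 1 means observed alive at that occasion.
    """

    individual_id: str
    cohort: int
    telemetry_occasions: int
    detections: tuple[int, ...]
    first_encounter_dead: bool = False
    direct_release: bool = False

    def __post_init__(self) -> None:
        if len(self.detections) != N_OCCASIONS:
            raise ValidationError(
                f"{self.individual_id}: expected {N_OCCASIONS} detection flags, "
                f"got {len(self.detections)}"
            )
        if any(x not in (0, 1) for x in self.detections):
            raise ValidationError(
                f"{self.individual_id}: detection flags must be 0/1"
            )
        if self.cohort in YEARS:
            r = YEARS.index(self.cohort)
            if any(self.detections[:r]):
                raise ValidationError(
                    f"{self.individual_id}: detection before release "
                    f"occasion ({self.cohort})"
                )
            if not 0 <= self.telemetry_occasions <= N_OCCASIONS - r:
                raise ValidationError(
                    f"{self.individual_id}: telemetry span exceeds study "
                    f"occasions (cohort {self.cohort}, "
                    f"{self.telemetry_occasions} occasions tracked)"
                )

    @property
    def release_occasion(self) -> int:
        """0-based index of the release occasion."""
        return YEARS.index(self.cohort)


@dataclass(frozen=True)
class CohortGroup:
    """A release cohort subdivided by telemetry duration.

    ``n_released`` is the group's fixed superpopulation: the number of
    headstarted turtles released into it, whether or not ever re-encountered.
    """

    cohort: int
    telemetry_occasions: int
    n_released: int

    def __post_init__(self) -> None:
        if self.cohort not in YEARS:
            raise ValidationError(f"unknown cohort year {self.cohort}")
        if self.n_released < 0:
            raise ValidationError("n_released must be non-negative")
        r = YEARS.index(self.cohort)
        if self.telemetry_occasions < 0 or r + self.telemetry_occasions > N_OCCASIONS:
            raise ValidationError(
                f"telemetry span exceeds last occasion for cohort {self.cohort}"
            )

    @property
    def release_occasion(self) -> int:
        return YEARS.index(self.cohort)

    @property
    def key(self) -> tuple[int, int]:
        return (self.cohort, self.telemetry_occasions)


@dataclass
class StudyDesign:
    """Occasions, groups, and the per-cell detection mask / entry schedule."""

    years: tuple[int, ...]
    survey_years: tuple[int, ...]
    groups: list[CohortGroup]
    detection_mask: np.ndarray  # (G, T) of MaskState
    entry_fix: np.ndarray       # (G, T) of float, 1 at the release occasion

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_occasions(self) -> int:
        return len(self.years)

    def group_index(self) -> dict[tuple[int, int], int]:
        return {g.key: i for i, g in enumerate(self.groups)}

    def mask_frame(self) -> pd.DataFrame:
        """Mask as a group x occasion table (FREE / FIXED_0 / FIXED_1)."""
        rows = {}
        for g, grp in enumerate(self.groups):
            rows[f"{grp.cohort}_d{grp.telemetry_occasions}"] = [
                self.detection_mask[g, t].name for t in range(self.n_occasions)
            ]
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(self.years))


def table1_groups() -> list[CohortGroup]:
    """The 23 cohort-by-telemetry groups of the published analysis."""
    return [
        CohortGroup(cohort, d, n) for (cohort, d), n in TELEMETRY_PLAN.items()
    ]


def build_design(
    groups: Iterable[CohortGroup],
    survey_years: Sequence[int] = SURVEY_YEARS,
) -> StudyDesign:
    """Expand a group table into the full detection mask and entry schedule.

    Rules: FIXED_0 before release and at non-survey occasions for untracked
    availability; FIXED_1 exactly at a group's telemetry occasions (assumed
    consecutive starting at release); FREE at remaining survey occasions.
    Groups with ``n_released == 0`` are dropped with a warning.
    """
    kept: list[CohortGroup] = []
    for g in groups:
        if g.n_released == 0:
            warnings.warn(f"dropping empty group {g.key}", stacklevel=2)
            continue
        kept.append(g)
    if not kept:
        raise ValidationError("no non-empty groups")
    seen = set()
    for g in kept:
        if g.key in seen:
            raise ValidationError(f"duplicate group {g.key}")
        seen.add(g.key)

    G, T = len(kept), N_OCCASIONS
    mask = np.empty((G, T), dtype=object)
    entry = np.zeros((G, T))
    for i, g in enumerate(kept):
        r = g.release_occasion
        entry[i, r] = 1.0
        for t in range(T):
            if t < r:
                mask[i, t] = MaskState.FIXED_0
            elif t < r + g.telemetry_occasions:
                mask[i, t] = MaskState.FIXED_1
            elif YEARS[t] in survey_years:
                mask[i, t] = MaskState.FREE
            else:
                mask[i, t] = MaskState.FIXED_0
    return StudyDesign(
        years=YEARS,
        survey_years=tuple(survey_years),
        groups=kept,
        detection_mask=mask,
        entry_fix=entry,
    )


def default_design() -> StudyDesign:
    """The published 23-group design (260 released, surveys 2018-2020)."""
    return build_design(table1_groups())


# ---------------------------------------------------------------------------
# Tabular (CSV/XLSX) dialect
# ---------------------------------------------------------------------------

_CANONICAL_COLUMNS = ("id", "cohort", "telemetry_occasions") + tuple(
    f"y{y}" for y in YEARS
)


def histories_to_frame(histories: Iterable[EncounterHistory]) -> pd.DataFrame:
    rows = []
    for h in histories:
        row = {
            "id": h.individual_id,
            "cohort": h.cohort,
            "telemetry_occasions": h.telemetry_occasions,
        }
        row.update({f"y{y}": x for y, x in zip(YEARS, h.detections)})
        row["first_encounter_dead"] = int(h.first_encounter_dead)
        row["direct_release"] = int(h.direct_release)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=list(_CANONICAL_COLUMNS) + ["first_encounter_dead", "direct_release"],
    )


def frame_to_histories(
    df: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> list[EncounterHistory]:
    """Build histories from a table, reporting malformed rows by number.

    ``column_map`` maps canonical names (``id``, ``cohort``,
    ``telemetry_occasions``, ``y2015``..``y2020``) to the table's own headers,
    for spreadsheets with a different layout.
    """
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in _CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    out: list[EncounterHistory] = []
    errors: list[str] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            det = []
            for y in YEARS:
                v = row[f"y{y}"]
                iv = int(v)
                if iv not in (0, 1) or float(v) != iv:
                    raise ValidationError(f"non-binary detection symbol {v!r}")
                det.append(iv)
            out.append(
                EncounterHistory(
                    individual_id=str(row["id"]),
                    cohort=int(row["cohort"]),
                    telemetry_occasions=int(row["telemetry_occasions"]),
                    detections=tuple(det),
                    first_encounter_dead=bool(
                        int(row.get("first_encounter_dead", 0) or 0)
                    ),
                    direct_release=bool(int(row.get("direct_release", 0) or 0)),
                )
            )
        except (ValueError, ValidationError) as exc:
            errors.append(f"row {pos}: {exc}")
    if errors:
        raise ValidationError("; ".join(errors))
    return out


def read_histories(
    path: str | Path,
    format: str = "tabular",
    column_map: Mapping[str, str] | None = None,
    groups: Sequence[CohortGroup] | None = None,
) -> list[EncounterHistory]:
    """Read encounter histories from a tabular (CSV/XLSX) or ``.inp`` file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path)
        else:
            df = pd.read_csv(path, comment="#")
        return frame_to_histories(df, column_map)
    if format == "inp":
        if groups is None:
            raise ValidationError(".inp reading requires the group list")
        return read_inp(path, groups)
    raise ValueError(f"unknown format {format!r}")


def write_histories(histories: Iterable[EncounterHistory], path: str | Path) -> None:
    histories_to_frame(histories).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MARK .inp dialect
# ---------------------------------------------------------------------------

def write_inp(
    histories: Iterable[EncounterHistory],
    groups: Sequence[CohortGroup],
    path: str | Path,
) -> None:
    """Write a MARK-style ``.inp``: history string, one frequency column per
    group, trailing semicolon, with a comment header naming the groups."""
    gi = {g.key: i for i, g in enumerate(groups)}
    counts: dict[tuple[str, int], int] = {}
    for h in histories:
        key = (h.cohort, h.telemetry_occasions)
        if key not in gi:
            raise ValidationError(f"history {h.individual_id} has no group {key}")
        hist = "".join(str(x) for x in h.detections)
        counts[(hist, gi[key])] = counts.get((hist, gi[key]), 0) + 1
    lines = [
        "/* groups: "
        + " ".join(f"{i + 1}=({g.cohort},d{g.telemetry_occasions})" for i, g in enumerate(groups))
        + " */"
    ]
    for (hist, g), n in sorted(counts.items()):
        freq = ["0"] * len(groups)
        freq[g] = str(n)
        lines.append(f"{hist} {' '.join(freq)};")
    Path(path).write_text("\n".join(lines) + "\n")


def read_inp(path: str | Path, groups: Sequence[CohortGroup]) -> list[EncounterHistory]:
    """Read the ``.inp`` dialect written by :func:`write_inp`.

    Individual identities are not stored in ``.inp``; synthetic ids are
    assigned.  Comments ``/* ... */`` (possibly spanning lines) are ignored.
    """
    text = Path(path).read_text()
    text = re.sub(r"/\*.*?\*/", " ", text, flags=re.S)
    out: list[EncounterHistory] = []
    serial = 0
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if not line.endswith(";"):
            raise ValidationError(f"line {ln}: missing terminating ';'")
        parts = line[:-1].split()
        hist, freqs = parts[0], parts[1:]
        if not set(hist) <= {"0", "1"}:
            raise ValidationError(f"line {ln}: non-binary detection symbol in {hist!r}")
        if len(hist) != N_OCCASIONS:
            raise ValidationError(f"line {ln}: history length {len(hist)} != {N_OCCASIONS}")
        if len(freqs) != len(groups):
            raise ValidationError(
                f"line {ln}: expected {len(groups)} frequency columns, got {len(freqs)}"
            )
        det = tuple(int(c) for c in hist)
        for g, f in zip(groups, freqs):
            for _ in range(int(f)):
                serial += 1
                out.append(
                    EncounterHistory(
                        individual_id=f"inp{serial:05d}",
                        cohort=g.cohort,
                        telemetry_occasions=g.telemetry_occasions,
                        detections=det,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Inclusion rules
# ---------------------------------------------------------------------------

#: Rules applied to the raw encounter table before fitting, with the tags used
#: in the exclusion ledger.
DEFAULT_RULES: tuple[str, ...] = (
    "cohort_2014",
    "first_encounter_dead",
    "opportunistic_only",
    "direct_release",
)


def apply_inclusion_rules(
    raw: Iterable[EncounterHistory],
    rules: Sequence[str] = DEFAULT_RULES,
    survey_years: Sequence[int] = SURVEY_YEARS,
) -> tuple[list[EncounterHistory], pd.DataFrame]:
    """Filter raw histories; returns (retained, exclusion ledger).

    Rules: ``cohort_2014`` drops the 2014 release cohort (incomplete records);
    ``first_encounter_dead`` drops animals found dead at first encounter;
    ``opportunistic_only`` drops untracked animals whose only detections fall
    outside survey years (opportunistic sightings before trapping began);
    ``direct_release`` drops non-headstarted direct-release hatchlings.
    """
    retained: list[EncounterHistory] = []
    ledger_rows: list[dict[str, str]] = []
    survey_idx = {YEARS.index(y) for y in survey_years if y in YEARS}
    for h in raw:
        if h.cohort not in YEARS and h.cohort != 2014:
            raise ValidationError(
                f"{h.individual_id}: unknown cohort year {h.cohort}"
            )
        tag = None
        if "cohort_2014" in rules and h.cohort == 2014:
            tag = "cohort_2014"
        elif "direct_release" in rules and h.direct_release:
            tag = "direct_release"
        elif "first_encounter_dead" in rules and h.first_encounter_dead:
            tag = "first_encounter_dead"
        elif "opportunistic_only" in rules and h.telemetry_occasions == 0:
            det_idx = {t for t, x in enumerate(h.detections) if x}
            if det_idx and not det_idx & survey_idx:
                tag = "opportunistic_only"
        if tag is None:
            retained.append(h)
        else:
            ledger_rows.append({"individual_id": h.individual_id, "rule": tag})
    ledger = pd.DataFrame(ledger_rows, columns=["individual_id", "rule"])
    return retained, ledger
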