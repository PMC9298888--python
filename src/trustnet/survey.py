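"""Reading, validating and writing sociometric trust-survey data.

The survey instrument asks each member of a bounded partnership roster to
name up to seven partner organizations (a *name generator*), rate the
intensity of collaboration with each on a 6-level ordinal scale
(0 = "no interaction at all" ... 5 = "collaboration"), and rate agreement
with seven trust statements about each named partner on a 5-point Likert
scale (1 = strongly disagree ... 5 = strongly agree).

On disk a survey is long-format CSV, one row per (respondent, alter) dyad::

    respondent_id,alter_id,collaboration,trust_1,...,trust_7

Identifiers are opaque case-sensitive strings; nominated alters may fall
outside the roster (respondents were free to name unlisted organizations).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

MAX_NOMINATIONS = 7
N_DIMENSIONS = 7
TRUST_COLUMNS = tuple(f"trust_{d}" for d in range(1, N_DIMENSIONS + 1))
SURVEY_COLUMNS = ("respondent_id", "alter_id", "collaboration") + TRUST_COLUMNS

#: Neutral midpoint of the 5-point agreement scale ("neither agree nor
#: disagree"); used by the lenient reader to stand in for a missing rating,
#: which yields no trust edge.
NEUTRAL_RATING = 3


class SurveyValidationError(ValueError):
    """A survey file or record violates the instrument's constraints."""


@dataclass(frozen=True)
class SurveyRecord:
    """One respondent's nominations and ratings.

    ``collaboration[i]`` and ``trust[i]`` refer to ``alters[i]``; ``trust[i]``
    holds the seven dimension ratings in instrument order.
    """

    respondent_id: str
    alters: tuple[str, ...]
    collaboration: tuple[int, ...]
    trust: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        r = self.respondent_id
        if len(self.alters) > MAX_NOMINATIONS:
            raise SurveyValidationError(
                f"respondent {r!r} names {len(self.alters)} alters; "
                f"the survey caps nominations at {MAX_NOMINATIONS}"
            )
        if len(set(self.alters)) != len(self.alters):
            raise SurveyValidationError(f"respondent {r!r} names a duplicate alter")
        if r in self.alters:
            raise SurveyValidationError(f"respondent {r!r} nominates themself")
        if not (len(self.collaboration) == len(self.trust) == len(self.alters)):
            raise SurveyValidationError(
                f"respondent {r!r}: ratings are not aligned with the alter list"
            )
        for a, c in zip(self.alters, self.collaboration):
            if c not in range(0, 6):
                raise SurveyValidationError(
                    f"respondent {r!r}, alter {a!r}: collaboration rating {c} "
                    "outside the ordinal range 0..5"
                )
        for a, ts in zip(self.alters, self.trust):
            if len(ts) != N_DIMENSIONS:
                raise SurveyValidationError(
                    f"respondent {r!r}, alter {a!r}: expected {N_DIMENSIONS} "
                    f"trust ratings, got {len(ts)}"
                )
            for d, t in enumerate(ts, start=1):
                if t not in range(1, 6):
                    raise SurveyValidationError(
                        f"respondent {r!r}, alter {a!r}, trust_{d}: rating {t} "
                        "outside the Likert range 1..5"
                    )

    def rating(self, alter: str, dim: int) -> int:
        """Likert rating (1..5) the respondent gave `alter` on dimension `dim`."""
        return self.trust[self.alters.index(alter)][dim - 1]


@dataclass(frozen=True)
class Roster:
    """The bounded group the sociometric survey targets."""

    member_ids: frozenset[str]
    roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_ids", frozenset(self.member_ids))


def node_universe(roster: Roster | None, records: Iterable[SurveyRecord]) -> frozenset[str]:
    """Full node set shared by every network layer: roster members, every
    respondent, and every nominated alter (non-respondents and isolates kept)."""
    nodes: set[str] = set(roster.member_ids) if roster is not None else set()
    for rec in records:
        nodes.add(rec.respondent_id)
        nodes.update(rec.alters)
    return frozenset(nodes)


def _parse_int(raw: str, *, row: int, column: str, lenient: bool) -> int:
    raw = raw.strip()
    if raw == "":
        if lenient and column.startswith("trust_"):
            return NEUTRAL_RATING
        raise SurveyValidationError(f"row {row}: missing value in column {column!r}")
    try:
        return int(raw)
    except ValueError:
        raise SurveyValidationError(
            f"row {row}: cannot parse {raw!r} in column {column!r} as an integer"
        ) from None


def read_survey(
    path: str | Path,
    roster: Roster | None = None,
    *,
    lenient_missing: bool = False,
) -> tuple[Roster, list[SurveyRecord]]:
    """Read and validate a long-format survey CSV.

    Parameters
    ----------
    path
        CSV with header ``respondent_id,alter_id,collaboration,trust_1..trust_7``.
    roster
        Known roster. When omitted, the roster is inferred as the set of
        respondents (the minimal set consistent with a complete response).
    lenient_missing
        If True, a missing trust rating is treated as the neutral midpoint
        (no trust edge results). By default missing ratings are rejected.

    Returns
    -------
    (roster, records); the node universe is ``node_universe(roster, records)``.

    Raises
    ------
    SurveyValidationError
        Malformed rows (named with row number and column), more than seven
        nominations, out-of-range ordinal codes, duplicate dyads.
    """
    path = Path(path)
    rows_by_resp: dict[str, list[tuple[str, int, tuple[int, ...]]]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in SURVEY_COLUMNS if c not in header]
        if missing:
            raise SurveyValidationError(
                f"{path.name}: missing required column(s) {missing}"
            )
        for i, row in enumerate(reader, start=2):  # header is line 1
            resp = (row["respondent_id"] or "").strip()
            alter = (row["alter_id"] or "").strip()
            if not resp:
                raise SurveyValidationError(f"row {i}: empty respondent_id")
            if not alter:
                # a respondent who named no one: a single all-empty row
                rest = [row[c] for c in ("collaboration",) + TRUST_COLUMNS]
                if any((cell or "").strip() for cell in rest):
                    raise SurveyValidationError(
                        f"row {i}: ratings present but alter_id is empty"
                    )
                if rows_by_resp.setdefault(resp, []):
                    raise SurveyValidationError(
                        f"row {i}: respondent {resp!r} mixes an empty-alter row "
                        "with nominations"
                    )
                continue
            if resp in rows_by_resp and not rows_by_resp[resp]:
                raise SurveyValidationError(
                    f"row {i}: respondent {resp!r} mixes an empty-alter row "
                    "with nominations"
                )
            collab = _parse_int(
                row["collaboration"], row=i, column="collaboration", lenient=False
            )
            trust = tuple(
                _parse_int(row[c], row=i, column=c, lenient=lenient_missing)
                for c in TRUST_COLUMNS
            )
            rows_by_resp.setdefault(resp, []).append((alter, collab, trust))

    records = []
    for resp, rows in rows_by_resp.items():
        records.append(
            SurveyRecord(
                respondent_id=resp,
                alters=tuple(a for a, _, _ in rows),
                collaboration=tuple(c for _, c, _ in rows),
                trust=tuple(t for _, _, t in rows),
            )
        )
    if roster is None:
        roster = Roster(frozenset(r.respondent_id for r in records))
    else:
        stray = {r.respondent_id for r in records} - set(roster.member_ids)
        if stray:
            raise SurveyValidationError(
                f"respondent(s) not on the roster: {sorted(stray)}"
            )
    return roster, records


def read_roster(path: str | Path) -> Roster:
    """Read a roster CSV: ``member_id`` column required, ``role`` optional."""
    path = Path(path)
    members: dict[str, str] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if not reader.fieldnames or "member_id" not in reader.fieldnames:
            raise SurveyValidationError(f"{path.name}: need a member_id column")
        for row in reader:
            member = (row["member_id"] or "").strip()
            if member:
                members[member] = (row.get("role") or "").strip()
    return Roster(frozenset(members), {m: r for m, r in members.items() if r})


def write_roster(roster: Roster, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["member_id", "role"])
        for m in sorted(roster.member_ids):
            writer.writerow([m, roster.roles.get(m, "")])
    return path


def write_survey(records: Sequence[SurveyRecord], path: str | Path) -> Path:
    """Write records as long-format CSV; inverse of :func:`read_survey`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SURVEY_COLUMNS)
        for rec in records:
            if not rec.alters:  # respondent who named no one
                writer.writerow([rec.respondent_id] + [""] * (len(SURVEY_COLUMNS) - 1))
            for alter, collab, trust in zip(rec.alters, rec.collaboration, rec.trust):
                writer.writerow([rec.respondent_id, alter, collab, *trust])
    return path
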