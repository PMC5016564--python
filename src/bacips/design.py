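"""Study-design and encounter-history data model.

A BACI paired-series mark-recapture study is described by an ordered list of
sampling occasions (calendar dates), the seasonal intervals between them,
the date the restoration action was installed, and a table of sampled sites
with their lengths.  Survival over an interval of ``d`` days is standardized
to a common base period (a 3-month quarter by default) by raising the
base-period survival probability to the exponent ``d / base_period_days``.

Encounter histories are one 0/1 detection code per occasion per individual,
conditional on first capture, with optional right-censoring: an individual
detected emigrating is removed from the risk set immediately after its last
detection occasion so that permanent emigration does not bias survival.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "SamplingOccasion",
    "SeasonalInterval",
    "EncounterHistory",
    "Site",
    "StudyDesign",
    "SessionClassification",
    "interval_days",
    "standardization_exponent",
    "classify_sessions",
    "read_encounter_histories",
    "write_encounter_histories",
    "read_design",
    "write_design",
]

DEFAULT_BASE_PERIOD_DAYS = 91.25  # one quarter of a 365-day year

_SEASONS = ("spring", "fall", "winter")
_ERAS = ("before", "after")
_WATERSHEDS = ("treatment", "control")


def interval_days(start: _dt.date, end: _dt.date) -> int:
    """Exact Gregorian calendar-day count from ``start`` to ``end``.

    Raises
    ------
    ValueError
        If ``end`` precedes ``start``.
    """
    if end < start:
        raise ValueError(f"end date {end} precedes start date {start}")
    return (end - start).days


def standardization_exponent(days: float, base_period_days: float = DEFAULT_BASE_PERIOD_DAYS) -> float:
    """Exponent mapping base-period survival to an interval of ``days`` days.

    An interval of length ``days`` contributes ``S ** (days / base_period_days)``
    to the likelihood, standardizing all survival estimates to the base period.
    """
    if days <= 0:
        raise ValueError(f"interval length must be positive, got {days}")
    if base_period_days <= 0:
        raise ValueError(f"base period must be positive, got {base_period_days}")
    return days / base_period_days


@dataclass
class SamplingOccasion:
    """A dated capture occasion."""

    occasion_id: int
    date: _dt.date
    season_label: str
    era: str | None = None

    def __post_init__(self) -> None:
        if self.season_label not in _SEASONS:
            raise ValueError(f"unknown season {self.season_label!r}; expected one of {_SEASONS}")
        if self.era is not None and self.era not in _ERAS:
            raise ValueError(f"unknown era {self.era!r}")


@dataclass
class SeasonalInterval:
    """The gap between two consecutive occasions, with its standardization exponent."""

    interval_id: int
    start_occasion: int
    end_occasion: int
    days: int
    exponent: float
    era: str | None = None

    def __post_init__(self) -> None:
        if self.days <= 0:
            raise ValueError("interval must span at least one day")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")


@dataclass
class EncounterHistory:
    """Per-individual detection record, conditional on first capture.

    ``censored_after`` marks the occasion after which the individual leaves
    the risk set (a detected emigrant); detections recorded after that
    occasion are ignored by every likelihood.
    """

    individual_id: str
    watershed: str
    site_id: str
    detections: tuple[int, ...]
    censored_after: int | None = None

    def __post_init__(self) -> None:
        self.detections = tuple(int(d) for d in self.detections)
        if any(d not in (0, 1) for d in self.detections):
            raise ValueError(f"detections must be 0/1, got {self.detections}")
        if 1 not in self.detections:
            raise ValueError("an encounter history must contain at least one detection")
        if self.watershed not in _WATERSHEDS:
            raise ValueError(f"unknown watershed {self.watershed!r}")
        if self.censored_after is not None:
            if self.censored_after < self.first_detection:
                raise ValueError(
                    f"censored_after={self.censored_after} precedes first detection "
                    f"occasion {self.first_detection}"
                )

    @property
    def first_detection(self) -> int:
        return self.detections.index(1)

    @property
    def last_detection(self) -> int:
        return len(self.detections) - 1 - self.detections[::-1].index(1)


@dataclass
class Site:
    watershed: str
    length_m: float

    def __post_init__(self) -> None:
        if self.watershed not in _WATERSHEDS:
            raise ValueError(f"unknown watershed {self.watershed!r}")
        if self.length_m <= 0:
            raise ValueError("site length must be positive")


@dataclass
class StudyDesign:
    """Occasions, derived intervals, installation date, and the site table.

    ``survival_start_index`` marks the first occasion that participates in the
    survival interval structure; occasions before it (e.g. an extra
    abundance-only session at the start of a study) carry no interval.
    """

    occasions: list[SamplingOccasion]
    installation_date: _dt.date
    base_period_days: float = DEFAULT_BASE_PERIOD_DAYS
    sites: dict[str, Site] = field(default_factory=dict)
    survival_start_index: int = 0
    intervals: list[SeasonalInterval] = field(init=False)

    def __post_init__(self) -> None:
        dates = [o.date for o in self.occasions]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("occasion dates must be strictly increasing")
        if self.base_period_days <= 0:
            raise ValueError("base_period_days must be positive")
        self.intervals = []
        survival_occs = self.occasions[self.survival_start_index:]
        for k, (a, b) in enumerate(zip(survival_occs, survival_occs[1:])):
            days = interval_days(a.date, b.date)
            self.intervals.append(
                SeasonalInterval(
                    interval_id=k,
                    start_occasion=a.occasion_id,
                    end_occasion=b.occasion_id,
                    days=days,
                    exponent=standardization_exponent(days, self.base_period_days),
                )
            )

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def site_length(self, site_id: str) -> float:
        return self.sites[site_id].length_m


@dataclass
class SessionClassification:
    """Era assignment summary produced by :func:`classify_sessions`."""

    occasion_eras: list[str]
    interval_eras: list[str]
    n_occasions_before: int
    n_occasions_after: int
    n_intervals_before: int
    n_intervals_after: int


def classify_sessions(design: StudyDesign) -> SessionClassification:
    """Assign before/after era labels to every occasion and interval.

    An interval is "after" iff it starts on or after the installation date.
    An occasion inherits the era of the interval it terminates; an occasion
    terminating no interval (the first occasion, or any occasion preceding
    the survival interval structure) is "before" when its date precedes the
    installation date and "after" otherwise.

    Era labels are written back onto the design's occasions and intervals.
    """
    first, last = design.occasions[0].date, design.occasions[-1].date
    if not (first <= design.installation_date <= last):
        raise ValueError(
            f"installation date {design.installation_date} falls outside the "
            f"study span [{first}, {last}]"
        )

    terminating: dict[int, SeasonalInterval] = {}
    for iv in design.intervals:
        start_date = design.occasions[iv.start_occasion].date
        iv.era = "after" if start_date >= design.installation_date else "before"
        terminating[iv.end_occasion] = iv

    occ_eras: list[str] = []
    for occ in design.occasions:
        iv = terminating.get(occ.occasion_id)
        if iv is not None:
            occ.era = iv.era
        else:
            occ.era = "before" if occ.date < design.installation_date else "after"
        occ_eras.append(occ.era)

    iv_eras = [iv.era for iv in design.intervals]
    return SessionClassification(
        occasion_eras=occ_eras,
        interval_eras=iv_eras,
        n_occasions_before=occ_eras.count("before"),
        n_occasions_after=occ_eras.count("after"),
        n_intervals_before=iv_eras.count("before"),
        n_intervals_after=iv_eras.count("after"),
    )


# ---------------------------------------------------------------------------
# encounter-history file formats
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(r"/\*.*?\*/", re.DOTALL)


class EncounterFileError(ValueError):
    """Malformed encounter-history file; message carries the line number."""


def _parse_inp(text: str, n_occasions: int, site_id: str, watershed: str) -> list[EncounterHistory]:
    """Parse the classic capture-history ``.inp`` dialect.

    Each statement is ``<history> <frequency>;`` with comments ``/* ... */``
    stripped.  A negative frequency marks a loss on (last) capture: the
    history is right-censored immediately after its final detection.
    """
    histories: list[EncounterHistory] = []
    counter = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _COMMENT_RE.sub(" ", raw).strip()
        if not line:
            continue
        for stmt in filter(None, (s.strip() for s in line.split(";"))):
            parts = stmt.split()
            if len(parts) != 2:
                raise EncounterFileError(f"line {lineno}: expected '<history> <freq>;', got {stmt!r}")
            hist, freq_s = parts
            if len(hist) != n_occasions:
                raise EncounterFileError(
                    f"line {lineno}: history {hist!r} has {len(hist)} codes for a "
                    f"{n_occasions}-occasion design"
                )
            if set(hist) - {"0", "1"}:
                raise EncounterFileError(f"line {lineno}: non-0/1 code in history {hist!r}")
            try:
                freq = int(freq_s)
            except ValueError:
                raise EncounterFileError(f"line {lineno}: bad frequency {freq_s!r}") from None
            detections = tuple(int(c) for c in hist)
            censored = freq < 0
            for _ in range(abs(freq)):
                counter += 1
                h = EncounterHistory(
                    individual_id=f"{site_id}-{counter:06d}",
                    watershed=watershed,
                    site_id=site_id,
                    detections=detections,
                    censored_after=None,
                )
                if censored:
                    h.censored_after = h.last_detection
                histories.append(h)
    return histories


def _parse_long_csv(text: str, n_occasions: int, site_watershed: Mapping[str, str] | None) -> list[EncounterHistory]:
    reader = csv.DictReader(io.StringIO(text))
    required = {"individual_id", "site_id", "occasion_id", "detected"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise EncounterFileError(f"long CSV must have columns {sorted(required)}")
    rows: dict[str, dict] = {}
    for lineno, row in enumerate(reader, start=2):
        iid = row["individual_id"]
        occ = int(row["occasion_id"])
        if not 0 <= occ < n_occasions:
            raise EncounterFileError(f"line {lineno}: occasion_id {occ} outside 0..{n_occasions - 1}")
        det = row["detected"].strip()
        if det not in ("0", "1"):
            raise EncounterFileError(f"line {lineno}: detected must be 0/1, got {det!r}")
        rec = rows.setdefault(
            iid,
            {
                "site_id": row["site_id"],
                "watershed": row.get("watershed", ""),
                "detections": [0] * n_occasions,
                "censored_after": None,
            },
        )
        if site_watershed is not None and row["site_id"] in site_watershed:
            rec["watershed"] = site_watershed[row["site_id"]]
        rec["detections"][occ] = int(det)
        cens = (row.get("censored") or "").strip()
        if cens not in ("", "0") and det == "1":
            prev = rec["censored_after"]
            rec["censored_after"] = occ if prev is None else min(prev, occ)
    out = []
    for iid, rec in rows.items():
        out.append(
            EncounterHistory(
                individual_id=iid,
                watershed=rec["watershed"] or "treatment",
                site_id=rec["site_id"],
                detections=tuple(rec["detections"]),
                censored_after=rec["censored_after"],
            )
        )
    return out


def read_encounter_histories(
    path: str | Path,
    dialect: str = "csv",
    *,
    n_occasions: int | None = None,
    design: StudyDesign | None = None,
    site_id: str = "site-1",
    watershed: str = "treatment",
) -> list[EncounterHistory]:
    """Read encounter histories from a ``.inp`` dialect or long-format CSV file.

    ``n_occasions`` (or a ``design`` to take it from) is required to validate
    history lengths.  For the ``inp`` dialect, all histories are assigned to
    ``site_id``/``watershed`` since the format carries no group labels.
    """
    if design is not None:
        n_occasions = design.n_occasions
    if n_occasions is None:
        raise ValueError("n_occasions (or design) is required")
    text = Path(path).read_text()
    if dialect == "inp":
        histories = _parse_inp(text, n_occasions, site_id, watershed)
    elif dialect == "csv":
        site_ws = None
        if design is not None:
            site_ws = {sid: s.watershed for sid, s in design.sites.items()}
        histories = _parse_long_csv(text, n_occasions, site_ws)
        if design is not None and design.sites:
            for h in histories:
                if h.site_id not in design.sites:
                    raise EncounterFileError(f"unknown site {h.site_id!r} for individual {h.individual_id!r}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'inp' or 'csv'")
    return histories


def write_encounter_histories(path: str | Path, histories: Iterable[EncounterHistory], dialect: str = "csv") -> None:
    """Write histories in the long CSV format or the ``.inp`` dialect."""
    path = Path(path)
    histories = list(histories)
    if dialect == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["individual_id", "watershed", "site_id", "occasion_id", "detected", "censored"])
            for h in histories:
                for occ, det in enumerate(h.detections):
                    cens = int(h.censored_after == occ)
                    w.writerow([h.individual_id, h.watershed, h.site_id, occ, det, cens])
    elif dialect == "inp":
        with path.open("w") as fh:
            for h in histories:
                hist = "".join(str(d) for d in h.detections)
                freq = -1 if h.censored_after is not None else 1
                fh.write(f"/* {h.individual_id} */ {hist} {freq};\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# study-design files: occasions CSV + YAML config
# ---------------------------------------------------------------------------

def write_design(design: StudyDesign, occasions_csv: str | Path, config_yaml: str | Path) -> None:
    with Path(occasions_csv).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["occasion_id", "date", "season", "era"])
        for o in design.occasions:
            w.writerow([o.occasion_id, o.date.isoformat(), o.season_label, o.era or ""])
    cfg = {
        "installation_date": design.installation_date.isoformat(),
        "base_period_days": design.base_period_days,
        "survival_start_index": design.survival_start_index,
        "sites": {sid: {"watershed": s.watershed, "length_m": s.length_m} for sid, s in design.sites.items()},
    }
    Path(config_yaml).write_text(yaml.safe_dump(cfg, sort_keys=False))


def read_design(occasions_csv: str | Path, config_yaml: str | Path) -> StudyDesign:
    cfg = yaml.safe_load(Path(config_yaml).read_text())
    occasions = []
    with Path(occasions_csv).open() as fh:
        for row in csv.DictReader(fh):
            occasions.append(
                SamplingOccasion(
                    occasion_id=int(row["occasion_id"]),
                    date=_dt.date.fromisoformat(row["date"]),
                    season_label=row["season"],
                    era=row.get("era") or None,
                )
            )
    sites = {
        sid: Site(watershed=s["watershed"], length_m=float(s["length_m"]))
        for sid, s in (cfg.get("sites") or {}).items()
    }
    design = StudyDesign(
        occasions=occasions,
        installation_date=_dt.date.fromisoformat(cfg["installation_date"]),
        base_period_days=float(cfg.get("base_period_days", DEFAULT_BASE_PERIOD_DAYS)),
        sites=sites,
        survival_start_index=int(cfg.get("survival_start_index", 0)),
    )
    classify_sessions(design)
    return design
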