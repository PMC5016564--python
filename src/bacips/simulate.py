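"""Synthetic BACI paired-series mark-recapture datasets with known truth.

Emulates the structure of a two-watershed (treatment/control) seasonal
study: staggered PIT-tag releases, Bernoulli survival over unequal-length
intervals (probability S_t^exponent), Bernoulli detection at each later
occasion, optional detected-emigration censoring, and two-day closed capture
sessions at each site for abundance.  Survival follows three seasonal levels
with lower winter and higher spring/fall values; a treatment effect k_S is
applied on the odds scale to treatment-watershed after-era survival (which
keeps probabilities inside (0,1)), and k_D multiplies treatment after-era
abundance.  k = 1 reproduces the null.  Because the ratio statistic lives on
the probability scale, recovery targets are always computed from the
realized simulated probabilities, not from k directly.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .closed_capture import SessionCounts
from .design import (
    EncounterHistory,
    SamplingOccasion,
    Site,
    StudyDesign,
    classify_sessions,
)

__all__ = [
    "SimulationTruth",
    "simulate_open_population",
    "simulate_closed_sessions",
    "make_seasonal_study_design",
    "make_desk_design",
    "simulate_baci_dataset",
    "season_of_month",
]

# Table of seasonal study boundaries: 16 survival intervals spanning
# 2007-06-04 .. 2012-09-11, eight per era around a December 2009 action,
# preceded by one abundance-only winter 2007 session.
_SEASONAL_BOUNDARIES = [
    "2007-06-04", "2007-09-01", "2007-11-28", "2008-06-01", "2008-09-01",
    "2008-12-12", "2009-06-10", "2009-09-14", "2010-01-22", "2010-06-09",
    "2010-09-13", "2011-01-24", "2011-06-24", "2011-09-16", "2012-01-10",
    "2012-06-21", "2012-09-11",
]
_EXTRA_WINTER_SESSION = "2007-01-15"  # day within "January 2007" chosen as a convention
_INSTALLATION = "2009-12-01"

# default seasonal base-period survival levels: winter low, spring/fall high
DEFAULT_SEASONAL_S = {"spring": 0.72, "fall": 0.68, "winter": 0.52}


def season_of_month(month: int) -> str:
    """Seasonal label of an occasion date: Jun-Aug spring, Sep-Oct fall, else winter."""
    if month in (6, 7, 8):
        return "spring"
    if month in (9, 10):
        return "fall"
    return "winter"


def _default_sites(n_treatment: int, n_control: int, length_m: float) -> dict[str, Site]:
    sites = {}
    for i in range(n_treatment):
        sites[f"t{i + 1:02d}"] = Site(watershed="treatment", length_m=length_m)
    for i in range(n_control):
        sites[f"c{i + 1:02d}"] = Site(watershed="control", length_m=length_m)
    return sites


def make_seasonal_study_design(
    n_treatment_sites: int = 9,
    n_control_sites: int = 3,
    site_length_m: float = 750.0,
) -> StudyDesign:
    """The 16-interval seasonal design plus the extra winter 2007 session.

    Occasion 0 is the abundance-only January 2007 session; survival
    intervals start from the June 2007 occasion (``survival_start_index=1``).
    Era labels are assigned on construction.
    """
    dates = [_dt.date.fromisoformat(_EXTRA_WINTER_SESSION)] + [
        _dt.date.fromisoformat(d) for d in _SEASONAL_BOUNDARIES
    ]
    occasions = [
        SamplingOccasion(occasion_id=i, date=d, season_label=season_of_month(d.month))
        for i, d in enumerate(dates)
    ]
    design = StudyDesign(
        occasions=occasions,
        installation_date=_dt.date.fromisoformat(_INSTALLATION),
        sites=_default_sites(n_treatment_sites, n_control_sites, site_length_m),
        survival_start_index=1,
    )
    classify_sessions(design)
    return design


def make_desk_design(
    n_before: int = 6,
    n_after: int = 6,
    first_date: _dt.date = _dt.date(2008, 1, 1),
    interval_days_: int = 91,
    n_treatment_sites: int = 3,
    n_control_sites: int = 3,
    site_length_m: float = 750.0,
) -> StudyDesign:
    """A small regular design: quarterly occasions, n_before + n_after intervals."""
    n_occ = n_before + n_after + 1
    dates = [first_date + _dt.timedelta(days=interval_days_ * i) for i in range(n_occ)]
    occasions = [
        SamplingOccasion(occasion_id=i, date=d, season_label=season_of_month(d.month))
        for i, d in enumerate(dates)
    ]
    design = StudyDesign(
        occasions=occasions,
        installation_date=dates[n_before],
        sites=_default_sites(n_treatment_sites, n_control_sites, site_length_m),
    )
    classify_sessions(design)
    return design


def _apply_odds_effect(s: np.ndarray, k: float, mask: np.ndarray) -> np.ndarray:
    """Multiply survival odds by k where mask holds; stays inside (0, 1)."""
    out = s.copy()
    odds = k * s[mask] / (1.0 - s[mask])
    out[mask] = odds / (1.0 + odds)
    return out


@dataclass
class SimulationTruth:
    """Known generating values for one synthetic BACI dataset."""

    s_treatment: np.ndarray          # (T,) base-period survival per interval
    s_control: np.ndarray
    p_detect: np.ndarray             # (T,) detection probability at occasions 1..T
    p_capture: float                 # closed-session per-day capture probability
    n_site_period: dict[str, list[int]]  # site -> true N per abundance period
    k_s: float = 1.0
    k_d: float = 1.0
    emigration_prob: float = 0.0     # per-detection probability of detected emigration
    seed: int = 0
    interval_eras: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.s_treatment = np.asarray(self.s_treatment, dtype=float)
        self.s_control = np.asarray(self.s_control, dtype=float)
        self.p_detect = np.asarray(self.p_detect, dtype=float)
        for name, arr in (("s_treatment", self.s_treatment), ("s_control", self.s_control),
                          ("p_detect", self.p_detect)):
            if np.any(arr <= 0) or np.any(arr >= 1):
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        if not 0 < self.p_capture < 1:
            raise ValueError("p_capture must lie in (0, 1)")
        if not 0 <= self.emigration_prob < 1:
            raise ValueError("emigration_prob must lie in [0, 1)")

    @classmethod
    def from_design(
        cls,
        design: StudyDesign,
        seasonal_s: dict[str, float] | None = None,
        treatment_offset: float = 0.9,
        p_detect: float = 0.45,
        p_capture: float = 0.35,
        mean_site_n: int = 150,
        k_s: float = 1.0,
        k_d: float = 1.0,
        emigration_prob: float = 0.02,
        seed: int = 0,
    ) -> "SimulationTruth":
        """Build truth values on a design's interval/era scaffold.

        Control survival follows the seasonal levels; the treatment
        watershed's baseline odds are scaled by ``treatment_offset`` (a
        background difference the paired design must absorb); k_s then
        multiplies treatment odds on after-era intervals only.  Site
        abundances are Poisson around ``mean_site_n``, with k_d applied to
        treatment after-era periods.
        """
        seasonal_s = dict(DEFAULT_SEASONAL_S, **(seasonal_s or {}))
        eras = [iv.era for iv in design.intervals]
        if any(e is None for e in eras):
            raise ValueError("design intervals carry no era labels; run classify_sessions first")
        rng = np.random.default_rng(seed)
        seasons = [design.occasions[iv.start_occasion].season_label for iv in design.intervals]
        s_ctrl = np.array([seasonal_s[s] for s in seasons])
        s_treat = _apply_odds_effect(s_ctrl, treatment_offset, np.ones(len(eras), dtype=bool))
        after = np.array([e == "after" for e in eras])
        s_treat = _apply_odds_effect(s_treat, k_s, after)

        occ_eras = [o.era for o in design.occasions]
        n_site_period: dict[str, list[int]] = {}
        for site_id, site in design.sites.items():
            ns = []
            for occ_era in occ_eras:
                base = rng.poisson(mean_site_n)
                if site.watershed == "treatment" and occ_era == "after":
                    base = int(round(base * k_d))
                ns.append(max(base, 0))
            n_site_period[site_id] = ns

        T = len(eras)
        return cls(
            s_treatment=s_treat,
            s_control=s_ctrl,
            p_detect=np.full(T, p_detect),
            p_capture=p_capture,
            n_site_period=n_site_period,
            k_s=k_s,
            k_d=k_d,
            emigration_prob=emigration_prob,
            seed=seed,
            interval_eras=list(eras),
        )

    def true_r_s_baci(self) -> float:
        """R_BACI implied by the generating survival probabilities."""
        r = np.log(self.s_treatment / self.s_control)
        eras = np.asarray(self.interval_eras)
        return float(np.exp(r[eras == "after"].mean() - r[eras == "before"].mean()))

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("s_treatment", "s_control", "p_detect"):
            d[key] = list(np.asarray(d[key], dtype=float))
        Path(path).write_text(json.dumps(d, indent=2, default=float))


def simulate_open_population(
    truth: SimulationTruth,
    n_released_per_occasion: int,
    design: StudyDesign,
    seed: int | None = None,
) -> list[EncounterHistory]:
    """Simulate encounter histories for both watersheds on the survival frame.

    ``n_released_per_occasion`` newly tagged individuals enter per watershed
    at each occasion except the last.  Each survives interval t with
    probability S_t^exponent, is detected at later occasions with the
    occasion's detection probability, and each detection may be a detected
    emigration (censoring the history there).  Histories are indexed on the
    survival occasions (``design.survival_start_index`` onward).
    """
    T = design.n_intervals
    if truth.s_treatment.shape[0] != T:
        raise ValueError(
            f"truth has {truth.s_treatment.shape[0]} intervals; design has {T}"
        )
    K = T + 1
    exponents = np.array([iv.exponent for iv in design.intervals])
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    sites_by_ws = {
        ws: [sid for sid, s in design.sites.items() if s.watershed == ws]
        for ws in ("treatment", "control")
    }
    histories: list[EncounterHistory] = []
    for ws, s_true in (("treatment", truth.s_treatment), ("control", truth.s_control)):
        se = s_true ** exponents
        sites = sites_by_ws[ws] or [f"{ws}-site"]
        counter = 0
        for release_occ in range(K - 1):
            for _ in range(n_released_per_occasion):
                counter += 1
                det = [0] * K
                det[release_occ] = 1
                censored_after: int | None = None
                alive = True
                for t in range(release_occ, T):
                    alive = rng.random() < se[t]
                    if not alive:
                        break
                    if rng.random() < truth.p_detect[t]:
                        det[t + 1] = 1
                        if truth.emigration_prob and rng.random() < truth.emigration_prob:
                            censored_after = t + 1
                            break
                histories.append(
                    EncounterHistory(
                        individual_id=f"{ws[0]}{counter:06d}",
                        watershed=ws,
                        site_id=sites[counter % len(sites)],
                        detections=tuple(det),
                        censored_after=censored_after,
                    )
                )
    return histories


def simulate_closed_sessions(
    N: int,
    p: float,
    seed_or_rng: int | np.random.Generator = 0,
    site_id: str = "site-1",
    period_id: int = 0,
) -> SessionCounts:
    """Two-day closed-capture session tallies for one site and period.

    Each of the N individuals is captured independently on each day with
    probability p, giving multinomial (n10, n11, n01, unseen) counts.
    """
    if N < 0:
        raise ValueError("N must be nonnegative")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    probs = [p * (1 - p), p * p, (1 - p) * p, (1 - p) * (1 - p)]
    n10, n11, n01, _ = rng.multinomial(N, probs)
    return SessionCounts(site_id=site_id, period_id=period_id, n10=int(n10), n11=int(n11), n01=int(n01))


def simulate_baci_dataset(
    design: StudyDesign,
    truth: SimulationTruth | None = None,
    n_released_per_occasion: int = 300,
    seed: int = 0,
    **truth_kwargs,
) -> tuple[list[EncounterHistory], list[SessionCounts], SimulationTruth]:
    """One full synthetic dataset: histories, closed-session counts, truth."""
    if truth is None:
        truth = SimulationTruth.from_design(design, seed=seed, **truth_kwargs)
    rng = np.random.default_rng(seed)
    histories = simulate_open_population(
        truth, n_released_per_occasion, design, seed=int(rng.integers(2**31 - 1))
    )
    counts = []
    for site_id, ns in truth.n_site_period.items():
        for period_id, N in enumerate(ns):
            counts.append(
                simulate_closed_sessions(
                    N, truth.p_capture,
                    np.random.default_rng(int(rng.integers(2**31 - 1))),
                    site_id=site_id, period_id=period_id,
                )
            )
    return histories, counts, truth
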