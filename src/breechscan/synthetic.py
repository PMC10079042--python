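"""Seeded synthetic birth cohorts for a before/after screening-policy study.

The generator emulates the statistical structure the analyses assume, so the
whole pipeline is testable without any real maternity records: two epochs of
births, a 3-4% term breech rate, an epoch-dependent fraction of breech
presentations missed antenatally (high before a universal-scanning policy,
low after), and rare adverse neonatal outcomes whose risk is elevated when
the breech was undiagnosed.  Alongside the records it returns a "truth tally"
of every planted count, which downstream tests compare against the pipeline's
own aggregation.

Default rates correspond to the study conditions the pipeline targets: breech
prevalence 3.4% at term, undiagnosed fraction 14.2% before and 2.8% after the
policy change.  Conditional adverse-outcome risks are simulation knobs chosen
to make rare events observable at test sample sizes while preserving the
risk ordering (undiagnosed > diagnosed > non-breech).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cohort import TERM_DAYS, BirthRecord, EpochSpec

#: (risk if breech antenatally diagnosed, risk if breech undiagnosed)
DEFAULT_OUTCOME_RISKS: dict[str, tuple[float, float]] = {
    "apgar_lt7": (0.008, 0.08),
    "nnu_admission": (0.015, 0.07),
    "hie": (0.002, 0.02),
    "perinatal_death": (0.001, 0.012),
}

#: Risk of each outcome among non-breech births; keeps whole-cohort tables
#: populated even though the comparisons of interest condition on breech.
DEFAULT_BASELINE_RISKS: dict[str, float] = {
    "apgar_lt7": 0.004,
    "nnu_admission": 0.010,
    "hie": 0.0005,
    "perinatal_death": 0.0005,
}

_ETHNICITY_LEVELS = ("caucasian", "black", "asian", "mixed", "other", "not_stated")
_ETHNICITY_PROBS = (0.50, 0.06, 0.13, 0.04, 0.10, 0.17)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated two-epoch cohort."""

    n_before: int
    n_after: int
    months_before: int = 12
    months_after: int = 12
    cut_date: dt.date = dt.date(2020, 1, 1)
    p_breech: float = 0.034
    p_undiagnosed_given_breech: tuple[float, float] = (0.142, 0.028)
    p_multiple: float = 0.015
    p_preterm: float = 0.06
    p_anomaly: float = 0.02
    p_planned_cs_given_diagnosed: float = 0.70
    outcome_risks: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_RISKS)
    )
    baseline_risks: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RISKS)
    )
    age_mean: tuple[float, float] = (33.2, 35.7)
    age_sd: float = 5.3
    bmi_mean: float = 25.6
    bmi_sd: float = 5.35
    p_parous: float = 0.49
    site: str = "routine_us"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_before <= 0 or self.n_after <= 0:
            raise ValueError("n_before and n_after must be positive")
        if self.months_before <= 0 or self.months_after <= 0:
            raise ValueError("months_before and months_after must be positive")
        probs = {
            "p_breech": self.p_breech,
            "p_multiple": self.p_multiple,
            "p_preterm": self.p_preterm,
            "p_anomaly": self.p_anomaly,
            "p_planned_cs_given_diagnosed": self.p_planned_cs_given_diagnosed,
            "p_undiagnosed(before)": self.p_undiagnosed_given_breech[0],
            "p_undiagnosed(after)": self.p_undiagnosed_given_breech[1],
            "p_parous": self.p_parous,
        }
        for name, risks in self.outcome_risks.items():
            probs[f"outcome_risks[{name}][diagnosed]"] = risks[0]
            probs[f"outcome_risks[{name}][undiagnosed]"] = risks[1]
        for name, risk in self.baseline_risks.items():
            probs[f"baseline_risks[{name}]"] = risk
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} is not a probability")

    @property
    def epoch(self) -> EpochSpec:
        return EpochSpec(cut_date=self.cut_date)


def _month_start(date: dt.date, months_back: int) -> dt.date:
    """First day of the month ``months_back`` calendar months before ``date``'s month."""
    month = date.month - 1 - months_back
    year = date.year + month // 12
    return dt.date(year, month % 12 + 1, 1)


def generate_cohort(
    config: SimConfig,
) -> tuple[list[BirthRecord], dict[str, dict]]:
    """Simulate a two-epoch cohort; returns (records, truth tally).

    One seeded pseudo-random stream drives the whole cohort, so identical
    configs (including seed) give identical record lists.  The truth tally
    has one entry per epoch label with the planted counts the pipeline
    should recover::

        n_births, excluded_multiple, excluded_preterm, excluded_anomaly,
        n_eligible                -- term singleton non-anomalous births
        n_breech                  -- breech among eligible
        n_planned_cs_breech       -- planned cesareans for breech among those
        n_undiagnosed             -- undiagnosed breech among eligible breech
        outcomes[name]            -- events among eligible breech (all, and
                                     excluding planned cesareans)

    Exclusion counts use the same reason priority as the pipeline filter
    (multiple pregnancy, then preterm, then anomaly).
    """
    rng = np.random.default_rng(config.seed)
    records: list[BirthRecord] = []
    truth: dict[str, dict] = {}

    epoch_defs = [
        ("before", config.n_before, _month_start(config.cut_date, config.months_before),
         config.cut_date, config.p_undiagnosed_given_breech[0]),
        ("after", config.n_after, config.cut_date,
         _month_start(config.cut_date, -config.months_after),
         config.p_undiagnosed_given_breech[1]),
    ]

    for label, n, start, end, p_undiag in epoch_defs:
        span_days = (end - start).days
        day_offsets = rng.integers(0, span_days, size=n)

        multiple = rng.random(n) < config.p_multiple
        preterm = rng.random(n) < config.p_preterm
        anomaly = rng.random(n) < config.p_anomaly
        breech = rng.random(n) < config.p_breech
        eligible = ~multiple & ~preterm & ~anomaly

        diagnosed = np.zeros(n, dtype=bool)
        diagnosed[breech] = rng.random(breech.sum()) >= p_undiag
        undiag = breech & ~diagnosed

        planned_cs = np.zeros(n, dtype=bool)
        dx_idx = np.flatnonzero(breech & diagnosed)
        planned_cs[dx_idx] = (
            rng.random(dx_idx.size) < config.p_planned_cs_given_diagnosed
        )

        # Labour onset: planned cesareans never labour; everyone else gets a
        # mixture of spontaneous labour, prelabour ROM, and induction.
        onset = rng.choice(
            ["spontaneous_labour", "prelabour_rom", "induction"],
            size=n,
            p=[0.55, 0.15, 0.30],
        ).astype(object)
        onset[planned_cs] = "planned_cesarean"
        # A fraction of diagnosed breeches not booked for cesarean are still
        # delivered before labour (e.g. cesarean for another indication).
        dx_nocs = np.flatnonzero(breech & diagnosed & ~planned_cs)
        pre_labour = dx_nocs[rng.random(dx_nocs.size) < 0.2]
        onset[pre_labour] = "planned_cesarean"

        mode = np.empty(n, dtype=object)
        vertex = ~breech
        mode[vertex] = rng.choice(
            [
                "vaginal_vertex_spontaneous",
                "vaginal_vertex_operative",
                "emergency_cesarean",
                "elective_cesarean",
            ],
            size=int(vertex.sum()),
            p=[0.59, 0.17, 0.12, 0.12],
        )
        br_idx = np.flatnonzero(breech)
        mode[br_idx] = rng.choice(
            [
                "emergency_cesarean",
                "vaginal_breech_spontaneous",
                "vaginal_breech_extraction",
                "vaginal_breech_forceps",
            ],
            size=br_idx.size,
            p=[0.80, 0.13, 0.05, 0.02],
        )
        mode[planned_cs] = "elective_cesarean"
        mode[pre_labour] = "elective_cesarean"

        ga = np.where(
            preterm,
            rng.integers(196, TERM_DAYS, size=n),
            rng.integers(TERM_DAYS, 295, size=n),
        )

        outcome_events: dict[str, np.ndarray] = {}
        for name, (risk_dx, risk_undx) in config.outcome_risks.items():
            risk = np.full(n, config.baseline_risks.get(name, 0.0))
            risk[breech & diagnosed] = risk_dx
            risk[undiag] = risk_undx
            outcome_events[name] = rng.random(n) < risk

        apgar_low = outcome_events.get("apgar_lt7", np.zeros(n, dtype=bool))
        apgar5 = np.where(
            apgar_low, rng.integers(0, 7, size=n), rng.integers(7, 11, size=n)
        )

        age = rng.normal(
            config.age_mean[0] if label == "before" else config.age_mean[1],
            config.age_sd,
            size=n,
        )
        bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
        parous = rng.random(n) < config.p_parous
        ethnicity = rng.choice(_ETHNICITY_LEVELS, size=n, p=_ETHNICITY_PROBS)
        imd = rng.integers(1, 6, size=n)

        dates = [start + dt.timedelta(days=int(d)) for d in day_offsets]
        nnu = outcome_events.get("nnu_admission", np.zeros(n, dtype=bool))
        hie = outcome_events.get("hie", np.zeros(n, dtype=bool))
        death = outcome_events.get("perinatal_death", np.zeros(n, dtype=bool))
        for i in range(n):
            records.append(
                BirthRecord(
                    record_id=f"{label[0]}{i:06d}",
                    site=config.site,
                    birth_date=dates[i],
                    gestational_age_days=int(ga[i]),
                    plurality=2 if multiple[i] else 1,
                    presentation_at_birth="breech" if breech[i] else "cephalic",
                    antenatally_diagnosed_breech=bool(breech[i] and diagnosed[i]),
                    onset=str(onset[i]),
                    planned_cesarean_for_breech=bool(planned_cs[i]),
                    mode_of_birth=str(mode[i]),
                    apgar5=int(apgar5[i]),
                    nnu_admission=bool(nnu[i]),
                    hie=bool(hie[i]),
                    perinatal_death=bool(death[i]),
                    congenital_anomaly=bool(anomaly[i]),
                    maternal_age_years=round(float(age[i]), 1),
                    bmi=round(float(bmi[i]), 1),
                    parous=bool(parous[i]),
                    ethnicity=str(ethnicity[i]),
                    imd_quintile=int(imd[i]),
                )
            )

        elig_breech = eligible & breech
        elig_undiag = elig_breech & undiag
        elig_cs = elig_breech & planned_cs
        # Undiagnosed breeches diagnosed only at onset can, by definition,
        # never have a planned cesarean for breech, so the planned-CS rule
        # removes denominators but no events.
        epoch_truth = {
            "n_births": int(n),
            "excluded_multiple": int(multiple.sum()),
            "excluded_preterm": int((preterm & ~multiple).sum()),
            "excluded_anomaly": int((anomaly & ~multiple & ~preterm).sum()),
            "n_eligible": int(eligible.sum()),
            "n_breech": int(elig_breech.sum()),
            "n_planned_cs_breech": int(elig_cs.sum()),
            "n_undiagnosed": int(elig_undiag.sum()),
            "outcomes": {},
        }
        for name, events in outcome_events.items():
            epoch_truth["outcomes"][name] = {
                "breech_events": int((events & elig_breech).sum()),
                "breech_total": int(elig_breech.sum()),
                "breech_nocs_events": int((events & elig_breech & ~planned_cs).sum()),
                "breech_nocs_total": int((elig_breech & ~planned_cs).sum()),
            }
        truth[label] = epoch_truth

    return records, truth


def planted_rr(truth: dict[str, dict], outcome_name: str) -> float:
    """Realised risk ratio (after vs before) from a truth tally.

    For ``"undiagnosed_breech"`` the denominator excludes planned cesareans
    for breech, matching the pipeline's planned-cesarean rule for
    non-neonatal outcomes; neonatal outcomes use all eligible breech births.
    """
    if "before" not in truth or "after" not in truth:
        raise ValueError("truth tally must contain both epochs")

    def risk(epoch: dict) -> tuple[int, int]:
        if outcome_name == "undiagnosed_breech":
            return (
                epoch["n_undiagnosed"],
                epoch["n_breech"] - epoch["n_planned_cs_breech"],
            )
        entry = epoch["outcomes"][outcome_name]
        return entry["breech_events"], entry["breech_total"]

    a, n1 = risk(truth["before"])
    c, n2 = risk(truth["after"])
    if n1 == 0 or n2 == 0:
        raise ValueError("empty denominator in truth tally")
    if a == 0:
        raise ZeroDivisionError(
            "zero events in 'before' epoch: planted risk ratio undefined"
        )
    return (c / n2) / (a / n1)
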