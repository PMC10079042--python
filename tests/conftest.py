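import datetime as dt

import pytest

from breechscan import BirthRecord, EpochSpec

CUT = dt.date(2020, 1, 1)


def make_record(**overrides) -> BirthRecord:
    """A valid term singleton cephalic birth; override fields as needed."""
    base = dict(
        record_id="r0",
        site="routine_us",
        birth_date=dt.date(2019, 6, 15),
        gestational_age_days=280,
        plurality=1,
        presentation_at_birth="cephalic",
        antenatally_diagnosed_breech=False,
        onset="spontaneous_labour",
        planned_cesarean_for_breech=False,
        mode_of_birth="vaginal_vertex_spontaneous",
        apgar5=9,
        nnu_admission=False,
        hie=False,
        perinatal_death=False,
        congenital_anomaly=False,
        maternal_age_years=32.0,
        bmi=25.0,
        parous=False,
        ethnicity="caucasian",
        imd_quintile=3,
    )
    base.update(overrides)
    return BirthRecord(**base)


@pytest.fixture
def epoch() -> EpochSpec:
    return EpochSpec(cut_date=CUT)


def breech_cohort(n_breech_before, n_undiag_before, n_breech_after, n_undiag_after,
                  n_other_before=0, n_other_after=0, modes_before=None,
                  modes_after=None):
    """Deterministic cohort realising exact epoch-level counts.

    Undiagnosed breeches present in spontaneous labour and deliver by
    emergency cesarean; diagnosed ones take one mode each from the optional
    ``modes_*`` list (length ``n_breech - n_undiag``), defaulting to elective
    cesarean.  Cesareans are recorded at mode level only (no planned-cesarean
    flag), so every record survives the exclusion filters and the
    planned-cesarean rule and exact epoch denominators are preserved.
    """
    records = []
    i = 0
    for label, n_breech, n_undiag, n_other, modes, date in [
        ("b", n_breech_before, n_undiag_before, n_other_before, modes_before,
         dt.date(2019, 3, 15)),
        ("a", n_breech_after, n_undiag_after, n_other_after, modes_after,
         dt.date(2020, 8, 15)),
    ]:
        modes = modes or ["elective_cesarean"] * (n_breech - n_undiag)
        assert len(modes) == n_breech - n_undiag
        for j in range(n_breech):
            undiag = j < n_undiag
            mode = "emergency_cesarean" if undiag else modes[j - n_undiag]
            records.append(
                make_record(
                    record_id=f"{label}{i}",
                    birth_date=date,
                    presentation_at_birth="breech",
                    antenatally_diagnosed_breech=not undiag,
                    onset=(
                        "spontaneous_labour"
                        if undiag or mode != "elective_cesarean"
                        else "planned_cesarean"
                    ),
                    mode_of_birth=mode,
                )
            )
            i += 1
        for _ in range(n_other):
            records.append(make_record(record_id=f"{label}{i}", birth_date=date))
            i += 1
    return records
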