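"""Booking-record cleansing and derivation of the analysis variables.

Bookings live in a pandas DataFrame with one row per booking.  Raw columns:

====================  ===========================================
age                   consumer age in years
gender                category (e.g. ``male``/``female``)
booking_date          date the reservation was made
booking_type          category (``in-person``/``online``/``other``)
examination_date      date of the examination
set_id                examination-set name
price                 examination price (NTD)
group_size            number of people booking together (>= 1)
cancellation_date     date of cancellation, NaT if never cancelled
no_show               optional flag: booked, never cancelled, absent
====================  ===========================================

Cleansing turns a reservation with N reschedule events into N+1 bookings
(each reschedule is a cancellation plus a new booking), imputes missing
booking dates, and derives the modelling variables: appointment lead time,
last-minute flag (lead <= 7 days), group-booking flag (group size >= 2),
holiday-examination flag, season, age-interval flag (45-70 inclusive) and
the late-cancellation label.  A *late* cancellation is one within seven days
of the examination (too late to refill the slot); no-shows count as late
cancellations throughout.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "DERIVED_COLUMNS",
    "DEFAULT_SEASON_MAP",
    "make_season_map",
    "split_reschedules",
    "impute_missing_booking_date",
    "derive_features",
    "drop_unrecoverable",
]

REQUIRED_COLUMNS = (
    "age",
    "gender",
    "booking_date",
    "booking_type",
    "examination_date",
    "set_id",
    "price",
    "group_size",
    "cancellation_date",
)

DERIVED_COLUMNS = (
    "lead_time",
    "last_minute",
    "group_booking",
    "holiday_examination",
    "season",
    "age_interval",
    "late_cancellation",
)

#: Cancellations no more than this many days before the examination are late.
LATE_CANCEL_WINDOW_DAYS = 7

#: Lead times no greater than this are last-minute bookings.
LAST_MINUTE_DAYS = 7

AGE_INTERVAL = (45, 70)


def make_season_map(
    winter_months: Iterable[int] = (11, 12, 1),
    summer_months: Iterable[int] = (8, 9),
) -> dict[int, str]:
    """Month -> season label; months in neither group are ``off-peak``."""
    winter, summer = set(winter_months), set(summer_months)
    if winter & summer:
        raise ValueError("winter and summer month groups overlap")
    return {
        m: "winter" if m in winter else "summer" if m in summer else "off-peak"
        for m in range(1, 13)
    }


#: Winter = Nov-Jan, summer = Aug-Sep, everything else off-peak.
DEFAULT_SEASON_MAP = make_season_map()


def impute_missing_booking_date(
    original_booking_date: dt.date, new_examination_date: dt.date
) -> dt.date:
    """Calendar midpoint of the two dates, rounded down to a whole day.

    Used when the reschedule request date (which becomes the new booking's
    booking date) was not recorded.
    """
    d1 = pd.Timestamp(original_booking_date).date()
    d2 = pd.Timestamp(new_examination_date).date()
    if d1 > d2:
        raise ValueError(f"booking date {d1} is after examination date {d2}")
    return d1 + (d2 - d1) // 2


def split_reschedules(raw: Sequence[Mapping]) -> pd.DataFrame:
    """Break each rescheduled reservation into one booking per episode.

    Each element of ``raw`` is a mapping with the raw booking fields plus an
    optional ``reschedules`` key: a time-ordered list of
    ``(request_date, new_examination_date)`` pairs.  A reservation with N
    reschedules becomes N+1 rows: row k is cancelled on the k-th request
    date, and row k+1 is booked on that same date with the new examination
    date.  The final row keeps the original cancellation status.  A request
    date with value ``None`` is imputed as the calendar midpoint of the
    previous booking date and the new examination date.
    """
    rows: list[dict] = []
    for booking in raw:
        booking = dict(booking)
        events = list(booking.pop("reschedules", ()) or ())
        booking_date = pd.Timestamp(booking["booking_date"]).date()
        exam_date = pd.Timestamp(booking["examination_date"]).date()
        final_cancel = booking.get("cancellation_date")
        attrs = {
            k: v
            for k, v in booking.items()
            if k not in ("booking_date", "examination_date", "cancellation_date")
        }
        for request_date, new_exam in events:
            new_exam = pd.Timestamp(new_exam).date()
            if request_date is None:
                request_date = impute_missing_booking_date(booking_date, new_exam)
            else:
                request_date = pd.Timestamp(request_date).date()
            if request_date > exam_date:
                raise ValueError(
                    f"reschedule requested on {request_date}, after the "
                    f"then-current examination date {exam_date}"
                )
            rows.append(
                dict(
                    attrs,
                    booking_date=booking_date,
                    examination_date=exam_date,
                    cancellation_date=request_date,
                )
            )
            booking_date, exam_date = request_date, new_exam
        rows.append(
            dict(
                attrs,
                booking_date=booking_date,
                examination_date=exam_date,
                cancellation_date=(
                    pd.Timestamp(final_cancel).date()
                    if final_cancel is not None and not pd.isna(final_cancel)
                    else None
                ),
            )
        )
    frame = pd.DataFrame(rows)
    for col in ("booking_date", "examination_date", "cancellation_date"):
        if col in frame:
            frame[col] = pd.to_datetime(frame[col])
    logger.info(
        "split %d reservations into %d bookings", len(raw), len(frame)
    )
    return frame


def derive_features(
    records: pd.DataFrame,
    holidays: Iterable[dt.date] = (),
    season_map: Mapping[int, str] = DEFAULT_SEASON_MAP,
) -> pd.DataFrame:
    """Return a copy of ``records`` with the derived analysis columns.

    Idempotent: derived columns are recomputed from the raw ones each call.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    df = records.copy()
    booked = pd.to_datetime(df["booking_date"])
    exam = pd.to_datetime(df["examination_date"])
    cancel = pd.to_datetime(df["cancellation_date"])
    if (booked > exam).any():
        raise ValueError("booking_date after examination_date in some row(s)")
    if (cancel.notna() & (cancel < booked)).any():
        raise ValueError("cancellation_date before booking_date in some row(s)")

    df["lead_time"] = (exam - booked).dt.days
    df["last_minute"] = (df["lead_time"] <= LAST_MINUTE_DAYS).astype(int)
    df["group_booking"] = (df["group_size"] >= 2).astype(int)
    holiday_set = {pd.Timestamp(h).date() for h in holidays}
    df["holiday_examination"] = exam.dt.date.isin(holiday_set).astype(int)
    df["season"] = exam.dt.month.map(dict(season_map))
    lo, hi = AGE_INTERVAL
    df["age_interval"] = df["age"].between(lo, hi).astype(int)
    cancelled_late = cancel.notna() & (
        (exam - cancel).dt.days <= LATE_CANCEL_WINDOW_DAYS
    )
    if "no_show" in df.columns:
        cancelled_late |= df["no_show"].fillna(False).astype(bool)
    df["late_cancellation"] = cancelled_late.astype(int)
    return df


def drop_unrecoverable(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows missing a mandatory raw value; return (kept, n_dropped).

    ``cancellation_date`` may legitimately be missing (never cancelled), so
    it is not checked.
    """
    mandatory = [c for c in REQUIRED_COLUMNS if c != "cancellation_date"]
    mask = records[mandatory].notna().all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("dropped %d booking(s) with unrecoverable missing values", dropped)
    return records[mask].reset_index(drop=True), dropped
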