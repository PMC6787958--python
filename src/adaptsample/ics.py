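"""Minimal iCalendar (RFC 5545) export of recording schedules.

Field deployments push each site's next-day schedule to the calendar that
its recording device polls, so schedules are exportable as one ICS
calendar per site with a 60-second VEVENT per sample.  Only the small
subset of RFC 5545 needed for that round-trip is implemented (floating
local times, no time zones, no recurrence); a matching reader is provided
so exports can be verified without third-party calendar libraries.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable, Mapping

from .scheduling import DailySchedule

__all__ = ["schedules_to_ics", "parse_ics", "export_ics"]

_PRODID = "-//adaptsample//acoustic sampling schedules//EN"


def _fold(line: str) -> str:
    # RFC 5545 75-octet line folding; our lines are ASCII and short, but
    # fold defensively for long site ids.
    out = []
    while len(line) > 75:
        out.append(line[:75])
        line = " " + line[75:]
    out.append(line)
    return "\r\n".join(out)


def _fmt(dtval: dt.datetime) -> str:
    return dtval.strftime("%Y%m%dT%H%M%S")


def schedules_to_ics(site_id: str, schedules: Iterable[DailySchedule]) -> str:
    """Serialize one site's daily schedules as an ICS calendar string."""
    lines = [
        "BEGIN:VCALENDAR",
        "VERSION:2.0",
        f"PRODID:{_PRODID}",
        f"X-WR-CALNAME:{site_id}",
    ]
    n = 0
    for sched in schedules:
        if sched.site_id != site_id:
            raise ValueError(
                f"schedule for site {sched.site_id!r} passed to calendar "
                f"{site_id!r}"
            )
        for start in sched.sample_starts:
            begin = dt.datetime.combine(sched.date, start)
            n += 1
            lines += [
                "BEGIN:VEVENT",
                f"UID:{site_id}-{_fmt(begin)}@adaptsample",
                f"DTSTART:{_fmt(begin)}",
                f"DTEND:{_fmt(begin + dt.timedelta(seconds=60))}",
                f"SUMMARY:record {site_id}",
                "END:VEVENT",
            ]
    lines.append("END:VCALENDAR")
    return "\r\n".join(_fold(ln) for ln in lines) + "\r\n"


def parse_ics(text: str) -> list[dict]:
    """Parse an ICS string into event dicts (uid, start, end, summary)."""
    # Unfold continuation lines first.
    unfolded: list[str] = []
    for raw in text.splitlines():
        if raw.startswith((" ", "\t")) and unfolded:
            unfolded[-1] += raw[1:]
        else:
            unfolded.append(raw)
    events = []
    current: dict | None = None
    for line in unfolded:
        if line == "BEGIN:VEVENT":
            current = {}
        elif line == "END:VEVENT":
            if current is None:
                raise ValueError("END:VEVENT without BEGIN:VEVENT")
            events.append(current)
            current = None
        elif current is not None and ":" in line:
            key, value = line.split(":", 1)
            key = key.split(";", 1)[0].upper()
            if key in ("DTSTART", "DTEND"):
                current[key.lower()] = dt.datetime.strptime(value, "%Y%m%dT%H%M%S")
            elif key in ("UID", "SUMMARY"):
                current[key.lower()] = value
    if current is not None:
        raise ValueError("unterminated VEVENT")
    return events


def export_ics(
    schedules: Iterable[DailySchedule], out_dir
) -> Mapping[str, Path]:
    """Write one ICS calendar per site; returns site_id -> file path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_site: dict[str, list[DailySchedule]] = {}
    for s in schedules:
        by_site.setdefault(s.site_id, []).append(s)
    paths = {}
    for site_id in sorted(by_site):
        text = schedules_to_ics(site_id, by_site[site_id])
        path = out_dir / f"{site_id}.ics"
        path.write_text(text)
        paths[site_id] = path
    return paths
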