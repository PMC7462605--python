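"""Small programmatic fixtures for tests and worked examples.

All fixtures are synthetic stand-ins built in code; none contain field
data beyond published summary counts.
"""

from __future__ import annotations

import pandas as pd

#: successful-hunt counts per (group, prey) as published: 59 in total
PUBLISHED_HUNT_COUNTS = {
    ("Ekalakala", "anomalure"): 31,
    ("Ekalakala", "duiker"): 1,
    ("Ekalakala", "squirrel"): 1,
    ("Kokoalongo", "anomalure"): 3,
    ("Kokoalongo", "duiker"): 11,
    ("Kokoalongo", "squirrel"): 12,
}

#: unsuccessful attempt counts per (group, prey): 11 in total
ATTEMPT_COUNTS = {
    ("Ekalakala", "duiker"): 2,
    ("Kokoalongo", "duiker"): 2,
    ("Ekalakala", "anomalure"): 4,
    ("Kokoalongo", "anomalure"): 3,
}


def published_hunts():
    """Hunt table whose successful counts reproduce the published tally
    (59 successes: 33 Ekalakala, 26 Kokoalongo) plus the 11 recorded
    unsuccessful attempts. Locations/timestamps are synthetic placeholders."""
    rows = []
    i = 0
    for (group, prey), n in PUBLISHED_HUNT_COUNTS.items():
        for _ in range(n):
            rows.append({"hunt_id": f"h{i:03d}",
                         "timestamp": "2018-01-01 10:00:00",
                         "x_km": 0.0, "y_km": 0.0, "prey": prey,
                         "catcher_group": group, "success": 1})
            i += 1
    for (group, prey), n in ATTEMPT_COUNTS.items():
        for _ in range(n):
            rows.append({"hunt_id": f"h{i:03d}",
                         "timestamp": "2019-08-01 10:00:00",
                         "x_km": 0.0, "y_km": 0.0, "prey": prey,
                         "catcher_group": group, "success": 0})
            i += 1
    return pd.DataFrame(rows)


def toy_scan_set():
    """20-scan, 6-individual association toy set with hand-checkable SRI.

    Individuals a0/a1 appear in every scan (SRI 1); a2 and b0 never
    co-occur (SRI 0); a2 appears in scans 0-9 and b1 in scans 6-13
    (P_A=10, P_B=8, P_AB=4 → SRI 4/14).
    """
    rows = []
    for s in range(20):
        ts = pd.Timestamp("2018-06-01 07:00:00") + pd.Timedelta(minutes=30 * s)
        members = ["a0", "a1"]
        if s < 10:
            members.append("a2")
        else:
            members.append("b0")
        if 6 <= s < 14:
            members.append("b1")
        if s % 4 == 0:
            members.append("b2")
        for m in members:
            rows.append({"scan_id": f"s{s:02d}", "timestamp": ts,
                         "individual_id": m})
    return pd.DataFrame(rows)


def toy_individuals():
    rows = []
    for i, sex in zip(range(3), "MMF"):
        rows.append({"individual_id": f"a{i}", "group_id": "A", "sex": sex,
                     "present_from": "2018-01-01", "present_to": "2018-12-31"})
    for i, sex in zip(range(3), "FFM"):
        rows.append({"individual_id": f"b{i}", "group_id": "B", "sex": sex,
                     "present_from": "2018-01-01", "present_to": "2018-12-31"})
    return pd.DataFrame(rows)
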