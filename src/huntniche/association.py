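"""Party-scan processing: dyadic association, encounters, hunt covariates.

Party composition is sampled as cumulative 30-minute scans of the adults
present in a travelling party. Dyadic association for a year is the Simple
Ratio Index, SRI = P_AB / (P_A + P_B − P_AB), where P_A and P_B count scans
in which A or B appeared and P_AB scans with both. A hunt is an intergroup
hunt when the scan immediately before or during it contained members of
both groups. Per-hunt covariates mirror the prey-model predictors: catcher
group, counts of adult males and females present, the mean pairwise SRI of
the party (social cohesion), the spatial usage-difference score, and the
sine/cosine of the date on an annual cycle.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SRIMatrix",
    "compute_sri",
    "classify_encounter",
    "hunt_party_covariates",
    "seasonal_terms",
]

DEFAULT_PERIOD_DAYS = 365.25
# a scan covers the half-hour after its timestamp; a hunt with no scan in
# the preceding hour has no resolvable party
SCAN_COVER_MIN = 30.0
DEFAULT_WINDOW_MIN = 60.0


@dataclass
class SRIMatrix:
    """Symmetric dyadic SRI for one year, with the underlying counts."""

    year: int
    individual_ids: list
    values: pd.DataFrame          # SRI, NaN where undefined
    p_a: pd.Series                # scans with each individual
    p_ab: pd.DataFrame            # scans with both members of the dyad
    n_scans: int = 0

    def sri(self, a, b):
        if a == b:
            return np.nan
        return float(self.values.loc[a, b])

    def to_long(self):
        """Long-format dyad table: id_a, id_b, p_a, p_b, p_ab, sri."""
        rows = []
        ids = self.individual_ids
        for a, b in itertools.combinations(ids, 2):
            rows.append({
                "id_a": a, "id_b": b,
                "p_a": int(self.p_a[a]), "p_b": int(self.p_a[b]),
                "p_ab": int(self.p_ab.loc[a, b]),
                "sri": self.values.loc[a, b],
            })
        return pd.DataFrame(rows)


def compute_sri(scans, year=None):
    """Dyadic Simple Ratio Index from a scan table.

    ``scans`` has one row per (scan_id, individual_id); ``timestamp`` is
    needed only when ``year`` filters to a calendar year. Dyads never seen
    in any scan (denominator 0) are NaN — undefined, not zero.
    """
    df = scans
    if year is not None:
        ts = pd.to_datetime(df["timestamp"])
        df = df[ts.dt.year == year]
    if df.empty:
        raise ValueError(f"no scans for year {year}")
    inc = (pd.crosstab(df["scan_id"], df["individual_id"]) > 0).astype(int)
    ids = list(inc.columns)
    m = inc.to_numpy()
    p_a = m.sum(axis=0)
    p_ab = m.T @ m
    denom = p_a[:, None] + p_a[None, :] - p_ab
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(denom > 0, p_ab / np.where(denom > 0, denom, 1), np.nan)
    np.fill_diagonal(sri, np.nan)
    if year is None and "timestamp" in df.columns:
        year = int(pd.to_datetime(df["timestamp"]).dt.year.mode().iloc[0])
    return SRIMatrix(
        year=year if year is not None else -1,
        individual_ids=ids,
        values=pd.DataFrame(sri, index=ids, columns=ids),
        p_a=pd.Series(p_a, index=ids),
        p_ab=pd.DataFrame(p_ab, index=ids, columns=ids),
        n_scans=inc.shape[0],
    )


def _scan_members(scans):
    """scan_id -> (timestamp, list of individual_ids), time-sorted."""
    grouped = scans.groupby("scan_id").agg(
        timestamp=("timestamp", "first"))
    grouped["timestamp"] = pd.to_datetime(grouped["timestamp"])
    members = scans.groupby("scan_id")["individual_id"].apply(list)
    grouped["members"] = members
    return grouped.sort_values("timestamp")


def _resolve_hunt_scan(hunt_time, scan_table, window_min=DEFAULT_WINDOW_MIN):
    """The scan covering the hunt, else the nearest preceding scan within
    the window; None when no scan qualifies."""
    before = scan_table[scan_table["timestamp"] <= hunt_time]
    if before.empty:
        return None
    last = before.iloc[-1]
    age_min = (hunt_time - last["timestamp"]).total_seconds() / 60.0
    if age_min <= window_min:
        return last
    return None


def classify_encounter(hunt_time, scans, group_of, window_min=DEFAULT_WINDOW_MIN):
    """Is the hunt an intergroup hunt?

    True iff the scan at or immediately before the hunt (within
    ``window_min`` minutes) contains members of both groups. A hunt with a
    mixed preceding scan counts as intergroup even if only one group is
    present at the capture itself. Returns None when no scan resolves.
    """
    hunt_time = pd.Timestamp(hunt_time)
    table = _scan_members(scans)
    scan = _resolve_hunt_scan(hunt_time, table, window_min)
    if scan is None:
        return None
    groups = {group_of[i] for i in scan["members"] if i in group_of}
    return len(groups) > 1


def seasonal_terms(date, period_days=DEFAULT_PERIOD_DAYS):
    """Circular encoding of date: (sin θ, cos θ) with θ = 2π(doy−1)/period.

    January 1 maps to (0, 1); dates a full period apart coincide.
    """
    d = pd.to_datetime(date)
    if isinstance(d, pd.Series):
        doy = d.dt.dayofyear.to_numpy()
    elif isinstance(d, pd.Timestamp):
        doy = d.dayofyear
    else:
        doy = np.asarray(d.dayofyear)
    theta = 2 * np.pi * (np.asarray(doy, dtype=float) - 1) / period_days
    return np.sin(theta), np.cos(theta)


def hunt_party_covariates(hunts, scans, individuals, sri_by_year,
                          usage_scores=None, window_min=DEFAULT_WINDOW_MIN,
                          period_days=DEFAULT_PERIOD_DAYS,
                          same_group_only=False):
    """Assemble the per-hunt model covariates from scans and usage scores.

    One row per hunt: group (catcher's), n_available_males/females, the
    party's mean pairwise SRI, usage_difference (joined on hunt_id when
    ``usage_scores`` is given), seasonal sine/cosine, the intergroup flag
    and the prey category. Hunts whose party cannot be resolved, or with
    fewer than two party members, get NaN covariates and are flagged; with
    ``same_group_only`` the sex counts include only the catcher group's
    adults, otherwise all adults in the hunt scan.
    """
    ind = individuals.set_index("individual_id")
    sex_of = ind["sex"].to_dict()
    group_of = ind["group_id"].to_dict()
    scan_table = _scan_members(scans)
    usage = (usage_scores.set_index("hunt_id")["usage_difference"]
             if usage_scores is not None else None)

    unknown_sex = set()
    rows = []
    for hunt in hunts.itertuples(index=False):
        t = pd.Timestamp(hunt.timestamp)
        scan = _resolve_hunt_scan(t, scan_table, window_min)
        row = {
            "hunt_id": hunt.hunt_id,
            "group": hunt.catcher_group,
            "prey": hunt.prey,
            "n_available_males": np.nan,
            "n_available_females": np.nan,
            "mean_association": np.nan,
            "is_intergroup": np.nan,
        }
        sin_d, cos_d = seasonal_terms(t, period_days)
        row["sin_date"], row["cos_date"] = float(sin_d), float(cos_d)
        if usage is not None:
            row["usage_difference"] = usage.get(hunt.hunt_id, np.nan)
        if scan is None:
            logger.warning("hunt %s: no scan within %.0f min; covariates missing",
                           hunt.hunt_id, window_min)
            rows.append(row)
            continue
        members = [i for i in scan["members"] if i in group_of]
        scan_groups = {group_of[i] for i in members}
        row["is_intergroup"] = len(scan_groups) > 1
        counted = members
        if same_group_only:
            counted = [i for i in members if group_of[i] == hunt.catcher_group]
        sexes = []
        for i in counted:
            s = sex_of.get(i)
            if s in ("M", "F"):
                sexes.append(s)
            else:
                unknown_sex.add(i)
        row["n_available_males"] = sum(s == "M" for s in sexes)
        row["n_available_females"] = sum(s == "F" for s in sexes)
        sri = sri_by_year.get(t.year)
        if sri is not None and len(members) >= 2:
            vals = [sri.values.loc[a, b]
                    for a, b in itertools.combinations(members, 2)
                    if a in sri.values.index and b in sri.values.index]
            vals = [v for v in vals if np.isfinite(v)]
            if vals:
                row["mean_association"] = float(np.mean(vals))
        if not np.isfinite(row["mean_association"]):
            logger.warning("hunt %s: mean association undefined", hunt.hunt_id)
        rows.append(row)
    if unknown_sex:
        logger.warning("individuals with unknown sex excluded from counts: %s",
                       sorted(unknown_sex))
    out = pd.DataFrame(rows)
    cols = ["hunt_id", "group", "n_available_males", "n_available_females",
            "mean_association"]
    if usage is not None:
        cols.append("usage_difference")
    cols += ["sin_date", "cos_date", "is_intergroup", "prey"]
    return out[cols]
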