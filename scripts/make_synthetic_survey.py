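"""Regenerate the bundled synthetic literature-survey table.

Writes ``src/cultepi/data/synthetic_survey_raw.csv``: a fully synthetic
stand-in for a raw rock-art survey with 190 records that clean down to
133 via ``cultepi.io.clean_and_merge`` with category counts
(merged 5, duplicates 12, modern 1, criteria 13, unreliable 5,
no-coordinates 12, disputed 8, retracted 1).  Of the 133 clean records,
80 are Holocene (< 10,000 BP) and 5 fall outside the non-equatorial
latitude bands / 46,300-year window.  Deterministic under its fixed seed.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

SEED = 133_190
OUT = Path(__file__).resolve().parents[1] / "src" / "cultepi" / "data"

METHODS = ["radiocarbon", "luminescence", "uranium-thorium"]
COUNTRIES = ["France", "Spain", "Portugal", "Australia", "India", "Brazil",
             "South Africa", "China", "Indonesia", "Argentina", "Mexico", "Egypt"]

COLUMNS = ["name", "latitude", "longitude", "earliest_date", "latest_date",
           "country", "method", "direct", "date_kind", "calibrated_by_authors",
           "disputed", "unreliable_source", "retracted", "meets_criteria",
           "modern", "report_year"]


def rand_coords(rng, n, band="non-equatorial"):
    lat = np.where(rng.random(n) < 0.6,
                   rng.uniform(20, 60, n), rng.uniform(-40, -10, n))
    if band == "equatorial":
        lat = rng.uniform(-9, 19, n)
    lon = np.round(rng.uniform(-120, 155, n), 4)
    return np.round(lat, 4), lon


def base_record(rng, name, lat, lon, earliest):
    latest = earliest - rng.integers(50, 2000)
    latest = max(float(latest), 0.0)
    method = METHODS[rng.integers(0, 3)]
    return {
        "name": name,
        "latitude": lat,
        "longitude": lon,
        "earliest_date": float(earliest),
        "latest_date": latest,
        "country": COUNTRIES[rng.integers(0, len(COUNTRIES))],
        "method": method,
        "direct": bool(rng.random() < 0.6),
        "date_kind": ["exact", "minimum", "maximum", "mixed"][
            int(rng.choice(4, p=[0.55, 0.2, 0.15, 0.1]))],
        "calibrated_by_authors": bool(rng.random() < 0.6),
        "disputed": False,
        "unreliable_source": False,
        "retracted": False,
        "meets_criteria": True,
        "modern": False,
        "report_year": int(rng.integers(2000, 2020)),
    }


def main() -> None:
    rng = np.random.default_rng(SEED)

    clean = []
    # 80 Holocene + 48 Pleistocene, all inside the analysis window
    lat, lon = rand_coords(rng, 128)
    dates = np.concatenate([
        rng.uniform(500, 9999, 80),
        rng.uniform(10000, 46300, 48),
    ]).round(0)
    for i in range(128):
        clean.append(base_record(rng, f"Site_{i + 1:03d}", lat[i], lon[i], dates[i]))
    # 5 records outside the window: 3 equatorial, 2 older than 46,300 BP
    lat_eq, lon_eq = rand_coords(rng, 3, band="equatorial")
    for j in range(3):
        clean.append(base_record(rng, f"Site_{129 + j:03d}", lat_eq[j], lon_eq[j],
                                 float(round(rng.uniform(10000, 30000)))))
    lat_o, lon_o = rand_coords(rng, 2)
    for j in range(2):
        clean.append(base_record(rng, f"Site_{132 + j:03d}", lat_o[j], lon_o[j],
                                 float(round(rng.uniform(47000, 60000)))))
    assert len(clean) == 133
    assert sum(r["earliest_date"] < 10000 for r in clean) == 80

    rows = list(clean)

    def pick(n):
        return rng.choice(len(clean), size=n, replace=False)

    # 5 merge-extras: same coordinates, overlapping interval, older report
    for i in pick(5):
        tgt = clean[i]
        extra = dict(tgt)
        extra["name"] = tgt["name"] + "_early_report"
        extra["earliest_date"] = tgt["earliest_date"] + 300.0
        extra["latest_date"] = max(tgt["earliest_date"] - 100.0, 0.0)
        extra["report_year"] = 1980 + int(rng.integers(0, 19))
        rows.append(extra)
    # 12 exact duplicates
    for i in pick(12):
        rows.append(dict(clean[i]))
    # flagged exclusions
    for count, flag in ((1, "modern"), (13, "criteria"), (5, "unreliable"),
                        (8, "disputed"), (1, "retracted")):
        for _ in range(count):
            lat1, lon1 = rand_coords(rng, 1)
            r = base_record(rng, f"Excl_{flag}_{_}", float(lat1[0]), float(lon1[0]),
                            float(round(rng.uniform(1000, 40000))))
            if flag == "modern":
                r["modern"] = True
                r["earliest_date"] = 10.0
                r["latest_date"] = 0.0
            elif flag == "criteria":
                r["meets_criteria"] = False
            elif flag == "unreliable":
                r["unreliable_source"] = True
            elif flag == "disputed":
                r["disputed"] = True
            else:
                r["retracted"] = True
            rows.append(r)
    # 12 rows without coordinates
    for j in range(12):
        r = base_record(rng, f"Excl_nocoord_{j}", 0.0, 0.0,
                        float(round(rng.uniform(1000, 40000))))
        r["latitude"] = ""
        r["longitude"] = ""
        rows.append(r)

    assert len(rows) == 190
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    OUT.mkdir(parents=True, exist_ok=True)
    path = OUT / "synthetic_survey_raw.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    print(f"wrote {path} ({len(rows)} rows)")


if __name__ == "__main__":
    main()
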