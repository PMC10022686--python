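"""Filter the two simulated MS screens and intersect their hit lists.

Applies the pulldown rule (twofold over control, >10 total spectral
counts) to the 2+2 replicate table and the proximity-labeling rule
(twofold, >5 counts) to the 5+5 table, exports enrichment and volcano
tables, and reports the cross-screen overlap against the planted truth.

Run after 01_simulate.py:  python analysis/03_ms_enrichment.py
"""

import json
from pathlib import Path

from filotip.ms_enrichment import (
    DatasetFilter,
    apply_filter,
    dataset_overlap,
    read_count_table,
    records_to_frame,
    volcano_table,
)

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "ms_enrichment"

FILTERS = {
    "pulldown": DatasetFilter("pulldown", "bait", ("control",),
                              min_fold_change=2.0, count_threshold=10),
    "bioid": DatasetFilter("bioid", "bait", ("control",),
                           min_fold_change=2.0, count_threshold=5),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    planted = {k: set(v) for k, v in
               json.loads((DATA / "planted_hits.json").read_text()).items()}

    passing = {}
    for name, filt in FILTERS.items():
        table = read_count_table(DATA / f"counts_{name}.csv")
        records = apply_filter(table, filt)
        records_to_frame(records).to_csv(OUT / f"enrichment_{name}.csv", index=False)
        volcano_table(records).to_csv(OUT / f"volcano_{name}.csv", index=False)
        passing[name] = {r.protein_id for r in records if r.passes_filter}
        exact = passing[name] == planted[name]
        print(f"{name}: {len(passing[name])}/{len(table)} proteins pass "
              f"(planted {len(planted[name])}; recovered exactly: {exact})")

    inter, excl = dataset_overlap(passing)
    report = {
        "intersection": sorted(inter),
        "exclusive": {k: sorted(v) for k, v in excl.items()},
        "planted_overlap": sorted(planted["pulldown"] & planted["bioid"]),
        "overlap_matches_planted": inter == {p.upper() for p in
                                             planted["pulldown"] & planted["bioid"]},
    }
    (OUT / "overlap.json").write_text(json.dumps(report, indent=2))
    print(f"overlap of the two screens: {report['intersection']} "
          f"(matches planted overlap: {report['overlap_matches_planted']})")


if __name__ == "__main__":
    main()
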