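"""Generate all synthetic inputs for the downstream analyses.

Produces, under results/data/:
  * tip-to-base line profiles for two imaging conditions — a protein
    planted at filopodia tips (4:1 tip:shaft intensity) and a control
    protein with no tip accumulation;
  * two spectral-count tables emulating the two MS screens — a 2+2
    replicate pulldown-style table and a 5+5 replicate proximity-
    labeling-style table, with partially overlapping planted hits;
  * tip-spot trajectories for two live-imaging conditions — control
    cells with long-lived tips and "destabilized" cells whose tracks
    die early.

Run:  python analysis/01_simulate.py --seed 1
"""

import argparse
import json
from pathlib import Path

import numpy as np

from filotip import profiles, synthetic_data as syn
from filotip.ms_enrichment import write_count_table

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    DATA.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    # -- profiles: tip-enriched vs control, 300 filopodia each -------------
    for cond, tip_amp in [("tip_enriched", 3.0), ("control", 0.0)]:
        specs = [
            syn.straight_filopodium(f"{cond}_{i:04d}", (0, 0), (2, 0),
                                    (tip_amp,), (1.0,), tip_fraction=0.15)
            for i in range(300)
        ]
        profs = syn.generate_profiles(specs, samples_per_profile=120,
                                      noise_sd=0.2, seed=int(rng.integers(2**31)))
        profiles.write_profiles(DATA / f"profiles_{cond}.csv", profs)
        print(f"profiles_{cond}.csv: {len(profs)} profiles "
              f"(tip amplitude {tip_amp}, shaft 1.0, noise sd 0.2)")

    # -- spectral counts: two screens with overlapping planted hits --------
    ids = [f"P{i:04d}" for i in range(50)]
    planted = {"pulldown": frozenset(ids[:12]), "bioid": frozenset(ids[8:20])}
    designs = {
        "pulldown": dict(n_replicates_bait=2, n_replicates_control=2,
                         baseline_mean=3.0),
        # streptavidin background is sparse: ~1 expected total count keeps
        # chance passes of the >5-count rule rare
        "bioid": dict(n_replicates_bait=5, n_replicates_control=5,
                      baseline_mean=1.0),
    }
    for name, kw in designs.items():
        gt = syn.CountTableGroundTruth(
            n_proteins=50, enriched_ids=planted[name], enrichment_factor=20.0,
            seed=int(rng.integers(2**31)), **kw,
        )
        write_count_table(DATA / f"counts_{name}.csv", syn.generate_count_table(gt))
        print(f"counts_{name}.csv: 50 proteins, {len(planted[name])} planted at 20x")
    (DATA / "planted_hits.json").write_text(
        json.dumps({k: sorted(v) for k, v in planted.items()}, indent=2)
    )
    shared = sorted(planted["pulldown"] & planted["bioid"])
    print(f"planted overlap between screens: {shared}")

    # -- tracks: control vs destabilized tips, 6 cells each ----------------
    for cond, n_frames in [("control", 20), ("destabilized", 8)]:
        gts = []
        for cell in range(6):
            gts += [
                syn.TrackGroundTruth(
                    cell_id=f"{cond}_cell{cell}",
                    spawn_frame=0, death_frame=n_frames - 1,
                    positions=t.positions[:n_frames],
                )
                for t in syn.random_walk_tracks(
                    8, cell_id=f"{cond}_cell{cell}", n_frames=n_frames,
                    step_sd_um=0.1, spacing_um=5.0,
                    seed=int(rng.integers(2**31)),
                )
            ]
        spots = syn.generate_tracks(gts, detection_noise_um=0.05,
                                    seed=int(rng.integers(2**31)))
        spots.to_csv(DATA / f"spots_{cond}.csv", index=False)
        print(f"spots_{cond}.csv: {len(spots)} detections, "
              f"{len(gts)} tracks of {n_frames} frames (5 s interval)")


if __name__ == "__main__":
    main()
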