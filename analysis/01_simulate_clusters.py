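"""Generate desk-scale confined water-cluster trajectories.

Simulates the four cluster geometries (narrow chain with and without the
excess proton, disc, droplet) with the toy flexible-water model under the
study's harmonic confinements, writing NVE-segment XYZ files with synthetic
Wannier centers and JSON manifests under results/trajectories/.

Desk-scale protocol: 2 ps Langevin equilibration at 300 K, four 2 ps NVE
segments per system (the full-scale protocol is 15 ps + 26 x 5 ps).
"""

import argparse
import json
from pathlib import Path

from protir.pipeline import RunConfig, cmd_simulate

RUNS = [
    ("chain_narrow", True),
    ("chain_narrow", False),
    ("disc", True),
    ("droplet", True),
]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/trajectories")
    ap.add_argument("--segments", type=int, default=4)
    ap.add_argument("--segment-time", type=float, default=2.0)
    args = ap.parse_args()

    index = {}
    for geometry, protonated in RUNS:
        tag = f"{geometry}_{'prot' if protonated else 'neutral'}"
        cfg = RunConfig(
            geometry=geometry,
            n_waters=26 if geometry == "droplet" else 15,
            protonated=protonated,
            equil_time=2.0,
            segment_time=args.segment_time,
            n_segments=args.segments,
            charge_mode="wannier_full",
            outdir=str(Path(args.outdir) / tag),
            seed=args.seed,
        )
        out = cmd_simulate(cfg)
        manifest = json.loads(Path(out["manifest"]).read_text())
        print(f"{tag}: {len(out['trajectories'])} NVE segments, "
              f"net charge {manifest['net_charge']} e, "
              f"NVT <T> = {manifest['nvt_mean_temperature_K']:.1f} K")
        index[tag] = out
    Path(args.outdir, "index.json").write_text(json.dumps(index, indent=2))
    print(f"wrote {Path(args.outdir) / 'index.json'}")


if __name__ == "__main__":
    main()
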