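"""Simulate the synthetic metacommunity and write the per-plot inputs.

Generates 40 stem-mapped plots along a 0-60 degree latitudinal gradient
with a declining AM species pool and a flat EcM pool, then writes each
plot's stem map (TSV), metadata, climate vector, corner-elevation grid and
species-type lookup under results/plots/.

Run from the repository root:  python analysis/01_simulate.py [--seed 1]
"""

import argparse
from pathlib import Path

from mycobeta import SimConfig, generate_metacommunity
from mycobeta.io import write_synthetic_plot


def config(seed: int) -> SimConfig:
    return SimConfig(
        n_plots=40, plot_width=100.0, plot_height=100.0,
        trees_per_plot_mean=2000.0, latitude_range=(0.0, 60.0),
        am_pool_intercept=100.0, am_pool_slope=-1.5,
        ecm_pool_intercept=25.0, ecm_pool_slope=0.0,
        am_fraction_intercept=0.6, am_fraction_slope=0.0,
        seed=seed,
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/plots"))
    args = ap.parse_args()

    plots = generate_metacommunity(config(args.seed))
    for p in plots:
        write_synthetic_plot(p, args.out)
    n_trees = sum(p.stem_map.n_trees for p in plots)
    lats = [p.metadata.latitude for p in plots]
    print(f"wrote {len(plots)} plots ({n_trees} trees) to {args.out}")
    print(f"latitudes span {min(lats):.1f} to {max(lats):.1f} degrees")


if __name__ == "__main__":
    main()
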