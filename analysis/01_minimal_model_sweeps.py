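#!/usr/bin/env python
"""Minimal mass-model sweeps: evoked input quenches variability and correlation.

Simulates the one-unit model (variance vs boxcar amplitude) and the two-unit
model (inter-unit Pearson correlation vs amplitude), computes the
characteristic timescale at each amplitude's noise-free fixed point, and
reports how well the timescale rank-predicts the simulated statistics.

Writes sweep_1d.tsv, sweep_2d.tsv and associations.tsv under --out.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from neuroquench.dynamics import (
    timescale_statistic_association,
    timescale_sweep_1d,
    timescale_sweep_2d,
)
from neuroquench.neural_mass import (
    default_1d_spec,
    default_2d_spec,
    evoked_sweep_1d,
    evoked_sweep_2d,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--step", type=float, default=0.01,
                    help="amplitude grid step (use 0.1 for a quick look)")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    grid = np.round(np.arange(-5.0, 5.0 + 1e-9, args.step), 4)

    spec1, spec2 = default_1d_spec(), default_2d_spec()
    ss = np.random.SeedSequence(args.seed)
    s1, s2 = ss.spawn(2)

    ts1 = timescale_sweep_1d(spec1, grid)
    sw1 = evoked_sweep_1d(spec1, grid, seed=s1)
    out1 = sw1.merge(ts1, on="amplitude")
    out1.to_csv(args.out / "sweep_1d.tsv", sep="\t", index=False)
    rho1 = timescale_statistic_association(sw1, ts1)

    ts2 = timescale_sweep_2d(spec2, grid)
    sw2 = evoked_sweep_2d(spec2, grid, seed=s2)
    out2 = sw2.merge(ts2, on="amplitude")
    out2.to_csv(args.out / "sweep_2d.tsv", sep="\t", index=False)
    rho2 = timescale_statistic_association(sw2, ts2)

    assoc = pd.DataFrame([
        {"analysis": "1d_variance_vs_timescale", "spearman_rho": rho1,
         "n_amplitudes": grid.size},
        {"analysis": "2d_correlation_vs_timescale", "spearman_rho": rho2,
         "n_amplitudes": grid.size},
    ])
    assoc.to_csv(args.out / "associations.tsv", sep="\t", index=False)

    peak = sw1.loc[sw1["variance"].idxmax(), "amplitude"]
    print(f"1D: variance peaks at s={peak:+.2f}; timescale explains variance "
          f"with Spearman rho = {rho1:.4f}")
    print(f"2D: correlation at s=0 is {sw2.set_index('amplitude').loc[0.0, 'dependence']:.3f}; "
          f"generalized timescale explains correlation with rho = {rho2:.4f}")
    print("Both statistics are maximal without stimulation and fall as evoked "
          "input pushes the attractor into the saturated, fast-relaxing regime.")


if __name__ == "__main__":
    main()
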