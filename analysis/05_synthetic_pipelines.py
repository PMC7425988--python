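#!/usr/bin/env python
"""Trial- and block-design pipelines exercised on ground-truth synthetic cohorts.

Part A (spiking-style): generates trial-structured six-area rate data with a
state-dependent shared latent, removes the cross-trial mean response, and
contrasts rest (ITI) vs task (cue) cross-trial variance, noise correlations,
and participation-ratio dimensionality in 25-trial bins.

Part B (fMRI-style): generates a block-design BOLD-like cohort, runs FIR task
regression, z-normalization, block variance / FC, cross-block statistics
without regression, dimensionality, and the activation-quenching association.

Writes trial_contrasts.tsv and bold_cohort_contrasts.tsv under --out.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from neuroquench.fmri import (
    activation_quenching_association,
    block_fc,
    block_sample_mask,
    block_variance,
    build_canonical_design,
    build_fir_design,
    cross_block_stats,
    mean_offdiagonal,
    participation_ratio,
    regress_out,
    state_dimensionality_contrast,
    znormalize_runs,
)
from neuroquench.synthetic import (
    BoldGeneratorSpec,
    TrialGeneratorSpec,
    gen_block_bold,
    gen_trial_rates,
)
from neuroquench.trial_stats import (
    cross_trial_correlation,
    cross_trial_variance,
    epoch_trial_rates,
    paired_contrast,
    remove_cross_trial_mean,
)


def trial_part(seed, out):
    data = gen_trial_rates(TrialGeneratorSpec(n_trials=1000, seed=seed))
    resid = remove_cross_trial_mean(data)
    rows = []
    v = {e: cross_trial_variance(resid, e) for e in ("rest", "task")}
    c = {e: cross_trial_correlation(resid, e) for e in ("rest", "task")}
    tv = paired_contrast(v["task"].variance.mean(axis=1),
                         v["rest"].variance.mean(axis=1))
    tc = paired_contrast(np.nanmean(c["task"].correlation, axis=1),
                         np.nanmean(c["rest"].correlation, axis=1))
    dims = {}
    for e in ("rest", "task"):
        r = epoch_trial_rates(resid, e)
        prs = [participation_ratio(np.cov(r[a:b].T, ddof=1))
               for a, b in [(i * 25, (i + 1) * 25) for i in range(len(r) // 25)]]
        dims[e] = np.asarray(prs)
    td = paired_contrast(dims["task"], dims["rest"])
    rows += [
        {"statistic": "cross_trial_variance", "rest": v["rest"].variance.mean(),
         "task": v["task"].variance.mean(), "t": tv["t"].iloc[0], "p": tv["p"].iloc[0]},
        {"statistic": "noise_correlation_z", "rest": np.nanmean(c["rest"].correlation),
         "task": np.nanmean(c["task"].correlation), "t": tc["t"].iloc[0],
         "p": tc["p"].iloc[0]},
        {"statistic": "participation_ratio", "rest": dims["rest"].mean(),
         "task": dims["task"].mean(), "t": td["t"].iloc[0], "p": td["p"].iloc[0]},
    ]
    table = pd.DataFrame(rows)
    table.to_csv(out / "trial_contrasts.tsv", sep="\t", index=False)
    print("Trial pipeline (1000 trials, 6 areas, 25-trial bins):")
    print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print("Cue-period variability and noise correlations fall below the ITI "
          "baseline while dimensionality rises, matching the designed "
          "shared-variance quench.\n")


def bold_part(seed, out):
    spec = BoldGeneratorSpec(n_regions=40, n_subjects=30,
                             activation_coupling=0.8, seed=seed)
    task, rest, design, truth = gen_block_bold(spec)
    si, n_t = spec.sampling_interval, task[0].n_timepoints
    Xf, _ = build_fir_design(design, n_t, si)
    Xc, _ = build_canonical_design(design, n_t, si)
    betas, d_var, d_fc, tv, rv, tfc, rfc = [], [], [], [], [], [], []
    cb_task, cb_rest, zt_runs, zr_runs = [], [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t_run, r_run in zip(task, rest):
            betas.append(regress_out(t_run, Xc).coefficients[:, :len(design.conditions)])
            zt = znormalize_runs(regress_out(t_run, Xf).residuals)
            zr = znormalize_runs(regress_out(r_run, Xf).residuals)
            zt_runs.append(zt); zr_runs.append(zr)
            bt, br = block_variance(zt, design), block_variance(zr, design)
            tv.append(bt.mean()); rv.append(br.mean()); d_var.append(bt - br)
            Zt, Zr = block_fc(zt, design), block_fc(zr, design)
            tfc.append(mean_offdiagonal(Zt)); rfc.append(mean_offdiagonal(Zr))
            m = ~np.eye(spec.n_regions, dtype=bool)
            d_fc.append((Zt - Zr).sum(axis=1) / m.sum(axis=1))
            cb_task.append(cross_block_stats(t_run, design)["variance"].mean())
            cb_rest.append(cross_block_stats(r_run, design)["variance"].mean())
        # dimensionality uses the same residual data as the FC analysis
        dims, dim_contrast = state_dimensionality_contrast(zt_runs, zr_runs, design)
    assoc = activation_quenching_association(
        np.stack(betas), np.mean(d_var, axis=0), np.mean(d_fc, axis=0))
    t_var = paired_contrast(np.asarray(tv), np.asarray(rv))
    t_fc = paired_contrast(np.asarray(tfc), np.asarray(rfc))
    t_cb = paired_contrast(np.asarray(cb_task), np.asarray(cb_rest))
    table = pd.DataFrame([
        {"statistic": "block_variance", "rest": np.mean(rv), "task": np.mean(tv),
         "t": t_var["t"].iloc[0], "p": t_var["p"].iloc[0]},
        {"statistic": "block_fc_z", "rest": np.mean(rfc), "task": np.mean(tfc),
         "t": t_fc["t"].iloc[0], "p": t_fc["p"].iloc[0]},
        {"statistic": "cross_block_variance_noFIR", "rest": np.mean(cb_rest),
         "task": np.mean(cb_task), "t": t_cb["t"].iloc[0], "p": t_cb["p"].iloc[0]},
        {"statistic": "participation_ratio",
         "rest": dims["rest_dimensionality"].mean(),
         "task": dims["task_dimensionality"].mean(),
         "t": dim_contrast["t"].iloc[0], "p": dim_contrast["p"].iloc[0]},
        {"statistic": "activation_vs_variance_change",
         "rest": np.nan, "task": np.nan,
         "t": assoc.loc[assoc["measure"] == "variance", "rho"].iloc[0],
         "p": assoc.loc[assoc["measure"] == "variance", "p"].iloc[0]},
        {"statistic": "activation_vs_fc_change", "rest": np.nan, "task": np.nan,
         "t": assoc.loc[assoc["measure"] == "fc", "rho"].iloc[0],
         "p": assoc.loc[assoc["measure"] == "fc", "p"].iloc[0]},
    ])
    table.to_csv(out / "bold_cohort_contrasts.tsv", sep="\t", index=False)
    print("BOLD cohort pipeline (40 regions, 30 subjects, FIR + z-norm):")
    print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print("Task blocks show reduced variance (relative to the unit-variance "
          "normalization) and reduced background FC; dimensionality rises; "
          "strongly activated regions quench more (negative rank "
          "correlations in the last two rows, reported in the t column).")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    trial_part(args.seed, args.out)
    bold_part(args.seed, args.out)


if __name__ == "__main__":
    main()
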