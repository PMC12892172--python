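#!/usr/bin/env python
"""Full simulation-based calibration run (intended as a long/nightly job).

For each replicate, hyper-model and hierarchy parameters are drawn from
their priors, a desk-scale synthetic monitoring world is generated with
those truths, the integrated model is refit, and 90% credible-interval
coverage of the generating values is tallied.  With >= 20 replicates a
correctly calibrated sampler should show per-parameter coverage roughly
between 0.75 and 0.99.

Usage::

    python scripts/sbc.py --replicates 20 --iterations 4000 --seed 1 \
        --out results/sbc.json
"""

import argparse
import json
from dataclasses import replace
from pathlib import Path

import numpy as np

import occabund as oa

PARAMS = ["beta0", "beta1", "beta2", "mu_psi", "mu_rho", "mu_p"]


def run_replicate(rep: int, seed: int, iterations: int, chains: int) -> dict:
    pr = oa.PriorSpec()
    rng = np.random.default_rng([seed, rep])
    truth = {
        "beta0": rng.normal(pr.beta0.mean, pr.beta0.sd),
        "beta1": rng.normal(0, pr.beta1.sd),
        "beta2": rng.normal(0, pr.beta2.sd),
        "mu_p": rng.normal(pr.mu_p.mean, pr.mu_p.sd),
        "mu_rho": rng.normal(0, 1),
        "mu_psi": rng.normal(0, 1),
        "beta_rho": rng.normal(0, pr.beta_rho.sd),
        "beta_psi": rng.normal(0, pr.beta_psi.sd),
        "sigma_eps": float(pr.sigma.rvs(rng)),
        "sigma_g": float(pr.sigma.rvs(rng)),
        "sigma_y": float(pr.sigma.rvs(rng)),
        "sigma_m": float(pr.sigma.rvs(rng)),
        "sigma_resid": float(pr.sigma.rvs(rng)),
    }
    cfg = replace(oa.preset("desk_small"), **truth)
    captures, tubes, registry, _ = oa.simulate(cfg, seed=1000 + rep)
    model = oa.IntegratedAbundanceModel.from_raw(captures, tubes, registry,
                                                 timescale="short")
    res = model.fit(chains=chains, iterations=iterations, seed=rep)
    summ = res.summary(PARAMS)
    return {p: bool(summ.loc[p, "q05"] <= truth[p] <= summ.loc[p, "q95"])
            for p in PARAMS}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--replicates", type=int, default=20)
    ap.add_argument("--iterations", type=int, default=4000)
    ap.add_argument("--chains", type=int, default=2)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args()

    hits = {p: 0 for p in PARAMS}
    for rep in range(args.replicates):
        covered = run_replicate(rep, args.seed, args.iterations, args.chains)
        for p, ok in covered.items():
            hits[p] += ok
        print(f"replicate {rep + 1}/{args.replicates}: "
              + ", ".join(f"{p}={'Y' if covered[p] else 'n'}" for p in PARAMS))
    coverage = {p: hits[p] / args.replicates for p in PARAMS}
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(
        {"replicates": args.replicates, "coverage": coverage}, indent=1))
    print(json.dumps(coverage, indent=1))


if __name__ == "__main__":
    main()
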