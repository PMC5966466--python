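#!/usr/bin/env python
"""Monte Carlo validation of the statistical machinery.

Re-derives the pipeline's operating characteristics by simulation: type-I
error of the G11 vs G22 contrast, bias of the planted group difference,
rank-recovery of the planted synchrony gradient, decision accuracy of the
encoding-model pattern, PLSR loading recovery, and the family-wise error of
permutation-calibrated cluster correction. Defaults are reduced for a quick
look; ``--full`` runs the study sizes used by the acceptance checks.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from narrsync import studies


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/validation.json")
    ap.add_argument("--full", action="store_true",
                    help="acceptance-scale study sizes (several minutes)")
    args = ap.parse_args()
    f = 1 if args.full else 5  # reduction factor for the quick look

    results = {}
    results["type1_error"] = studies.lme_type1_error(
        n_sims=1000 // f, seed=args.seed + 1)
    print(f"type-I error of G11 vs G22 at alpha=0.05: {results['type1_error']:.3f}")
    results["contrast_bias"] = studies.lme_contrast_bias(
        n_sims=200 // f, seed=args.seed + 2)
    print(f"bias of planted 0.2 group difference: {results['contrast_bias']:+.4f}")
    rhos = studies.ak_rank_rho_study(n_reps=100 // f, seed=args.seed + 3)
    results["ak_rank_rho_median"] = float(np.median(rhos))
    print(f"median-ISC vs trait-rank rho (median): {results['ak_rank_rho_median']:.3f}")
    acc = studies.event_pattern_study(n_reps=200 // f, seed=args.seed + 4)
    results["event_pattern_accuracy"] = acc
    print("event-model decision accuracies:",
          ", ".join(f"{k}={v:.2f}" for k, v in acc.items()))
    rec = studies.plsr_recovery_study(n_reps=200 // f, seed=args.seed + 5)
    results["plsr_recovery"] = rec
    print(f"PLSR loading recovery median cosine: {rec['median_cosine']:.3f}")
    results["cluster_fwe"] = studies.cluster_fwe_study(
        n_datasets=200 // f, n_perm=100, seed=args.seed + 6)
    print(f"cluster-correction FWE at nominal 0.05: {results['cluster_fwe']:.3f}")

    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(results, indent=2, default=float))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
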