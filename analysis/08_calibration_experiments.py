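#!/usr/bin/env python
"""Validation stage: calibration and recovery experiments (reduced scale).

Runs quick versions of the package's calibration experiments — the full
versions back the test suite and scripts/acceptance.py — and prints what
they establish: the permutation test holds its nominal level, the sampled
null agrees with exhaustive enumeration, the binormal AUC matches its
closed form, the planted Glu/GABA signal is recoverable at n = 9 + 11,
and null cohorts raise no excess flags.
"""

import json
from pathlib import Path

from neurometab import experiments as ex

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    res = {
        "permutation_calibration": ex.permutation_calibration(n_rep=300, seed=21),
        "exhaustive_vs_sampled": ex.exhaustive_vs_sampled(seed=22),
        "binormal_closed_form": ex.binormal_closed_form_check(seed=23),
        "glu_gaba_recovery": ex.glu_gaba_recovery(n_rep=60, B=2000, seed=24),
        "null_calibration": ex.null_screen_calibration(n_rep=100, B=1000, seed=25),
        "quantifier": ex.quantifier_recovery(n_seeds=30, seed=26),
    }
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "calibration_summary.json").write_text(json.dumps(res, indent=2, sort_keys=True))

    print(f"permutation null rejection rate at 0.05: "
          f"{res['permutation_calibration']['rejection_rate']:.3f}")
    print(f"sampled vs exhaustive p gap: "
          f"{abs(res['exhaustive_vs_sampled']['p_sampled'] - res['exhaustive_vs_sampled']['p_exact']):.4f} "
          f"(MC SE {res['exhaustive_vs_sampled']['mc_se']:.4f})")
    print(f"binormal fit AUC at unit separation: "
          f"{res['binormal_closed_form']['auc_binormal_fit']:.4f} (closed form 0.8413)")
    print(f"Glu/GABA q95 selection rate: {res['glu_gaba_recovery']['q95_selection_rate']:.2f}; "
          f"mean AUC {res['glu_gaba_recovery']['mean_estimated_auc']:.3f} "
          f"vs generative {res['glu_gaba_recovery']['generative_auc']:.3f}")
    print(f"null cohorts: q95 flag rate {res['null_calibration']['q95_flag_rate']:.3f}, "
          f"Welch rejection rate {res['null_calibration']['welch_rejection_rate']:.3f}")
    print(f"quantifier: noiseless max rel error "
          f"{res['quantifier']['max_rel_error_noiseless']:.1e}, "
          f"CRLB noise-doubling ratio {res['quantifier']['mean_crlb_ratio']:.3f}")


if __name__ == "__main__":
    main()
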