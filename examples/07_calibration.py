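"""Calibrate a model to synthetic patient data and check recovery.

Generates a synthetic patient with known truth, then infers the final
parameter subset {tree_alpha, k3 per group, global ks2, ks3 per group} by
multistart SQP minimization of the residual sum of squares.  With a known
truth the estimates can be compared directly.  (Four starts here for a
quick demonstration; the identifiability protocol uses twelve.)
"""

from pulsetree.inference import CalibrationProblem, InferenceConfig
from pulsetree.solver import SolverConfig
from pulsetree.synthetic import generate, three_vessel_network

cfg = SolverConfig(points_per_cm=0.25, min_points=5)
pat = generate("DORV", seed=7, network=three_vessel_network("DORV"),
               solver_config=cfg, Tp=20)
prob = CalibrationProblem(pat.network, pat.inflow, pat.theta_true,
                          pat.patient_data(), cfg)

subset = pat.inference_subset()
result = prob.calibrate(subset, InferenceConfig(n_starts=4, seed=3))

print("pruning history:")
for line in result.history:
    print("  ", line)
print(f"identifiable: {result.identifiable}")
print(f"{'parameter':<12s} {'truth':>10s} {'estimate':>10s} {'error':>7s} {'CV':>7s}")
for name in result.subset:
    t, e = subset[name], result.best_theta[name]
    print(f"{name:<12s} {t:10.4g} {e:10.4g} {100 * abs(e / t - 1):6.1f}% "
          f"{result.cv[name]:7.4f}")
print(f"best RSS {result.best_rss:.4f}; per-site flow R^2 "
      f"{[round(r, 3) for r in result.r2]}")
# CV is the spread of estimates across starts (identifiability criterion
# CV < 0.1); the error column is recovery of the known truth at 5%
# measurement noise plus deliberate branch-flow de-conservation.
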