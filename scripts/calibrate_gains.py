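"""One-off calibration of the drive gains for the feedforward variant.

The mapping from classifier outputs to rate-unit drives has three free
gains (cortical, subcortical, motor). This script fixes them by bisection
against the behavioral anchors — mean antisaccade RT 241 ms (cortex-only,
set by the motor gain at unit cortical gain) and mean prosaccade RT 189 ms
(set by the subcortical logit gain) — on a balanced 500-pair test set at
zero noise. The resulting values are frozen as the package defaults.

Run:  python scripts/calibrate_gains.py
"""

import numpy as np

import shallowbrain as sb
from shallowbrain.decision import Gains


def mean_rt(model, trials, sigma=0.0):
    results, _ = sb.run_trials(model, trials, sigma, rng=np.random.default_rng(0))
    rts = [r.rt_ms for r in results if r.rt_ms is not None]
    if not rts:
        return float("inf"), 0  # no crossings: drive too weak
    return float(np.mean(rts)), len(rts)


def calibrate_for_cortical_gain(model, pro, anti, g_c):
    """Bisect motor gain to the ANTI anchor, then subcortical gain to the
    PRO anchor, at fixed cortical gain."""
    model.gains = Gains(cortical=g_c, subcortical=0.05, motor=1.0, inhibition=5.0)
    lo, hi = 0.2, 20.0
    for _ in range(25):
        model.gains.motor = 0.5 * (lo + hi)
        rt, _ = mean_rt(model, anti)
        if rt > 241.0:
            lo = model.gains.motor
        else:
            hi = model.gains.motor
    model.gains.motor = 0.5 * (lo + hi)
    lo, hi = 0.002, 0.11  # keep g_s*max|logit| below the inhibition gain
    for _ in range(25):
        model.gains.subcortical = 0.5 * (lo + hi)
        rt, _ = mean_rt(model, pro)
        if rt > 189.0:
            lo = model.gains.subcortical
        else:
            hi = model.gains.subcortical
    model.gains.subcortical = 0.5 * (lo + hi)
    return model.gains


def main():
    from collections import Counter

    model = sb.ModelBundle.build_ff(seed=0)
    test = sb.make_test_set(500, seed=101)
    pro = [sb.TrialSpec.make(sb.CueType.PRO, p) for p in test.pairs]
    anti = [sb.TrialSpec.make(sb.CueType.ANTI, p) for p in test.pairs]

    # scan cortical gain: smaller values slow the cortical module crossing
    # so the subcortex wins the easy prosaccade trials (winner structure)
    for g_c in (0.25, 0.3, 0.35, 0.5, 0.7, 1.0):
        gains = calibrate_for_cortical_gain(model, pro, anti, g_c)
        res_p, _ = sb.run_trials(model, pro, 0.0, rng=np.random.default_rng(1))
        res_a, _ = sb.run_trials(model, anti, 0.0, rng=np.random.default_rng(1))
        summ = sb.rt_summary(res_p + res_a)
        easy = [r for r in res_p if r.difficulty < 0.6]
        easy_sub = np.mean([r.winner.value == "subcortex" for r in easy])
        da = sb.difficulty_analysis(res_p)
        ratios = da["choice_ratio"].to_numpy()
        print(f"g_c={g_c:.2f} g_m={gains.motor:.3f} g_s={gains.subcortical:.4f} | "
              f"pro={summ.mean_rt_ms[0]:.1f}±{summ.sd_rt_ms[0]:.0f} "
              f"anti={summ.mean_rt_ms[1]:.1f} | "
              f"acc={sb.choice_accuracy(res_p):.3f}/{sb.choice_accuracy(res_a):.3f} | "
              f"easy sub-win {easy_sub:.2f} | "
              f"winners {Counter(r.winner.value for r in res_p)} | "
              f"ratios {np.round(ratios, 2)}")


if __name__ == "__main__":
    main()
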