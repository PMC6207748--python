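"""Atrioventricular-block grading on veratridine-like recordings.

First-degree AV block: every atrial beat conducts but PR is prolonged
beyond the baseline reference (mean + 3 SD).  High-degree block: P
waves appear without a following QRS.  The veratridine scenario steps
PR from 58 to 85 ms at the injection; a separate scenario drops 30% of
QRS complexes.
"""

import zfecg
from zfecg.preprocess import FilterConfig
from zfecg.simulator import RhythmSpec, ScenarioSpec, render_record

FILTER = FilterConfig(notch_enabled=False)
BASELINE_PR = (62.0, 4.0)  # reference mean +/- SD

record, _ = zfecg.render_record(zfecg.preset("veratridine_avblock", seed=0))
post = zfecg.analyze_record(record.crop(65.0, 180.0), FILTER)
call = zfecg.classify_av_block(post.intervals, 0, *BASELINE_PR)
print("veratridine (PR steps 58 -> 85 ms at t=60 s):")
print(f"  post-injection mean PR {call.mean_pr_ms:.1f} ms "
      f"(threshold {call.pr_threshold_ms:.0f} ms)")
print(f"  grade: {call.grade}   evidence: {call.evidence}")

spec = ScenarioSpec(name="high_degree_block", duration_s=60.0, seed=3,
                    rhythm=RhythmSpec(dropped_qrs_prob=0.3))
record, truth = render_record(spec)
res = zfecg.analyze_record(record, FILTER)
call = zfecg.classify_av_block(res.intervals, truth.p_events, *BASELINE_PR)
print("high-degree scenario (30% of P waves not conducted):")
print(f"  dropped-QRS ratio {call.dropped_ratio:.2f}  grade: {call.grade}")
print("A first-degree call needs PR prolongation with full conduction; "
      "any substantial dropped-QRS ratio escalates to high-degree.")
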