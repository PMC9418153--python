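"""Build the MAT timeline and simulate a labelled fNIRS cohort.

The mental-arithmetic task (MAT) is a 555 s stress protocol: 60 s rest,
45 arithmetic cycles of 7 s, 180 s recovery.  The simulator produces
four-channel HbO/HHb prefrontal recordings for healthy controls (HC),
chronic migraine (CM) and medication-overuse headache (MOH) subjects.
"""

import numpy as np

from nirsmat import build_protocol, simulate_cohort

protocol = build_protocol()
print(f"total duration: {protocol.total_duration:.0f} s")
for stage, (lo, hi) in protocol.stage_boundaries().items():
    print(f"  {stage:<9s} [{lo:5.0f}, {hi:5.0f}) s")

cohort = simulate_cohort(seed=0)  # default sizes: 13 HC, 9 CM, 12 MOH
groups, counts = np.unique([r.group for r in cohort], return_counts=True)
print("cohort:", {str(g): int(c) for g, c in zip(groups, counts)})

rec = cohort[0]
print(
    f"subject {rec.subject_id}: {rec.n_samples} samples per channel at "
    f"{rec.sampling_rate} Hz, age {rec.age:.1f} y"
)
# Each channel holds an HbO and an HHb concentration series (a.u.); ch3
# (right PFC) carries the group-dependent task-evoked response.
task = slice(round(60 * rec.sampling_rate), round(375 * rec.sampling_rate))
rest = slice(0, round(60 * rec.sampling_rate))
delta = rec.hbo["ch3"][task].mean() - rec.hbo["ch3"][rest].mean()
print(f"task-rest HbO contrast at ch3: {delta:+.3f} a.u.")
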