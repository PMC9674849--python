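"""Rebuild subject maps from events and run quality control.

Painting events are rasterized with a disk brush, smoothed with a
Gaussian kernel, merged into one signed map (activation positive) and
masked to the body.  QC then flags subjects who completed too few maps
(below mean - 2.5 SD) and, separately, likely anomalous responders.
"""

from bodymaps import (
    CohortConfig,
    anomaly_flags,
    build_cohort_bsms,
    build_default_template,
    completion_screen,
    default_topography_specs,
    simulate_cohort,
)

template = build_default_template(60, 120)
config = CohortConfig(n_subjects=20, completion_prob=0.85, anomaly_rate=0.1, seed=7)
cohort = simulate_cohort(template, default_topography_specs(), config)

qc = completion_screen(cohort, template, k=2.5)
print(f"completed-map counts: mean {qc.mean:.2f}, SD {qc.sd:.2f}")
print(f"exclusion threshold mean - 2.5*SD = {qc.threshold:.2f} maps")
print(f"excluded for low completion: {qc.excluded or 'none'}")

flags = anomaly_flags(cohort, template)
for sid, reasons in sorted(flags.items()):
    print(f"anomaly suspect {sid}: {'; '.join(reasons)}")
print(f"(planted anomalous subjects were {sorted(cohort.anomalous_subjects)})")

keep = set(qc.kept) - set(flags)
bsms = build_cohort_bsms(
    type(cohort)(records=[r for r in cohort.records if r.subject_id in keep],
                 truths=cohort.truths, anomalous_subjects=set(), config=config),
    template, brush_radius=6, sigma=5.0,
)
print(f"built {len(bsms)} signed subject maps after QC "
      f"(each {template.n_in_mask} in-body pixels)")
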