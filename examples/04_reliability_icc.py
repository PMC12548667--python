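"""Estimate test-retest reliability: metric-level and edge-wise ICC(3,1).

Simulates a cohort with a known generative edge ICC, computes within-network
connectivity for both sessions of every subject, estimates the metric-level
ICC with its 95% CI, and maps edge-wise reliability bins.
"""

import numpy as np

import connrel as cr

parcellation = cr.make_parcellation(30, [10, 10, 10], atlas_name="demo30")
spec = cr.CohortSpec(
    n_subjects_per_group={"groupA": 30},
    target_edge_icc=0.6,
    motion_fd_mean_by_group={"groupA": 0.0},
    spike_rate=0.0,
    nuisance_amplitudes={"global": 0.0, "wm": 0.0, "csf": 0.0},
    seed=12,
)
runs, truth = cr.simulate_cohort(spec, parcellation)

wn = {}
z = {}
for run in runs:
    cleaned = cr.run_pipeline(run, cr.get_variant("primary"))
    conn = cr.build_connectome(cleaned.signals, parcellation)
    _, wn[(run.subject_id, run.session)] = cr.within_network_connectivity(
        conn, parcellation
    )
    # for the edge-wise recovery check, estimate edges from the raw session
    # signals (no filtering, no negative censoring): both steps attenuate or
    # truncate single-edge ICCs, which is exactly what the comparison below
    # with the metric-level value illustrates
    post = cr.discard_nonsteady(run, 4)
    z[(run.subject_id, run.session)] = cr.fisher_z(cr.correlate(post.signals))

subjects = sorted({r.subject_id for r in runs})
x1 = np.array([wn[(s, 1)] for s in subjects])
x2 = np.array([wn[(s, 2)] for s in subjects])
res = cr.icc_3_1(x1, x2)
print(f"within-network connectivity ICC(3,1) = {res.icc:.3f} "
      f"[{res.ci_low:.3f}, {res.ci_high:.3f}], bin: {res.bin}")

z1 = np.stack([z[(s, 1)] for s in subjects])
z2 = np.stack([z[(s, 2)] for s in subjects])
icc, _, _, bins = cr.edgewise_icc(z1, z2)
print(f"generative edge ICC target: 0.6, expected at T = 296: "
      f"{truth.expected_observed_icc(296):.3f}; "
      f"mean recovered edge ICC: {np.nanmean(icc[np.triu_indices(30, 1)]):.3f}")
print("edge reliability bin proportions:")
print(bins.to_string(index=False))

# The recovered edge-level ICC matches the generative expectation up to the
# n = 30 estimator noise; the per-edge spread across bins at a single true
# ICC shows why edge-wise reliability maps look heterogeneous even when the
# underlying reliability is uniform.
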