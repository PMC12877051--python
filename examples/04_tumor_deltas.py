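"""Map tumor masks to regions and summarize deltas by involvement bin.

Thresholds probabilistic voxel masks at 0.1, computes the per-region
involvement fraction, expresses each patient's region metrics as deltas
versus the control-group mean, and pools them into the four involvement
bins. Negative deltas mark reductions versus controls.
"""

from neuroignite import (CohortSpec, IgnitionParams, bin_summary,
                         build_delta_table, compute_profile, generate_bold,
                         generate_tumor_masks, mask_to_region_fraction,
                         run_preprocess)

spec = CohortSpec(seed=11)  # full default study conditions (10/14/10, 268 regions)
cohort, truth = generate_bold(spec)
overlaps, masks, atlas = generate_tumor_masks(spec, with_voxels=True)

# voxel-level round trip for one subject
sub = "men-01"
recovered = mask_to_region_fraction(masks[sub], atlas)
print(f"{sub}: {int((recovered.fractions > 0).sum())} tumor-involved regions "
      f"recovered from the voxel mask (threshold 0.1, inclusive)")

profiles = {}
for name, bold in cohort.items():
    _, raster = run_preprocess(bold)
    profiles[name] = compute_profile(raster, IgnitionParams.for_tr(bold.tr_ms))

delta = build_delta_table(profiles, spec.groups, overlaps)
for group in ("meningioma", "glioma"):
    print(f"\n{group} bin summary (mean delta ignition | n regions | % of group):")
    for _, row in bin_summary(delta, group).iterrows():
        mean = row["mean_delta_ignition"]
        mean_s = f"{mean:+.3f}" if mean == mean else "  n/a"
        print(f"  {row['bin']:<12} {mean_s}   n={int(row['n']):4d}  "
              f"{row['pct']:5.1f}%")
print("\nGlioma-like cohorts sit below zero even in the zero-tumor bin "
      "(diffuse effect); meningioma-like cohorts only where the tumor is.")
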