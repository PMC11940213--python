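"""Digital DRG phantom -> B1-corrected T2 map -> per-ganglion measurements.

Builds a four-ganglion phantom (bilateral L5 and S1, known true T2 and
volume), simulates the multi-echo acquisition with a smooth B1 field and
Rician noise at SNR 50, fits the EPG dictionary voxelwise, and extracts the
per-ganglion VOI median T2 and volume.
"""

from drg_t2map import (
    FitConfig,
    PhantomSpec,
    compute_volume,
    extract_voi,
    fit_volume,
    generate_phantom,
)

spec = PhantomSpec(seed=1)  # 32x32x12 voxels at 1.5 x 1.5 x 1.8 mm, SNR 50
vol, mask, truth = generate_phantom(spec)
print(f"simulated volume {vol.shape}, B1 field range "
      f"[{truth.b1.min():.2f}, {truth.b1.max():.2f}]")

t2map = fit_volume(vol, truth.echo_times_ms, FitConfig(method="epg_dict"),
                   affine=truth.affine, voxel_dims_mm=spec.voxel_dims_mm)
print(f"fitted {t2map.n_fitted} voxels ({t2map.n_unfittable} unfittable)\n")

print(f"{'ganglion':>10} {'true T2':>8} {'VOI T2':>8} {'true vol':>10} {'vol':>10}")
for name, info in truth.drg_truth.items():
    t2, n_vox = extract_voi(t2map, mask, info["label_value"], "median")
    volume = compute_volume(mask, info["label_value"], spec.voxel_dims_mm)
    print(f"{name:>10} {info['true_t2_ms']:8.1f} {t2:8.1f} "
          f"{info['volume_mm3']:10.1f} {volume:10.1f}")

print(
    "\nVOI medians land within one 1-ms dictionary step of the true T2, and"
    "\nvolumes are exact (voxel count x voxel volume) because the mask is the"
    "\nground-truth segmentation."
)
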