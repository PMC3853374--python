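"""Compare surface-area-to-volume ratios of loculated vs free-flowing shapes.

Loculated intraperitoneal pockets are roughly spherical — the minimum
surface area for their volume — while free-flowing contrast spreads into
thin irregular films over the peritoneal surfaces.  At equal volume, the
film presents far more surface to the tissue it bathes, which is the
geometric rationale for why a high SA:V compartment predicts better drug
distribution.
"""

import periquant as pq

(v_sphere, gt_sphere, _), (v_sheet, gt_sheet, _) = pq.loculation_contrast_pair(seed=0)
ms = pq.metrics(gt_sphere)
mf = pq.metrics(gt_sheet)

print(f"sphere: V = {ms.total_volume_cm3:6.1f} cm^3, SA = {ms.total_surface_area_cm2:7.1f} cm^2, "
      f"SA:V = {ms.total_surface_area_cm2 / ms.total_volume_cm3:.2f} /cm")
print(f"sheet : V = {mf.total_volume_cm3:6.1f} cm^3, SA = {mf.total_surface_area_cm2:7.1f} cm^2, "
      f"SA:V = {mf.total_surface_area_cm2 / mf.total_volume_cm3:.2f} /cm")
ratio = (mf.total_surface_area_cm2 / mf.total_volume_cm3) / (
    ms.total_surface_area_cm2 / ms.total_volume_cm3
)
print(f"SA:V ratio, sheet / sphere: {ratio:.2f}")
# Equal volumes, but the thin sheet's SA:V is several times the sphere's.
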