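"""Segment alveoli in a reflectance image and measure walls.

The segmentation chain (top-hat of the inverted image, Gaussian blur, Otsu
threshold, erosion/dilation) isolates dark lumens; radial rays from each
lumen centroid measure the tissue gap to neighboring lumens, giving wall
thicknesses. Speckle-sized and outlier components are filtered before the
per-image summary statistics are computed.
"""
import numpy as np

from octfib import (
    class_presets,
    filter_alveoli,
    generate_phantom,
    measure_walls,
    segment_alveoli,
    summarize_morphometry,
)

spec = class_presets()["normal"]
pair, truth = generate_phantom(spec)

labels, records = segment_alveoli(pair.reflectance)
records = measure_walls(labels, records)
kept = filter_alveoli(records)

print(f"ground truth: {len(truth.centroids)} lumens")
print(f"segmented:    {len(records)} components, {len(kept)} kept after filtering")

summary = summarize_morphometry(kept)
print(f"area  mean={summary.area_stats['mean']:.1f} px^2, "
      f"median={summary.area_stats['p50']:.1f}, sd={summary.area_stats['sd']:.1f}")
print(f"wall  mean={summary.wall_stats['mean']:.1f} px, "
      f"median={summary.wall_stats['p50']:.1f}, sd={summary.wall_stats['sd']:.1f}")

# compare recovered areas against ground truth for matched centroids
gt = np.asarray(truth.centroids)
errors = []
for rec in kept:
    d = np.hypot(gt[:, 0] - rec.centroid[0], gt[:, 1] - rec.centroid[1])
    i = int(np.argmin(d))
    if d[i] <= 5:
        errors.append(abs(rec.area_px - truth.areas_px[i]) / truth.areas_px[i])
print(f"mean absolute relative area error vs ground truth: {np.mean(errors):.3f}")
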