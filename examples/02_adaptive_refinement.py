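"""Watch the Zienkiewicz-Zhu driven refinement loop concentrate.

Runs only the adaptive stage on a gamma-corrected phantom and prints the
per-iteration log: triangle/node counts, the largest error indicator and
how many triangles were marked for bisection.
"""

import numpy as np

from zzdetect import (
    LesionSpec,
    MarkingConfig,
    PhantomSpec,
    adapt,
    gamma_correct,
    generate,
)

image, truth, _ = generate(
    PhantomSpec(seed=3, lesion=LesionSpec(center=(85.0, 115.0), radius=24.0, intensity=0.96))
)
corrected = gamma_correct(image, 4.0)

result = adapt(corrected, nt=1200, cfg=MarkingConfig(p=0.25, cref=0.60, max_iter=8))

print(f"{'iter':>4} {'triangles':>10} {'nodes':>7} {'max eta':>10} {'marked':>7}")
for h in result.history:
    print(f"{h['iteration']:>4} {h['triangles']:>10} {h['nodes']:>7} {h['max_eta']:>10.4f} {h['marked']:>7}")
print(f"finally {result.mesh.num_triangles} triangles")

areas = result.areas.values
bary = result.mesh.triangle_coords().mean(axis=1)
rows, cols = np.nonzero(truth.values)
in_lesion = (
    (bary[:, 1] >= rows.min()) & (bary[:, 1] <= rows.max())
    & (bary[:, 0] >= cols.min()) & (bary[:, 0] <= cols.max())
)
print(f"mean triangle area inside lesion box : {areas[in_lesion].mean():.3f} px^2")
print(f"mean triangle area elsewhere         : {areas[~in_lesion].mean():.3f} px^2")
print()
print("Marked counts track where the intensity varies; the area contrast shows")
print("the mesh ending far denser over the lesion than over quiet tissue.")
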