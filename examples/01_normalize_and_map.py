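"""Generate a synthetic tissue slice, normalize it, and render one protein map.

Walks the first half of the pipeline: simulate a 30x30 micro-well slice with
208 specimens, TIC-center the log2 abundances, reference-normalize against
the pooled QC runs, z-score, and draw the distribution map of one planted
regional marker as a PNG (green = low, red = high, gray = missing).
"""

import numpy as np

import masp

grid = masp.generate_grid()  # 30x30 wells at 400 um, 208 occupied
truth = masp.make_brain_slice_truth(grid, n_proteins=500, seed=11)
mat, qcset, truth = masp.generate_dataset(truth, grid, n_proteins=500)
print(f"simulated {mat.n_samples} micro-specimens x {mat.n_features} proteins, "
      f"{qcset.n_runs} QC runs")

tic, report = masp.tic_normalize(mat)
offsets = np.array(list(report.per_sample_offset.values()))
print(f"TIC centering: grand mean {report.grand_mean:.2f} log2, "
      f"per-sample offsets span [{offsets.min():.2f}, {offsets.max():.2f}]")

ref = masp.reference_normalize(tic, qcset)
z = masp.zscore(ref)

marker = truth.regional_proteins[0]
m = masp.build_map(z, grid, marker)
masp.render_map(m, f"map_{marker}.png", clip=(-1.0, 1.0))
print(f"map of {marker}: {m.n_observed}/{grid.n_wells} wells observed, "
      f"written to map_{marker}.png")
# The PNG shows the planted region glowing red against a green background;
# the clip (-1, 1) puts the z-score display scale on the usual green-to-red range.
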