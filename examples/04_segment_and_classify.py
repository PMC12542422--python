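"""Segment a rendered site, extract features and classify each cell.

Trains the phenotype classifier on simulator-labeled cells (the stand-in
for manual annotation), then runs the nucleus/ring/feature/classify chain
on a fresh site and compares predictions with the rendering ground truth.
"""

import numpy as np

import nucleoscreen as ns
from nucleoscreen.plate_io import make_training_features
from nucleoscreen.segmentation import LabelGrid

optics = ns.OpticsConfig(vignette=False)  # post-correction regime

feats = make_training_features(optics, n_cells=600, seed=3)
model = ns.train_classifier(feats, feats["true_class"], seed=1)

p = np.zeros(ns.N_CLASSES)
p[:4] = 0.25
cells = ns.sample_well_cells(p, 35, seed=8, optics=optics)
img, truth_labels, truth = ns.render_site(cells, optics=optics, seed=8)

nuclei = ns.segment_nuclei(img[0], pixel_size_um=optics.pixel_size_um)
rings = ns.cytoplasm_rings(nuclei, width_um=6.5)
table = ns.extract_features(nuclei, rings, img)
pred = ns.classify_cells(model, table)

print("nuclei segmented:", nuclei.n_labels, "of", len(cells), "rendered")
print("ring width:", ns.ring_width_px(6.5, optics.pixel_size_um), "px")
print("predicted class counts:", pred["predicted_class"].value_counts().to_dict())
print("true class counts     :", truth["true_class"].value_counts().to_dict())
# With default SNR the per-class counts should agree closely; residual
# differences come from border exclusion and touching-nucleus splits.
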