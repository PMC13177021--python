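"""Pick representative frames and connected components by PCA.

Frames are flattened to coordinate vectors (12 columns per molecule) and
the ones nearest the trajectory mean in the reduced space are selected;
components of one size class are summarized by four descriptors (sum and
spread of bond lengths, mean and spread of edge energies) and the one
nearest the group mean is chosen for downstream electronic-structure work.
"""

import dataclasses

import numpy as np

from scwnet import (ClusterSpec, CriterionParameters, build_network,
                    component_descriptors, planted_cluster_frame,
                    select_representative_component,
                    select_representative_frames)

rng = np.random.default_rng(7)
base, _ = planted_cluster_frame(ClusterSpec(counts={2: 4, 3: 3}), seed=3)


def jiggle(frame, scale):
    mols = []
    for m in frame.molecules:
        d = scale * rng.standard_normal(3)
        mols.append(dataclasses.replace(m, pos_Ha=m.pos_Ha + d,
                                        pos_O=m.pos_O + d, pos_M=m.pos_M + d,
                                        pos_Hb=m.pos_Hb + d))
    return dataclasses.replace(frame, molecules=mols)


frames = [jiggle(base, 0.01) for _ in range(9)] + [jiggle(base, 0.8)]
chosen = select_representative_frames(frames, n=3)
print(f"representative frames (of {len(frames)}): {chosen}")
print("the deliberately distorted frame 9 is never selected:",
      9 not in chosen)

params = CriterionParameters.at_temperature(673.0)
net = build_network(base, params)
descs = [d for d in component_descriptors(net, base) if d.size == 3]
rep = select_representative_component(descs)
print(f"3-molecule components: {[d.component_id for d in descs]}, "
      f"representative: {rep}")
# The chosen component sits closest to the mean of its size class in the
# standardized descriptor space, making it a typical specimen of that class.
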