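"""From influential sub-signals to a map of critical morphologies.

Extracts each sample's top-2 most influential 25-step sub-signals of
signal 0, pools them into the global set G, trains a small SOM on their
shapes, and projects the mean influence score per neuron (the E-matrix).
"""

import numpy as np

from tsocclude import (
    SOMConfig,
    SyntheticSpec,
    build_e_matrix,
    build_influential_set,
    generate_dataset,
    make_black_box,
    train_som,
    unit_members,
)

X, _ = generate_dataset(SyntheticSpec(s=12, h=250, n=2, seed=3))
model = make_black_box("echo", j=0)

G = build_influential_set(X, 0, model, d=25, k=2, n_global=24)
print(f"global set: {len(G)} sub-signals, top score {G.scores()[0]:.4f}")

som = train_som(G.sub_signals, SOMConfig(rows=6, cols=8, steps=5000, seed=3))
E = build_e_matrix(som, G.sub_signals, normalize=True)
u, v = np.unravel_index(np.argmax(E.values), E.values.shape)
members = unit_members(som, G.sub_signals, (int(u), int(v)))
print(f"most active neuron ({u},{v}): E={E.values[u, v]:.3f}, "
      f"{len(members)} mapped sub-signals, occupancy {int((E.counts > 0).sum())} cells")
# Neurons cluster sub-signals by shape; bright E cells are the morphologies
# whose occlusion hurts the model most. The members of the brightest cell
# are the prototypical "critical" waveform snippets to show a clinician.
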