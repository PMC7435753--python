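"""Run the three-stage cascade on one phantom and inspect the stage maps.

Stage 1 masks the lung parenchyma, stage 2 flags every small bright
inside-lung structure, stage 3 keeps only true nodules.  With untrained
weights the maps are uninformative; see 05_train_and_evaluate.py for a
trained cascade.
"""

import numpy as np

from nodulecascade import NoduleCascade, PhantomParams, generate_phantom, tiny_cascade_config

sample = generate_phantom(PhantomParams(), seed=7)
cascade = NoduleCascade(tiny_cascade_config(seed=0))
out = cascade.predict(sample.image)

for name, prob in [("parenchyma", out.parenchyma_prob),
                   ("candidates", out.candidate_prob),
                   ("nodule", out.nodule_prob)]:
    print(f"{name:10s} map: shape {prob.shape}, range "
          f"[{prob.min():.3f}, {prob.max():.3f}]")
print(f"ground truth: {len(sample.nodules)} annotated nodule(s)")
# Every map has the input's resolution; values are probabilities in [0,1].
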