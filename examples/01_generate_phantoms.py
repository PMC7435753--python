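"""Generate a small seeded phantom dataset and inspect its ground truth.

Each phantom is a 64x64 chest slice: a bright thorax, two dark lung
fields, nodule discs inside the lungs, vessel-like distractors inside
and rib-like blobs outside.  Masks are nested: nodules ⊆ candidates ⊆
parenchyma.
"""

from nodulecascade import PhantomParams, generate_dataset

params = PhantomParams()
samples = generate_dataset(6, params, seed=42, negative_fraction=0.3)

for i, s in enumerate(samples):
    print(f"sample {i}: {len(s.nodules)} nodule(s), "
          f"nodule px {int(s.nodule_mask.sum()):3d}, "
          f"candidate px {int(s.candidate_mask.sum()):3d}, "
          f"parenchyma px {int(s.parenchyma_mask.sum())}")
# A sample with 0 nodules is a negative slice; its candidate pixels are
# vessels only, which the third cascade stage must learn to reject.
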