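"""Dilated-convolution size algebra and the channel contracts of the blocks.

The dilated kernel spans n = k + (k-1)(d-1) input pixels and a
convolution maps size i to o = floor((i + 2p - n)/s) + 1.
"""

import numpy as np

from nodulecascade import BlockSpec, conv_output_size, effective_kernel_size
from nodulecascade.autograd import Tensor
from nodulecascade.blocks import MultiResBlock, MultiScalePool

for k, d in [(3, 1), (3, 2), (5, 3)]:
    print(f"kernel {k} at dilation {d}: effective size {effective_kernel_size(k, d)}")

spec = BlockSpec(kernel_rows=3, kernel_cols=3, dilation=2, padding=(2, 2))
print(f"64-px axis through a 'same'-padded dilated conv: {conv_output_size(64, spec)}")

rng = np.random.default_rng(0)
x = Tensor(rng.random((1, 16, 32, 32), dtype=np.float32))
mr = MultiResBlock(16, rng=rng)
print(f"multi-resolution block: 16 channels -> {mr(x).shape[1]} (tripled)")
pool = MultiScalePool(48, rng=rng)
y = pool(Tensor(rng.random((1, 48, 32, 32), dtype=np.float32)))
print(f"multi-scale pooling: (48, 32, 32) -> {tuple(y.shape[1:])} "
      "(channels conserved, size halved)")
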