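"""Generator and discriminator architectures for the unpaired translation stage.

The generators are residual convolutional networks with a tanh output and the
discriminators are strided patch classifiers, following the original
cycle-consistent translation recipe; a width/depth scale in the config shrinks
them so that toy models train on a CPU in seconds while the structure (and the
objective they optimise) is unchanged.  Images are handled internally as
(N, C, H, W) tensors in [-1, 1].
"""

from __future__ import annotations

import numpy as np

from flimcoreg.translate._autograd import Tensor, add, conv2d, leaky_relu, relu, tanh

__all__ = ["Generator", "Discriminator", "IdentityGenerator"]


def _winit(rng: np.random.Generator, shape) -> Tensor:
    return Tensor(rng.normal(0.0, 0.02, shape))


class _Conv:
    def __init__(self, rng, cin, cout, k=3, stride=1, pad=1):
        self.w = _winit(rng, (cout, cin, k, k))
        self.b = Tensor(np.zeros(cout))
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def parameters(self):
        return [self.w, self.b]


class _ResBlock:
    def __init__(self, rng, ch):
        self.c1 = _Conv(rng, ch, ch)
        self.c2 = _Conv(rng, ch, ch)

    def __call__(self, x: Tensor) -> Tensor:
        return add(x, self.c2(relu(self.c1(x))))

    def parameters(self):
        return self.c1.parameters() + self.c2.parameters()


class Generator:
    """Fully convolutional residual generator, 3 channels to 3 channels, tanh output."""

    def __init__(self, rng: np.random.Generator, channels: int = 3, width: int = 8, n_res: int = 1):
        self.head = _Conv(rng, channels, width)
        self.blocks = [_ResBlock(rng, width) for _ in range(n_res)]
        self.tail = _Conv(rng, width, channels)

    def __call__(self, x: Tensor) -> Tensor:
        h = relu(self.head(x))
        for blk in self.blocks:
            h = blk(h)
        return tanh(self.tail(h))

    def parameters(self):
        ps = self.head.parameters() + self.tail.parameters()
        for blk in self.blocks:
            ps += blk.parameters()
        return ps


class IdentityGenerator:
    """Pass-through generator; useful as a translator stub and in objective checks."""

    def __call__(self, x: Tensor) -> Tensor:
        return x

    def parameters(self):
        return []


class Discriminator:
    """Strided patch discriminator: real/fake score per receptive-field patch."""

    def __init__(self, rng: np.random.Generator, channels: int = 3, width: int = 8):
        self.c1 = _Conv(rng, channels, width, stride=2)
        self.c2 = _Conv(rng, width, width * 2, stride=2)
        self.c3 = _Conv(rng, width * 2, 1, stride=1)

    def __call__(self, x: Tensor) -> Tensor:
        h = leaky_relu(self.c1(x))
        h = leaky_relu(self.c2(h))
        return self.c3(h)

    def parameters(self):
        return self.c1.parameters() + self.c2.parameters() + self.c3.parameters()
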