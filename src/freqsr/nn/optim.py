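"""Adam optimizer with checkpointable moment state."""

from __future__ import annotations

import numpy as np

_F32 = np.float32


class Adam:
    def __init__(self, named_params, lr=1e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = dict(named_params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m, v = self.m[k], self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data -= _F32(self.lr) * (m / bc1) / (np.sqrt(v / bc2) + _F32(self.eps))

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def state_dict(self):
        out = {"t": np.asarray(self.t)}
        for k in self.params:
            out["m:" + k] = self.m[k].copy()
            out["v:" + k] = self.v[k].copy()
        return out

    def load_state_dict(self, state):
        self.t = int(state["t"])
        for k in self.params:
            self.m[k][...] = state["m:" + k]
            self.v[k][...] = state["v:" + k]
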