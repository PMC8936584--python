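"""Shared test helpers: finite-difference gradient checking."""

import numpy as np


def numeric_grad(f, tensor, eps=1e-6):
    """Central-difference gradient of scalar ``f()`` w.r.t. ``tensor.data``."""
    g = np.zeros_like(tensor.data)
    it = np.nditer(tensor.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = tensor.data[i]
        tensor.data[i] = orig + eps
        lp = f().item()
        tensor.data[i] = orig - eps
        lm = f().item()
        tensor.data[i] = orig
        g[i] = (lp - lm) / (2 * eps)
    return g


def gradcheck(f, tensors, eps=1e-6, atol=1e-5):
    """Assert autodiff gradients of scalar ``f(*tensors)`` match finite
    differences for every tensor that requires a gradient."""
    out = f(*tensors)
    for t in tensors:
        t.grad = None
    out.backward()
    for t in tensors:
        if not t.requires_grad:
            continue
        analytic = t.grad.copy()
        numeric = numeric_grad(lambda: f(*tensors), t, eps=eps)
        err = np.abs(analytic - numeric).max()
        assert err < atol, f"gradient mismatch {err:.3e} for shape {t.shape}"
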