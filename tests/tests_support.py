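"""Shared helpers for the test suite."""

import numpy as np


def numeric_grad(f, p, eps=1e-6):
    """Central finite-difference gradient of scalar ``f()`` w.r.t. ``p.data``."""
    num = np.zeros_like(p.data)
    it = np.nditer(p.data, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = p.data[idx]
        p.data[idx] = orig + eps
        fp = f()
        p.data[idx] = orig - eps
        fm = f()
        p.data[idx] = orig
        num[idx] = (fp - fm) / (2 * eps)
    return num


from qcsanet.quaternion import conjugate, hamilton_product  # noqa: E402


def loop_hamilton_conv(x, weight, bias, stride=(1, 1), pad=(0, 0)):
    """Brute-force oracle: per-window Hamilton-product sums, double precision."""
    x = np.asarray(x, dtype=float)
    b, c4, h, w = x.shape
    o, cin, kh, kw, _ = weight.shape
    x = np.pad(x, ((0, 0), (0, 0), (pad[0], pad[0]), (pad[1], pad[1])))
    xq = x.reshape(b, cin, 4, x.shape[2], x.shape[3])
    ho = (x.shape[2] - kh) // stride[0] + 1
    wo = (x.shape[3] - kw) // stride[1] + 1
    out = np.zeros((b, o, ho, wo, 4))
    for bi in range(b):
        for oi in range(o):
            for i in range(ho):
                for j in range(wo):
                    acc = np.zeros(4)
                    for ci in range(cin):
                        for u in range(kh):
                            for v in range(kw):
                                acc = acc + hamilton_product(
                                    weight[oi, ci, u, v],
                                    xq[bi, ci, :, i * stride[0] + u,
                                       j * stride[1] + v])
                    if bias is not None:
                        acc = acc + bias[oi]
                    out[bi, oi, i, j] = acc
    return np.moveaxis(out, -1, 2).reshape(b, 4 * o, ho, wo)


def loop_rotation_conv(x, weight, scales, stride=(1, 1)):
    """Brute-force sandwich-product oracle for the rotation variant."""
    x = np.asarray(x, dtype=float)
    b, c4, h, w = x.shape
    o, cin, kh, kw, _ = weight.shape
    xq = x.reshape(b, cin, 4, h, w)
    ho = (h - kh) // stride[0] + 1
    wo = (w - kw) // stride[1] + 1
    out = np.zeros((b, o, ho, wo, 4))
    for bi in range(b):
        for oi in range(o):
            for i in range(ho):
                for j in range(wo):
                    acc = np.zeros(4)
                    for ci in range(cin):
                        for u in range(kh):
                            for v in range(kw):
                                wq = weight[oi, ci, u, v]
                                qq = xq[bi, ci, :, i * stride[0] + u,
                                        j * stride[1] + v]
                                acc = acc + hamilton_product(
                                    hamilton_product(wq, qq), conjugate(wq)
                                ) / scales[oi, ci, u, v]
                    out[bi, oi, i, j] = acc
    return np.moveaxis(out, -1, 2).reshape(b, 4 * o, ho, wo)
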