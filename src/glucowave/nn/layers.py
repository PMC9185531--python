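"""Neural-network layers with explicit forward and backward passes.

Conventions
-----------
* images are ``(B, C, H, W)`` float64 arrays; sequences are ``(B, T, F)``;
* every layer caches what its backward pass needs during ``forward`` and
  releases it on the next call;
* parameters are :class:`Param` objects holding a value and an accumulated
  gradient; optimisers consume ``module.parameters()``;
* ``train`` mode only changes batch-normalisation statistics handling.
"""

from __future__ import annotations

import math

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: recursive parameter collection and mode switching."""

    training: bool = False

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for attr in vars(self).values():
            out.extend(_collect(attr))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for attr in vars(self).values():
            for m in _collect_modules(attr):
                m.set_training(flag)

    def state_dict(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.parameters()]
        for m in _walk(self):
            if isinstance(m, BatchNorm2d):
                state.append(m.running_mean.copy())
                state.append(m.running_var.copy())
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, v in zip(params, state):
            p.value[...] = v
        idx = len(params)
        for m in _walk(self):
            if isinstance(m, BatchNorm2d):
                m.running_mean[...] = state[idx]
                m.running_var[...] = state[idx + 1]
                idx += 2


def _collect(obj) -> list[Param]:
    if isinstance(obj, Param):
        return [obj]
    if isinstance(obj, Module):
        return obj.parameters()
    if isinstance(obj, (list, tuple)):
        out = []
        for item in obj:
            out.extend(_collect(item))
        return out
    return []


def _collect_modules(obj) -> list["Module"]:
    if isinstance(obj, Module):
        return [obj]
    if isinstance(obj, (list, tuple)):
        out = []
        for item in obj:
            out.extend(_collect_modules(item))
        return out
    return []


def _walk(module: Module) -> list[Module]:
    found = [module]
    for attr in vars(module).values():
        for m in _collect_modules(attr):
            found.extend(_walk(m))
    return found


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    sb, sc, sh, sw = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, oh, ow, k, k),
        strides=(sb, sc, sh * stride, sw * stride, sh, sw),
        writeable=False,
    )
    # (B*OH*OW, C*k*k)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * oh * ow, c * k * k)
    return np.ascontiguousarray(cols), (oh, ow)


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int, oh: int, ow: int):
    b, c, h, w = xshape
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(b, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d6[
                :, :, i, j
            ]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2d(Module):
    """2-D convolution with square kernel, He-normal initialisation."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        bias: bool = True,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        k = int(kernel_size)
        fan_in = in_channels * k * k
        self.weight = Param(
            rng.standard_normal((out_channels, in_channels, k, k))
            * math.sqrt(2.0 / fan_in)
        )
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self.kernel_size = k
        self.stride = int(stride)
        self.pad = k // 2
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (oh, ow) = _im2col(x, self.kernel_size, self.stride, self.pad)
        wmat = self.weight.value.reshape(self.weight.value.shape[0], -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.value
        b = x.shape[0]
        self._cache = (x.shape, cols, oh, ow)
        return out.reshape(b, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xshape, cols, oh, ow = self._cache
        self._cache = None
        b = xshape[0]
        cout = dout.shape[1]
        dmat = dout.transpose(0, 2, 3, 1).reshape(b * oh * ow, cout)
        wmat = self.weight.value.reshape(cout, -1)
        self.weight.grad += (dmat.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dmat.sum(axis=0)
        dcols = dmat @ wmat
        return _col2im(dcols, xshape, self.kernel_size, self.stride, self.pad, oh, ow)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        self._cache = None
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not self.training:
            return dxhat * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        # batch statistics participate in the forward pass
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (term1 - term2 - term3) * inv[None, :, None, None]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class AvgPool2d(Module):
    """Non-overlapping k x k average pooling (trailing rows/cols dropped)."""

    def __init__(self, k: int = 2):
        self.k = int(k)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        b, c, h, w = x.shape
        oh, ow = h // k, w // k
        view = x[:, :, : oh * k, : ow * k].reshape(b, c, oh, k, ow, k)
        self._cache = (x.shape, oh, ow)
        return view.mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xshape, oh, ow = self._cache
        self._cache = None
        k = self.k
        dx = np.zeros(xshape, dtype=dout.dtype)
        expanded = np.repeat(np.repeat(dout, k, axis=2), k, axis=3) / (k * k)
        dx[:, :, : oh * k, : ow * k] = expanded
        return dx


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Param(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Param(np.zeros(out_features))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        self.weight.grad += x.T @ dout
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value.T


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class BasicBlock(Module):
    """Residual block: conv-BN-ReLU-conv-BN plus a (projected) skip."""

    def __init__(self, cin: int, cout: int, stride: int = 1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng, bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, rng=rng, bias=False)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, stride=stride, rng=rng, bias=False)
            self.proj_bn = BatchNorm2d(cout)
        else:
            self.proj = None
            self.proj_bn = None
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.bn1.forward(self.conv1.forward(x))
        out = self.relu1.forward(out)
        out = self.bn2.forward(self.conv2.forward(out))
        skip = x if self.proj is None else self.proj_bn.forward(self.proj.forward(x))
        return self.relu_out.forward(out + skip)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dout)
        dmain = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(self.conv2.backward(self.bn2.backward(dsum)))
            )
        )
        if self.proj is None:
            dskip = dsum
        else:
            dskip = self.proj.backward(self.proj_bn.backward(dsum))
        return dmain + dskip


# ---------------------------------------------------------------------------
# recurrent layers


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _LSTMDirection(Module):
    """One direction of an LSTM layer; gate order (i, f, g, o)."""

    def __init__(self, in_features: int, hidden: int, rng=None):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / math.sqrt(hidden)
        self.w_x = Param(rng.uniform(-bound, bound, (in_features, 4 * hidden)))
        self.w_h = Param(rng.uniform(-bound, bound, (hidden, 4 * hidden)))
        bias = np.zeros(4 * hidden)
        bias[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Param(bias)
        self.hidden = hidden
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        h = self.hidden
        h_t = np.zeros((b, h), dtype=x.dtype)
        c_t = np.zeros((b, h), dtype=x.dtype)
        outs = np.empty((b, t, h), dtype=x.dtype)
        steps = []
        for ti in range(t):
            z = x[:, ti] @ self.w_x.value + h_t @ self.w_h.value + self.b.value
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_new = f * c_t + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            steps.append((x[:, ti], h_t, c_t, i, f, g, o, tanh_c))
            h_t, c_t = h_new, c_new
            outs[:, ti] = h_new
        self._cache = (steps, x.shape)
        return outs

    def backward(self, douts: np.ndarray) -> np.ndarray:
        steps, xshape = self._cache
        self._cache = None
        b, t, fdim = xshape
        h = self.hidden
        dx = np.zeros(xshape, dtype=douts.dtype)
        dh_next = np.zeros((b, h), dtype=douts.dtype)
        dc_next = np.zeros((b, h), dtype=douts.dtype)
        for ti in range(t - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = steps[ti]
            dh = douts[:, ti] + dh_next
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            do = dh * tanh_c
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.w_x.grad += x_t.T @ dz
            self.w_h.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, ti] = dz @ self.w_x.value.T
            dh_next = dz @ self.w_h.value.T
            dc_next = dc * f
        return dx


class BiLSTM(Module):
    """Bidirectional LSTM layer: (B, T, F) -> (B, T, 2H)."""

    def __init__(self, in_features: int, hidden: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.fwd = _LSTMDirection(in_features, hidden, rng)
        self.bwd = _LSTMDirection(in_features, hidden, rng)
        self.hidden = hidden

    def forward(self, x: np.ndarray) -> np.ndarray:
        out_f = self.fwd.forward(x)
        out_b = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([out_f, out_b], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h = self.hidden
        dx_f = self.fwd.backward(dout[:, :, :h])
        dx_b = self.bwd.backward(dout[:, ::-1, h:])[:, ::-1]
        return dx_f + dx_b


# ---------------------------------------------------------------------------
# loss


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    b = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(b), labels] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(b), labels] -= 1.0
    return loss, dlogits / b
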