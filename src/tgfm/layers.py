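"""Small neural-network layer library on top of the autodiff engine.

Provides the module/parameter registry, linear and two-layer feed-forward
maps, layer normalisation and a weight-only scale normalisation.  Linear
layers default to bias-free: the backbone's parameter budget is carried by
the weight matrices, and biases are enabled only where a layer needs an
output offset (the regression head).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor


class Module:
    """Base class with recursive parameter discovery in attribute order."""

    def __setattr__(self, name, value):
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = False):
        self.weight = Parameter(rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class FFN(Module):
    """Two-layer perceptron with GELU, bias-free."""

    def __init__(self, n_in: int, hidden: int, n_out: int, rng: np.random.Generator):
        self.fc1 = Linear(n_in, hidden, rng)
        self.fc2 = Linear(hidden, n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class LayerNorm(Module):
    """Layer normalisation over the trailing (embedding) axis, with weight
    and bias."""

    def __init__(self, dim: int, eps: float = 1e-6):
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        object.__setattr__(self, "eps", eps)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.weight + self.bias


class ScaleNorm(Module):
    """Weight-only RMS normalisation (no centring, no bias)."""

    def __init__(self, dim: int, eps: float = 1e-6):
        self.weight = Parameter(np.ones(dim))
        object.__setattr__(self, "eps", eps)

    def __call__(self, x: Tensor) -> Tensor:
        ms = (x * x).mean(axis=-1, keepdims=True)
        return x * ((ms + self.eps) ** -0.5) * self.weight


def rms_normalize(x: Tensor, eps: float = 1e-6) -> Tensor:
    """Parameter-free RMS normalisation."""
    ms = (x * x).mean(axis=-1, keepdims=True)
    return x * ((ms + eps) ** -0.5)


class Embedding(Module):
    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator,
                 scale: float = 0.1):
        self.weight = Parameter(rng.normal(0.0, scale, (n_rows, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        from .autodiff import gather_rows
        return gather_rows(self.weight, idx)
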