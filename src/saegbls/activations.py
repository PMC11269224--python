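"""Activation functions for feature and enhancement nodes.

``tansig`` (the name used in the MATLAB neural-network tradition) is the
same function as ``tanh``: tansig(x) = 2/(1+e^(-2x)) - 1 = tanh(x). Both
names are accepted so configurations written against either convention work.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.special import expit


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic sigmoid 1/(1+e^(-x)), mapping into (0, 1)."""
    return expit(x)


def tanh(x: np.ndarray) -> np.ndarray:
    return np.tanh(x)


def tansig(x: np.ndarray) -> np.ndarray:
    """2/(1+e^(-2x)) - 1; numerically identical to tanh."""
    return np.tanh(x)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": sigmoid,
    "tanh": tanh,
    "tansig": tansig,
    "relu": relu,
}


def get_activation(name: str) -> Callable[[np.ndarray], np.ndarray]:
    """Look up an activation by name.

    Raises
    ------
    ParameterError
        If ``name`` is not one of sigmoid, tanh, tansig, relu.
    """
    from .errors import ParameterError

    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ParameterError(
            f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}"
        ) from None
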