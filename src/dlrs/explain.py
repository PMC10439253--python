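"""Guided Grad-CAM saliency for the DLRS prediction.

Grad-CAM weights each channel of a chosen convolutional activation by the
spatial mean of the output-score gradient, rectifies the weighted sum, and
upsamples it to the input resolution. Guided backpropagation refines this
with a pixel-level gradient map in which every ReLU passes only positive
gradients; the overlay is the elementwise product of the two maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .exceptions import ConfigError
from .nn.autodiff import Tensor, guided_backprop
from .nn.model import HRRadNet
from .volumes import ModelInput

__all__ = ["Heatmap", "grad_cam", "guided_backprop_map", "guided_backprop_overlay"]


@dataclass
class Heatmap:
    """Non-negative saliency map at input resolution, max-normalized for rendering."""

    values: np.ndarray
    target_layer: str
    case_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0:
            raise ConfigError("heatmap values must be non-negative")

    def normalized(self) -> np.ndarray:
        m = self.values.max()
        return self.values / m if m > 0 else self.values


def _forward_with_grad(model: HRRadNet, inp: ModelInput, radiomics: np.ndarray):
    x = Tensor(inp.channels[None], requires_grad=True)
    r = Tensor(np.asarray(radiomics, dtype=np.float64)[None])
    prob = model.forward(x, r, capture=True)
    return x, prob


def grad_cam(model: HRRadNet, inp: ModelInput, radiomics: np.ndarray,
             target_layer: str | None = None) -> Heatmap:
    """Class-activation heatmap of the DLRS output at ``target_layer``.

    Defaults to the last highest-resolution convolutional block.
    """
    layer = target_layer or model.default_cam_layer()
    x, prob = _forward_with_grad(model, inp, radiomics)
    if layer not in model.activations:
        raise ConfigError(
            f"unknown layer {layer!r}; available: {sorted(model.activations)}"
        )
    act = model.activations[layer]
    model.zero_grad()
    prob.backward()
    if act.grad is None:  # no gradient flow (e.g. image branch zeroed out)
        cam = np.zeros(act.data.shape[2:])
    else:
        weights = act.grad.mean(axis=(2, 3))  # (1, C) spatial-mean gradients
        cam = np.maximum((weights[0][:, None, None] * act.data[0]).sum(axis=0), 0.0)
    size = inp.size
    cam_up = resize(cam, (size, size), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    return Heatmap(values=np.maximum(cam_up, 0.0), target_layer=layer,
                   case_id=inp.case_id)


def guided_backprop_map(model: HRRadNet, inp: ModelInput,
                        radiomics: np.ndarray) -> np.ndarray:
    """Pixel-level guided-backpropagation gradient magnitude of the CT channel."""
    x, prob = _forward_with_grad(model, inp, radiomics)
    model.zero_grad()
    with guided_backprop():
        prob.backward()
    if x.grad is None:
        return np.zeros(inp.channels.shape[1:])
    return np.abs(x.grad[0, 0])


def guided_backprop_overlay(model: HRRadNet, inp: ModelInput,
                            radiomics: np.ndarray, heatmap: Heatmap) -> np.ndarray:
    """Guided Grad-CAM: guided-backprop map multiplied by the upsampled CAM."""
    gb = guided_backprop_map(model, inp, radiomics)
    return gb * heatmap.values
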