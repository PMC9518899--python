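"""Read and write circuit model configurations (YAML key-value documents).

One document per circuit with keys: kind, the circuit rates (k0, or
k0_1/k0_2 for the toggle, k1, K, n, d0), and the growth-feedback triple
J, kg0, m.  Fixture configs for the four reference parameter sets ship with
the package (see :func:`fixture_config_path`).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Union

import yaml

from .core_models import (
    ConstitutiveCircuit,
    GrowthFeedbackParams,
    SelfActivationCircuit,
    ToggleCircuit,
)

__all__ = ["load_model", "save_model", "fixture_config_path"]

_GF_KEYS = ("kg0", "J", "m")


def _model_to_dict(model) -> dict:
    doc = {"kind": model.kind}
    if model.kind == "constitutive":
        doc.update(k0=model.k0, d0=model.d0)
    elif model.kind == "self_activation":
        doc.update(k0=model.k0, k1=model.k1, K=model.K, n=model.n, d0=model.d0)
    elif model.kind == "toggle":
        for name in ("k0", "k1", "K", "n", "d0"):
            pair = getattr(model, name)
            doc[f"{name}_1"], doc[f"{name}_2"] = pair
    else:  # pragma: no cover
        raise ValueError(f"unknown model kind {model.kind!r}")
    doc.update(J=model.gf.J, kg0=model.gf.kg0, m=model.gf.m)
    return doc


def save_model(model, path: Union[str, Path]) -> None:
    """Write a circuit model as a single-document YAML config."""
    with open(path, "w") as fh:
        yaml.safe_dump(_model_to_dict(model), fh, sort_keys=False)


def _model_from_dict(doc: dict):
    doc = dict(doc)
    kind = doc.pop("kind", None)
    gf = GrowthFeedbackParams(
        kg0=float(doc.pop("kg0")), J=float(doc.pop("J")), m=float(doc.pop("m"))
    )
    if kind == "constitutive":
        return ConstitutiveCircuit(k0=float(doc.pop("k0")), d0=float(doc.pop("d0")), gf=gf)
    if kind == "self_activation":
        return SelfActivationCircuit(
            k0=float(doc.pop("k0")),
            k1=float(doc.pop("k1")),
            K=float(doc.pop("K")),
            n=float(doc.pop("n")),
            d0=float(doc.pop("d0")),
            gf=gf,
        )
    if kind == "toggle":
        pairs = {}
        for name in ("k0", "k1", "K", "n", "d0"):
            if name in doc:  # one value for both genes
                v = float(doc.pop(name))
                pairs[name] = (v, v)
            else:
                pairs[name] = (float(doc.pop(f"{name}_1")), float(doc.pop(f"{name}_2")))
        return ToggleCircuit(gf=gf, **pairs)
    raise ValueError(f"unknown or missing circuit kind {kind!r}")


def load_model(path: Union[str, Path]):
    """Load a circuit model from a YAML config written by :func:`save_model`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} is not a key-value document")
    return _model_from_dict(doc)


def fixture_config_path(name: str) -> Path:
    """Path to one of the shipped reference configs.

    ``name`` is one of constitutive, self_activation, toggle_tristable,
    toggle_quadstable.
    """
    ref = resources.files(__package__) / "configs" / f"{name}.yaml"
    with resources.as_file(ref) as p:
        if not p.exists():
            raise ValueError(f"no shipped config named {name!r}")
        return p
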