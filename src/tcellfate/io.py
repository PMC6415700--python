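"""Reading and writing model configuration files.

A model config is a flat YAML (or JSON) document::

    units: per_minute
    blood: {mu: 1.478e-5, lambda: 1.458e-5}
    compartments:
      - {label: C1, xi_in: 1.59e-2, xi_out: 2.60e-3, mu: ..., lambda: ...}
      - ...
    split_compartment:        # optional -> ExtendedModel
      xi_B_C1a: ...
      xi_B_C1b: ...
      xi_C1a_C1b: ...
      xi_C1b_B: ...
      mu: ...                 # shared by C1a and C1b, or mu_a / mu_b
      lambda: ...

When ``split_compartment`` is present the ``compartments`` list holds
only C2..CM and an :class:`~tcellfate.models.ExtendedModel` is returned.

The packaged fixture ``table1`` carries the published mouse CD4+ T-cell
rates (star topology around the blood with M = 5 tissue compartments);
``table1_extended`` carries the same rates with the mesenteric-LN /
Peyer's-patch pair kept split, including the direct C1a -> C1b edge.
The fixture's effective C1 return rate is the published rounded value;
:func:`~tcellfate.models.merge_split_compartment` recomputes it from the
split rates (the two differ in the third digit because the published
value was derived from unrounded sources).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .models import ExtendedModel, ModelValidationError, StarModel, validate

__all__ = [
    "load_model",
    "loads_model",
    "save_model",
    "model_to_dict",
    "load_table1",
    "load_table1_extended",
]


def _get(d: dict, key: str, where: str):
    if key not in d:
        raise ModelValidationError(f"missing key {key!r} in {where}")
    return d[key]


def loads_model(text: str) -> StarModel | ExtendedModel:
    """Parse a model from YAML/JSON text."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ModelValidationError("model config must be a mapping")
    units = doc.get("units", "per_minute")
    if units != "per_minute":
        raise ModelValidationError(
            f"units must be 'per_minute', got {units!r}"
        )
    blood = _get(doc, "blood", "model config")
    mu_B = float(_get(blood, "mu", "blood"))
    lam_B = float(_get(blood, "lambda", "blood"))
    comps = doc.get("compartments", []) or []
    labels = tuple(str(c.get("label", f"C{i + 1}")) for i, c in enumerate(comps))
    xi_in = np.array([float(_get(c, "xi_in", "compartment")) for c in comps])
    xi_out = np.array([float(_get(c, "xi_out", "compartment")) for c in comps])
    mu = np.array([float(_get(c, "mu", "compartment")) for c in comps])
    lam = np.array([float(_get(c, "lambda", "compartment")) for c in comps])

    split = doc.get("split_compartment")
    if split is None:
        return validate(StarModel(
            xi_in=xi_in, xi_out=xi_out, mu=mu, lam=lam,
            mu_B=mu_B, lam_B=lam_B, labels=labels,
        ))
    mu_a = float(split.get("mu_a", split.get("mu", np.nan)))
    mu_b = float(split.get("mu_b", split.get("mu", np.nan)))
    lam_a = float(split.get("lambda_a", split.get("lambda", np.nan)))
    lam_b = float(split.get("lambda_b", split.get("lambda", np.nan)))
    return validate(ExtendedModel(
        xi_B_C1a=float(_get(split, "xi_B_C1a", "split_compartment")),
        xi_B_C1b=float(_get(split, "xi_B_C1b", "split_compartment")),
        xi_C1a_C1b=float(_get(split, "xi_C1a_C1b", "split_compartment")),
        xi_C1b_B=float(_get(split, "xi_C1b_B", "split_compartment")),
        mu_C1a=mu_a, lam_C1a=lam_a, mu_C1b=mu_b, lam_C1b=lam_b,
        xi_in=xi_in, xi_out=xi_out, mu=mu, lam=lam,
        mu_B=mu_B, lam_B=lam_B, labels=labels,
    ))


def load_model(path: str | Path) -> StarModel | ExtendedModel:
    """Load and validate a model from a YAML or JSON file."""
    return loads_model(Path(path).read_text())


def model_to_dict(model: StarModel | ExtendedModel) -> dict:
    """Config-document representation of a model (round-trips)."""
    doc: dict = {
        "units": "per_minute",
        "blood": {"mu": float(model.mu_B), "lambda": float(model.lam_B)},
    }
    if isinstance(model, ExtendedModel):
        doc["split_compartment"] = {
            "xi_B_C1a": model.xi_B_C1a,
            "xi_B_C1b": model.xi_B_C1b,
            "xi_C1a_C1b": model.xi_C1a_C1b,
            "xi_C1b_B": model.xi_C1b_B,
            "mu_a": model.mu_C1a, "lambda_a": model.lam_C1a,
            "mu_b": model.mu_C1b, "lambda_b": model.lam_C1b,
        }
    doc["compartments"] = [
        {
            "label": lab,
            "xi_in": float(model.xi_in[i]),
            "xi_out": float(model.xi_out[i]),
            "mu": float(model.mu[i]),
            "lambda": float(model.lam[i]),
        }
        for i, lab in enumerate(model.labels)
    ]
    return doc


def save_model(model: StarModel | ExtendedModel, path: str | Path) -> None:
    """Write a model config; format chosen by suffix (.json else YAML)."""
    doc = model_to_dict(model)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def _load_packaged(name: str) -> StarModel | ExtendedModel:
    text = (resources.files("tcellfate") / "data" / name).read_text()
    return loads_model(text)


def load_table1() -> StarModel:
    """Published mouse CD4+ T-cell rates, merged star model (M = 5).

    C1 pools the mesenteric lymph nodes and Peyer's patches with the
    published effective migration rates; the remaining compartments are
    lung, liver, spleen and subcutaneous lymph nodes.  Division and
    death rates are uniform across compartments.
    """
    model = _load_packaged("table1.yaml")
    assert isinstance(model, StarModel)
    return model


def load_table1_extended() -> ExtendedModel:
    """Published rates with the C1a/C1b pair kept split (direct edge)."""
    model = _load_packaged("table1_extended.yaml")
    assert isinstance(model, ExtendedModel)
    return model
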