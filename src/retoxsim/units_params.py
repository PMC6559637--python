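"""Physical constants of the outer-retina oxygen model and unit conversions.

The model treats the dark-adapted outer retina as a stack of passive
diffusive layers with a single zero-order oxygen sink in the photoreceptor
inner segments (IS).  Oxygen enters from two sides: the choriocapillaris,
represented as a fixed-concentration (Dirichlet) boundary at the basal face
of Bruch's membrane, and the deep retinal capillary plexus, represented as a
constant influx (Neumann) boundary at the apical face of the OPL.

All lengths at the public API are in micrometres; concentrations are in
mol/m^3; partial pressures in mmHg.  The concentration <-> pO2 conversion is
linear (Henry's law) and anchored by the single literature pair
0.1107 mol/m^3 <-> 80 mmHg.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Mapping

import yaml

log = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "load_params",
    "conc_to_po2",
    "po2_to_conc",
    "retinal_supply_fraction",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical and anatomical constants of the oxygen transport model.

    Attributes
    ----------
    diffusion_coefficient :
        Oxygen diffusion coefficient D in retinal tissue, m^2/s.  Applied to
        every tissue domain (passive layers, drusen, and the consuming IS).
    consumption_rate_is :
        Zero-order dark-adapted oxygen consumption rate Q in the IS,
        mol/(m^3 s).  Zero everywhere else.
    choroid_concentration :
        Soluble oxygen concentration at the choriocapillaris boundary,
        mol/m^3 (Dirichlet value at the basal Bruch's-membrane face).
    retinal_flux :
        Constant soluble oxygen influx from the deep retinal capillary
        plexus, mol/(m^2 s), applied at the apical OPL face.
    height_sub_is :
        Combined Bruch's membrane + RPE + outer segment thickness in the
        generic laminar model, micrometres.
    height_is :
        Inner segment layer thickness, micrometres.  Also the IS maximum in
        the patient-style IS reconstruction.
    height_onl_opl :
        Combined outer nuclear + outer plexiform layer thickness,
        micrometres.
    solubility_alpha :
        Linear solubility constant alpha, mol/(m^3 mmHg), so that
        pO2 = c / alpha.
    """

    diffusion_coefficient: float = 1.97e-9
    consumption_rate_is: float = 0.148
    choroid_concentration: float = 0.1107
    retinal_flux: float = 5.05e-7
    height_sub_is: float = 55.0
    height_is: float = 25.0
    height_onl_opl: float = 45.0
    solubility_alpha: float = 0.1107 / 80.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise TypeError(f"{f.name} must be numeric, got {v!r}")
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")

    def with_overrides(self, **kwargs: float) -> "ModelParams":
        return replace(self, **kwargs)


_FIELD_NAMES = tuple(f.name for f in fields(ModelParams))


def load_params(config_source: str | Path | Mapping[str, float] | None = None) -> ModelParams:
    """Build :class:`ModelParams` from defaults plus optional overrides.

    Parameters
    ----------
    config_source :
        ``None`` for pure defaults, a mapping of field names to values, or a
        path to a flat JSON/YAML document whose keys are a subset of the
        :class:`ModelParams` field names.

    Raises
    ------
    KeyError
        If an unknown key is present.
    ValueError / TypeError
        If an override is non-numeric or non-positive (the offending key is
        named in the message).
    """
    if config_source is None:
        return ModelParams()
    if isinstance(config_source, (str, Path)):
        text = Path(config_source).read_text()
        try:
            doc = json.loads(text)
        except json.JSONDecodeError:
            doc = yaml.safe_load(text)
    else:
        doc = dict(config_source)
    if doc is None:
        return ModelParams()
    if not isinstance(doc, Mapping):
        raise TypeError("config must be a flat key/value mapping")

    unknown = set(doc) - set(_FIELD_NAMES)
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    for key, value in doc.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise TypeError(f"parameter {key!r} must be numeric, got {value!r}")
        if not math.isfinite(value) or value <= 0:
            raise ValueError(f"parameter {key!r} must be strictly positive, got {value!r}")

    defaults = ModelParams()
    for key, value in doc.items():
        if value != getattr(defaults, key):
            log.info("non-default parameter %s = %r", key, value)
    return defaults.with_overrides(**{k: float(v) for k, v in doc.items()})


def conc_to_po2(c, params: ModelParams):
    """Convert soluble oxygen concentration (mol/m^3) to pO2 (mmHg).

    Negative concentrations are rejected: fields are clamped non-negative
    upstream, so a negative value here signals a solver bug.
    """
    import numpy as np

    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative concentration passed to conc_to_po2")
    out = c / params.solubility_alpha
    return float(out) if out.ndim == 0 else out


def po2_to_conc(p, params: ModelParams):
    """Convert pO2 (mmHg) to soluble oxygen concentration (mol/m^3)."""
    import numpy as np

    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative partial pressure passed to po2_to_conc")
    out = p * params.solubility_alpha
    return float(out) if out.ndim == 0 else out


def retinal_supply_fraction(params: ModelParams) -> float:
    """Fraction of total IS consumption supplied by the retinal vasculature.

    With no anoxia, a column of IS consumes Q * h_IS per unit area; the
    apical Neumann boundary supplies J_ret of it and the choroid the rest.
    The healthy outer retina draws 10-15% from the retinal side.
    """
    return params.retinal_flux / (params.consumption_rate_is * params.height_is * 1e-6)
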