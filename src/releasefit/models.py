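"""The four parametric release models.

Cumulative release Qt (percent of the loaded amount) as a function of time t
(minutes):

* ``zero_order``        Qt = K0·t + b0
* ``first_order``       Qt = K1·e^(a·t) + b1   (saturating when K1 < 0, a < 0,
                        approaching the plateau b1)
* ``higuchi``           Qt = KH·√t + bH        (matrix diffusion)
* ``korsmeyer_peppas``  Qt = K·t^n             (semi-empirical power law,
                        valid for the first 60 % of fractional release)

Each model is described by a :class:`KineticModelSpec`; the module-level
registry :data:`MODEL_REGISTRY` is the single source of model names, parameter
orderings and the fitting-domain rule, and its iteration order is the
deterministic tie-break order used by model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ParameterArityError

__all__ = [
    "KineticModelSpec",
    "MODEL_REGISTRY",
    "MODEL_ORDER",
    "get_model",
    "evaluate_model",
]

#: Domain-rule markers.
ALL_POINTS = "all_points"
BELOW_60_PERCENT = "below_60_percent"


@dataclass(frozen=True)
class KineticModelSpec:
    """Static description of one kinetic model.

    Attributes
    ----------
    name:
        Registry key, one of ``zero_order``, ``first_order``, ``higuchi``,
        ``korsmeyer_peppas``.
    parameter_names:
        Ordered parameter symbols; fitted parameter vectors follow this order.
    domain_rule:
        ``below_60_percent`` restricts fitting to the prefix of the curve
        below 60 % cumulative release (Korsmeyer–Peppas only), ``all_points``
        uses the full curve.
    """

    name: str
    parameter_names: tuple[str, ...]
    domain_rule: str = ALL_POINTS

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)


MODEL_REGISTRY: dict[str, KineticModelSpec] = {
    "zero_order": KineticModelSpec("zero_order", ("K0", "b0")),
    "first_order": KineticModelSpec("first_order", ("K1", "a", "b1")),
    "higuchi": KineticModelSpec("higuchi", ("KH", "bH")),
    "korsmeyer_peppas": KineticModelSpec(
        "korsmeyer_peppas", ("K", "n"), domain_rule=BELOW_60_PERCENT
    ),
}

#: Fixed registry order; used as the deterministic tie-break in selection.
MODEL_ORDER: tuple[str, ...] = tuple(MODEL_REGISTRY)


def get_model(model: "str | KineticModelSpec") -> KineticModelSpec:
    """Resolve a model name (or pass a spec through) to a registry entry."""
    if isinstance(model, KineticModelSpec):
        return model
    try:
        return MODEL_REGISTRY[model]
    except KeyError:
        raise KeyError(
            f"unknown model {model!r}; known models: {', '.join(MODEL_ORDER)}"
        ) from None


def evaluate_model(model, params, t):
    """Evaluate a kinetic model at time(s) ``t`` (minutes, ≥ 0).

    ``params`` must match the model's parameter order exactly.  For the
    Korsmeyer–Peppas model, 0^n is defined as 0 for n > 0 so the power law
    passes through the origin; t = 0 with n ≤ 0 is a domain error.

    Returns a scalar for scalar ``t`` and an ndarray for array ``t``.
    """
    spec = get_model(model)
    p = np.asarray(params, dtype=float)
    if p.shape != (spec.n_params,):
        raise ParameterArityError(
            f"{spec.name} expects {spec.n_params} parameters "
            f"({', '.join(spec.parameter_names)}), got {p.size}"
        )
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time values must be non-negative")

    if spec.name == "zero_order":
        q = p[0] * t_arr + p[1]
    elif spec.name == "first_order":
        q = p[0] * np.exp(p[1] * t_arr) + p[2]
    elif spec.name == "higuchi":
        q = p[0] * np.sqrt(t_arr) + p[1]
    else:  # korsmeyer_peppas
        K, n = p
        if np.any(t_arr == 0.0) and n <= 0:
            raise DomainError(
                "korsmeyer_peppas is undefined at t = 0 unless n > 0"
            )
        q = K * np.power(t_arr, n)

    if np.ndim(t) == 0:
        return float(q)
    return q
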