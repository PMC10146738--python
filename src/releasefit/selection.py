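"""Best-model selection and release-mechanism classification.

Selection formalises the two-step reasoning used to read goodness-of-fit
tables: shortlist the fits whose adjusted R² is within a relative tolerance
of the best, then pick the smallest residual sum of squares, breaking any
remaining tie by the smallest reduced χ² and finally by the fixed model
registry order.  RSS precedes reduced χ² deliberately: with the
Korsmeyer–Peppas 60 %-window restriction the power-law fit can show a higher
reduced χ² (fewer degrees of freedom) while its RSS is far lower, and it is
still the better description of the data it is valid on.

The transport mechanism is read off the Korsmeyer–Peppas exponent n for a
cylindrical release geometry (viscose fibres are thin cylinders):

    n < 0.45          Fickian diffusion
    0.45 ≤ n < 0.89   non-Fickian (anomalous) transport
    n = 0.89          Case II transport
    n > 0.89          super Case II transport

The boundary n = 0.45 is assigned to the non-Fickian class so the partition
is exhaustive; n = 0.89 is matched within an absolute tolerance.  A burst
release is flagged when the power-law rate constant K reaches a threshold
(default 6.0 %·min⁻ⁿ, the lower edge of the empirical burst cluster; the
non-burst cluster sits below ~0.9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError, DomainError, SelectionError
from .fitting import FitResult
from .models import MODEL_ORDER

__all__ = [
    "ModelComparison",
    "MechanismCall",
    "rank_models",
    "classify_mechanism",
    "flag_burst",
    "call_mechanism",
]

TRANSPORT_CLASSES = ("fickian", "non_fickian", "case_II", "super_case_II")


@dataclass(frozen=True)
class ModelComparison:
    """All fitted models with the selected winner and the criteria applied."""

    fits: tuple[FitResult, ...]
    selected: str
    rationale: tuple[str, ...]

    @property
    def selected_fit(self) -> FitResult:
        return next(f for f in self.fits if f.model_name == self.selected)


@dataclass(frozen=True)
class MechanismCall:
    """Transport classification and burst flag from Korsmeyer–Peppas (K, n)."""

    n: float
    K: float
    geometry: str
    transport_class: str
    burst_flag: bool
    thresholds_used: tuple[float, float, float]  # (n_low, n_high, burst_K)


def _finite(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


def rank_models(fits, adj_r2_tolerance: float = 0.05) -> ModelComparison:
    """Select the best fit from ``fits`` (≥ 2 FitResults).

    Candidate set: fits whose adjusted R² is within ``adj_r2_tolerance``
    (relative) of the maximum.  Among candidates the smallest RSS wins; exact
    ties fall through to the smallest reduced χ² and then to the registry
    order.  The rationale records each criterion that was actually applied.
    """
    fits = tuple(fits)
    if len(fits) < 2:
        raise SelectionError("need at least 2 fits to rank")
    valid = [
        f
        for f in fits
        if f.converged and _finite(f.adj_r_square) and _finite(f.rss)
    ]
    if not valid:
        raise SelectionError("no converged fit with valid metrics")

    best_adj = max(f.adj_r_square for f in valid)
    threshold = best_adj - adj_r2_tolerance * abs(best_adj)
    candidates = [f for f in valid if f.adj_r_square >= threshold]
    rationale = ["adj_r2"]

    min_rss = min(f.rss for f in candidates)
    candidates = [f for f in candidates if f.rss == min_rss]
    rationale.append("rss")

    if len(candidates) > 1:
        chis = [
            f.reduced_chi_sq if _finite(f.reduced_chi_sq) else math.inf
            for f in candidates
        ]
        min_chi = min(chis)
        candidates = [f for f, c in zip(candidates, chis) if c == min_chi]
        rationale.append("reduced_chi_sq")

    if len(candidates) > 1:
        candidates.sort(key=lambda f: MODEL_ORDER.index(f.model_name))
        rationale.append("registry_order")

    return ModelComparison(fits, candidates[0].model_name, tuple(rationale))


def classify_mechanism(
    n: float,
    geometry: str = "cylinder",
    *,
    n_low: float = 0.45,
    n_high: float = 0.89,
    case2_tolerance: float = 1e-6,
) -> str:
    """Transport class from the release exponent n (cylindrical geometry)."""
    if geometry != "cylinder":
        raise ConfigurationError(
            f"unsupported geometry {geometry!r}: only cylinder thresholds ship; "
            "supply your own threshold table for other geometries"
        )
    if not math.isfinite(n):
        raise DomainError("release exponent must be finite")
    if abs(n - n_high) <= case2_tolerance:
        return "case_II"
    if n < n_low:
        return "fickian"
    if n < n_high:
        return "non_fickian"
    return "super_case_II"


def flag_burst(K: float, threshold: float = 6.0) -> bool:
    """True iff the release rate constant reaches the burst threshold."""
    if K < 0:
        raise DomainError("rate constant K must be non-negative")
    if threshold <= 0:
        raise DomainError("burst threshold must be positive")
    return K >= threshold


def call_mechanism(
    n: float,
    K: float,
    geometry: str = "cylinder",
    *,
    n_low: float = 0.45,
    n_high: float = 0.89,
    case2_tolerance: float = 1e-6,
    burst_threshold: float = 6.0,
) -> MechanismCall:
    """Bundle classification and burst flag into a :class:`MechanismCall`."""
    return MechanismCall(
        n=float(n),
        K=float(K),
        geometry=geometry,
        transport_class=classify_mechanism(
            n, geometry, n_low=n_low, n_high=n_high, case2_tolerance=case2_tolerance
        ),
        burst_flag=flag_burst(K, burst_threshold),
        thresholds_used=(n_low, n_high, burst_threshold),
    )
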