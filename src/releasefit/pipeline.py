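"""Batch analysis pipeline, configuration and report rendering.

``run_pipeline`` takes release-curve files (or in-memory curves), fits the
configured kinetic models to each, selects the best model, classifies the
transport mechanism from the Korsmeyer–Peppas (K, n), attaches
group-contribution solubility parameters when a multiset is known for the
drug label, and emits one machine-readable results table plus a
human-readable per-drug report whose per-model blocks mirror the layout of
the published fitting tables (equation string, adjusted R², RSS, reduced χ²
or Pearson's r).  Per-drug failures are recorded without aborting the batch,
and identical config + inputs + seed produce byte-identical outputs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError, SelectionError
from .fitting import FitOptions, FitResult, fit_all_models
from .models import MODEL_ORDER, get_model
from .quantitation import CalibrationLine, ReleaseCurve, read_curve_csv
from .selection import MechanismCall, ModelComparison, call_mechanism, rank_models
from .solubility import SolubilityParameters, _default_molecules, solubility_parameters

__all__ = [
    "AnalysisConfig",
    "DrugRecord",
    "PipelineResult",
    "run_pipeline",
    "analyze_curve",
    "format_equation",
    "parse_equation",
    "render_report",
]

log = logging.getLogger("releasefit")


@dataclass
class AnalysisConfig:
    """All tunables of the pipeline in one place (YAML-loadable)."""

    models: tuple = MODEL_ORDER
    kp_cutoff_percent: float = 60.0
    adj_r2_tolerance: float = 0.05
    burst_threshold: float = 6.0
    n_case2_tolerance: float = 1e-6
    geometry: str = "cylinder"
    # calibration / quantitation (raw-absorbance inputs only)
    slope_k: float | None = None
    intercept_b: float = 0.0
    wavelength_nm: float = 254.0
    volume_V: float = 0.250
    volume_V1: float = 0.150
    fabric_mass_G1: float = 1.0
    loading_capacity_LA: float | None = None
    # fitting
    fit_scale: str = "untransformed"
    max_restarts: int = 3
    seed: int = 0

    def __post_init__(self):
        self.models = tuple(self.models)
        for name in self.models:
            get_model(name)
        for attr in ("kp_cutoff_percent", "adj_r2_tolerance", "burst_threshold",
                     "n_case2_tolerance"):
            if getattr(self, attr) <= 0:
                raise ConfigurationError(f"{attr} must be positive")
        if self.geometry != "cylinder":
            raise ConfigurationError("only cylinder geometry is supported")

    @property
    def fit_options(self) -> FitOptions:
        return FitOptions(
            kp_cutoff_percent=self.kp_cutoff_percent,
            fit_scale=self.fit_scale,
            max_restarts=self.max_restarts,
            seed=self.seed,
        )

    @property
    def calibration(self) -> CalibrationLine | None:
        if self.slope_k is None:
            return None
        return CalibrationLine(self.slope_k, self.intercept_b, self.wavelength_nm)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class DrugRecord:
    """Everything the pipeline derived for one drug."""

    drug_id: str
    fits: dict[str, FitResult]
    comparison: ModelComparison | None
    mechanism: MechanismCall | None
    solubility: SolubilityParameters | None = None
    fit_errors: dict[str, str] = field(default_factory=dict)


@dataclass
class PipelineResult:
    """Batch output: per-drug records, flat results table, per-input failures."""

    records: list[DrugRecord]
    results: pd.DataFrame
    failures: dict[str, str]


# ---------------------------------------------------------------------------
# equation rendering


def _fmt(v: float) -> str:
    # 4 fixed decimals for ordinary magnitudes, 5 significant digits for
    # small rate constants (e.g. 0.00363), matching the published style
    if v == 0 or abs(v) >= 1e-3:
        return f"{v:.4f}"
    return f"{v:.5g}"


def _signed(v: float) -> str:
    return f"+{_fmt(v)}" if v >= 0 else f"-{_fmt(-v)}"


def format_equation(model_name: str, params) -> str:
    """Render a fitted equation in the tabular report style."""
    spec = get_model(model_name)
    p = np.asarray(params, dtype=float)
    if p.shape != (spec.n_params,):
        from .errors import ParameterArityError

        raise ParameterArityError(f"{model_name} expects {spec.n_params} parameters")
    if model_name == "zero_order":
        return f"Qt={_fmt(p[0])}·t{_signed(p[1])}"
    if model_name == "higuchi":
        return f"Qt={_fmt(p[0])}·t^1/2{_signed(p[1])}"
    if model_name == "korsmeyer_peppas":
        return f"Qt={_fmt(p[0])}·t^{_fmt(p[1])}"
    # first_order, plateau-first like the published tables
    return f"Qt={_fmt(p[2])}{_signed(p[0])}·e^({_fmt(p[1])}·t)"


_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"
_PATTERNS = (
    ("first_order", re.compile(
        rf"^Qt=({_NUM})([+-]{_NUM})·e\^\(({_NUM})·t\)$")),
    ("higuchi", re.compile(rf"^Qt=({_NUM})·t\^1/2([+-]{_NUM})$")),
    ("korsmeyer_peppas", re.compile(rf"^Qt=({_NUM})·t\^({_NUM})$")),
    ("zero_order", re.compile(rf"^Qt=({_NUM})·t([+-]{_NUM})$")),
)


def parse_equation(text: str) -> tuple[str, np.ndarray]:
    """Inverse of :func:`format_equation` (to rendered precision)."""
    for name, pattern in _PATTERNS:
        m = pattern.match(text.strip())
        if not m:
            continue
        g = [float(x) for x in m.groups()]
        if name == "first_order":
            params = np.array([g[1], g[2], g[0]])  # (K1, a, b1)
        else:
            params = np.array(g)
        return name, params
    raise ValueError(f"unparseable equation string: {text!r}")


# ---------------------------------------------------------------------------
# per-drug analysis


def analyze_curve(curve: ReleaseCurve, config: AnalysisConfig | None = None) -> DrugRecord:
    """Fit, select, classify (and look up solubility) for one curve."""
    config = config or AnalysisConfig()
    fits: dict[str, FitResult] = {}
    fit_errors: dict[str, str] = {}
    for name in config.models:
        try:
            fits[name] = fit_all_models(curve, [name], config.fit_options)[name]
        except Exception as exc:  # per-model failure is data, not fatal
            fit_errors[name] = str(exc)
    comparison = None
    if len(fits) >= 2:
        try:
            comparison = rank_models(list(fits.values()), config.adj_r2_tolerance)
        except SelectionError as exc:
            fit_errors["selection"] = str(exc)
    mechanism = None
    kp = fits.get("korsmeyer_peppas")
    if kp is not None:
        K, n = kp.params
        mechanism = call_mechanism(
            n, K,
            config.geometry,
            case2_tolerance=config.n_case2_tolerance,
            burst_threshold=config.burst_threshold,
        )
    sol = None
    if curve.drug_id in _default_molecules():
        sol = solubility_parameters(curve.drug_id)
    if comparison is not None:
        log.info(
            "%s: selected %s via %s; n_used=%s",
            curve.drug_id, comparison.selected, "→".join(comparison.rationale),
            {m: f.n_used for m, f in fits.items()},
        )
    return DrugRecord(curve.drug_id, fits, comparison, mechanism, sol, fit_errors)


def _record_rows(rec: DrugRecord):
    for name, f in rec.fits.items():
        p = list(np.asarray(f.params, float)) + [np.nan] * (3 - len(f.params))
        yield {
            "drug": rec.drug_id,
            "model": name,
            "equation": format_equation(name, f.params),
            "p1": p[0],
            "p2": p[1],
            "p3": p[2],
            "adj_r_square": f.adj_r_square,
            "rss": f.rss,
            "reduced_chi_sq": f.reduced_chi_sq,
            "pearson_r": f.pearson_r,
            "n_used": f.n_used,
            "dof": f.dof,
            "converged": f.converged,
            "selected": rec.comparison is not None
            and rec.comparison.selected == name,
            "transport_class": rec.mechanism.transport_class if rec.mechanism else "",
            "burst_flag": rec.mechanism.burst_flag if rec.mechanism else "",
            "delta_t": rec.solubility.delta_t if rec.solubility else np.nan,
        }


def render_report(rec: DrugRecord) -> str:
    """Markdown block for one drug, mirroring the published table layout."""
    lines = [f"## {rec.drug_id}", ""]
    lines.append("| model | equation | Adj. R-Square | RSS | Reduced Chi-Sqr | Pearson's r |")
    lines.append("|---|---|---|---|---|---|")
    for name, f in rec.fits.items():
        lines.append(
            f"| {name} | {format_equation(name, f.params)} "
            f"| {f.adj_r_square:.5f} | {f.rss:.5f} | {f.reduced_chi_sq:.5f} "
            f"| {f.pearson_r:.5f} |"
        )
    if rec.comparison is not None:
        lines.append("")
        lines.append(
            f"Selected model: **{rec.comparison.selected}** "
            f"(criteria: {' → '.join(rec.comparison.rationale)})"
        )
    if rec.mechanism is not None:
        m = rec.mechanism
        lines.append(
            f"Transport: **{m.transport_class}** (n = {m.n:.4f}, thresholds "
            f"{m.thresholds_used[0]:g}/{m.thresholds_used[1]:g}); burst: "
            f"{'yes' if m.burst_flag else 'no'} "
            f"(K = {m.K:.4f}, threshold {m.thresholds_used[2]:g})"
        )
    if rec.solubility is not None:
        s = rec.solubility
        lines.append(
            f"Solubility parameters (MJ/m³)^1/2: δd = {s.delta_d:.3f}, "
            f"δp = {s.delta_p:.3f}, δh = {s.delta_h:.3f}, δt = {s.delta_t:.3f} "
            f"(V = {s.molar_volume:.1f} cm³/mol)"
        )
    for name, err in rec.fit_errors.items():
        lines.append(f"Fit failure ({name}): {err}")
    lines.append("")
    return "\n".join(lines)


def _collect_inputs(inputs):
    if isinstance(inputs, (str, Path)):
        path = Path(inputs)
        if path.is_dir():
            files = sorted(path.glob("*.csv"))
            if not files:
                raise DomainError(f"no .csv curve files found in {path}")
            return files
        return [path]
    items = list(inputs)
    if not items:
        raise DomainError("no input curves supplied")
    return items


def run_pipeline(config: AnalysisConfig | None, inputs, output_dir=None) -> PipelineResult:
    """Analyse a batch of curve files (or ReleaseCurve objects).

    ``inputs`` may be a directory of ``.csv`` curve files, a list of paths, or
    a list of in-memory :class:`ReleaseCurve` objects.  Unreadable or invalid
    inputs are recorded in ``failures`` without aborting the batch.
    """
    config = config or AnalysisConfig()
    records: list[DrugRecord] = []
    failures: dict[str, str] = {}
    for item in _collect_inputs(inputs):
        if isinstance(item, ReleaseCurve):
            name, curve = item.drug_id, item
        else:
            name = Path(item).name
            try:
                curve = read_curve_csv(
                    item,
                    cal=config.calibration,
                    volume_V1=config.volume_V1,
                    fabric_mass_G1=config.fabric_mass_G1,
                    LA=config.loading_capacity_LA,
                )
            except Exception as exc:
                failures[name] = f"input error: {exc}"
                log.warning("skipping %s: %s", name, exc)
                continue
        try:
            records.append(analyze_curve(curve, config))
        except Exception as exc:
            failures[name] = f"analysis error: {exc}"
            log.warning("analysis failed for %s: %s", name, exc)

    rows = [row for rec in records for row in _record_rows(rec)]
    results = pd.DataFrame(rows)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False, float_format="%.12g")
        report = "\n".join(render_report(rec) for rec in records)
        (out / "report.md").write_text(report)
        if failures:
            (out / "failures.txt").write_text(
                "".join(f"{k}\t{v}\n" for k, v in failures.items())
            )
    return PipelineResult(records, results, failures)
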